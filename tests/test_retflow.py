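"""Retinal flow frames and their curl/divergence features."""

import numpy as np
import pytest

from gazeflow import retflow, synth, vfield
from gazeflow.eyemodel import FrameProjection, orient_to_fixation
from gazeflow.retflow import (
    RetinalFlowError,
    RetinalGridSpec,
    ZeroVelocityError,
    analyze_scenario,
    backproject_scalar,
    chart,
    flow_frame,
    foveal_curl,
    foveal_isocontour,
    heading_angles,
    max_divergence,
    point_flow,
    signed_ground_angle,
    unchart,
)


class TestChart:
    def test_fovea_maps_to_origin(self):
        x, y = chart(1.234, 0.0)
        assert (x, y) == (0.0, 0.0)

    def test_upper_meridian(self):
        x, y = chart(np.pi / 2, 10.0)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert y == pytest.approx(10.0)

    def test_round_trip(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 100)
        rho = rng.uniform(0.01, 60.0, 100)
        th2, rh2 = unchart(*chart(theta, rho))
        assert np.allclose(rh2, rho, atol=1e-12)
        assert np.allclose(np.angle(np.exp(1j * (th2 - theta))), 0.0, atol=1e-12)


class TestPointFlow:
    def test_stationary_eye_zero_flow(self):
        proj = FrameProjection(
            ids=np.arange(5),
            theta=np.linspace(-1, 1, 5),
            rho=np.linspace(1, 20, 5),
        )
        ids, _, disp, vel = point_flow(proj, proj, fps=30.0)
        assert np.allclose(disp, 0.0) and np.allclose(vel, 0.0)
        assert np.array_equal(ids, np.arange(5))

    def test_new_points_excluded(self):
        prev = FrameProjection(ids=np.array([1, 2]), theta=np.zeros(2), rho=np.ones(2))
        curr = FrameProjection(ids=np.array([2, 3]), theta=np.zeros(2), rho=np.ones(2))
        ids, *_ = point_flow(prev, curr, fps=30.0)
        assert np.array_equal(ids, [2])

    def test_bad_fps_rejected(self):
        proj = FrameProjection(ids=np.array([0]), theta=np.zeros(1), rho=np.ones(1))
        with pytest.raises(RetinalFlowError):
            point_flow(proj, proj, fps=0.0)

    def test_approach_flow_is_outward(self, aligned_features):
        """During a straight approach all in-view points stream away from
        the fovea (positive radial velocity component)."""
        _, frames = aligned_features
        fr = frames[-1]
        pos = fr.point_pos
        vel = fr.point_vel
        r = np.linalg.norm(pos, axis=1)
        sel = r > 1.0  # radial direction ill-defined at the fovea
        radial = np.sum(pos[sel] * vel[sel], axis=1) / r[sel]
        assert (radial > 0).mean() > 0.99


class TestFlowFrame:
    def test_divergence_consistent_with_grid_flow(self, aligned_features):
        _, frames = aligned_features
        fr = frames[0]
        recomputed = vfield.divergence(fr.grid_flow)
        m = fr.div_field.mask
        assert np.allclose(fr.div_field.value[m], recomputed.value[m], atol=1e-12)

    def test_positive_divergence_near_fovea_on_approach(self, aligned_features):
        _, frames = aligned_features
        fr = frames[-1]
        xx, yy = fr.div_field.meshgrid()
        near = (np.hypot(xx, yy) <= 5.0) & fr.div_field.mask
        assert np.all(fr.div_field.value[near] > 0)

    def test_degenerate_scatter_rejected(self):
        ids = np.arange(2)
        pos = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(vfield.DegenerateScatterError):
            flow_frame(ids, pos, pos, RetinalGridSpec(10, 1.0), fps=30.0)


class TestFovealCurl:
    @pytest.mark.parametrize("offset, sign", [(0.0, 0), (6.0, 1), (-6.0, -1)])
    def test_sign_follows_fixation_side(self, offset, sign, coarse_spec):
        sc = synth.straight_approach(duration=0.2, fps=30, fixation_offset_angle=offset)
        df, _ = analyze_scenario(sc, spec=coarse_spec, ground_spacing=0.4)
        vals = df.foveal_curl.iloc[1:]
        if sign == 0:
            assert np.all(np.abs(vals) < 0.02)
        else:
            assert np.all(np.sign(vals) == sign)

    def test_empty_window_rejected(self, aligned_features):
        _, frames = aligned_features
        with pytest.raises(retflow.EmptyFovealWindowError):
            foveal_curl(frames[0], window_deg=-1.0)


class TestMaxDivergence:
    def test_ground_point_on_velocity_line(self, aligned_features):
        """The eye's ground-projected velocity line (here the y axis)
        passes through the max-divergence ground point."""
        df, _ = aligned_features
        gx = df.maxdiv_gx.iloc[1:].to_numpy()
        assert np.all(np.abs(gx) < 0.25)  # within one ground-grid spacing

    def test_peak_crosses_to_upper_field_past_45(self, coarse_spec):
        sc = synth.straight_approach(duration=3.2, fps=10)
        df, _ = analyze_scenario(sc, spec=coarse_spec, ground_spacing=0.4)
        early = df[(df.declination_deg > 15) & (df.declination_deg < 40)]
        late = df[df.declination_deg > 50]
        # chart y < 0 is the lower visual field
        assert np.all(np.sin(early.maxdiv_theta) < 0)
        assert np.all(np.sin(late.maxdiv_theta.iloc[1:]) > 0)


class TestIsoContour:
    def test_contour_closes_then_constricts_at_eye_height(self, coarse_spec):
        """Approaching the fixated point, the foveal iso-contour closes and
        its area shrinks to a minimum at one eye height from the fixation
        point (45 degree declination).  Full-resolution degeneration to a
        point is exercised in the acceptance suite; at this coarse grid the
        constriction shows as the area minimum."""
        sc = synth.straight_approach(duration=3.2, fps=10)
        df, _ = analyze_scenario(sc, spec=coarse_spec, ground_spacing=0.4)
        mid = df[(df.declination_deg > 33) & (df.declination_deg < 43)]
        assert (mid.isocontour_state == "closed").all()
        closed = df[df.isocontour_state == "closed"]
        tightest = closed.loc[closed.isocontour_area.idxmin()]
        assert tightest.declination_deg == pytest.approx(45.0, abs=3.5)
        assert tightest.isocontour_area < 0.05 * closed.isocontour_area.max()

    def test_unique_maximum_at_fovea_is_degenerate(self):
        # synthetic frame whose divergence peaks exactly at the fovea
        spec = RetinalGridSpec(fov_deg=10.0, spacing_deg=1.0)
        ax = spec.axes()
        xx, yy = np.meshgrid(ax, ax)
        # v = -r^2 (x, y)-ish gives divergence with a foveal maximum
        vx = xx - 0.01 * xx * (xx**2 + yy**2)
        vy = yy - 0.01 * yy * (xx**2 + yy**2)
        grid = vfield.VectorField2D(ax, ax, vx, vy)
        frame = retflow.RetinalFlowFrame(
            t=0.0, fps=30.0, point_ids=np.arange(1), point_pos=np.zeros((1, 2)),
            point_vel=np.zeros((1, 2)), grid_flow=grid,
            curl_field=vfield.curl_z(grid), div_field=vfield.divergence(grid),
            spec=spec,
        )
        iso = foveal_isocontour(frame)
        assert iso.state == "degenerate"


class TestHeadingAngles:
    def test_velocity_at_fixation_gives_zero(self):
        pose = orient_to_fixation([0.0, 0.0, 1.25], [0.0, 4.0, 0.0])
        vel_fix, _ = heading_angles(pose, np.array([0.0, 1.0, 0.0]), [np.nan, np.nan])
        assert vel_fix == pytest.approx(0.0, abs=1e-12)

    def test_mirrored_offsets_give_opposite_angles(self):
        for a in (3.0, 11.0):
            left = synth.straight_approach(duration=0.1, fps=30, fixation_offset_angle=a)
            right = synth.straight_approach(duration=0.1, fps=30, fixation_offset_angle=-a)
            pl = orient_to_fixation(left.centers[0], left.fixations[0])
            pr = orient_to_fixation(right.centers[0], right.fixations[0])
            v = np.array([0.0, 1.0, 0.0])
            al, _ = heading_angles(pl, v, [np.nan, np.nan])
            ar, _ = heading_angles(pr, v, [np.nan, np.nan])
            assert al == pytest.approx(a, abs=1e-9)
            assert ar == pytest.approx(-a, abs=1e-9)

    def test_zero_velocity_rejected(self):
        with pytest.raises(ZeroVelocityError):
            signed_ground_angle([0.0, 0.0], [0.0, 0.0], [1.0, 1.0])


class TestBackprojection:
    def test_fovea_maps_to_fixation_and_round_trip(self, aligned_features, aligned_approach):
        _, frames = aligned_features
        fr = frames[3]
        i = 4  # frames list starts at scenario frame 1
        pose = orient_to_fixation(
            aligned_approach.centers[i], aligned_approach.fixations[i]
        )
        df, dropped = backproject_scalar(fr.div_field, pose)
        # the retinal node at the fovea lands on the fixation point
        at_fovea = df[(df.x == 0.0) & (df.y == 0.0)]
        assert len(at_fovea) == 1
        assert at_fovea.gx.iloc[0] == pytest.approx(pose.fixation[0], abs=1e-9)
        assert at_fovea.gy.iloc[0] == pytest.approx(pose.fixation[1], abs=1e-9)
        # re-projection returns the original chart locations
        from gazeflow.eyemodel import project_points

        pts = np.column_stack([df.gx, df.gy, np.zeros(len(df))])
        ok, th, rh = project_points(pose, pts, fov_deg=90.0)
        x2, y2 = chart(th[ok], rh[ok])
        assert np.allclose(x2, df.x.to_numpy()[ok], atol=1e-6)
        assert np.allclose(y2, df.y.to_numpy()[ok], atol=1e-6)

    def test_two_routes_to_maxdiv_ground_agree(self, aligned_features, aligned_approach):
        df, frames = aligned_features
        fr = frames[3]
        i = 4
        pose = orient_to_fixation(
            aligned_approach.centers[i], aligned_approach.fixations[i]
        )
        md = max_divergence(fr, pose)
        ground_map, _ = backproject_scalar(fr.div_field, pose)
        best = ground_map.loc[ground_map.value.idxmax()]
        assert np.hypot(best.gx - md.ground_xy[0], best.gy - md.ground_xy[1]) < 0.4


class TestPerfectFixationNull:
    def test_foveal_flow_vanishes(self, aligned_features):
        df, _ = aligned_features
        assert np.all(df.foveal_speed < 1e-6)


class TestSlipAdditivity:
    def test_velocity_shift_bounded_by_foveal_slip(self, coarse_spec):
        sc = synth.straight_approach(duration=0.8, fps=30)
        pert = synth.Perturbation(
            kind="slip", onset=0.3, duration=0.25,
            direction=(-0.37, -0.93), magnitude_deg=1.0,
        )
        scp = synth.apply_perturbation(sc, pert)
        _, fr0 = analyze_scenario(sc, spec=coarse_spec, ground_spacing=0.4, keep_frames=True)
        _, fr1 = analyze_scenario(scp, spec=coarse_spec, ground_spacing=0.4, keep_frames=True)
        slip_speed = pert.magnitude_deg / pert.duration  # 4 deg/s
        for a, b in zip(fr0, fr1):
            if not (pert.onset + 1e-9 < a.t <= pert.onset + pert.duration + 1e-9):
                continue
            m = a.grid_flow.mask & b.grid_flow.mask
            dv = np.hypot(
                b.grid_flow.vel_x[m] - a.grid_flow.vel_x[m],
                b.grid_flow.vel_y[m] - a.grid_flow.vel_y[m],
            )
            assert dv.max() <= slip_speed * 1.05
            # at the fovea the shift is the slip speed itself
            dfov = np.hypot(*(b.flow_at_fovea() - a.flow_at_fovea()))
            assert dfov == pytest.approx(slip_speed, rel=0.15)
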