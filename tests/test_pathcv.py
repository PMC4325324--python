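"""Reference-path construction and path-CV evaluation tests."""

import numpy as np
import pytest

from pathmetad.geometry import Configuration, NO_ALIGNMENT, msd_after_alignment
from pathmetad.pathcv import (ReferencePath, build_morph_path, eval_path_cv,
                              eval_path_cv_series, eval_path_cv_with_grad,
                              resample_equal_msd, select_lambda)


def sz_oracle(config, path):
    """Direct-summation reference implementation of s and z."""
    d2 = np.array([msd_after_alignment(config, f, path.align_idx,
                                       path.measure_idx)
                   for f in path.frames])
    w = np.exp(-path.lam * d2)
    l = np.arange(1, len(d2) + 1)
    return float((l * w).sum() / w.sum()), float(-np.log(w.sum()) / path.lam)


def straight_line_path(P=7, step=0.1, lam=None):
    """Single-particle collinear path with the raw-coordinate metric."""
    frames = [Configuration([[i * step, 0.0, 0.0]]) for i in range(P)]
    spacing = np.full(P - 1, step ** 2)
    lam = 1.0 / step ** 2 if lam is None else lam
    return ReferencePath(frames, lam, NO_ALIGNMENT, None, spacing)


@pytest.fixture(scope="module")
def toy_path():
    from pathmetad.sampler import make_two_domain_model
    m = make_two_domain_model(seed=5)
    sel = np.union1d(m.closed_endpoint.selections["CORE"],
                     m.closed_endpoint.selections["LID"])
    raw = build_morph_path(m.closed_endpoint, m.open_endpoint, 40,
                           align_idx=sel)
    return resample_equal_msd(raw, 9, 0.02, align_idx=sel, measure_idx=sel)


class TestMorph:
    def test_identical_endpoints_give_identical_frames(self):
        cfg = Configuration(np.random.default_rng(0).normal(size=(4, 3)))
        frames = build_morph_path(cfg, cfg, 5)
        for f in frames:
            assert np.allclose(f.coords, cfg.coords, atol=1e-12)

    def test_interior_frames_are_linear_interpolants(self, hinge_pair):
        a, b = hinge_pair
        frames = build_morph_path(a, b, 7)
        from pathmetad.geometry import optimal_align, apply_superposition
        b_al = apply_superposition(b.coords, optimal_align(b, a))
        for i, t in enumerate(np.linspace(0, 1, 7)):
            assert np.allclose(frames[i].coords,
                               (1 - t) * a.coords + t * b_al, atol=1e-12)
        assert np.allclose(frames[0].coords, a.coords, atol=1e-15)

    def test_mismatched_particle_sets_rejected(self):
        a = Configuration(np.zeros((4, 3)) + np.eye(4, 3))
        b = Configuration(np.zeros((5, 3)) + np.eye(5, 3))
        with pytest.raises(ValueError):
            build_morph_path(a, b, 3)


class TestResample:
    def test_uniform_collinear_path_spacing(self):
        # single particle moved 0 -> 0.9 nm, resampled to P=10:
        # every successive MSD must be exactly (0.1)^2 = 0.01 nm^2
        raw = [Configuration([[x, 0.0, 0.0]])
               for x in np.linspace(0.0, 0.9, 4)]
        path = resample_equal_msd(raw, 10, 1e-6, align_idx=NO_ALIGNMENT)
        assert np.allclose(path.spacing, 0.01, atol=1e-9)
        assert path.lam == pytest.approx(100.0, rel=1e-6)
        # endpoints preserved exactly
        assert np.allclose(path.frames[0].coords, raw[0].coords, atol=1e-15)
        assert np.allclose(path.frames[-1].coords, raw[-1].coords, atol=1e-15)

    def test_curved_path_meets_tolerance(self, toy_path):
        cv = toy_path.spacing.std() / toy_path.spacing.mean()
        assert cv <= 0.02
        # post-hoc check through the metric itself
        msds = [msd_after_alignment(toy_path.frames[i], toy_path.frames[i + 1],
                                    toy_path.align_idx, toy_path.measure_idx)
                for i in range(toy_path.n_frames - 1)]
        msds = np.array(msds)
        assert msds.std() / msds.mean() <= 0.02

    def test_degenerate_path_rejected(self):
        cfg = Configuration(np.random.default_rng(1).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            resample_equal_msd([cfg, cfg], 5)


class TestLambda:
    def test_reciprocal_mean_spacing(self):
        path = straight_line_path(step=0.1)
        assert select_lambda(path) == pytest.approx(100.0)
        # the equal-spacing postcondition: lambda * mean spacing = 1 exactly
        assert select_lambda(path) * path.spacing.mean() == pytest.approx(
            1.0, abs=1e-14)

    @pytest.mark.parametrize("target", [225.0, 146.0])
    def test_known_metric_constants(self, target):
        """Paths whose mean successive MSD is 1/lambda reproduce the
        production metric constants 225 and 146 nm^-2."""
        step = np.sqrt(1.0 / target)
        path = straight_line_path(P=5, step=step)
        assert select_lambda(path) == pytest.approx(target, rel=1e-9)


class TestEvalPathCV:
    def test_equidistant_config_gives_midpoint_s(self):
        path = straight_line_path(P=2, step=0.2)
        mid = Configuration(path.frames[0].coords + [0.1, 0.0, 0.0])
        assert eval_path_cv(mid, path).s == pytest.approx(1.5, abs=1e-12)

    def test_s_equals_index_on_interior_nodes(self):
        # sharp-lambda regime: softmax localized, asymmetric tails negligible
        path = straight_line_path(P=7, step=0.1, lam=10.0 / 0.01)
        for l in range(2, 7):
            v = eval_path_cv(path.frames[l - 1], path)
            assert v.s == pytest.approx(l, abs=1e-12)

    def test_center_node_exact_under_selected_lambda(self):
        path = straight_line_path(P=7, step=0.1)  # lam * spacing = 1
        v = eval_path_cv(path.frames[3], path)
        assert v.s == pytest.approx(4.0, abs=1e-12)

    def test_z_tends_to_min_distance_at_large_lambda(self):
        path = straight_line_path(P=5, step=0.1)
        off = Configuration(path.frames[2].coords + [0.0, 0.03, 0.0])
        d2min = min(msd_after_alignment(off, f, NO_ALIGNMENT)
                    for f in path.frames)
        for lam in (1e4, 1e5, 1e6):
            p = ReferencePath(path.frames, lam, NO_ALIGNMENT, None,
                              path.spacing)
            assert abs(eval_path_cv(off, p).z - d2min) < 10.0 / lam

    def test_z_monotone_in_lambda_toward_min_distance(self, toy_path, rng):
        """The softmin z rises monotonically toward min_l d_l^2 as lambda
        grows (it sits below the nearest-frame distance for any finite
        lambda), checked on 100 random configurations."""
        base = toy_path.frames[3].coords
        lams = [toy_path.lam * f for f in (0.5, 1.0, 2.0, 4.0)]
        for _ in range(100):
            coords = base + rng.normal(0, 0.03, base.shape) * [1, 1, 0]
            cfg = toy_path.frames[0].with_coords(coords)
            zs = []
            for lam in lams:
                p = ReferencePath(toy_path.frames, lam, toy_path.align_idx,
                                  toy_path.measure_idx, toy_path.spacing)
                zs.append(eval_path_cv(cfg, p).z)
            assert all(z2 >= z1 - 1e-12 for z1, z2 in zip(zs, zs[1:]))
            d2min = min(msd_after_alignment(cfg, f, toy_path.align_idx,
                                            toy_path.measure_idx)
                        for f in toy_path.frames)
            assert all(z <= d2min + 1e-12 for z in zs)

    def test_matches_direct_summation_oracle(self, toy_path, rng):
        for _ in range(25):
            coords = toy_path.frames[4].coords + rng.normal(
                0, 0.05, toy_path.frames[0].coords.shape)
            cfg = toy_path.frames[0].with_coords(coords)
            v = eval_path_cv(cfg, toy_path)
            s_ref, z_ref = sz_oracle(cfg, toy_path)
            assert v.s == pytest.approx(s_ref, abs=1e-12)
            assert v.z == pytest.approx(z_ref, abs=1e-12)

    def test_reversal_maps_s_and_preserves_z(self, toy_path, rng):
        P = toy_path.n_frames
        rev = toy_path.reversed()
        for _ in range(20):
            coords = toy_path.frames[2].coords + rng.normal(
                0, 0.04, toy_path.frames[0].coords.shape)
            cfg = toy_path.frames[0].with_coords(coords)
            v_f = eval_path_cv(cfg, toy_path)
            v_r = eval_path_cv(cfg, rev)
            assert v_r.s == pytest.approx(P + 1 - v_f.s, abs=1e-12)
            assert v_r.z == pytest.approx(v_f.z, abs=1e-12)

    def test_s_within_bounds_and_z_above_softmin_bound(self, toy_path, rng):
        P, lam = toy_path.n_frames, toy_path.lam
        for _ in range(50):
            coords = rng.normal(0, 1.0, toy_path.frames[0].coords.shape)
            v = eval_path_cv(toy_path.frames[0].with_coords(coords), toy_path)
            assert 1.0 <= v.s <= P
            assert v.z > -np.log(P) / lam
            assert np.isfinite(v.s) and np.isfinite(v.z)

    def test_gradients_match_finite_differences(self, toy_path, rng):
        coords = toy_path.frames[4].coords + rng.normal(
            0, 0.02, toy_path.frames[0].coords.shape) * [1, 1, 0]
        s, z, gs, gz = eval_path_cv_with_grad(coords, toy_path)
        h = 1e-6
        for j in (0, 5, 6):
            for k in (0, 1):
                p = coords.copy()
                p[j, k] += h
                sp, zp, _, _ = eval_path_cv_with_grad(p, toy_path)
                p[j, k] -= 2 * h
                sm, zm, _, _ = eval_path_cv_with_grad(p, toy_path)
                assert gs[j, k] == pytest.approx((sp - sm) / (2 * h), abs=2e-5)
                assert gz[j, k] == pytest.approx((zp - zm) / (2 * h), abs=2e-5)


class TestSeries:
    def test_single_frame_equals_pointwise(self, toy_path):
        cfg = toy_path.frames[2]
        trace = eval_path_cv_series([cfg], toy_path)
        v = eval_path_cv(cfg, toy_path)
        assert trace.values[0, 0] == pytest.approx(v.s, abs=1e-14)
        assert trace.values[0, 1] == pytest.approx(v.z, abs=1e-14)

    def test_path_frames_give_increasing_s(self, toy_path):
        trace = eval_path_cv_series(toy_path.frames, toy_path)
        assert np.all(np.diff(trace.column("s")) > 0)

    def test_matches_per_frame_loop(self, toy_path, rng):
        traj = np.stack([toy_path.frames[1].coords
                         + rng.normal(0, 0.02, toy_path.frames[0].coords.shape)
                         for _ in range(30)])
        trace = eval_path_cv_series(traj, toy_path,
                                    times=np.arange(30) * 0.5)
        for i in range(30):
            v = eval_path_cv(toy_path.frames[0].with_coords(traj[i]), toy_path)
            assert trace.values[i, 0] == pytest.approx(v.s, abs=1e-14)
        assert np.allclose(trace.times, np.arange(30) * 0.5)
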