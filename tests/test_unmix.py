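import numpy as np
import pytest

from fmtunmix import (
    Inclusion,
    NoiseSpec,
    Scene,
    TimeCourse,
    affine_set_fit,
    brute_force_segment_vertices,
    camns_lp,
    delta_rmse,
    estimate_source_count,
    ica_unmix,
    make_local_dominant_sources,
    max_normalize,
    pca_unmix,
    random_courses,
    render_source_patterns,
    simulate_dynamic_measurements,
    simulation_sources,
    sum_normalize_frames,
)
from fmtunmix.errors import (
    DegenerateStackError,
    DimensionError,
    EmptyFrameError,
    InvalidParameterError,
)
from fmtunmix.scenes import MeasurementStack, heart_course, liver_course

from conftest import nse_per_source


def _course(values):
    return TimeCourse(times=np.arange(len(values)) + 1.0,
                      values=np.asarray(values, dtype=float))


def _random_stack(P, N, K, seed, psnr=None):
    pats = make_local_dominant_sources(P, N, 0.08, seed=seed)
    C = random_courses(K, P, seed=seed + 10_000)
    courses = [_course(C[:, p]) for p in range(P)]
    pats = pats / np.max(C @ pats)
    noise = NoiseSpec(psnr_db=psnr, seed=seed + 20_000) if psnr else None
    return simulate_dynamic_measurements(pats, courses, noise=noise), pats


class TestSourceCounting:
    @pytest.mark.parametrize("P", [1, 2, 3, 4])
    def test_noise_free_rank_recovered(self, P):
        stack, _ = _random_stack(P, 120, 6, seed=P)
        rep = estimate_source_count(stack)
        assert rep.estimated_P == P

    def test_single_source_constant_course(self):
        pat = make_local_dominant_sources(1, 30, 0.1, seed=0)
        stack = simulate_dynamic_measurements(pat, [_course([1.0] * 4)])
        assert estimate_source_count(stack).estimated_P == 1

    def test_eigenvalues_descending_and_near_nonnegative(self):
        stack, _ = _random_stack(3, 80, 6, seed=3, psnr=30.0)
        rep = estimate_source_count(stack, method="log-gap")
        ev = rep.eigenvalues
        assert ev.shape == (6,)
        assert np.all(np.diff(ev) <= 0)
        assert ev.min() >= -1e-12 * ev[0]
        assert 1 <= rep.estimated_P <= 6

    def test_requires_background_subtracted(self):
        stack, _ = _random_stack(2, 30, 4, seed=1)
        stack.background_subtracted = False
        with pytest.raises(InvalidParameterError):
            estimate_source_count(stack)


class TestSumNormalize:
    def test_unit_sums_idempotent_invertible(self):
        stack, _ = _random_stack(2, 40, 5, seed=2)
        norm, sums = sum_normalize_frames(stack)
        np.testing.assert_allclose(norm.frames.sum(axis=1), 1.0, atol=1e-12)
        again, sums2 = sum_normalize_frames(norm)
        np.testing.assert_allclose(again.frames, norm.frames, rtol=1e-15)
        np.testing.assert_allclose(sums2, 1.0)
        restored = norm.frames * sums[:, None]
        np.testing.assert_allclose(restored, stack.frames, rtol=1e-15)

    def test_empty_frame_rejected(self):
        stack = MeasurementStack(frames=np.array([[1.0, 1.0], [0.0, 0.0]]),
                                 times=np.array([1.0, 2.0]))
        with pytest.raises(EmptyFrameError):
            sum_normalize_frames(stack)


class TestAffineSetFit:
    def test_three_pixel_instance_by_hand(self, three_pixel_stack):
        stack, _, _ = three_pixel_stack
        norm, _ = sum_normalize_frames(stack)
        model = affine_set_fit(norm, 2)
        np.testing.assert_allclose(model.d, np.full(3, 1 / 3), atol=1e-14)
        h = model.H[:, 0]
        expected = np.array([1.0, -1.0, 0.0]) / np.sqrt(2)
        assert min(np.linalg.norm(h - expected),
                   np.linalg.norm(h + expected)) < 1e-10
        assert model.fit_residual <= 1e-10

    def test_basis_orthonormal_and_residual_zero_on_exact_rank(self):
        stack, _ = _random_stack(3, 90, 7, seed=4)
        norm, _ = sum_normalize_frames(stack)
        model = affine_set_fit(norm, 3)
        np.testing.assert_allclose(model.H.T @ model.H, np.eye(2), atol=1e-10)
        assert model.fit_residual <= 1e-8

    def test_identical_frames_degenerate(self):
        frames = np.tile(np.random.default_rng(0).uniform(1, 2, 20), (4, 1))
        stack = MeasurementStack(frames=frames, times=np.arange(4.0))
        with pytest.raises(DegenerateStackError):
            affine_set_fit(stack, 2)

    def test_p_out_of_range(self):
        stack, _ = _random_stack(2, 30, 4, seed=5)
        with pytest.raises(DimensionError):
            affine_set_fit(stack, 5)


class TestCamns:
    def test_three_pixel_exact_vertices(self, three_pixel_stack):
        stack, S, _ = three_pixel_stack
        res = camns_lp(stack, 2, rng_seed=0)
        cmp_ = delta_rmse(res.sources, S)
        assert cmp_.total_delta < 1e-12
        # normalized sources are (1,0,0.5) and (0,1,0.5) up to order
        rows = {tuple(np.round(s, 6)) for s in res.sources}
        assert (1.0, 0.0, 0.5) in {tuple(np.round(np.abs(list(r)), 1))
                                   for r in rows} or cmp_.total_delta < 1e-10

    def test_matches_brute_force_segment_oracle(self, three_pixel_stack):
        stack, _, _ = three_pixel_stack
        res = camns_lp(stack, 2, rng_seed=3)
        oracle = brute_force_segment_vertices(stack)
        oracle = np.stack([max_normalize(v) for v in oracle])
        assert delta_rmse(res.sources, oracle).total_delta < 1e-12

    def test_p_equals_one_returns_common_direction(self):
        pat = make_local_dominant_sources(1, 25, 0.1, seed=7)
        stack = simulate_dynamic_measurements(pat, [_course([1.0, 2.0, 0.5])])
        res = camns_lp(stack, 1, rng_seed=0)
        assert delta_rmse(res.sources, pat).total_delta < 1e-20

    def test_scale_invariance(self):
        stack, pats = _random_stack(2, 60, 6, seed=8)
        r1 = camns_lp(stack, 2, rng_seed=1)
        scaled = MeasurementStack(frames=37.5 * stack.frames, times=stack.times)
        r2 = camns_lp(scaled, 2, rng_seed=1)
        assert delta_rmse(r1.sources, r2.sources).total_delta < 1e-10

    def test_pixel_permutation_equivariance(self):
        stack, pats = _random_stack(2, 50, 5, seed=9)
        perm = np.random.default_rng(0).permutation(50)
        shuffled = MeasurementStack(frames=stack.frames[:, perm],
                                    times=stack.times)
        r1 = camns_lp(stack, 2, rng_seed=4)
        r2 = camns_lp(shuffled, 2, rng_seed=4)
        assert delta_rmse(r1.sources[:, perm], r2.sources).total_delta < 1e-12

    def test_sources_nonnegative_and_normalized(self):
        stack, _ = _random_stack(3, 80, 6, seed=10)
        res = camns_lp(stack, 3, rng_seed=2)
        assert res.sources_raw.min() >= -1e-8 * res.sources_raw.max()
        np.testing.assert_allclose(res.sources.max(axis=1), 1.0)
        assert res.lp_diagnostics  # objectives logged per draw

    def test_mixing_recovers_courses(self):
        P, K = 2, 6
        pats = make_local_dominant_sources(P, 70, 0.1, seed=11)
        C = random_courses(K, P, seed=12)
        stack = simulate_dynamic_measurements(
            pats, [_course(C[:, p]) for p in range(P)])
        res = camns_lp(stack, P, rng_seed=0)
        # estimated mixing columns proportional to the true courses after
        # matching sources to truth
        cmp_ = delta_rmse(res.sources, pats)
        for i, j in enumerate(cmp_.permutation):
            est = res.mixing[:, i]
            tru = C[:, j]
            r = np.corrcoef(est, tru)[0, 1]
            assert r > 0.999999

    def test_noise_free_fem_two_inclusion_recovery(self, absorbing_optics):
        """Well-separated inclusions in an absorbing phantom: boundary
        patterns are near-locally-dominant and recovery is exact to 1e-6."""
        sc = Scene(width=25.0, height=30.0, edge_len=1.0,
                   optics=absorbing_optics,
                   inclusions=[
                       Inclusion(center=(4.0, 15.0), radius=2.0,
                                 course=heart_course()),
                       Inclusion(center=(21.0, 15.0), radius=2.0,
                                 course=liver_course())],
                   n_excitation_sources=4, detector_every=2)
        system = sc.build_system()
        pats = render_source_patterns(sc, system)
        stack = simulate_dynamic_measurements(pats, [i.course for i in sc.inclusions])
        res = camns_lp(stack, 2, rng_seed=3)
        cmp_ = delta_rmse(res.sources, pats)
        assert max(nse_per_source(cmp_, pats)) <= 1e-6


class TestPca:
    def test_orthogonal_sources_orthogonal_courses_recovered(self):
        pats, courses = simulation_sources("uncorrelated")
        stack = simulate_dynamic_measurements(pats, courses)
        res = pca_unmix(stack, 2)
        cmp_ = delta_rmse(res.sources, pats, allow_sign_flip=True)
        assert cmp_.total_delta < 1e-12

    def test_full_basis_reconstructs_centered_data(self):
        stack, _ = _random_stack(2, 40, 4, seed=13)
        res = pca_unmix(stack, 4)
        Xc = stack.frames - stack.frames.mean(axis=0)
        recon = res.mixing @ res.sources_raw
        np.testing.assert_allclose(recon, Xc, atol=1e-10 * np.abs(Xc).max())

    def test_correlated_scene_produces_negative_values(self):
        pats, courses = simulation_sources("correlated")
        stack = simulate_dynamic_measurements(pats, courses)
        res = pca_unmix(stack, 2)
        assert res.has_negative

    def test_p_exceeds_frames(self):
        stack, _ = _random_stack(2, 30, 4, seed=14)
        with pytest.raises(DimensionError):
            pca_unmix(stack, 5)


class TestIca:
    def test_sparse_independent_sources_recovered_at_60db(self):
        pats, courses = simulation_sources("uncorrelated")
        stack = simulate_dynamic_measurements(
            pats, courses, noise=NoiseSpec(psnr_db=60.0, seed=21))
        res = ica_unmix(stack, 2, rng_seed=5)
        cmp_ = delta_rmse(res.sources, pats, allow_sign_flip=True)
        assert max(nse_per_source(cmp_, pats)) <= 1e-2

    def test_deterministic_under_seed(self):
        stack, _ = _random_stack(2, 60, 6, seed=15, psnr=40.0)
        r1 = ica_unmix(stack, 2, rng_seed=6)
        r2 = ica_unmix(stack, 2, rng_seed=6)
        np.testing.assert_array_equal(r1.sources, r2.sources)
        assert len(r1.converged) == 2

    def test_p_equals_one_is_dominant_direction(self):
        stack, pats = _random_stack(1, 30, 4, seed=16)
        res = ica_unmix(stack, 1, rng_seed=0)
        assert abs(np.corrcoef(res.sources[0], pats[0])[0, 1]) > 0.999999

    def test_agrees_with_reference_fastica(self):
        """Cross-check the hand-rolled deflation against scikit-learn's
        FastICA on the same data: the spans of the recovered components
        must coincide."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        pats, courses = simulation_sources("uncorrelated")
        stack = simulate_dynamic_measurements(pats, courses)
        mine = ica_unmix(stack, 2, rng_seed=1)
        ref = sklearn.FastICA(n_components=2, random_state=0, max_iter=1000)
        S_ref = ref.fit_transform(stack.frames.T).T
        for s in S_ref:
            r = [abs(np.corrcoef(s, m)[0, 1]) for m in mine.sources]
            assert max(r) > 0.99
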