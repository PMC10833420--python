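"""Similarity score, phase-difference trigonometry, FoM, PRTF, half-bit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xdiscreen import (
    RANDOM_PHASE_LIMIT,
    DensityMap,
    effective_resolution,
    fom_map,
    forward_structure_factor,
    half_bit_curve,
    make_resolution_shells,
    pair_phase_difference,
    prtf_curve,
    random_phase_limit,
    score_matrix,
    shell_score_constant_phase,
    shell_trig_terms,
    similarity_score_real,
    similarity_score_reciprocal,
)


def _sf_from_phases(phases, amplitude=1.0):
    return amplitude * np.exp(1j * phases)


class TestSimilarityScoreReal:
    def test_identical_maps_score_zero(self, three_disk_map):
        assert similarity_score_real(three_disk_map, three_disk_map) == 0.0

    def test_zero_partner_scores_one(self, three_disk_map):
        z = DensityMap(values=np.zeros(three_disk_map.values.shape), pixel_size=1.0)
        assert similarity_score_real(three_disk_map, z) == pytest.approx(1.0)

    def test_matches_naive_double_loop(self, random_map_pair):
        a, b = random_map_pair
        num = den = 0.0
        for i in range(a.n):
            for j in range(a.n):
                num += (a.values[i, j] - b.values[i, j]) ** 2
                den += (a.values[i, j] + b.values[i, j]) ** 2
        assert similarity_score_real(a, b) == pytest.approx(np.sqrt(num / den),
                                                            abs=1e-12)

    def test_zero_denominator_rejected(self):
        a = DensityMap(values=np.ones((16, 16)), pixel_size=1.0)
        b = DensityMap(values=-np.ones((16, 16)), pixel_size=1.0)
        with pytest.raises(ValueError):
            similarity_score_real(a, b)

    def test_l1_variant_matches_direct_sum(self, random_map_pair):
        a, b = random_map_pair
        expected = np.abs(a.values - b.values).sum() / np.abs(a.values + b.values).sum()
        assert similarity_score_real(a, b, norm="l1") == pytest.approx(expected)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_symmetric_and_scale_invariant(self, seed, scale):
        rng = np.random.default_rng(seed)
        a = DensityMap(values=rng.random((16, 16)), pixel_size=1.0)
        b = DensityMap(values=rng.random((16, 16)), pixel_size=1.0)
        s_ab = similarity_score_real(a, b)
        s_ba = similarity_score_real(b, a)
        assert s_ab == pytest.approx(s_ba, abs=1e-14)
        a2 = DensityMap(values=scale * a.values, pixel_size=1.0)
        b2 = DensityMap(values=scale * b.values, pixel_size=1.0)
        assert similarity_score_real(a2, b2) == pytest.approx(s_ab, rel=1e-10)


class TestSimilarityScoreReciprocal:
    def test_identical_structure_factors_score_zero(self, rng):
        f = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        assert similarity_score_reciprocal(f, f) == 0.0

    def test_parseval_bridge_to_real_space(self, random_map_pair):
        a, b = random_map_pair
        fa = forward_structure_factor(a)
        fb = forward_structure_factor(b)
        s_real = similarity_score_real(a, b)
        s_recip = similarity_score_reciprocal(fa, fb)
        assert s_recip == pytest.approx(s_real, rel=1e-10)

    def test_constant_quarter_pi_phase_difference_scores_one(self):
        # shared amplitudes, dalpha = pi/2 everywhere -> |tan(pi/4)| = 1
        rng = np.random.default_rng(0)
        amp = rng.random((32, 32)) + 0.1
        fi = _sf_from_phases(np.zeros((32, 32)), amp)
        fj = _sf_from_phases(np.full((32, 32), np.pi / 2), amp)
        assert similarity_score_reciprocal(fi, fj) == pytest.approx(1.0, abs=1e-12)

    def test_amplitude_weighted_trig_identity(self, rng):
        # with common |F_obs| the score equals
        # sqrt(sum w sin^2(d/2) / sum w cos^2(d/2)), w = |F_obs|^2
        amp = rng.random((32, 32)) + 0.1
        pi_, pj_ = rng.uniform(-np.pi, np.pi, (2, 32, 32))
        fi, fj = _sf_from_phases(pi_, amp), _sf_from_phases(pj_, amp)
        half = 0.5 * (pi_ - pj_)
        w = amp**2
        expected = np.sqrt((w * np.sin(half) ** 2).sum()
                           / (w * np.cos(half) ** 2).sum())
        assert similarity_score_reciprocal(fi, fj) == pytest.approx(expected,
                                                                    abs=1e-12)

    def test_masked_pixels_excluded(self, rng):
        fi = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        fj = fi.copy()
        fj[0, 0] += 1000.0  # discrepancy hidden behind the mask
        valid = np.ones((16, 16), dtype=bool)
        valid[0, 0] = False
        assert similarity_score_reciprocal(fi, fj, valid) == 0.0


class TestPairPhaseField:
    def test_identical_pair_zero_everywhere(self, rng):
        f = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        field = pair_phase_difference(f, f)
        np.testing.assert_array_equal(field.delta_alpha, 0.0)
        np.testing.assert_array_equal(field.loi, 0.0)

    def test_negated_pair_gives_pi_and_double_amplitude(self, rng):
        amp = rng.random((16, 16)) + 0.5
        f = _sf_from_phases(rng.uniform(-np.pi / 2, np.pi / 2, (16, 16)), amp)
        field = pair_phase_difference(f, -f, amplitude=amp)
        np.testing.assert_allclose(np.abs(field.delta_alpha), np.pi, atol=1e-12)
        np.testing.assert_allclose(field.loi, 2 * amp, rtol=1e-12)

    def test_loi_equals_direct_complex_difference(self, rng):
        fi = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        fj = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        field = pair_phase_difference(fi, fj)
        np.testing.assert_allclose(field.loi, np.abs(fi - fj), atol=1e-12)

    def test_loi_identity_with_shared_amplitudes(self, rng):
        amp = rng.random((32, 32)) + 0.1
        pi_, pj_ = rng.uniform(-np.pi, np.pi, (2, 32, 32))
        fi, fj = _sf_from_phases(pi_, amp), _sf_from_phases(pj_, amp)
        field = pair_phase_difference(fi, fj, amplitude=amp)
        np.testing.assert_allclose(
            field.loi, 2 * amp * np.abs(np.sin(0.5 * field.delta_alpha)), atol=1e-9)
        np.testing.assert_allclose(np.abs(field.a_field), amp, rtol=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_delta_alpha_wrapped_to_half_open_interval(self, seed):
        rng = np.random.default_rng(seed)
        fi = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        fj = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        d = pair_phase_difference(fi, fj).delta_alpha
        assert np.all(d > -np.pi) and np.all(d <= np.pi)


class TestShellTrig:
    def test_identical_maps_cos_one_sin_zero(self, three_disk_map):
        shells = make_resolution_shells(64, 1.0, 8)
        trig = shell_trig_terms([three_disk_map, three_disk_map], shells)
        occupied = trig.counts > 0
        np.testing.assert_allclose(trig.mean_cos[occupied], 1.0, atol=1e-12)
        np.testing.assert_allclose(trig.mean_sin[occupied], 0.0, atol=1e-12)

    def test_uniform_random_phases_approach_random_phase_limit(self):
        rng = np.random.default_rng(11)
        n = 256
        shells = make_resolution_shells(n, 1.0, 4)
        fi = _sf_from_phases(rng.uniform(-np.pi, np.pi, (n, n)))
        fj = _sf_from_phases(rng.uniform(-np.pi, np.pi, (n, n)))
        trig = shell_trig_terms([fi, fj], shells)
        big = trig.counts >= 1e4
        assert big.any()
        np.testing.assert_allclose(trig.mean_cos[big], 0.64, atol=0.02)
        np.testing.assert_allclose(trig.mean_sin[big], 0.64, atol=0.02)

    def test_constant_pi_shell_has_sin_one_cos_zero(self):
        n = 64
        shells = make_resolution_shells(n, 1.0, 4)
        phases_j = np.zeros((n, n))
        phases_i = np.where(shells.label == 2, np.pi, 0.0)
        trig = shell_trig_terms([_sf_from_phases(phases_i),
                                 _sf_from_phases(phases_j)], shells)
        assert trig.mean_sin[2] == pytest.approx(1.0, abs=1e-12)
        assert trig.mean_cos[2] == pytest.approx(0.0, abs=1e-12)
        assert trig.mean_cos[1] == pytest.approx(1.0, abs=1e-12)

    def test_empty_shell_flagged_nan_not_zero(self, rng):
        # a masked-out shell must be reported absent
        n = 64
        shells = make_resolution_shells(n, 1.0, 8)
        valid = shells.label != 3
        f = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        g = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        trig = shell_trig_terms([f, g], shells, valid=valid)
        assert np.isnan(trig.mean_cos[3])
        assert trig.counts[3] == 0

    def test_pair_accounting_all_vs_best(self, rng):
        n = 32
        shells = make_resolution_shells(n, 1.0, 4)
        sfs = [rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
               for _ in range(4)]
        trig_all = shell_trig_terms(sfs, shells, pairs="all")
        trig_best = shell_trig_terms(sfs, shells, pairs="best")
        occupancy = shells.pixel_counts()
        np.testing.assert_array_equal(trig_all.counts, occupancy * 6)  # C(4,2)
        np.testing.assert_array_equal(trig_best.counts, occupancy)


class TestConstantPhaseScore:
    def test_zero_at_zero(self):
        assert shell_score_constant_phase(0.0) == 0.0

    def test_one_at_half_pi(self):
        assert shell_score_constant_phase(np.pi / 2) == pytest.approx(1.0)

    def test_diverges_toward_pi(self):
        assert shell_score_constant_phase(np.pi) == np.inf
        assert shell_score_constant_phase(np.pi - 1e-6) > 1e6

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            shell_score_constant_phase(-0.1)


class TestRandomPhaseLimit:
    def test_closed_form_is_two_over_pi(self):
        assert RANDOM_PHASE_LIMIT == pytest.approx(2 / np.pi)

    def test_monte_carlo_converges_and_rounds_to_printed_value(self):
        est = random_phase_limit(n_samples=1_000_000, seed=0)
        assert est == pytest.approx(2 / np.pi, abs=0.002)
        assert round(est, 2) == 0.64

    def test_same_seed_reproduces_estimate(self):
        assert random_phase_limit(10_000, seed=7) == random_phase_limit(10_000, seed=7)


class TestFoM:
    def test_identical_phases_give_unity(self, rng):
        f = _sf_from_phases(rng.uniform(-np.pi, np.pi, (16, 16)))
        fom = fom_map([f, f, f], n_bins=None)
        np.testing.assert_allclose(fom.values, 1.0, atol=1e-12)

    def test_two_maps_sixty_degrees_about_mean_give_half(self):
        # phases at +60 and -60 degrees: resultant length cos(60) = 0.5,
        # the interpretability threshold
        fi = _sf_from_phases(np.full((8, 8), np.pi / 3))
        fj = _sf_from_phases(np.full((8, 8), -np.pi / 3))
        fom = fom_map([fi, fj], n_bins=None)
        np.testing.assert_allclose(fom.values, 0.5, atol=1e-12)

    def test_uniform_phases_give_small_fom(self, rng):
        # resultant of M uniform phasors: P(R > r) = exp(-M r^2), so the
        # 95th percentile for M = 100 sits at sqrt(ln 20 / 100) ~ 0.173
        m = 100
        sfs = [_sf_from_phases(rng.uniform(-np.pi, np.pi, (32, 32)))
               for _ in range(m)]
        fom = fom_map(sfs, n_bins=36)
        r95 = np.sqrt(np.log(20) / m)
        assert np.mean(fom.values < r95) == pytest.approx(0.95, abs=0.02)
        assert fom.values.mean() == pytest.approx(np.sqrt(np.pi / 4 / m), abs=0.01)

    def test_binned_matches_unbinned_at_bin_centers(self):
        # phases exactly on 10-degree bin centers: binning is lossless
        width = 2 * np.pi / 36
        centers = -np.pi + (np.arange(36) + 0.5) * width
        rng = np.random.default_rng(3)
        phases = rng.choice(centers, size=(5, 16, 16))
        sfs = [_sf_from_phases(p) for p in phases]
        np.testing.assert_allclose(fom_map(sfs, n_bins=36).values,
                                   fom_map(sfs, n_bins=None).values, atol=1e-9)

    def test_single_map_rejected(self, rng):
        with pytest.raises(ValueError):
            fom_map([_sf_from_phases(rng.random((8, 8)))])


class TestPRTF:
    def test_identical_phases_give_unit_curve(self, rng):
        shells = make_resolution_shells(64, 1.0, 8)
        f = _sf_from_phases(rng.uniform(-np.pi, np.pi, (64, 64)))
        curve = prtf_curve([f, f, f, f], shells)
        occupied = ~np.isnan(curve.values)
        np.testing.assert_allclose(curve.values[occupied], 1.0, atol=1e-12)

    def test_two_map_prtf_equals_mean_cos(self, rng):
        shells = make_resolution_shells(64, 1.0, 8)
        fi = _sf_from_phases(rng.uniform(-np.pi, np.pi, (64, 64)))
        fj = _sf_from_phases(rng.uniform(-np.pi, np.pi, (64, 64)))
        curve = prtf_curve([fi, fj], shells)
        trig = shell_trig_terms([fi, fj], shells)
        occupied = trig.counts > 0
        np.testing.assert_allclose(curve.values[occupied],
                                   trig.mean_cos[occupied], atol=1e-12)

    def test_curve_decreases_with_ensemble_size_for_random_phases(self):
        rng = np.random.default_rng(5)
        n = 64
        shells = make_resolution_shells(n, 1.0, 6)
        sfs = [_sf_from_phases(rng.uniform(-np.pi, np.pi, (n, n)))
               for _ in range(50)]
        v2 = prtf_curve(sfs[:2], shells).values
        v10 = prtf_curve(sfs[:10], shells).values
        v50 = prtf_curve(sfs, shells).values
        occupied = ~np.isnan(v2)
        assert np.all(v2[occupied] > v10[occupied])
        assert np.all(v10[occupied] > v50[occupied])


class TestHalfBit:
    def test_large_shell_limit(self):
        shells = make_resolution_shells(64, 1.0, 4)
        t = half_bit_curve(shells, pixel_counts=np.array([10**8, 10**8, 10**8, 10**8]))
        np.testing.assert_allclose(t, 0.2071 / 1.2071, atol=1e-3)

    def test_single_sample_value(self):
        shells = make_resolution_shells(64, 1.0, 1)
        t = half_bit_curve(shells, pixel_counts=np.array([2]))  # n_k = 1
        assert t[0] == pytest.approx((0.2071 + 1.9102) / (1.2071 + 0.9102), abs=1e-6)

    def test_strictly_decreasing_in_shell_size(self):
        shells = make_resolution_shells(64, 1.0, 6)
        counts = np.array([2, 8, 32, 128, 512, 2048])
        t = half_bit_curve(shells, pixel_counts=counts)
        assert np.all(np.diff(t) < 0)

    def test_empty_shell_absent(self):
        shells = make_resolution_shells(64, 1.0, 3)
        t = half_bit_curve(shells, pixel_counts=np.array([0, 10, 10]))
        assert np.isnan(t[0])


class TestEffectiveResolution:
    def test_flat_unit_curve_never_crosses(self):
        centers = np.linspace(0.5, 9.5, 10)
        q, res_nm, crossed = effective_resolution(np.ones(10), centers)
        assert not crossed
        assert q == pytest.approx(9.5)

    def test_constructed_crossing_found_within_one_shell(self):
        hits = 0
        n, n_shells = 512, 16
        for seed in range(20):
            rng = np.random.default_rng(seed)
            k_star = 4 + seed % 8
            shells = make_resolution_shells(n, 1.0, n_shells)
            phases_i = np.zeros((n, n))
            phases_j = np.zeros((n, n))
            high = shells.label >= k_star
            phases_i[high] = rng.uniform(-np.pi, np.pi, int(high.sum()))
            phases_j[high] = rng.uniform(-np.pi, np.pi, int(high.sum()))
            trig = shell_trig_terms([_sf_from_phases(phases_i),
                                     _sf_from_phases(phases_j)], shells)
            q, _, crossed = effective_resolution(trig.mean_cos, trig.shell_centers)
            k_hit = int(np.argmin(np.abs(trig.shell_centers - q)))
            if crossed and abs(k_hit - k_star) <= 1:
                hits += 1
        assert hits >= 18

    def test_fixed_threshold_mode_with_one_over_e(self):
        centers = np.linspace(0.5, 9.5, 10)
        curve = np.linspace(1.0, 0.0, 10)
        q, _, crossed = effective_resolution(curve, centers,
                                             mode="fixed_threshold",
                                             threshold=1 / np.e)
        assert crossed
        expected_idx = np.argmax(curve <= 1 / np.e)
        assert q == pytest.approx(centers[expected_idx])

    def test_half_bit_mode_uses_shell_dependent_criterion(self):
        shells = make_resolution_shells(64, 1.0, 8)
        curve = np.full(8, 0.3)
        q, _, crossed = effective_resolution(curve, shells.centers,
                                             mode="half_bit", shells=shells)
        crit = half_bit_curve(shells)
        expected_idx = np.flatnonzero(curve <= crit)[0]
        assert crossed
        assert q == pytest.approx(shells.centers[expected_idx])

    def test_too_short_curve_rejected(self):
        with pytest.raises(ValueError):
            effective_resolution(np.array([1.0]), np.array([1.0]))


class TestScoreMatrix:
    def test_duplicate_stack_all_zero(self, three_disk_map):
        mat = score_matrix([three_disk_map] * 4)
        np.testing.assert_array_equal(mat, 0.0)

    def test_matches_brute_force_and_symmetric(self, rng):
        maps = [DensityMap(values=rng.random((16, 16)), pixel_size=1.0)
                for _ in range(5)]
        mat = score_matrix(maps)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert mat[i, j] == pytest.approx(
                        similarity_score_real(maps[i], maps[j]), abs=1e-12)
        np.testing.assert_allclose(mat, mat.T, atol=1e-15)
        np.testing.assert_array_equal(np.diag(mat), 0.0)


class TestLowResolutionDominance:
    def test_score_driven_by_low_resolution_phases(self):
        # on power-law amplitude spectra, randomising phases only above a
        # cutoff moves the score far less than randomising below it
        rng = np.random.default_rng(21)
        n = 128
        shells = make_resolution_shells(n, 1.0, 16)
        s = np.hypot(*np.meshgrid(*[np.arange(n) - n // 2] * 2, indexing="ij"))
        amp = 1.0 / (1.0 + s) ** 2
        base_phase = rng.uniform(-np.pi, np.pi, (n, n))
        f0 = amp * np.exp(1j * base_phase)
        k0 = 4
        lo, hi = shells.label < k0, shells.label >= k0
        for region_big, region_small in ((lo, hi),):
            p_hi = base_phase.copy()
            p_hi[hi] = rng.uniform(-np.pi, np.pi, int(hi.sum()))
            p_lo = base_phase.copy()
            p_lo[lo] = rng.uniform(-np.pi, np.pi, int(lo.sum()))
            s_hi = similarity_score_reciprocal(f0, amp * np.exp(1j * p_hi))
            s_lo = similarity_score_reciprocal(f0, amp * np.exp(1j * p_lo))
            assert s_hi < 0.10 * s_lo
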