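"""Punctum calling, extents, and enrichment against brute-force oracles."""

import numpy as np
import pytest

from punctakit.profiles import IntensityProfile, mask_regions
from punctakit.quant import (
    FullyMaskedError,
    QuantParams,
    call_puncta,
    detect_candidates,
    punctum_extent,
    quantify_animal,
    synaptic_enrichment,
)
from punctakit.quant import _extent_indices, _extents_for_set
from punctakit.synthetic import make_profile

from .conftest import bump_profile, profile_from
from .oracles import (
    direct_se,
    maximal_self_consistent_subset,
    naive_candidates,
    naive_extent,
)


def noisy_profile(seed, n=120, spacing=0.5, quantize=True):
    """Random seeded profile with plateaus (via quantization) and a mask."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(1, 30, size=n)
    if quantize:
        y = np.round(y)
    mask = np.zeros(n, dtype=bool)
    if rng.random() < 0.5:
        a = int(rng.integers(0, n - 10))
        mask[a : a + int(rng.integers(2, 8))] = True
    return profile_from(y, spacing=spacing, mask=mask)


def oracle_profile(seed):
    """Noiseless multi-bump profile with ratios straddling the threshold."""
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(3, 6)
    k = int(rng.integers(2, 9))
    centers = 4.0 + np.arange(k) * rng.uniform(3.5, 4.5) + rng.uniform(-0.5, 0.5, k)
    heights = rng.uniform(0.3, 3.5, k) * baseline
    sigmas = rng.uniform(0.4, 0.9, k)
    length = centers[-1] + 4.0
    return bump_profile(length, 0.25, baseline, centers, heights, sigmas)


class TestDetectCandidates:
    def test_monotone_profile_has_no_candidates(self):
        assert detect_candidates(profile_from(np.arange(20.0)), QuantParams()) == []

    def test_single_gaussian_bump_center(self):
        prof = bump_profile(20, 0.5, 2.0, [10.0], [8.0], [1.0])
        cands = detect_candidates(prof, QuantParams())
        assert len(cands) == 1
        assert cands[0].position_um == pytest.approx(10.0, abs=0.25)

    def test_fully_masked_profile_raises(self):
        prof = profile_from(np.ones(10), mask=np.ones(10, dtype=bool))
        with pytest.raises(FullyMaskedError):
            detect_candidates(prof, QuantParams())

    @pytest.mark.parametrize("min_sep,min_prom", [(1.0, 0.0), (2.0, 0.0), (1.5, 3.0)])
    def test_matches_exhaustive_oracle(self, min_sep, min_prom):
        params = QuantParams(min_separation_um=min_sep, min_prominence=min_prom)
        for seed in range(40):
            prof = noisy_profile(seed)
            got = [c.index for c in detect_candidates(prof, params)]
            expected = naive_candidates(
                prof.intensities, prof.exclude_mask, prof.positions_um, min_sep, min_prom
            )
            assert got == expected, f"seed {seed}"

    def test_plateau_reports_center_sample(self):
        y = np.array([0.0, 1, 5, 5, 5, 1, 0, 2, 2, 0, 0])
        cands = detect_candidates(profile_from(y), QuantParams())
        assert [c.index for c in cands] == [3, 7]


class TestPunctumExtent:
    def test_gaussian_fwhm(self):
        sigma = 1.2
        prof = bump_profile(30, 0.1, 4.0, [15.0], [10.0], [sigma])
        start, end = punctum_extent(prof, 150, avg_ipf=4.0)
        width = (end - start) + 0.1  # half-open width in µm
        assert width == pytest.approx(2.355 * sigma, abs=0.1)

    def test_degenerate_peak_gets_single_sample(self):
        y = np.full(21, 5.0)
        y[10] = 5.0  # peak exactly at baseline height
        prof = profile_from(y)
        i0, i1 = _extent_indices(prof.intensities, prof.exclude_mask, 10, 5.0)
        assert (i0, i1) == (10, 11)

    def test_matches_linear_walk_oracle(self):
        for seed in range(30):
            prof = noisy_profile(seed, quantize=False)
            y, mask = prof.intensities, prof.exclude_mask
            rng = np.random.default_rng(1000 + seed)
            for _ in range(5):
                peak = int(rng.integers(1, len(y) - 1))
                if mask[peak]:
                    continue
                avg = float(rng.uniform(0, 20))
                assert _extent_indices(y, mask, peak, avg) == naive_extent(y, mask, peak, avg)


class TestCallPuncta:
    def test_flat_profile_calls_nothing(self):
        puncta, avg_ipf, flags = call_puncta(profile_from(np.full(50, 9.0)))
        assert puncta == [] and avg_ipf == pytest.approx(9.0)

    def test_triangular_peak_over_threshold_called(self):
        # peak 10 on baseline 4 → ratio 2.5 ≥ 2 → one punctum
        y = np.full(41, 4.0)
        y[18:23] = [6, 8, 10, 8, 6]
        puncta, avg_ipf, _ = call_puncta(profile_from(y))
        assert len(puncta) == 1
        assert puncta[0].peak_intensity == 10.0
        assert puncta[0].ratio == pytest.approx(10.0 / avg_ipf)

    def test_threshold_is_inclusive_at_exactly_two(self):
        # impulse of height 8 on baseline 4: ratio exactly 2.0 → retained
        y = np.full(41, 4.0)
        y[20] = 8.0
        puncta, avg_ipf, _ = call_puncta(profile_from(y))
        assert avg_ipf == 4.0
        assert len(puncta) == 1 and puncta[0].ratio == 2.0

    def test_just_below_threshold_rejected(self):
        y = np.full(41, 4.0)
        y[20] = 7.99
        puncta, _, _ = call_puncta(profile_from(y))
        assert puncta == []

    def test_matches_subset_enumeration_oracle(self):
        params = QuantParams()
        for seed in range(60):
            prof = oracle_profile(seed)
            cands = detect_candidates(prof, params)
            assert len(cands) <= 12
            puncta, avg_ipf, flags = call_puncta(prof, params)
            assert not flags
            combo, oracle_ipf = maximal_self_consistent_subset(
                prof.intensities,
                prof.exclude_mask,
                [c.index for c in cands],
                params.ratio_threshold,
            )
            got = tuple(
                i for i, c in enumerate(cands)
                if any(p.peak_position_um == c.position_um for p in puncta)
            )
            assert got == combo, f"seed {seed}"
            if combo:
                assert avg_ipf == pytest.approx(oracle_ipf, rel=1e-9)

    def test_converges_within_candidate_count_iterations(self):
        for seed in range(30):
            prof = oracle_profile(seed)
            k = len(detect_candidates(prof, QuantParams()))
            params = QuantParams(max_iterations=k + 1)
            _, _, flags = call_puncta(prof, params)
            assert "not_converged" not in flags

    def test_wide_bump_never_exhausts_ipf(self):
        # half-max extents can never swallow the profile minimum (it always
        # sits below the half level), so even a bump spanning nearly the
        # whole profile converges with a finite inter-punctal baseline
        prof = bump_profile(6, 0.5, 0.05, [3.0], [10.0], [4.0])
        _, avg_ipf, flags = call_puncta(prof)
        assert "zero_ipf" not in flags and np.isfinite(avg_ipf)


class TestSynapticEnrichment:
    def test_se_is_ratio_of_sums(self):
        # punctal samples sum 300 AU, inter-punctal samples sum 100 AU → SE = 3
        y = np.concatenate([np.full(25, 2.0), [100.0, 100.0, 100.0], np.full(25, 2.0)])
        prof = profile_from(y, spacing=1.0)
        params = QuantParams(window_length_um=200.0)
        puncta, avg_ipf, flags = call_puncta(prof, params)
        q = synaptic_enrichment(prof, puncta, params, flags)
        assert q.total_pf == pytest.approx(300.0)
        assert q.total_ipf == pytest.approx(100.0)
        assert q.se == pytest.approx(3.0)
        assert "window_truncated" in q.flags

    def test_window_of_only_punctal_samples_flags_zero_ipf(self):
        # shrink the window onto the punctum itself: no inter-punctal sample
        # remains and SE is undefined
        y = np.full(41, 4.0)
        y[20] = 20.0
        prof = profile_from(y, spacing=1.0)
        params = QuantParams(window_length_um=0.5)
        puncta, _, flags = call_puncta(prof, params)
        q = synaptic_enrichment(prof, puncta, params, flags)
        assert q.pn == 1 and "zero_ipf" in q.flags and np.isnan(q.se)

    def test_flat_profile_reports_zero_se_with_flag(self):
        q = quantify_animal(profile_from(np.full(120, 5.0)))
        assert q.pn == 0 and q.se == 0.0 and "no_puncta" in q.flags

    def test_matches_direct_summation_oracle(self, wild_type):
        params = QuantParams()
        for seed in range(30):
            prof, _ = make_profile(wild_type, 110.0, 0.1, 7000 + seed)
            puncta, _, flags = call_puncta(prof, params)
            q = synaptic_enrichment(prof, puncta, params, flags)
            pf, ipf = direct_se(
                prof.intensities,
                prof.exclude_mask,
                [p.extent_idx for p in puncta],
                q.window_um[0],
                q.window_um[1],
                prof.positions_um,
            )
            assert q.se == pytest.approx(pf / ipf, rel=1e-9)

    def test_window_is_centered_100um(self, wild_type):
        prof, _ = make_profile(wild_type, 150.0, 0.1, 1)
        q = quantify_animal(prof)
        assert q.window_um == pytest.approx((25.0, 125.0))
        assert "window_truncated" not in q.flags


class TestQuantifyAnimal:
    def test_two_isolated_peaks_counted(self):
        prof = bump_profile(60, 0.5, 3.0, [20.0, 40.0], [9.0, 12.0], [1.0, 1.0])
        q = quantify_animal(prof, QuantParams(window_length_um=60.0))
        assert q.pn == 2

    def test_gain_invariance_and_offset_sensitivity(self, wild_type):
        # PN and SE are scale-free (ratio statistics); additive offsets are not
        params = QuantParams()
        import dataclasses

        prof, _ = make_profile(wild_type, 110.0, 0.1, 77)
        base = quantify_animal(prof, params)
        for c in (0.1, 10.0):
            scaled = dataclasses.replace(prof, intensities=prof.intensities * c)
            q = quantify_animal(scaled, params)
            assert q.pn == base.pn
            assert q.se == pytest.approx(base.se, rel=1e-9)
        shifted = dataclasses.replace(prof, intensities=prof.intensities + 200.0)
        q = quantify_animal(shifted, params)
        assert q.pn != base.pn or q.se != pytest.approx(base.se, rel=1e-3)

    def test_isolation_additivity(self):
        # concatenating two profiles with a long flat spacer adds their PNs
        a = bump_profile(40, 0.5, 3.0, [20.0], [9.0], [1.0])
        b = bump_profile(40, 0.5, 3.0, [12.0, 28.0], [12.0, 15.0], [1.0, 0.8])
        spacer = np.full(80, 3.0)
        joined = profile_from(
            np.concatenate([a.intensities, spacer, b.intensities]), spacing=0.5
        )
        params = QuantParams(window_length_um=1000.0)
        pa = quantify_animal(a, QuantParams(window_length_um=1000.0)).pn
        pb = quantify_animal(b, QuantParams(window_length_um=1000.0)).pn
        assert quantify_animal(joined, params).pn == pa + pb

    def test_se_monotone_in_amplitude_and_diffuse_level(self, wild_type):
        # averaged over 50 seeds: brighter puncta raise SE, a brighter
        # diffuse background lowers it
        import dataclasses

        def mean_se(preset):
            return float(
                np.mean(
                    [
                        quantify_animal(make_profile(preset, 110.0, 0.1, 400 + s)[0]).se
                        for s in range(50)
                    ]
                )
            )

        base = mean_se(wild_type)
        brighter = mean_se(dataclasses.replace(wild_type, amplitude_mean=180.0))
        hazier = mean_se(dataclasses.replace(wild_type, diffuse_level=45.0))
        assert brighter > base > hazier

    def test_fully_masked_profile_flagged(self):
        prof = profile_from(np.ones(30), mask=np.ones(30, dtype=bool))
        q = quantify_animal(prof)
        assert q.flags == {"all_masked"} and q.pn == 0 and np.isnan(q.se)
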