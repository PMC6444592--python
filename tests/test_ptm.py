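"""Citrullination site-localization: fragments, filtering, scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chromodwell import (
    CITRULLINE_DELTA,
    PeptideSpectrum,
    match_fragments,
    ptm_score,
    site_probabilities,
    synth_spectrum,
    theoretical_fragments,
    top_peaks_per_window,
)

PEPTIDE = "VLDRRVVNGK"            # candidate arginines at positions 4 and 5
LONG_PEPTIDE = "VLDRRVVNGKVEYFLK"


def spectrum_from_mz(mz, peptide=PEPTIDE, n_mods=1, intensity=1e4):
    mz = np.asarray(mz, dtype=float)
    return PeptideSpectrum(peptide=peptide, n_mods=n_mods, mz=mz,
                           intensity=np.full(mz.size, float(intensity)))


def common_ions(peptide=PEPTIDE, sites=(4, 5)):
    """b/y ions shared by all single-site configurations (non-discriminating)."""
    frag_sets = [theoretical_fragments(peptide, [s]) for s in sites]
    common = [m for m in frag_sets[0]
              if all(np.any(np.abs(fs - m) < 1e-9) for fs in frag_sets[1:])]
    return np.asarray(common)


class TestFragments:
    def test_gk_dipeptide_hand_summed_masses(self):
        # b1 = Gly residue + proton; y1 = Lys residue + H2O + proton
        frags = theoretical_fragments("GK")
        np.testing.assert_allclose(sorted(frags), [58.0287, 147.1128],
                                   atol=1e-3)

    def test_citrulline_shift_is_additive(self):
        plain = theoretical_fragments(PEPTIDE)
        modded = theoretical_fragments(PEPTIDE, [4])
        deltas = np.sort(modded) - np.sort(plain)
        assert set(np.round(deltas, 6)) <= {0.0, round(CITRULLINE_DELTA, 6)}
        # fragments containing residue 4: b4..b9 and y7..y9 -> 9 shifted ions
        assert np.sum(deltas > 0.5 * CITRULLINE_DELTA) == 9

    def test_modifying_non_arginine_raises(self):
        with pytest.raises(ValueError, match="not arginine"):
            theoretical_fragments(PEPTIDE, [1])

    def test_unknown_residue_raises(self):
        with pytest.raises(ValueError, match="unknown residue"):
            theoretical_fragments("VLXK")

    def test_mass_range_restriction(self):
        frags = theoretical_fragments(PEPTIDE, mz_range=(200.0, 600.0))
        assert frags.min() >= 200.0 and frags.max() <= 600.0


class TestPeakFiltering:
    def test_few_peaks_all_retained(self, rng):
        mz = np.sort(rng.uniform(100, 199, 8))
        inten = rng.uniform(1, 100, 8)
        fmz, _ = top_peaks_per_window(mz, inten)
        assert fmz.size == 8

    def test_crowded_window_keeps_ten_largest(self, rng):
        mz = np.sort(rng.uniform(100, 199, 15))
        inten = rng.permutation(np.arange(1.0, 16.0))
        fmz, finten = top_peaks_per_window(mz, inten)
        assert finten.size == 10
        assert set(finten) == set(np.sort(inten)[-10:])  # full-sort oracle

    def test_windows_anchored_at_spectrum_minimum(self):
        mz = np.array([150.0, 151.0, 260.0])
        inten = np.array([5.0, 4.0, 3.0])
        fmz, _ = top_peaks_per_window(mz, inten, peaks_per_window=1)
        # windows [150,250) and [250,350): peaks 150 and 260 survive
        np.testing.assert_allclose(fmz, [150.0, 260.0])


class TestMatching:
    def test_empty_peak_list_matches_nothing(self):
        k, n = match_fragments([500.0, 600.0], [])
        assert (k, n) == (0, 2)

    def test_ppm_tolerance_arithmetic(self):
        # 20 ppm of 500 Th = 0.01 Th: a peak at 500.005 matches
        k, _ = match_fragments([500.0], [500.005], tolerance_ppm=20.0)
        assert k == 1
        k, _ = match_fragments([500.0], [500.015], tolerance_ppm=20.0)
        assert k == 0

    def test_each_peak_consumed_once(self):
        # one peak between two fragments: only the nearer fragment matches
        k, n = match_fragments([500.000, 500.004], [500.0041],
                               tolerance_ppm=20.0)
        assert (k, n) == (1, 2)


class TestScore:
    def test_no_matches_closed_form(self):
        p, score = ptm_score(5, 0)
        assert p == pytest.approx(0.96**5)
        assert score == pytest.approx(-10 * math.log10(0.96**5))

    def test_direct_binomial_oracle(self):
        p, score = ptm_score(5, 2)
        expected = math.comb(5, 2) * 0.04**2 * 0.96**3
        assert p == pytest.approx(expected, rel=1e-12)
        assert score == pytest.approx(-10 * math.log10(expected), rel=1e-12)

    def test_truncated_variant_drops_survivor_term(self):
        p_full, _ = ptm_score(5, 2)
        p_trunc, _ = ptm_score(5, 2, truncated=True)
        assert p_trunc == pytest.approx(p_full / 0.96**3, rel=1e-12)

    @given(st.integers(1, 23))
    def test_score_monotone_increasing_in_k(self, n):
        # the binomial pmf decreases in k above its mode; with match
        # probability 0.04 the mode sits at 0 for n < 24 (n*p/q < 1), so the
        # score is strictly increasing over the whole candidate range there
        scores = [ptm_score(n, k)[1] for k in range(n + 1)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_zero_candidates_raise(self):
        with pytest.raises(ValueError):
            ptm_score(0, 0)


class TestSiteProbabilities:
    def test_single_candidate_forced_to_one(self):
        spec = synth_spectrum("VLDKRVVNGK", [5], seed=1)
        res = site_probabilities(spec)
        assert res.site_probabilities == {5: pytest.approx(1.0)}

    def test_non_discriminating_spectrum_splits_fifty_fifty(self):
        spec = spectrum_from_mz(common_ions())
        res = site_probabilities(spec)
        assert res.site_probabilities[4] == pytest.approx(0.5, abs=1e-12)
        assert res.site_probabilities[5] == pytest.approx(0.5, abs=1e-12)

    def test_discriminating_ion_matches_manual_enumeration(self):
        # add b4 of the config modified at R4; recompute by hand from the
        # two binomial probabilities
        from chromodwell.ptm import _AA_MASS, PROTON
        b4 = sum(_AA_MASS[a] for a in "VLDR") + CITRULLINE_DELTA + PROTON
        mz = np.concatenate([common_ions(), [b4]])
        res = site_probabilities(spectrum_from_mz(mz))
        by_sites = {c.sites: c for c in res.configurations}
        kA, nA = by_sites[(4,)].k, by_sites[(4,)].n
        kB, nB = by_sites[(5,)].k, by_sites[(5,)].n
        assert kA == kB + 1  # exactly one discriminating match
        pA = math.comb(nA, kA) * 0.04**kA * 0.96 ** (nA - kA)
        pB = math.comb(nB, kB) * 0.04**kB * 0.96 ** (nB - kB)
        expected = (1 / pA) / (1 / pA + 1 / pB)
        assert res.site_probabilities[4] == pytest.approx(expected, rel=1e-9)
        assert res.site_probabilities[4] > 0.5

    def test_probabilities_conserve_mass(self):
        for seed in range(5):
            spec = synth_spectrum(LONG_PEPTIDE, [4], coverage=0.6,
                                  noise_peaks=30, seed=seed)
            res = site_probabilities(spec)
            assert sum(res.site_probabilities.values()) == pytest.approx(
                1.0, abs=1e-9)

    def test_swapping_discriminating_ions_swaps_probabilities(self):
        from chromodwell.ptm import _AA_MASS, PROTON
        b4_cit4 = sum(_AA_MASS[a] for a in "VLDR") + CITRULLINE_DELTA + PROTON
        b4_cit5 = sum(_AA_MASS[a] for a in "VLDR") + PROTON  # R4 unmodified
        base = common_ions()
        res_a = site_probabilities(
            spectrum_from_mz(np.concatenate([base, [b4_cit4]])))
        res_b = site_probabilities(
            spectrum_from_mz(np.concatenate([base, [b4_cit5]])))
        assert res_a.site_probabilities[4] == pytest.approx(
            res_b.site_probabilities[5], rel=1e-9)
        assert res_a.site_probabilities[5] == pytest.approx(
            res_b.site_probabilities[4], rel=1e-9)


class TestSyntheticSpectra:
    def test_full_coverage_localizes_true_site(self):
        spec = synth_spectrum(PEPTIDE, [4], coverage=1.0, seed=3)
        res = site_probabilities(spec)
        assert res.site_probabilities[4] >= 0.99

    def test_zero_coverage_is_uninformative(self):
        spec = synth_spectrum(PEPTIDE, [4], coverage=0.0, noise_peaks=0,
                              seed=4)
        res = site_probabilities(spec)
        assert res.site_probabilities[4] == pytest.approx(0.5, abs=1e-9)

    def test_coverage_out_of_range_raises(self):
        with pytest.raises(ValueError):
            synth_spectrum(PEPTIDE, [4], coverage=1.5)

    def test_reproducible_under_seed(self):
        a = synth_spectrum(PEPTIDE, [4], coverage=0.5, noise_peaks=10, seed=9)
        b = synth_spectrum(PEPTIDE, [4], coverage=0.5, noise_peaks=10, seed=9)
        np.testing.assert_array_equal(a.mz, b.mz)

    @pytest.mark.parametrize("peptide", [PEPTIDE, LONG_PEPTIDE])
    def test_true_site_wins_on_batch(self, peptide):
        # across 200 spectra with good coverage, the true site attains the
        # maximum probability in >= 95% of cases
        sites = tuple(i + 1 for i, aa in enumerate(peptide) if aa == "R")
        wins = total = 0
        for seed in range(200):
            true = sites[seed % len(sites)]
            spec = synth_spectrum(peptide, [true], coverage=0.8,
                                  noise_peaks=20, seed=seed)
            res = site_probabilities(spec)
            # only meaningful when discriminating ions were emitted
            probs = res.site_probabilities
            if max(probs.values()) - min(probs.values()) < 1e-9:
                continue
            total += 1
            wins += max(probs, key=probs.get) == true
        assert total >= 150
        assert wins / total >= 0.95
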