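"""MID mathematics: correction matrix, NNLS correction, contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisflux.isotope import (
    MID,
    NaturalAbundanceCorrector,
    contrast_conditions,
    correct_mid,
    labeled_fraction,
    mean_enrichment,
    natural_abundance_matrix,
    tca_mid_shift,
)
from conftest import random_mids


def brute_force_matrix(n_carbons: int, p13: float) -> np.ndarray:
    """Oracle: enumerate every heavy-atom placement on the non-tracer carbons.

    For a molecule with k tracer carbons, each of the n-k remaining carbon
    positions independently carries a heavy isotope with probability p13;
    summing the probability of every subset by its size gives the observed
    mass-shift distribution.
    """
    n = n_carbons
    mat = np.zeros((n + 1, n + 1))
    for k in range(n + 1):
        positions = range(n - k)
        for r in range(n - k + 1):
            prob = sum(
                p13 ** len(sub) * (1 - p13) ** (n - k - len(sub))
                for sub in itertools.combinations(positions, r)
            )
            mat[k + r, k] = prob
    return mat


class TestNaturalAbundanceMatrix:
    def test_zero_p13_is_identity(self):
        assert np.allclose(natural_abundance_matrix(3, 0.0), np.eye(4))

    def test_three_carbon_entry_matches_binomial_by_hand(self):
        mat = natural_abundance_matrix(3, 0.011)
        assert mat[0, 0] == pytest.approx((1 - 0.011) ** 3, abs=1e-12)
        assert mat[1, 0] == pytest.approx(3 * 0.011 * 0.989**2, abs=1e-12)

    @pytest.mark.parametrize("n,p", [(1, 0.0107), (3, 0.05), (6, 0.0107)])
    def test_columns_sum_to_one_and_lower_triangular(self, n, p):
        mat = natural_abundance_matrix(n, p)
        assert np.allclose(mat.sum(axis=0), 1.0)
        assert np.allclose(np.triu(mat, k=1), 0.0)

    @pytest.mark.parametrize("n", range(1, 7))
    @pytest.mark.parametrize("p", [0.0, 0.0107, 0.05])
    def test_agrees_with_heavy_atom_enumeration(self, n, p):
        assert np.allclose(natural_abundance_matrix(n, p),
                           brute_force_matrix(n, p), atol=1e-12)

    @pytest.mark.parametrize("bad_p", [-0.1, 1.0, 1.5])
    def test_invalid_p13_rejected(self, bad_p):
        with pytest.raises(ValueError):
            natural_abundance_matrix(3, bad_p)


class TestCorrection:
    def test_forward_convolve_round_trip(self):
        true = np.array([0.5, 0.0, 0.0, 0.5])
        mat = natural_abundance_matrix(3, 0.0107)
        mid = correct_mid(mat @ true, 3, p13=0.0107)
        assert np.allclose(mid.fractions, true, atol=1e-9)

    def test_pure_unlabeled_at_natural_abundance(self):
        mat = natural_abundance_matrix(4, 0.0107)
        mid = correct_mid(mat[:, 0] * 1e5, 4, p13=0.0107)
        expected = np.zeros(5)
        expected[0] = 1.0
        assert np.allclose(mid.fractions, expected, atol=1e-9)

    def test_p13_zero_is_normalization_only(self):
        mid = correct_mid([2, 1, 1, 0], 3, p13=0.0)
        assert np.allclose(mid.fractions, [0.5, 0.25, 0.25, 0.0])

    def test_all_zero_spectrum_errors(self):
        with pytest.raises(ValueError, match="no signal"):
            correct_mid([0, 0, 0, 0], 3)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            correct_mid([1, 2, 3], 3)

    def test_never_negative_even_at_low_signal(self, rng):
        mat = natural_abundance_matrix(6, 0.0107)
        for _ in range(50):
            obs = mat @ rng.dirichlet(np.ones(7)) + rng.normal(0, 0.002, 7)
            mid = correct_mid(np.clip(obs, 0, None) + 1e-12, 6, p13=0.0107)
            assert np.all(mid.fractions >= 0)
            assert mid.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n", range(1, 7))
    @pytest.mark.parametrize("p", [0.0107, 0.05])
    def test_random_mid_recovery_all_carbon_counts(self, n, p, rng):
        corr = NaturalAbundanceCorrector(p13=p).fit(np.zeros((1, n + 1)))
        true = random_mids(rng, n, 50)
        recovered = corr.transform(true @ corr.matrix_.T)
        assert np.max(np.abs(recovered - true)) < 1e-8

    def test_transformer_inverse_transform_is_forward_model(self, rng):
        corr = NaturalAbundanceCorrector().fit(np.zeros((1, 4)))
        true = random_mids(rng, 3, 5)
        assert np.allclose(corr.inverse_transform(true), true @ corr.matrix_.T)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 7))
        true = rng.dirichlet(np.ones(n + 1))
        mat = natural_abundance_matrix(n, 0.0107)
        mid = correct_mid(mat @ true, n, p13=0.0107)
        assert np.allclose(mid.fractions, true, atol=1e-8)


class TestDerivedQuantities:
    @pytest.mark.parametrize("fractions,expected", [
        ([1, 0, 0, 0], 0.0),
        ([0, 0, 0, 1], 100.0),
        ([0.35, 0, 0, 0.65], 65.0),
    ])
    def test_labeled_fraction(self, fractions, expected):
        mid = MID("lactate", 3, np.array(fractions, float))
        assert labeled_fraction(mid) == pytest.approx(expected)

    @pytest.mark.parametrize("fractions,expected", [
        ([1, 0, 0, 0], 0.0),
        ([0, 0, 0, 1], 100.0),
        ([0.5, 0, 0, 0.5], 50.0),
    ])
    def test_mean_enrichment(self, fractions, expected):
        mid = MID("pyruvate", 3, np.array(fractions, float))
        assert mean_enrichment(mid) == pytest.approx(expected)

    def test_enrichment_bounded_by_labeled_content(self, rng):
        for frac in random_mids(rng, 5, 20):
            mid = MID("x", 5, frac)
            assert 0.0 <= mid.mean_enrichment <= 100.0
            assert mid.mean_enrichment <= mid.labeled_fraction + 1e-9


def _mid_table(frac_a, frac_b, metabolite="citrate", n_carbons=None):
    n_carbons = n_carbons or len(frac_a[0]) - 1
    rows = []
    for cond, fracs in (("a", frac_a), ("b", frac_b)):
        for rep, f in enumerate(fracs, start=1):
            rows.append({"metabolite": metabolite, "n_carbons": n_carbons,
                         "condition": cond, "replicate": rep,
                         **{f"m{k}": v for k, v in enumerate(f)}})
    return pd.DataFrame(rows)


class TestContrasts:
    def test_identical_conditions_no_flags(self):
        fr = [[0.5, 0.3, 0.2]] * 3
        out = contrast_conditions(_mid_table(fr, fr, n_carbons=2), "a", "b")
        assert np.allclose(out["difference"], 0.0)
        assert not out["significant"].any()

    def test_t_statistic_matches_pooled_hand_computation(self):
        # means .61 vs .41, each sample var 1e-4 -> t = 0.2/(0.01*sqrt(2/3))
        a = [[1 - v, v] for v in (0.60, 0.62, 0.61)]
        b = [[1 - v, v] for v in (0.40, 0.42, 0.41)]
        out = contrast_conditions(_mid_table(a, b, n_carbons=1), "a", "b")
        row = out[out["isotopologue"] == 1].iloc[0]
        assert row["t"] == pytest.approx(0.2 / (0.01 * np.sqrt(2 / 3)), rel=1e-12)
        assert row["significant"]

    def test_emits_labeled_fraction_contrast(self):
        a = [[0.4, 0.6], [0.38, 0.62], [0.39, 0.61]]
        b = [[0.6, 0.4], [0.58, 0.42], [0.59, 0.41]]
        out = contrast_conditions(_mid_table(a, b, n_carbons=1), "a", "b")
        lab = out[out["isotopologue"] == "labeled"].iloc[0]
        assert lab["mean_a"] == pytest.approx(61.0)
        assert lab["mean_b"] == pytest.approx(41.0)

    def test_single_replicate_errors(self):
        tbl = _mid_table([[0.5, 0.5]], [[0.4, 0.6]], n_carbons=1)
        with pytest.raises(ValueError, match="insufficient replicates"):
            contrast_conditions(tbl, "a", "b")


class TestTcaMidShift:
    def test_restricts_to_requested_indices(self):
        a = [[0.5, 0.0, 0.3, 0.0, 0.15, 0.05, 0.0]] * 3
        b = [[0.6, 0.0, 0.2, 0.0, 0.15, 0.05, 0.0]] * 3
        out = tca_mid_shift(_mid_table(a, b, metabolite="citrate"), "a", "b")
        assert set(out["isotopologue"]) == {2, 4, 5}

    def test_identical_conditions_zero_differences(self):
        fr = [[0.5, 0.0, 0.3, 0.0, 0.2, 0.0, 0.0]] * 3
        out = tca_mid_shift(_mid_table(fr, fr, metabolite="citrate"), "a", "b")
        assert np.allclose(out["difference"], 0.0)

    def test_unknown_metabolite_errors(self):
        fr = [[0.5, 0.5]] * 2
        with pytest.raises(ValueError, match="unknown metabolite"):
            tca_mid_shift(_mid_table(fr, fr, n_carbons=1), "a", "b",
                          metabolites=["oxaloacetate"])

    def test_index_beyond_carbon_count_errors(self):
        fr = [[0.5, 0.5]] * 2
        tbl = _mid_table(fr, fr, metabolite="citrate", n_carbons=1)
        with pytest.raises(ValueError, match="out of range"):
            tca_mid_shift(tbl, "a", "b", metabolites=["citrate"],
                          indices={"citrate": (7,)})
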