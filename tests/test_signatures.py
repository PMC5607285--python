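"""Welch testing, FDR control, DA calling and signature selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atacmix import (
    NormalizedMatrix,
    SimulationParams,
    bh_fdr,
    call_differential_peaks,
    condition_number,
    select_signature_matrix,
    simulate_mixture_experiment,
    one_vs_rest_tests,
    tmm_normalize,
    welch_t_test,
)


def _norm_from_values(values: pd.DataFrame) -> NormalizedMatrix:
    ones = pd.Series(1.0, index=values.columns)
    return NormalizedMatrix(values=values, tmm_factors=ones, library_sizes=ones * 1e6)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_formula(self):
        a = np.array([10.0, 12.0, 11.0])
        b = np.array([2.0, 3.0, 2.0])
        t, df, p = welch_t_test(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 3 + vb / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(se2)
        df_hand = se2**2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand))
        # cross-check against the scipy implementation
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_antisymmetry(self):
        t1, _, p1 = welch_t_test([5.0, 6, 7, 8], [1.0, 2, 2.5])
        t2, _, p2 = welch_t_test([1.0, 2, 2.5], [5.0, 6, 7, 8])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t_test([1.0], [1.0, 2.0])

    def test_null_pvalues_uniform(self):
        # 5000 null peaks from a shared normal: p-values pass KS uniformity
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, size=(5000, 5))
        b = rng.normal(0, 1, size=(5000, 5))
        p = np.array([welch_t_test(a[i], b[i])[2] for i in range(0, 5000, 10)])
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr([0.03]), [0.03])

    def test_direct_formula(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            bh_fdr([0.5, 1.5])

    def test_matches_step_up_brute_force(self, rng):
        p = rng.uniform(size=37)
        order = np.argsort(p)
        n = p.size
        q_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected)


class TestDifferentialCalling:
    def test_labels_match_generator_classes_on_separated_data(self):
        # near-noiseless simulation: DA labels reproduce the peak classes
        params = SimulationParams(
            n_peaks=300, frac_specific=0.15, nb_dispersion=0.0,
            depths=2_000_000, seed=21,
        )
        exp = simulate_mixture_experiment(params)
        norm = tmm_normalize(exp.counts.subset_samples(list(exp.pure_samples)))
        labels = call_differential_peaks(norm, exp.groups)
        truth = exp.assignment.labels.map(
            {
                "shared": "shared/ns",
                "specific:alpha": "alpha-specific",
                "specific:beta": "beta-specific",
            }
        )
        assert (labels == truth).all()

    def test_small_fold_change_is_not_called(self):
        # consistent but small shift: passes q, fails the fold-change gate
        values = pd.DataFrame(
            {
                "a1": [100.0, 5], "a2": [101.0, 6], "a3": [102.0, 5],
                "b1": [90.0, 5], "b2": [91.0, 6], "b3": [92.0, 5],
            },
            index=["p1", "p2"],
        )
        groups = pd.Series(
            ["A"] * 3 + ["B"] * 3, index=["a1", "a2", "a3", "b1", "b2", "b3"]
        )
        labels = call_differential_peaks(_norm_from_values(values), groups)
        assert (labels == "shared/ns").all()

    def test_requires_two_groups_with_replicates(self, small_norm, small_experiment):
        groups = small_experiment.groups.copy()
        with pytest.raises(ValueError, match="2 replicates"):
            call_differential_peaks(small_norm, groups.drop(groups.index[0:2]))

    def test_global_null_fdr_control(self):
        # all peaks shared: q < 0.05 discovery fraction stays near zero
        params = SimulationParams(
            n_peaks=2000, frac_specific=0.0, depths=1_000_000, seed=29
        )
        exp = simulate_mixture_experiment(params)
        norm = tmm_normalize(exp.counts.subset_samples(list(exp.pure_samples)))
        res = one_vs_rest_tests(norm, exp.groups)["alpha"]
        frac = float((res["q"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert frac <= 0.05 + 3 * se


class TestConditionNumber:
    def test_orthonormal_is_one(self):
        assert condition_number(np.eye(4)[:, :2]) == pytest.approx(1.0)

    def test_diagonal(self):
        assert condition_number(np.diag([10.0, 1.0])) == pytest.approx(10.0)

    def test_matches_independent_decomposition(self, rng):
        m = rng.uniform(1, 50, size=(50, 2))
        assert condition_number(m) == pytest.approx(np.linalg.cond(m, 2))

    def test_rank_deficient_is_infinite(self):
        m = np.ones((5, 2))
        assert condition_number(m) == np.inf


class TestSignatureSelection:
    def test_grid_minimizes_condition_number(self, small_experiment, small_norm):
        exp = small_experiment
        pure = list(exp.pure_samples)
        pure_norm = NormalizedMatrix(
            values=small_norm.values[pure],
            tmm_factors=small_norm.tmm_factors[pure],
            library_sizes=small_norm.library_sizes[pure],
        )
        grid = range(5, 21)
        sig = select_signature_matrix(pure_norm, exp.groups, g_grid=grid)
        # brute-force recomputation of kappa across the same grid
        tests = one_vs_rest_tests(pure_norm, exp.groups)
        by_group = {"alpha": pure[:3], "beta": pure[3:]}
        kappas = {}
        for g in grid:
            ids = pd.Index([])
            for ct in ("alpha", "beta"):
                cand = tests[ct]
                cand = cand[(cand["q"] < 0.30) & (cand["log2fc"] > 0)]
                top = cand.sort_values("log2fc", ascending=False, kind="stable").index[:g]
                ids = ids.union(top, sort=False)
            med = pd.DataFrame(
                {ct: pure_norm.values.loc[ids, cols].median(axis=1)
                 for ct, cols in by_group.items()}
            )
            kappas[g] = np.linalg.cond(med.to_numpy(), 2)
        best_g = min(kappas, key=lambda g: (kappas[g], g))
        assert sig.kappa == pytest.approx(min(kappas.values()))
        assert sig.g == best_g

    def test_signature_invariants(self, small_experiment, small_norm):
        exp = small_experiment
        pure = list(exp.pure_samples)
        pure_norm = NormalizedMatrix(
            values=small_norm.values[pure],
            tmm_factors=small_norm.tmm_factors[pure],
            library_sizes=small_norm.library_sizes[pure],
        )
        sig = select_signature_matrix(pure_norm, exp.groups, g_grid=range(5, 21))
        tests = one_vs_rest_tests(pure_norm, exp.groups)
        for ct in ("alpha", "beta"):
            peaks = sig.peaks_for(ct)
            assert len(peaks) > 0
            assert (tests[ct].loc[peaks, "q"] < 0.30).all()
            assert (tests[ct].loc[peaks, "log2fc"] > 0).all()
        # median values recomputable from replicates
        for ct, cols in {"alpha": pure[:3], "beta": pure[3:]}.items():
            np.testing.assert_allclose(
                sig.values[ct].to_numpy(),
                pure_norm.values.loc[sig.peak_ids, cols].median(axis=1).to_numpy(),
            )

    def test_replicate_order_invariance(self, small_experiment, small_norm):
        exp = small_experiment
        pure = list(exp.pure_samples)
        shuffled = pure[2::-1] + pure[:2:-1]
        sigs = []
        for order in (pure, shuffled):
            pn = NormalizedMatrix(
                values=small_norm.values[order],
                tmm_factors=small_norm.tmm_factors[order],
                library_sizes=small_norm.library_sizes[order],
            )
            sigs.append(select_signature_matrix(pn, exp.groups, g_grid=range(5, 21)))
        pd.testing.assert_frame_equal(sigs[0].values, sigs[1].values)

    def test_identical_cell_types_rejected(self):
        col = [100.0, 50, 20, 400, 10, 70, 30, 250]
        values = pd.DataFrame({s: col for s in ["a1", "a2", "b1", "b2"]},
                              index=[f"p{i}" for i in range(8)])
        groups = pd.Series(["A", "A", "B", "B"], index=["a1", "a2", "b1", "b2"])
        with pytest.raises(ValueError, match="too few qualifying peaks"):
            select_signature_matrix(_norm_from_values(values), groups, g_grid=range(2, 5))
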