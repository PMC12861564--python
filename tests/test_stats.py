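from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.duration.hazard_regression import PHReg

from gliotype.io import ClinicalTable
from gliotype.simulate import SimCohortSpec, simulate_cohort
from gliotype.stats import (
    chi_square_test,
    cox_fit,
    enrichment_frame,
    km_logrank,
    mann_whitney,
    pathway_group_compare,
    pathway_scores_mlm,
    radiomic_enrichment,
    subtype_volume_correlation,
)

from conftest import make_table


class TestChiSquare:
    def test_homogeneous_table(self):
        chi2, df, p = chi_square_test([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_by_three_no_correction(self):
        chi2, df, _ = chi_square_test([[36, 49, 68], [46, 29, 18]])
        assert df == 2
        assert chi2 == pytest.approx(22.098, abs=0.005)

    def test_yates_on_two_by_two(self):
        chi2, df, _ = chi_square_test([[93, 60], [37, 56]])
        assert df == 1
        assert chi2 == pytest.approx(9.410, abs=0.005)
        chi2_u, _, _ = chi_square_test([[93, 60], [37, 56]], yates_2x2=False)
        assert chi2_u > chi2  # the correction shrinks the statistic

    def test_zero_column_dropped(self):
        chi2, df, p = chi_square_test([[5, 0, 7], [3, 0, 9]])
        assert df == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [0, 0]])


class TestMannWhitney:
    def test_identical_samples_z_zero(self):
        u, z, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_extreme_case_exact_enumeration_oracle(self):
        x, y = [1.0, 2, 3], [10.0, 11, 12]
        u, z, p = mann_whitney(x, y)
        assert u == 0.0
        # exact two-sided p by enumerating all 20 group assignments
        pooled = np.array(x + y)
        u_obs = 0.0
        count = 0
        total = 0
        for idx in combinations(range(6), 3):
            mask = np.zeros(6, bool)
            mask[list(idx)] = True
            ranks = sps.rankdata(pooled)
            u_perm = ranks[mask].sum() - 3 * 4 / 2
            # two-sided: as or more extreme in either direction
            if min(u_perm, 9 - u_perm) <= min(u_obs, 9 - u_obs):
                count += 1
            total += 1
        assert count / total == pytest.approx(0.1)

    def test_normal_approximation_close_to_exact(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8) + 0.8
        _, _, p_approx = mann_whitney(x, y)
        p_exact = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
        assert abs(p_approx - p_exact) / p_exact < 0.05

    def test_all_tied(self):
        u, z, p = mann_whitney([5, 5], [5, 5, 5])
        assert (z, p) == (0.0, 1.0)


class TestSurvival:
    def test_identical_groups_null_logrank(self):
        t = np.array([5.0, 8, 12, 5, 8, 12])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.repeat([1, 2], 3)
        res = km_logrank(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)

    def test_six_subject_hand_oracle(self):
        # A: events at 1,2,3; B: events at 4,5,6
        t = np.array([1.0, 2, 3, 4, 5, 6])
        e = np.ones(6, dtype=int)
        g = np.repeat(["A", "B"], 3)
        res = km_logrank(t, e, g)
        # direct O-E / hypergeometric-variance computation
        o_minus_e, var = 0.0, 0.0
        for ti in [1, 2, 3, 4, 5, 6]:
            at_risk = t >= ti
            n = at_risk.sum()
            na = (at_risk & (g == "A")).sum()
            d = 1
            o = 1.0 if (t == ti)[g == "A"].any() else 0.0
            o_minus_e += o - d * na / n
            if n > 1:
                var += d * na * (n - na) * (n - d) / (n ** 2 * (n - 1))
        expected = o_minus_e ** 2 / var
        assert res.chi2 == pytest.approx(expected, rel=1e-6)

    def test_cox_null_partial_likelihood_identity(self):
        # at beta = 0 with unique times, the Breslow log partial
        # likelihood is -sum over events of log(risk-set size)
        t = np.array([3.0, 5, 7, 11, 13])
        e = np.array([1, 1, 0, 1, 1])
        x = np.array([[0.2], [1.0], [-0.4], [0.7], [0.1]])
        model = PHReg(t, x, status=e, ties="breslow")
        expected = -sum(np.log((t >= ti).sum()) for ti in t[e == 1])
        assert model.loglike(np.zeros(1)) == pytest.approx(expected)

    def test_cox_ci_coverage_under_null(self):
        covered = 0
        n_rep = 30
        for rep in range(n_rep):
            spec = SimCohortSpec(n_samples=246,
                                 hazards_per_day=(1 / 500, 1 / 500),
                                 seed=1000 + rep)
            _, _, clinical, labels = simulate_cohort(spec)
            try:
                res = cox_fit(clinical, labels)
            except ValueError:
                continue
            if res.loc["high_risk", "hr_lo"] <= 1 <= res.loc["high_risk",
                                                             "hr_hi"]:
                covered += 1
        assert covered / n_rep >= 0.85

    def test_cox_rejects_constant_covariate(self):
        spec = SimCohortSpec(n_samples=60, seed=5)
        _, _, clinical, labels = simulate_cohort(spec)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(clinical, np.ones_like(labels))


class TestVolumeCorrelation:
    def test_identical_volumes_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            subtype_volume_correlation(np.array([0, 1, 0, 1]),
                                       np.full(4, 5.0))

    def test_closed_form_point_biserial(self):
        # balanced groups, perfectly separated volumes
        labels = np.repeat([0, 1], 10)
        volumes = np.concatenate([np.full(10, 10.0), np.full(10, 20.0)])
        volumes += np.tile([-1.0, 1.0], 10)  # within-group spread
        r, _ = subtype_volume_correlation(labels, volumes)
        m1, m0 = volumes[labels == 1].mean(), volumes[labels == 0].mean()
        s = volumes.std()
        expected = (m1 - m0) / s * np.sqrt(0.5 * 0.5)
        assert r == pytest.approx(expected)

    def test_sign_tracks_coding(self):
        spec = SimCohortSpec(n_samples=246, seed=2)
        _, _, clinical, labels = simulate_cohort(spec)
        vol = clinical.frame["tumor_volume_cm3"].to_numpy()
        # high-risk (label 1, larger tumors) coded LOW -> negative r
        r, ci = subtype_volume_correlation((labels == 2).astype(int), vol)
        assert r < 0
        assert ci[0] < r < ci[1]


class TestPathwayScores:
    def test_per_sample_ols_oracle(self, rng):
        # independent route: statsmodels OLS t-values per sample
        import statsmodels.api as sm
        genes = 50
        w = pd.DataFrame(rng.standard_normal((genes, 3)),
                         index=[f"G{i}" for i in range(genes)],
                         columns=["P1", "P2", "P3"])
        expr = pd.DataFrame(rng.standard_normal((4, genes)),
                            index=[f"S{i}" for i in range(4)],
                            columns=w.index)
        scores = pathway_scores_mlm(expr, w)
        x = sm.add_constant(w.to_numpy())
        for i in range(4):
            fit = sm.OLS(expr.iloc[i].to_numpy(), x).fit()
            np.testing.assert_allclose(scores.scores.iloc[i].to_numpy(),
                                       fit.tvalues[1:], rtol=1e-8)

    def test_exact_fit_dominates(self, rng):
        w = pd.DataFrame(rng.standard_normal((60, 3)),
                         index=[f"G{i}" for i in range(60)],
                         columns=["P1", "P2", "P3"])
        expr = pd.DataFrame((3.0 * w["P1"]).to_numpy()[None, :],
                            index=["S0"], columns=w.index)
        scores = pathway_scores_mlm(expr, w).scores.iloc[0]
        assert scores["P1"] > 1e3
        assert np.abs(scores[["P2", "P3"]]).max() < 1e-6

    def test_null_calibration(self, rng):
        w = pd.DataFrame(rng.standard_normal((200, 5)),
                         index=[f"G{i}" for i in range(200)],
                         columns=[f"P{j}" for j in range(5)])
        expr = pd.DataFrame(rng.standard_normal((40, 200)),
                            index=[f"S{i}" for i in range(40)],
                            columns=w.index)
        scores = pathway_scores_mlm(expr, w).scores.to_numpy()
        assert (np.abs(scores) < 3).mean() > 0.95

    def test_rank_deficient_weights_rejected(self, rng):
        w = pd.DataFrame(np.zeros((30, 2)),
                         index=[f"G{i}" for i in range(30)],
                         columns=["P1", "P2"])
        expr = pd.DataFrame(rng.standard_normal((2, 30)),
                            index=["a", "b"], columns=w.index)
        with pytest.raises(ValueError, match="rank"):
            pathway_scores_mlm(expr, w)

    def test_group_compare_antisymmetry(self, rng):
        w = pd.DataFrame(rng.standard_normal((80, 4)),
                         index=[f"G{i}" for i in range(80)],
                         columns=list("ABCD"))
        expr = pd.DataFrame(rng.standard_normal((30, 80)),
                            index=[f"S{i}" for i in range(30)],
                            columns=w.index)
        scores = pathway_scores_mlm(expr, w)
        groups = np.repeat([1, 2], 15)
        a = pathway_group_compare(scores, groups, high_label=1)
        b = pathway_group_compare(scores, groups, high_label=2)
        np.testing.assert_allclose(a["t"], -b["t"], atol=1e-12)


class TestEnrichment:
    def test_worked_enumeration_example(self):
        # cohort 30, cluster of 10, feature over-called in 12 samples of
        # which 9 fall in the cluster
        p_closed = sps.hypergeom.sf(8, 30, 12, 10)
        p_manual = sum(
            comb(12, x) * comb(18, 10 - x) / comb(30, 10)
            for x in (9, 10))
        assert p_closed == pytest.approx(p_manual, rel=1e-12)
        assert 9 / 10 >= 2 / 3 and 3 / 20 < 1 / 3  # fraction filters pass

    def test_hypergeom_equals_enumeration_small_cohorts(self):
        for n, big_k, size, k_in in [(25, 10, 8, 6), (20, 5, 10, 4),
                                     (15, 7, 6, 5), (12, 3, 4, 2)]:
            closed = sps.hypergeom.sf(k_in - 1, n, big_k, size)
            manual = sum(
                comb(big_k, x) * comb(n - big_k, size - x) / comb(n, size)
                for x in range(k_in, min(big_k, size) + 1))
            assert closed == pytest.approx(manual, rel=1e-10)

    def test_uniform_alteration_fails_fraction_filter(self, rng):
        x = rng.standard_normal((40, 6))
        labels = np.repeat([1, 2], 20)
        records = radiomic_enrichment(make_table(x), labels)
        assert not any(r.significant for r in records)

    def test_planted_shift_detected(self, rng):
        x = rng.standard_normal((60, 10))
        labels = np.repeat([1, 2], [20, 40])
        x[labels == 1, 0] += 5.0  # cluster-1-specific elevation
        records = radiomic_enrichment(make_table(x), labels)
        frame = enrichment_frame(records)
        hit = frame[(frame.feature == "f0") & (frame.cluster == 1) &
                    (frame.direction == "over")]
        assert bool(hit["significant"].iloc[0])

    def test_counts_consistent(self, rng):
        x = rng.standard_normal((30, 4))
        labels = np.repeat([1, 2, 3], 10)
        for r in radiomic_enrichment(make_table(x), labels):
            assert r.altered_in_cluster <= min(r.cluster_size,
                                               r.altered_overall)

    def test_sample_permutation_invariance(self, rng):
        x = rng.standard_normal((30, 5))
        x[:10, 2] += 4
        labels = np.repeat([1, 2, 3], 10)
        f1 = enrichment_frame(radiomic_enrichment(make_table(x), labels))
        perm = rng.permutation(30)
        f2 = enrichment_frame(
            radiomic_enrichment(make_table(x[perm]), labels[perm]))
        key = ["feature", "cluster", "direction"]
        merged = f1.merge(f2, on=key, suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_a"], merged["p_b"], atol=1e-12)
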