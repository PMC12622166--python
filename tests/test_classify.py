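"""ROC/AUC correctness, Youden point, group tests, LOOCV behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctdna_mpnst.classify import (
    MalignancyClassifier,
    auc_ci,
    cna_burden_baseline,
    group_separation,
    roc_auc,
    youden_point,
)
from ctdna_mpnst.features import feature_columns


def mannwhitney_auc(scores, labels):
    """Independent AUC oracle: U statistic / (n_pos * n_neg), ties half-counted."""
    pos = np.asarray(scores)[np.asarray(labels, bool)]
    neg = np.asarray(scores)[~np.asarray(labels, bool)]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        summary = roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert summary.auc == 1.0

    def test_all_tied_scores(self):
        summary = roc_auc([0.5] * 6, [True] * 3 + [False] * 3)
        assert summary.auc == 0.5

    def test_three_of_four_concordant_pairs(self):
        summary = roc_auc([0.9, 0.4, 0.5, 0.1], [True, True, False, False])
        assert summary.auc == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    def test_equals_mannwhitney_probability(self):
        """Trapezoidal AUC == U/(n1*n2) to 1e-12 on 200 random score sets."""
        rng = np.random.default_rng(12)
        for i in range(200):
            n_pos = int(rng.integers(2, 15))
            n_neg = int(rng.integers(2, 15))
            if i % 3 == 0:  # include heavy ties
                scores = rng.integers(0, 4, n_pos + n_neg).astype(float)
            else:
                scores = rng.normal(size=n_pos + n_neg)
            labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            got = roc_auc(scores, labels).auc
            assert got == pytest.approx(mannwhitney_auc(scores, labels), abs=1e-12)


class TestYouden:
    def test_perfect_separation_point(self):
        summary = roc_auc([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        _, sens, spec = youden_point(summary.roc_points)
        assert sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            scores = rng.normal(size=20)
            labels = rng.random(20) < 0.4
            if labels.all() or not labels.any():
                continue
            summary = roc_auc(scores, labels)
            thr, sens, spec = youden_point(summary.roc_points)
            # brute force over all candidate thresholds (score midpoints + extremes)
            best_j = -np.inf
            for t in np.r_[-np.inf, np.sort(scores)]:
                s = (scores > t)
                tpr = s[labels].mean()
                fpr = s[~labels].mean()
                best_j = max(best_j, tpr - fpr)
            assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)

    def test_degenerate_tied_scores(self):
        summary = roc_auc([0.5] * 6, [True] * 3 + [False] * 3)
        _, sens, spec = youden_point(summary.roc_points)
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_tie_breaks_toward_specificity(self):
        # two thresholds reach J=0.5; the high-specificity one must win
        scores = [0.9, 0.3, 0.5, 0.1]
        labels = [True, True, False, False]
        summary = roc_auc(scores, labels)
        _, sens, spec = youden_point(summary.roc_points)
        assert spec == 1.0 and sens == pytest.approx(0.5)


class TestAucCi:
    def test_perfect_separation_degenerate_interval(self):
        lo, hi = auc_ci([0.9, 0.8, 0.1, 0.2], [True, True, False, False],
                        n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_null_coverage(self):
        """The 95% interval covers 0.5 in >= 90% of null cohorts."""
        rng = np.random.default_rng(9)
        covered = 0
        for rep in range(100):
            scores = rng.normal(size=60)
            labels = np.r_[np.ones(26, bool), np.zeros(34, bool)]
            lo, hi = auc_ci(scores, labels, n_boot=200, seed=rep)
            covered += lo <= 0.5 <= hi
        assert covered >= 90

    def test_bootstrap_stability_in_n_boot(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 40)]
        labels = np.r_[np.ones(30, bool), np.zeros(40, bool)]
        lo1, hi1 = auc_ci(scores, labels, n_boot=2000, seed=0)
        lo2, hi2 = auc_ci(scores, labels, n_boot=4000, seed=0)
        assert abs(lo1 - lo2) < 0.02 and abs(hi1 - hi2) < 0.02

    def test_too_few_bootstraps_rejected(self):
        with pytest.raises(ValueError):
            auc_ci([0.9, 0.1], [True, False], n_boot=10)


class TestGroupSeparation:
    def test_exact_wilcoxon_enumeration(self):
        """{1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 arrangements,
        two-sided p = 2/20 = 0.1."""
        _, p = group_separation([1, 2, 3, 4, 5, 6],
                                [True, True, True, False, False, False],
                                test="wilcoxon")
        assert p == pytest.approx(0.1)

    def test_symmetric_toy_gives_p_one(self):
        _, p = group_separation([1, 2, 3, 4], [True, False, False, True],
                                test="wilcoxon")
        assert p == pytest.approx(1.0)

    def test_welch_separated_groups(self):
        values = [0.0, 0.0, 0.0, 0.001, 10.0, 10.0, 10.0, 10.001]
        labels = [True] * 4 + [False] * 4
        _, p = group_separation(values, labels, test="welch")
        assert p < 0.01

    def test_welch_constant_groups_error(self):
        with pytest.raises(ValueError):
            group_separation([1, 1, 2, 2], [True, True, False, False], test="welch")

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            group_separation([1, 2, 3], [True, False, False])


def toy_matrix(n=8, seed=0, separable=True):
    rng = np.random.default_rng(seed)
    cols = feature_columns()
    df = pd.DataFrame(0.0, index=[f"S{i}" for i in range(n)], columns=cols)
    labels = ["MPNST" if i < n // 2 else "PN" for i in range(n)]
    for i in range(n):
        sign = 1 if labels[i] == "MPNST" else -1
        if separable:
            df.iloc[i, df.columns.get_loc("cna_z_TP53")] = sign * 2 + rng.normal(0, 0.1)
            df.iloc[i, df.columns.get_loc("cna_log2_TP53")] = sign * 0.3 + rng.normal(0, 0.02)
        else:
            df.iloc[i, df.columns.get_loc("cna_z_TP53")] = rng.normal()
            df.iloc[i, df.columns.get_loc("cna_log2_TP53")] = rng.normal()
    df["label"] = labels
    return df


class TestLoocv:
    def test_separable_toy_probabilities_on_correct_side(self):
        matrix = toy_matrix(8, separable=True)
        results = MalignancyClassifier(matrix).fit(seed=0, n_boot=None)
        for sid in matrix.index:
            p = results.probabilities[sid]
            if matrix.loc[sid, "label"] == "MPNST":
                assert p > 0.5
            else:
                assert p < 0.5

    def test_label_permuted_cohort_auc_near_half(self):
        rng = np.random.default_rng(31)
        cols = feature_columns()
        df = pd.DataFrame(rng.normal(size=(60, len(cols))), columns=cols,
                          index=[f"S{i}" for i in range(60)])
        for c in cols:
            if c.startswith(("snv_", "sv_", "chr8")):
                df[c] = rng.integers(0, 2, 60)
        df["label"] = rng.permutation(["MPNST"] * 26 + ["PN"] * 34)
        results = MalignancyClassifier(df).fit(seed=31, n_boot=None)
        assert 0.35 <= results.auc <= 0.65

    def test_deterministic_given_seed(self):
        matrix = toy_matrix(10, seed=2)
        r1 = MalignancyClassifier(matrix).fit(seed=7, n_boot=None)
        r2 = MalignancyClassifier(matrix).fit(seed=7, n_boot=None)
        pd.testing.assert_series_equal(r1.probabilities, r2.probabilities)
        assert r1.auc == r2.auc

    def test_fold_scaling_ignores_held_out_row(self):
        """LOOCV leakage check: perturbing a held-out row's raw CNA values
        leaves that fold's training-scaling parameters unchanged."""
        matrix = toy_matrix(8)
        model = MalignancyClassifier(matrix)
        res = model.fit(seed=0, n_boot=None)
        held_out = model.features.index[0]
        perturbed = matrix.copy()
        perturbed.loc[held_out, "cna_log2_TP53"] = 99.0
        res2 = MalignancyClassifier(perturbed).fit(seed=0, n_boot=None)
        assert res.fold_scaling[0] == res2.fold_scaling[0]

    def test_degenerate_cohort_raises(self):
        matrix = toy_matrix(8)
        matrix["label"] = ["MPNST"] * 7 + ["PN"]
        with pytest.raises(ValueError):
            MalignancyClassifier(matrix)

    def test_summary_reports_key_quantities(self):
        results = MalignancyClassifier(toy_matrix(8)).fit(seed=0, n_boot=200)
        text = results.summary()
        assert "LOOCV AUC" in text and "Sensitivity" in text and "bootstrap CI" in text


class TestCnaBurdenBaseline:
    def _bins(self, log2, chrom="1"):
        n = len(log2)
        return pd.DataFrame({"chrom": chrom, "start": np.arange(n) * 1000,
                             "end": (np.arange(n) + 1) * 1000,
                             "log2_ratio": log2, "n_reads": 100})

    def test_sample_at_panel_mean_scores_zero(self):
        panel = {"P0": self._bins([0.2, -0.2, 0.1]),
                 "P1": self._bins([0.0, 0.0, -0.1]),
                 "P2": self._bins([-0.2, 0.2, 0.0])}
        per_bin_mean = np.mean([[0.2, -0.2, 0.1], [0.0, 0.0, -0.1], [-0.2, 0.2, 0.0]],
                               axis=0)
        bins = {**panel, "S1": self._bins(per_bin_mean)}
        scores = cna_burden_baseline(bins, list(panel))
        assert scores["S1"] == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_bin_order(self):
        rng = np.random.default_rng(2)
        panel = {f"P{i}": self._bins(rng.normal(0, 0.1, 10)) for i in range(4)}
        case = self._bins(rng.normal(0, 0.3, 10))
        shuffled = case.sample(frac=1, random_state=1).reset_index(drop=True)
        s1 = cna_burden_baseline({**panel, "S1": case}, list(panel))["S1"]
        s2 = cna_burden_baseline({**panel, "S1": shuffled}, list(panel))["S1"]
        assert s1 == pytest.approx(s2)

    def test_no_bins_is_error(self):
        with pytest.raises(ValueError):
            cna_burden_baseline({}, [])
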