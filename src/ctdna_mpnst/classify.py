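"""Integrated malignancy classifier with leave-one-out cross-validation.

The model is a binary L2-regularized logistic regression on the
integrated feature matrix, with the positive class being MPNST and the
negative class pooling plexiform neurofibroma and healthy plasma.  Each
sample's malignancy probability comes from a model trained on every
*other* sample (LOOCV), with feature scaling refit inside each fold so no
information leaks from the held-out row.  The results object carries the
pooled held-out probabilities, the ROC/AUC with a stratified-bootstrap
confidence interval, the Youden-index operating point, and group
separation tests (Wilcoxon rank-sum, Welch t).

A genome-wide copy-number burden score (mean |z| over off-target bins
against the healthy-panel bin reference) serves as the deliberately
simpler comparator arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

from .features import scale_features

logger = logging.getLogger(__name__)

__all__ = [
    "MalignancyClassifier",
    "MalignancyResults",
    "RocSummary",
    "roc_auc",
    "auc_ci",
    "youden_point",
    "group_separation",
    "cna_burden_baseline",
]

POSITIVE_LABEL = "MPNST"


@dataclass
class RocSummary:
    auc: float
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    ci_low: float | None = None
    ci_high: float | None = None
    youden_threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


def roc_auc(probabilities: Sequence[float], labels: Sequence[bool]) -> RocSummary:
    """Empirical ROC and trapezoidal AUC.

    The trapezoidal AUC over the empirical ROC equals the Mann-Whitney
    concordance probability (ties counted half).  Raises when either
    class is absent.
    """
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(probabilities, dtype=float)
    if y.all() or not y.any():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = roc_curve(y, p)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return RocSummary(auc=float(roc_auc_score(y, p)), roc_points=points)


def youden_point(roc_points: pd.DataFrame) -> tuple[float, float, float]:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties break toward higher specificity (lower false-positive rate),
    matching a screening context that privileges specificity.
    Returns (threshold, sensitivity, specificity).
    """
    if len(roc_points) == 0:
        raise ValueError("empty ROC")
    j = roc_points["tpr"] - roc_points["fpr"]
    best = roc_points.loc[j.round(12) == j.max().round(12)]
    row = best.sort_values("fpr").iloc[0]
    return float(row["threshold"]), float(row["tpr"]), float(1 - row["fpr"])


def auc_ci(
    probabilities: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified bootstrap percentile 95% interval for the AUC.

    Positive and negative samples are resampled within class, so every
    bootstrap replicate contains both classes by construction.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(probabilities, dtype=float)
    pos, neg = p[y], p[~y]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        scores = np.concatenate([bp, bn])
        lab = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
        aucs[b] = roc_auc_score(lab, scores)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def group_separation(
    values: Sequence[float], labels: Sequence[bool], test: str = "wilcoxon"
) -> tuple[float, float]:
    """Two-sided group test on a score: Wilcoxon rank-sum or Welch t.

    The rank-sum test uses exact enumeration when both groups have at
    most 10 observations and no ties span the groups, else the normal
    approximation with tie correction.  Returns (statistic, p).
    """
    y = np.asarray(labels, dtype=bool)
    x = np.asarray(values, dtype=float)
    a, b = x[y], x[~y]
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if test == "wilcoxon":
        method = "exact" if (a.size <= 10 and b.size <= 10) else "asymptotic"
        if method == "exact" and np.unique(x).size < x.size:
            method = "asymptotic"  # scipy's exact method does not handle ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "welch":
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("both groups constant; Welch t undefined")
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def cna_burden_baseline(
    bins_by_sample: Mapping[str, pd.DataFrame],
    panel_samples: Sequence[str],
) -> pd.Series:
    """Genome-wide CNA burden: mean |z| of bin log2 ratios vs the panel.

    Per-bin mean/SD come from the background-panel samples (SD floored at
    0.01); the score is the mean absolute z over a sample's bins.  This
    is the weaker, untargeted comparator arm for benchmarking.
    """
    if not bins_by_sample:
        raise ValueError("no bins supplied")
    panel = [bins_by_sample[s] for s in panel_samples if s in bins_by_sample]
    if not panel:
        raise ValueError("no panel samples among supplied bins")
    stacked = pd.concat(
        [df.set_index(["chrom", "start"])["log2_ratio"] for df in panel], axis=1
    )
    ref_mean = stacked.mean(axis=1)
    ref_sd = stacked.std(axis=1, ddof=1).clip(lower=0.01)
    scores = {}
    for sid, df in bins_by_sample.items():
        keyed = df.set_index(["chrom", "start"])["log2_ratio"]
        z = (keyed - ref_mean) / ref_sd
        scores[sid] = float(z.abs().mean())
    return pd.Series(scores, name="cna_burden")


@dataclass
class MalignancyResults:
    """LOOCV evaluation results for the integrated classifier."""

    probabilities: pd.Series  # held-out P(MPNST) per sample
    labels: pd.Series  # class labels per sample
    fold_coefficients: pd.DataFrame
    fold_scaling: list[dict]
    seed: int
    roc: RocSummary = field(init=False)
    wilcoxon_p: float = field(init=False)
    welch_p: float = field(init=False)

    def __post_init__(self):
        y = (self.labels == POSITIVE_LABEL).to_numpy()
        self.roc = roc_auc(self.probabilities.to_numpy(), y)
        thr, sens, spec = youden_point(self.roc.roc_points)
        self.roc.youden_threshold = thr
        self.roc.sensitivity = sens
        self.roc.specificity = spec
        _, self.wilcoxon_p = group_separation(self.probabilities.to_numpy(), y, "wilcoxon")
        try:
            _, self.welch_p = group_separation(self.probabilities.to_numpy(), y, "welch")
        except ValueError:
            self.welch_p = float("nan")

    @property
    def auc(self) -> float:
        return self.roc.auc

    def compute_ci(self, n_boot: int = 2000, seed: int | None = None) -> tuple[float, float]:
        y = (self.labels == POSITIVE_LABEL).to_numpy()
        lo, hi = auc_ci(
            self.probabilities.to_numpy(), y, n_boot=n_boot,
            seed=self.seed if seed is None else seed,
        )
        self.roc.ci_low, self.roc.ci_high = lo, hi
        return lo, hi

    def summary(self) -> str:
        """Human-readable evaluation table."""
        r = self.roc
        n_pos = int((self.labels == POSITIVE_LABEL).sum())
        n_neg = len(self.labels) - n_pos
        lines = [
            "Integrated ctDNA malignancy classifier — LOOCV evaluation",
            "=" * 60,
            f"Samples:            {len(self.labels)}  ({POSITIVE_LABEL}: {n_pos}, other: {n_neg})",
            f"LOOCV AUC:          {r.auc:.3f}",
        ]
        if r.ci_low is not None:
            lines.append(f"95% bootstrap CI:   {r.ci_low:.3f}-{r.ci_high:.3f}")
        lines += [
            f"Youden threshold:   {r.youden_threshold:.3f}",
            f"Sensitivity:        {100 * r.sensitivity:.1f}%",
            f"Specificity:        {100 * r.specificity:.1f}%",
            f"Wilcoxon rank-sum:  p = {self.wilcoxon_p:.3g}",
            f"Welch t:            p = {self.welch_p:.3g}",
            f"Seed:               {self.seed}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample table: label and held-out probability."""
        return pd.DataFrame(
            {"label": self.labels, "probability": self.probabilities}
        ).rename_axis("sample_id")

    def plot_roc(self, ax=None, label: str | None = None):
        """ROC curve with the Youden operating point marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        pts = self.roc.roc_points
        ax.plot(pts["fpr"], pts["tpr"], label=label or f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        if self.roc.sensitivity is not None:
            ax.plot(1 - self.roc.specificity, self.roc.sensitivity, "o", c="red", ms=5)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right")
        return ax


class MalignancyClassifier:
    """Binary malignancy model over the integrated feature matrix.

    Parameters
    ----------
    features : DataFrame
        One row per cfDNA sample with the fixed feature columns and a
        ``label`` column (healthy / PN / MPNST), as produced by
        :func:`ctdna_mpnst.features.build_feature_matrix`.
    C : float
        Inverse L2 regularization strength for the logistic regression.
    """

    def __init__(self, features: pd.DataFrame, labels: pd.Series | None = None, C: float = 1.0):
        if labels is None:
            if "label" not in features.columns:
                raise ValueError("feature matrix needs a 'label' column (or pass labels=)")
            labels = features["label"]
            features = features.drop(columns=["label"])
        self.features = features.sort_index()
        self.labels = labels.reindex(self.features.index)
        counts = self.labels.value_counts()
        if (self.labels == POSITIVE_LABEL).sum() < 2 or (self.labels != POSITIVE_LABEL).sum() < 2:
            raise ValueError(f"need >= 2 samples per class, have {counts.to_dict()}")
        self.C = C

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs):
        labels = df[label_col]
        return cls(df.drop(columns=[label_col]), labels=labels, **kwargs)

    def _fit_fold(self, train_idx, seed: int):
        scaled, params = scale_features(self.features, train_index=train_idx)
        X_train = scaled.loc[train_idx].to_numpy()
        y_train = (self.labels.loc[train_idx] == POSITIVE_LABEL).to_numpy()
        if y_train.all() or not y_train.any():
            raise ValueError("training fold has a single class; cohort is degenerate")
        model = LogisticRegression(
            C=self.C, solver="lbfgs", max_iter=2000, random_state=seed
        )
        model.fit(X_train, y_train)
        return model, scaled, params

    def fit(self, seed: int = 0, n_boot: int | None = 2000) -> MalignancyResults:
        """Run leave-one-out cross-validation and evaluate.

        Each sample's probability comes from a model (and feature scaler)
        fit on the other n-1 rows.  Deterministic given the seed.
        """
        index = self.features.index
        probs = pd.Series(index=index, dtype=float, name="probability")
        coefs = []
        fold_scaling = []
        for held_out in index:
            train_idx = index.drop(held_out)
            model, scaled, params = self._fit_fold(train_idx, seed)
            x = scaled.loc[[held_out]].to_numpy()
            probs.loc[held_out] = float(model.predict_proba(x)[0, 1])
            coefs.append(pd.Series(model.coef_[0], index=self.features.columns, name=held_out))
            fold_scaling.append(params)
        results = MalignancyResults(
            probabilities=probs,
            labels=self.labels.copy(),
            fold_coefficients=pd.DataFrame(coefs),
            fold_scaling=fold_scaling,
            seed=seed,
        )
        if n_boot:
            results.compute_ci(n_boot=n_boot)
        return results
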