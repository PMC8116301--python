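"""Biomarker statistics: outlier screening, group tests, ROC, QC.

The evaluation chain mirrors standard clinical-glycomics practice: per
(trait, group) outlier removal with Tukey's 1.5 x IQR fences, two-sided
Wilcoxon-Mann-Whitney comparisons with Bonferroni correction, ROC curves
with trapezoidal AUC and a Youden-index optimal cutpoint, Spearman rank
correlations (interlaboratory concordance, CRP/age associations), and
replicate coefficient-of-variation repeatability QC.

Because pathogenic HNF1A variants lower antennary fucosylation, the
default ROC direction treats *lower* trait values as case-like; direction
is auto-detected from the data and can be overridden.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve

__all__ = [
    "LOWER", "HIGHER",
    "MannWhitneyResult", "RocResult", "QcSummary",
    "flag_outliers_iqr", "mann_whitney", "bonferroni",
    "roc", "optimal_cutpoint", "CutpointClassifier",
    "spearman", "interlab_concordance", "qc_cv",
    "evaluate_biomarkers", "covariate_checks",
]

LOWER = "lower_indicates_case"
HIGHER = "higher_indicates_case"


# ---------------------------------------------------------------------------
# Outlier screening


def flag_outliers_iqr(values, k: float = 1.5) -> np.ndarray:
    """Tukey fences: flag values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics.  Groups
    with fewer than 4 values are not screened (a warning is issued and no
    value is flagged); NaNs are never flagged.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    flags = np.zeros(x.shape, dtype=bool)
    n = int(finite.sum())
    if n == 0:
        return flags
    if n < 4:
        warnings.warn(f"group of size {n} < 4: outliers not screened", stacklevel=2)
        return flags
    q1, q3 = np.percentile(x[finite], [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags[finite] = (x[finite] < lo) | (x[finite] > hi)
    return flags


# ---------------------------------------------------------------------------
# Group comparison


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # pairs where a > b, plus half-ties
    p_value: float    # two-sided
    mode: str         # "exact" or "asymptotic"


def mann_whitney(a, b, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Wilcoxon-Mann-Whitney test.

    ``mode="auto"`` uses exact enumeration when the smaller group has at
    most 8 observations and the pooled data are tie-free, and the normal
    approximation with tie and continuity corrections otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode == "auto":
        pooled = np.concatenate([a, b])
        tie_free = np.unique(pooled).size == pooled.size
        mode = "exact" if (min(a.size, b.size) <= 8 and tie_free) else "asymptotic"
    if mode not in ("exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=mode)
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue),
                             mode=mode)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` elementwise.

    ``m`` defaults to the number of p-values (the test family of one run).
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    """ROC curve with AUC and the Youden-optimal operating point."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    direction: str
    cutoff: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    scores: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    labels: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def roc(scores, labels, direction: str = "auto") -> RocResult:
    """ROC curve, trapezoidal AUC, and Youden-optimal cutpoint.

    ``labels`` is boolean-like (True = case).  With ``direction="auto"``
    the orientation is chosen so the training AUC is >= 0.5; with an
    explicit direction the AUC may fall below 0.5.  Ties in the scores are
    handled by the diagonal segments of the curve, so the trapezoidal AUC
    equals the tie-corrected Mann-Whitney U divided by n_case * n_control.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if y.all() or (~y).all():
        raise ValueError("both classes must be present")

    def curve(direction_: str):
        oriented = -s if direction_ == LOWER else s
        fpr, tpr, _ = roc_curve(y.astype(int), oriented)
        return fpr, tpr, float(np.trapezoid(tpr, fpr))

    if direction == "auto":
        fpr, tpr, auc = curve(HIGHER)
        direction = HIGHER
        if auc < 0.5:
            fpr, tpr, auc = curve(LOWER)
            direction = LOWER
    elif direction in (LOWER, HIGHER):
        fpr, tpr, auc = curve(direction)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    result = RocResult(fpr=fpr, tpr=tpr, auc=auc, direction=direction,
                       scores=s, labels=y)
    optimal_cutpoint(result)
    return result


def optimal_cutpoint(roc_result: RocResult) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity (Youden's J).

    Candidate cutoffs are the midpoints between adjacent distinct score
    values plus one candidate on each side of the score range; under
    ``lower_indicates_case`` a sample is called a case when its score is
    below the cutoff, otherwise when above.  Ties on J are broken toward
    higher specificity (fewer false positives in a screening setting).
    Returns (cutoff, sensitivity, specificity) and stores them on the
    result.
    """
    s, y = roc_result.scores, roc_result.labels
    if s.size == 0:
        raise ValueError("RocResult carries no scores; build it with roc()")
    distinct = np.unique(s)
    span = distinct[-1] - distinct[0] if distinct.size > 1 else 1.0
    candidates = np.concatenate((
        [distinct[0] - 0.5 * span],
        (distinct[:-1] + distinct[1:]) / 2.0,
        [distinct[-1] + 0.5 * span],
    ))
    n_case = int(y.sum())
    n_ctrl = int((~y).sum())
    best = None
    for c in candidates:
        called = s < c if roc_result.direction == LOWER else s > c
        sens = float((called & y).sum()) / n_case
        spec = float((~called & ~y).sum()) / n_ctrl
        j = sens + spec
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and spec > best[2] + 1e-12
        ):
            best = (j, sens, spec, float(c))
    _, sens, spec, cutoff = best
    roc_result.cutoff = cutoff
    roc_result.sensitivity = sens
    roc_result.specificity = spec
    return cutoff, sens, spec


class CutpointClassifier(BaseEstimator, ClassifierMixin):
    """Single-threshold classifier fitted by ROC cutpoint analysis.

    ``fit(X, y)`` takes one score column (1-D array or single-column 2-D)
    and boolean-like case labels, finds the Youden-optimal cutoff, and
    ``predict`` applies it.  Exposes ``auc_``, ``cutoff_``,
    ``sensitivity_``, ``specificity_`` and ``direction_``.
    """

    def __init__(self, direction: str = "auto"):
        self.direction = direction

    @staticmethod
    def _column(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("CutpointClassifier expects a single score column")
            X = X[:, 0]
        return X

    def fit(self, X, y) -> "CutpointClassifier":
        scores = self._column(X)
        result = roc(scores, np.asarray(y, dtype=bool), direction=self.direction)
        self.roc_ = result
        self.auc_ = result.auc
        self.cutoff_ = result.cutoff
        self.sensitivity_ = result.sensitivity
        self.specificity_ = result.specificity
        self.direction_ = result.direction
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X) -> np.ndarray:
        scores = self._column(X)
        if self.direction_ == LOWER:
            return scores < self.cutoff_
        return scores > self.cutoff_


# ---------------------------------------------------------------------------
# Correlation


def spearman(x, y) -> float:
    """Spearman rank correlation (mid-ranks for ties), pairwise-complete.

    Identical or exactly reversed rankings return +/-1 exactly rather than
    within floating-point error, so rank invariance under monotone
    transforms is literal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = sps.rankdata(x[keep])
    ry = sps.rankdata(y[keep])
    if np.array_equal(rx, ry):
        return 1.0
    if np.array_equal(rx, n + 1.0 - ry):
        return -1.0
    return float(sps.spearmanr(x[keep], y[keep]).statistic)


def interlab_concordance(lab1: pd.DataFrame, lab2: pd.DataFrame) -> pd.DataFrame:
    """Per-trait Spearman correlation between two laboratories' tables.

    Rows are aligned on the shared sample index and columns on the shared
    trait names.  A negative correlation is flagged as a direction
    inversion (the second laboratory's representation runs opposite to the
    first's), which rank correlation cannot distinguish from noise alone.
    """
    traits = [c for c in lab1.columns if c in lab2.columns]
    if not traits:
        raise ValueError("no shared trait columns between the laboratories")
    common = lab1.index.intersection(lab2.index)
    rows = []
    for t in traits:
        r = spearman(lab1.loc[common, t], lab2.loc[common, t])
        rows.append({"trait": t, "spearman_r": r, "n": len(common),
                     "direction_inverted": r < 0})
    return pd.DataFrame(rows).set_index("trait")


# ---------------------------------------------------------------------------
# Repeatability QC


@dataclass(frozen=True)
class QcSummary:
    """Average plate CVs over peaks above the relative-intensity filter."""

    mean_intra_cv_pct: float
    mean_inter_cv_pct: float
    n_peaks_included: int
    ri_threshold_pct: float


def qc_cv(triplicates: pd.DataFrame, plate_col: str = "plate",
          ri_threshold_pct: float = 1.0) -> tuple[pd.DataFrame, QcSummary]:
    """Intra- and inter-plate coefficients of variation per peak.

    Intra-plate CV: mean over plates of the within-plate sd/mean (plates
    with a single replicate are skipped).  Inter-plate CV: sd/mean of the
    plate means (requires >= 2 plates).  Both reported in percent.  The
    summary averages are restricted to peaks whose mean relative intensity
    exceeds ``ri_threshold_pct`` percent, mirroring the convention of
    reporting repeatability only for non-trace peaks.
    """
    if plate_col not in triplicates.columns:
        raise ValueError(f"missing plate column {plate_col!r}")
    peaks = [c for c in triplicates.columns if c != plate_col]
    grouped = triplicates.groupby(plate_col, sort=False)
    rows = []
    for peak in peaks:
        intra = []
        plate_means = []
        for _, sub in grouped:
            v = sub[peak].to_numpy(dtype=float)
            plate_means.append(v.mean())
            if v.size >= 2 and v.mean() != 0:
                intra.append(v.std(ddof=1) / v.mean())
        plate_means = np.array(plate_means)
        inter = (plate_means.std(ddof=1) / plate_means.mean()
                 if plate_means.size >= 2 and plate_means.mean() != 0 else np.nan)
        rows.append({
            "peak": peak,
            "mean_ri_pct": 100.0 * float(np.mean(plate_means)) if plate_means.size else np.nan,
            "intra_cv_pct": 100.0 * float(np.mean(intra)) if intra else np.nan,
            "inter_cv_pct": 100.0 * float(inter) if np.isfinite(inter) else np.nan,
        })
    report = pd.DataFrame(rows).set_index("peak")
    included = report[report["mean_ri_pct"] > ri_threshold_pct]
    summary = QcSummary(
        mean_intra_cv_pct=float(included["intra_cv_pct"].mean()),
        mean_inter_cv_pct=float(included["inter_cv_pct"].mean()),
        n_peaks_included=int(len(included)),
        ri_threshold_pct=ri_threshold_pct,
    )
    return report, summary


# ---------------------------------------------------------------------------
# End-to-end biomarker evaluation


def evaluate_biomarkers(
    traits: pd.DataFrame,
    groups: pd.Series,
    comparisons: Sequence[tuple[str, str]] = (("damaging", "none"), ("damaging", "benign")),
    trait_cols: Sequence[str] | None = None,
    iqr_k: float = 1.5,
    direction: str = "auto",
    vus_group: str = "vus",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate each trait as a classifier for each group comparison.

    Per trait: values are screened with the IQR rule within each group
    separately and flagged values excluded for that trait only.  Per
    (trait, comparison): Mann-Whitney p (raw and Bonferroni-adjusted over
    the full trait x comparison family of this run), ROC AUC and the
    optimal cutpoint with its sensitivity/specificity.

    Samples in ``vus_group`` (variants of unknown significance) are scored
    against the cutoff from each trait's first comparison and reported as
    classified-pathogenic or not — the triage readout for unresolved
    variants.

    Returns (report, vus_classification).
    """
    trait_cols = list(trait_cols) if trait_cols is not None else list(traits.columns)
    groups = groups.reindex(traits.index)
    missing_groups = {g for pair in comparisons for g in pair} - set(groups.unique())
    if missing_groups:
        raise ValueError(f"requested group(s) absent: {sorted(missing_groups)}")

    rows = []
    vus_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-group screening warnings
        outlier_flags = {
            t: groups.groupby(groups, group_keys=False).apply(
                lambda g, t=t: pd.Series(
                    flag_outliers_iqr(traits.loc[g.index, t], k=iqr_k), index=g.index
                )
            ).reindex(traits.index, fill_value=False)
            for t in trait_cols
        }
    for trait in trait_cols:
        flags = outlier_flags[trait]
        for i_cmp, (case, control) in enumerate(comparisons):
            sel_case = (groups == case) & ~flags & traits[trait].notna()
            sel_ctrl = (groups == control) & ~flags & traits[trait].notna()
            a = traits.loc[sel_case, trait].to_numpy()
            b = traits.loc[sel_ctrl, trait].to_numpy()
            if a.size == 0 or b.size == 0:
                raise ValueError(
                    f"comparison {case}:{control} empty for {trait} after outlier removal"
                )
            mw = mann_whitney(a, b)
            scores = np.concatenate([a, b])
            labels = np.concatenate([np.ones(a.size, bool), np.zeros(b.size, bool)])
            rr = roc(scores, labels, direction=direction)
            n_removed = int(flags[(groups == case) | (groups == control)].sum())
            rows.append({
                "trait": trait,
                "comparison": f"{case}:{control}",
                "n_case": int(a.size),
                "n_control": int(b.size),
                "n_outliers_removed": n_removed,
                "p_raw": mw.p_value,
                "u": mw.u,
                "auc": rr.auc,
                "direction": rr.direction,
                "cutoff": rr.cutoff,
                "sensitivity": rr.sensitivity,
                "specificity": rr.specificity,
            })
            if i_cmp == 0:
                vus_values = traits.loc[groups == vus_group, trait]
                for sid, v in vus_values.items():
                    called = bool(v < rr.cutoff) if rr.direction == LOWER \
                        else bool(v > rr.cutoff)
                    vus_rows.append({
                        "sample_id": sid, "trait": trait, "value": float(v),
                        "cutoff": rr.cutoff, "classified_pathogenic": called,
                    })
    report = pd.DataFrame(rows)
    report["p_bonferroni"] = bonferroni(report["p_raw"].to_numpy())
    vus = pd.DataFrame(vus_rows)
    return report, vus


def covariate_checks(traits: pd.DataFrame, meta: pd.DataFrame,
                     age_col: str = "age", sex_col: str = "sex") -> pd.DataFrame:
    """Descriptive per-trait covariate associations (not a modeling step).

    Spearman correlation against age and a Mann-Whitney comparison between
    the sexes, reported unadjusted.
    """
    rows = []
    for t in traits.columns:
        r_age = spearman(traits[t], meta.loc[traits.index, age_col])
        sex = meta.loc[traits.index, sex_col]
        male = traits.loc[sex == "M", t].dropna()
        female = traits.loc[sex == "F", t].dropna()
        p_sex = mann_whitney(male, female).p_value if male.size and female.size else np.nan
        rows.append({"trait": t, "spearman_age": r_age, "p_sex": p_sex})
    return pd.DataFrame(rows).set_index("trait")
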