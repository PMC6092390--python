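"""Cohort-level statistics for DR-stage analysis of vascular parameters.

The cohort is a per-eye table (the eye is the unit of analysis; some
patients contribute both eyes) over six ordinal severity groups:

    1 healthy, 2 no DR, 3 mild NPDR, 4 moderate NPDR, 5 severe NPDR, 6 PDR.

Three analyses are provided:

* quality filtering — scans with signal strength index <= 60 are dropped
  (strictly greater than the threshold is kept);
* adjusted severity trends — metric ~ severity + age + sex + dbp with a
  patient-level random intercept (linear mixed model; eyes of one patient
  are correlated), severity entered as the numeric ordinal code, reported
  as a slope per severity step with its Wald SE and two-tailed p;
* diagnostic accuracy — ROC curves over diabetic eyes for two contrasts
  (no DR vs any DR; early vs advanced DR), AUC with DeLong 95% CI, and
  the Youden-index cutoff with Wilson-score CIs on sensitivity and
  specificity.

The ROC machinery auto-orients each metric so that AUC >= 0.5 and records
whether a *lower* metric value indicates disease (true for circularity,
densities and CVI; false for FAZ area and perimeter).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "METRICS",
    "GROUP_LABELS",
    "CONTRASTS",
    "TrendResult",
    "DiagnosticResult",
    "ROCCurve",
    "validate_cohort",
    "filter_quality",
    "fit_adjusted_trend",
    "roc_points",
    "auc_with_ci",
    "youden_cutoff",
    "diagnostic_table",
    "trend_table",
]

#: canonical metric column names: SCP then DCP then choroid
METRICS = (
    "faz_area_scp", "faz_perim_scp", "faz_circ_scp", "vd_scp", "vld_scp",
    "faz_area_dcp", "faz_perim_dcp", "faz_circ_dcp", "vd_dcp", "vld_dcp",
    "cvi",
)

GROUP_LABELS = {
    1: "healthy", 2: "no_dr", 3: "mild_npdr",
    4: "moderate_npdr", 5: "severe_npdr", 6: "pdr",
}

#: diagnostic contrasts over diabetic eyes (groups 2-6):
#: negatives, positives by group code
CONTRASTS = {
    "no_dr_vs_dr": ((2,), (3, 4, 5, 6)),
    "early_vs_advanced": ((2, 3, 4), (5, 6)),
}

_REQUIRED_COLUMNS = ("eye_id", "patient_id", "group", "age", "sex", "dbp", "ssi")


def validate_cohort(cohort: pd.DataFrame, metrics: Iterable[str] = ()) -> pd.DataFrame:
    """Schema check; raises with the offending column named."""
    for col in (*_REQUIRED_COLUMNS, *metrics):
        if col not in cohort.columns:
            raise ValueError(f"cohort table is missing required column {col!r}")
    if cohort["eye_id"].duplicated().any():
        dupes = cohort.loc[cohort["eye_id"].duplicated(), "eye_id"].tolist()
        raise ValueError(f"duplicated eye_id values: {dupes[:5]}")
    bad = set(cohort["group"].unique()) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"group codes outside 1-6: {sorted(bad)}")
    return cohort


def filter_quality(cohort: pd.DataFrame, ssi_min: float = 60.0) -> pd.DataFrame:
    """Keep eyes with signal strength index strictly above ``ssi_min``.

    Idempotent; logs how many eyes were removed.
    """
    validate_cohort(cohort)
    kept = cohort[cohort["ssi"] > ssi_min]
    removed = len(cohort) - len(kept)
    if removed:
        logger.info("quality filter removed %d of %d eyes (ssi <= %g)",
                    removed, len(cohort), ssi_min)
    return kept.reset_index(drop=True)


# --- adjusted severity trend ---------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    """Covariate-adjusted severity slope for one metric."""

    metric: str
    beta: float
    se: float
    p_value: float
    n_eyes: int
    n_patients: int
    method: Literal["mixed", "ols"]


def fit_adjusted_trend(cohort: pd.DataFrame, metric: str,
                       include_healthy: bool = True) -> TrendResult:
    """Adjusted linear trend of a metric across severity steps.

    Fits metric ~ severity + age + sex + dbp with a random intercept per
    patient; severity is the ordinal group code treated as numeric.
    Healthy controls (group 1) are included by default so the slope spans
    all six columns of the severity layout; pass ``include_healthy=False``
    to restrict to diabetic eyes.  Falls back to OLS (with a logged
    warning) when the mixed fit is singular or fails to converge.
    """
    import statsmodels.formula.api as smf

    validate_cohort(cohort, metrics=[metric])
    df = cohort if include_healthy else cohort[cohort["group"] >= 2]
    if df["group"].nunique() < 2:
        raise ValueError("trend fit needs at least two severity groups")
    df = df[[metric, "group", "age", "sex", "dbp", "patient_id"]].rename(
        columns={metric: "y"}).copy()
    df["severity"] = df["group"].astype(float)
    formula = "y ~ severity + age + sex + dbp"

    result, method = None, "mixed"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = smf.mixedlm(formula, df, groups=df["patient_id"]).fit(reml=True)
        if np.isfinite(mixed.bse["severity"]) and mixed.bse["severity"] > 0:
            result = mixed
    except (np.linalg.LinAlgError, ValueError):
        result = None
    if result is None:
        logger.warning("mixed model singular or failed for %s; using OLS", metric)
        result, method = smf.ols(formula, df).fit(), "ols"

    return TrendResult(
        metric=metric,
        beta=float(result.params["severity"]),
        se=float(result.bse["severity"]),
        p_value=float(result.pvalues["severity"]),
        n_eyes=len(df),
        n_patients=df["patient_id"].nunique(),
        method=method,
    )


def trend_table(cohort: pd.DataFrame, metrics: Sequence[str] = METRICS,
                include_healthy: bool = True) -> pd.DataFrame:
    """Adjusted trend for each metric, as a tidy table."""
    rows = [fit_adjusted_trend(cohort, m, include_healthy) for m in metrics]
    return pd.DataFrame(
        {"metric": [r.metric for r in rows],
         "adjusted_beta": [r.beta for r in rows],
         "se": [r.se for r in rows],
         "p_value": [r.p_value for r in rows],
         "method": [r.method for r in rows]}
    )


# --- ROC / Youden ---------------------------------------------------------

@dataclass(frozen=True)
class ROCCurve:
    """ROC curve points with its trapezoidal AUC and orientation flag."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    lower_indicates_disease: bool


def _check_two_classes(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be non-empty")
    return scores, labels


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC (P[pos > neg] + 0.5 P[tie]) via midranks."""
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_points(scores: Sequence[float], labels: Sequence[int],
               auto_orient: bool = True) -> ROCCurve:
    """ROC curve sweeping every distinct threshold.

    The curve runs from (0, 0) to (1, 1), monotone in both coordinates,
    with ties grouped so the trapezoidal AUC equals the tie-corrected
    Mann-Whitney statistic U/(n1*n2).  When ``auto_orient`` is on and the
    raw AUC is below 0.5 the score sign is flipped internally and
    ``lower_indicates_disease`` is set.
    """
    scores, labels = _check_two_classes(scores, labels)
    flipped = False
    if auto_orient and _rank_auc(scores, labels) < 0.5:
        scores, flipped = -scores, True

    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    # cumulative counts at each distinct threshold (predict positive: score >= t)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    if flipped:
        thresholds = -thresholds
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                    lower_indicates_disease=flipped)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via structural components."""
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    m, n = len(pos), len(neg)
    # psi(x, y) = 1 if x > y, 0.5 if x == y, 0 otherwise, vectorised
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per-positive components
    v01 = psi.mean(axis=0)  # per-negative components
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def auc_with_ci(scores: Sequence[float], labels: Sequence[int],
                method: Literal["delong", "bootstrap"] = "delong",
                alpha: float = 0.05, n_boot: int = 2000,
                seed: int | None = None,
                auto_orient: bool = True) -> tuple[float, tuple[float, float]]:
    """Trapezoidal AUC with a 95% CI (DeLong by default).

    The CI is clipped to [0, 1]; with perfect separation the DeLong
    variance is zero and the interval collapses onto the AUC.
    """
    scores, labels = _check_two_classes(scores, labels)
    if labels.sum() < 2 or (1 - labels).sum() < 2:
        raise ValueError("each class needs >= 2 members for a CI")
    if auto_orient and _rank_auc(scores, labels) < 0.5:
        scores = -scores
    auc, var = _delong_variance(scores, labels)
    if method == "delong":
        half = norm.ppf(1 - alpha / 2) * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx_pos = np.nonzero(labels == 1)[0]
        idx_neg = np.nonzero(labels == 0)[0]
        stats = np.empty(n_boot)
        for b in range(n_boot):
            take = np.r_[rng.choice(idx_pos, len(idx_pos)), rng.choice(idx_neg, len(idx_neg))]
            stats[b] = _rank_auc(scores[take], labels[take])
        lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return auc, (float(max(lo, 0.0)), float(min(hi, 1.0)))


@dataclass(frozen=True)
class YoudenResult:
    """Youden-index cutoff with its operating characteristics."""

    cutoff: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    j: float
    lower_indicates_disease: bool


def youden_cutoff(scores: Sequence[float], labels: Sequence[int],
                  auto_orient: bool = True, alpha: float = 0.05) -> YoudenResult:
    """Cutoff maximising J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between adjacent distinct score values
    (so a clean class gap yields the gap midpoint).  Ties in J are broken
    toward higher sensitivity, then toward the lower cutoff.  Sensitivity
    and specificity CIs are Wilson score intervals.
    """
    scores, labels = _check_two_classes(scores, labels)
    flipped = False
    if auto_orient and _rank_auc(scores, labels) < 0.5:
        flipped = True
    oriented = -scores if flipped else scores  # disease = high oriented score

    uniq = np.unique(oriented)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if len(uniq) == 1:
        warnings.warn("constant scores: Youden cutoff degenerate, J = 0")
        cands = np.array([uniq[0]])
    else:
        cands = (uniq[:-1] + uniq[1:]) / 2.0

    best = None  # (J, sens, -cutoff_original_scale) maximised lexicographically
    for t in cands:
        pred = oriented > t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        cutoff = -t if flipped else t
        key = (round(j, 12), round(sens, 12), -cutoff)
        if best is None or key > best[0]:
            best = (key, t, sens, spec, j, cutoff)

    _, t, sens, spec, j, cutoff = best
    tp = int(round(sens * n_pos))
    tn = int(round(spec * n_neg))
    sens_ci = proportion_confint(tp, n_pos, alpha=alpha, method="wilson")
    spec_ci = proportion_confint(tn, n_neg, alpha=alpha, method="wilson")
    return YoudenResult(
        cutoff=float(cutoff), sensitivity=float(sens), specificity=float(spec),
        sens_ci=(float(sens_ci[0]), float(sens_ci[1])),
        spec_ci=(float(spec_ci[0]), float(spec_ci[1])),
        j=float(j), lower_indicates_disease=flipped,
    )


# --- diagnostic tables ----------------------------------------------------

@dataclass(frozen=True)
class DiagnosticResult:
    """AUC + Youden operating point for one metric and contrast."""

    metric: str
    contrast: str
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    sens_ci: tuple[float, float]
    specificity: float
    spec_ci: tuple[float, float]
    lower_indicates_disease: bool
    n_negative: int
    n_positive: int


def diagnostic_table(cohort: pd.DataFrame, metric: str, contrast: str,
                     include_healthy: bool = False,
                     ci_method: Literal["delong", "bootstrap"] = "delong",
                     seed: int | None = None) -> DiagnosticResult:
    """ROC/Youden diagnostics for one metric under a severity contrast.

    Contrasts (over diabetic eyes, groups 2-6, unless ``include_healthy``
    adds group 1 to the negatives):

    * ``no_dr_vs_dr`` — negatives: no DR; positives: any DR stage.
    * ``early_vs_advanced`` — negatives: no DR / mild / moderate NPDR;
      positives: severe NPDR / PDR.

    Both eyes of a patient enter as independent units (eye-level analysis;
    a documented simplification).  A constant metric yields AUC 0.5 with a
    warning rather than an error.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(CONTRASTS)}, got {contrast!r}")
    validate_cohort(cohort, metrics=[metric])
    neg_groups, pos_groups = CONTRASTS[contrast]
    if include_healthy:
        neg_groups = (1, *neg_groups)
    df = cohort[cohort["group"].isin(neg_groups + pos_groups)]
    labels = df["group"].isin(pos_groups).to_numpy().astype(int)
    scores = df[metric].to_numpy(dtype=float)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError(f"contrast {contrast!r} has an empty class in this cohort")

    if np.unique(scores).size == 1:
        warnings.warn(f"metric {metric!r} is constant; reporting AUC 0.5")
        auc, ci = 0.5, (0.0, 1.0)
        yr = youden_cutoff(scores, labels, auto_orient=False)
    else:
        auc, ci = auc_with_ci(scores, labels, method=ci_method, seed=seed)
        yr = youden_cutoff(scores, labels)
    return DiagnosticResult(
        metric=metric, contrast=contrast, auc=auc, auc_ci=ci,
        cutoff=yr.cutoff, sensitivity=yr.sensitivity, sens_ci=yr.sens_ci,
        specificity=yr.specificity, spec_ci=yr.spec_ci,
        lower_indicates_disease=yr.lower_indicates_disease,
        n_negative=int((labels == 0).sum()), n_positive=int(labels.sum()),
    )
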