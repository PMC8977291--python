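"""Quantitative diagnostic statistics.

Covers the downstream clinical pipeline: mono-exponential ADC fitting from
DWI series, peak-enhancement measures (ME, Er) from time-intensity curves,
ROC/AUC threshold analysis, integer-percent accuracy from confusion counts,
pooled two-sample t-tests, and a per-cohort summary report.

Conventions
-----------
* ADC is reported in 1e-3 mm^2/s (the physiological scale).
* Accuracy is truncated (not rounded) to an integer percent:
  floor(100 * n_correct / total).  46/49 -> 93, 41/49 -> 83.
* ROC positivity direction is a caller parameter; ``"greater"`` means
  higher scores are called positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import DWISeries, TimeIntensityCurve

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["patient_id", "group", "adc", "correct"]


# --------------------------------------------------------------------------
# result types
# --------------------------------------------------------------------------

@dataclass
class ADCResult:
    adc: float          # 1e-3 mm^2/s
    s0_fit: float
    r_squared: float

    def __post_init__(self):
        if not np.isfinite(self.adc):
            raise ValueError("adc must be finite")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class EnhancementResult:
    me: float   # baseline-corrected peak enhancement
    er: float   # peak / baseline ratio

    def __post_init__(self):
        if self.er < 0:
            raise ValueError("er must be nonnegative")


@dataclass(frozen=True)
class ConfusionCounts:
    n_correct: int
    n_error: int

    def __post_init__(self):
        if self.n_correct < 0 or self.n_error < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_correct + self.n_error < 1:
            raise ValueError("need at least one case")


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    chosen_threshold: float
    sens_at_chosen: float
    spec_at_chosen: float
    fixed_threshold: float | None = None
    sens_at_fixed: float | None = None
    spec_at_fixed: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


# --------------------------------------------------------------------------
# ADC
# --------------------------------------------------------------------------

def fit_adc(series: DWISeries) -> ADCResult:
    """Least-squares line fit of ln S(b) versus b; ADC = -slope * 1e3.

    Exact inverse of the noiseless mono-exponential simulator.  Rejects any
    nonpositive signal (log undefined).
    """
    b = series.b_values
    s = series.signals
    if np.any(s <= 0):
        raise ValueError("all signals must be positive for the log-linear fit")
    logs = np.log(s)
    slope, intercept = np.polyfit(b, logs, 1)
    pred = slope * b + intercept
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    ss_res = float(np.sum((logs - pred) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return ADCResult(adc=float(-slope * 1e3), s0_fit=float(np.exp(intercept)),
                     r_squared=r2)


# --------------------------------------------------------------------------
# enhancement
# --------------------------------------------------------------------------

def compute_me_er(tic: TimeIntensityCurve, baseline_correct: bool = True,
                  drift_correct: bool = True) -> EnhancementResult:
    """Peak enhancement measures from a time-intensity curve.

    Er is the ratio of the post-baseline peak to the baseline signal.  ME is
    the peak of the corrected curve: the baseline offset is subtracted and,
    when at least two pre-peak baseline frames exist, a linear drift fitted
    on them is removed as a second correction (both steps logged and
    switchable).
    """
    base = float(tic.signal[tic.baseline_index])
    if base <= 0:
        raise ValueError("baseline signal must be positive")
    post = tic.signal[tic.baseline_index:]
    peak = float(post.max())
    er = peak / base

    corrected = tic.signal.astype(float).copy()
    if baseline_correct:
        corrected -= base
        logger.info("ME correction 1: baseline offset %g subtracted", base)
    if drift_correct and tic.baseline_index >= 1:
        idx = np.arange(tic.baseline_index + 1)
        slope, intercept = np.polyfit(tic.times[idx], corrected[idx], 1)
        corrected -= slope * tic.times + intercept
        logger.info("ME correction 2: linear drift slope %g removed", slope)
    me = float(corrected[tic.baseline_index:].max())
    return EnhancementResult(me=me, er=er)


# --------------------------------------------------------------------------
# ROC
# --------------------------------------------------------------------------

def roc_analysis(table: pd.DataFrame, positive_group: str = "algorithm",
                 direction: str = "greater",
                 fixed_threshold: float | None = None,
                 score_column: str = "adc") -> ROCCurve:
    """Threshold-sweep ROC over the observed score midpoints.

    AUC by the trapezoid rule over (FPR, TPR); the operating threshold
    maximizes Youden's J = sensitivity + specificity - 1.  Sens/spec at a
    caller-specified ``fixed_threshold`` are reported alongside.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    groups = table["group"].unique()
    if positive_group not in groups or len(groups) < 2:
        raise ValueError("table must contain the positive group and at least "
                         "one other group")
    scores = table[score_column].to_numpy(dtype=float)
    pos = (table["group"] == positive_group).to_numpy()
    s_pos, s_neg = scores[pos], scores[~pos]

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))

    def call_positive(thr):
        return (scores > thr) if direction == "greater" else (scores < thr)

    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        called = call_positive(thr)
        sens[i] = called[pos].mean()
        spec[i] = 1.0 - called[~pos].mean()

    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # vertical segments traversed upward
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec - 1.0
    best = int(np.argmax(j))
    roc = ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                   auc=auc, chosen_threshold=float(thresholds[best]),
                   sens_at_chosen=float(sens[best]),
                   spec_at_chosen=float(spec[best]))
    if fixed_threshold is not None:
        called = call_positive(fixed_threshold)
        roc.fixed_threshold = float(fixed_threshold)
        roc.sens_at_fixed = float(called[pos].mean())
        roc.spec_at_fixed = float(1.0 - called[~pos].mean())
    return roc


# --------------------------------------------------------------------------
# accuracy / tests
# --------------------------------------------------------------------------

def accuracy_from_counts(counts: ConfusionCounts) -> int:
    """Integer-percent accuracy, truncated toward zero.

    Truncation (not rounding) is deliberate: 46/49 = 93.88% reports as 93
    and 41/49 = 83.67% as 83.
    """
    total = counts.n_correct + counts.n_error
    return int(100 * counts.n_correct // total)


def two_sample_t(a, b) -> tuple[float, int, float]:
    """Pooled-variance independent two-sample t-test (two-sided).

    Each argument is either a sample array or a ``(mean, sd, n)`` summary
    triple; the two modes agree exactly on matched data.
    Returns ``(t, df, p)`` with ``t`` computed as mean(a) - mean(b).
    """
    def as_stats(x):
        if isinstance(x, tuple) and len(x) == 3:
            mean, sd, n = x
            return float(mean), float(sd), int(n)
        arr = np.asarray(x, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least 2 observations per group")
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    m1, s1, n1 = as_stats(a)
    m2, s2, n2 = as_stats(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance: t undefined")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


# --------------------------------------------------------------------------
# cohort report
# --------------------------------------------------------------------------

@dataclass
class CohortReport:
    group_stats: pd.DataFrame
    t_statistic: float
    t_df: int
    t_pvalue: float
    roc: ROCCurve

    def to_text(self) -> str:
        lines = [self.group_stats.to_string(index=False),
                 f"t = {self.t_statistic:.3f}, df = {self.t_df}, "
                 f"p = {self.t_pvalue:.3g}",
                 f"AUC = {self.roc.auc:.3f}"]
        if self.roc.fixed_threshold is not None:
            lines.append(
                f"at threshold {self.roc.fixed_threshold:g}: "
                f"sens = {100 * self.roc.sens_at_fixed:.2f}%, "
                f"spec = {100 * self.roc.spec_at_fixed:.2f}%")
        return "\n".join(lines)


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort schema; raises naming missing columns / bad rows."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"cohort table missing columns {missing}; expected header "
            f"{','.join(COHORT_COLUMNS)}")
    adc = pd.to_numeric(table["adc"], errors="coerce")
    bad = table.index[adc.isna() | (adc <= 0)].tolist()
    if bad:
        raise ValueError(f"invalid adc values at rows {bad}")
    return table


def cohort_report(table: pd.DataFrame, adc_threshold: float = 1.25,
                  positive_group: str = "algorithm") -> CohortReport:
    """Per-group ADC summaries, pooled t-test, ROC with AUC and sens/spec at
    ``adc_threshold``, and per-group truncated accuracy."""
    validate_cohort_table(table)
    stats_rows = []
    samples = {}
    for name, g in table.groupby("group", sort=True):
        adc = g["adc"].to_numpy(dtype=float)
        samples[name] = adc
        counts = ConfusionCounts(int(g["correct"].sum()),
                                 int((1 - g["correct"]).sum()))
        stats_rows.append({
            "group": name, "n": len(g),
            "adc_mean": adc.mean(), "adc_sd": adc.std(ddof=1),
            "adc_min": adc.min(), "adc_max": adc.max(),
            "accuracy_pct": accuracy_from_counts(counts),
        })
    if len(samples) != 2:
        raise ValueError("cohort report needs exactly two groups")
    others = [n for n in samples if n != positive_group]
    t, df, p = two_sample_t(samples[positive_group], samples[others[0]])
    roc = roc_analysis(table, positive_group=positive_group,
                       fixed_threshold=adc_threshold)
    return CohortReport(group_stats=pd.DataFrame(stats_rows),
                        t_statistic=t, t_df=df, t_pvalue=p, roc=roc)
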