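"""Confusion-matrix metrics and subsampling confidence intervals.

Tile-level performance is summarised by the standard two-class rates
(sensitivity TPR, specificity TNR, predictive values PPV / NPV), the
Matthews correlation coefficient and Cohen's kappa.  Confidence intervals
follow the subsample scheme: the metric is recomputed on ``n`` random draws
of a fraction of the test tiles without replacement, and the interval is

    [M - z* sigma / sqrt(n),  M + z* sigma / sqrt(n)]

with M and sigma the mean and standard deviation of the resampled metric
values and z* = 1.96 for 95% confidence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

Z_STAR_95 = 1.96

METRIC_NAMES = ("TPR", "TNR", "PPV", "NPV", "MCC", "kappa")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ConfidenceInterval:
    M: float
    sigma: float
    n: int
    low: float
    high: float
    z_star: float = Z_STAR_95
    seed: Optional[int] = None
    skipped_resamples: int = 0


@dataclass
class MetricReport:
    """Metric values, each possibly None when its denominator vanishes."""

    metrics: Dict[str, Optional[float]]
    counts: ConfusionCounts
    intervals: Dict[str, ConfidenceInterval] = field(default_factory=dict)

    def __getitem__(self, name: str) -> Optional[float]:
        return self.metrics[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in METRIC_NAMES:
            ci = self.intervals.get(name)
            rows.append({
                "metric": name,
                "value": self.metrics.get(name),
                "ci_low": ci.low if ci else None,
                "ci_high": ci.high if ci else None,
                "ci_n": ci.n if ci else None,
                "seed": ci.seed if ci else None,
            })
        return pd.DataFrame(rows)


def count_confusion(decisions: pd.DataFrame,
                    truth_column: str = "label",
                    predicted_column: str = "predicted",
                    positive: str = "polyp") -> ConfusionCounts:
    """Tally a decisions table into TP / TN / FP / FN."""
    truth = decisions[truth_column].astype(str) == positive
    pred = decisions[predicted_column].astype(str) == positive
    return ConfusionCounts(
        TP=int((truth & pred).sum()),
        TN=int((~truth & ~pred).sum()),
        FP=int((~truth & pred).sum()),
        FN=int((truth & ~pred).sum()),
    )


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_metrics(c: ConfusionCounts) -> MetricReport:
    """TPR, TNR, PPV, NPV, MCC and Cohen's kappa from raw counts.

    Metrics whose denominator is zero are reported as None (undefined), not
    coerced to 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    metrics: Dict[str, Optional[float]] = {
        "TPR": _safe_div(tp, tp + fn),
        "TNR": _safe_div(tn, tn + fp),
        "PPV": _safe_div(tp, tp + fp),
        "NPV": _safe_div(tn, tn + fn),
    }
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    metrics["MCC"] = (tp * tn - fp * fn) / math.sqrt(mcc_den) \
        if mcc_den > 0 else None
    total = tp + tn + fp + fn
    p_o = (tp + tn) / total
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / total ** 2
    metrics["kappa"] = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else None
    return MetricReport(metrics=metrics, counts=c)


def interval_from_moments(M: float, sigma: float, n: int,
                          z_star: float = Z_STAR_95) -> ConfidenceInterval:
    """Interval M +/- z* sigma / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    half = z_star * sigma / math.sqrt(n)
    return ConfidenceInterval(M=M, sigma=sigma, n=n,
                              low=M - half, high=M + half, z_star=z_star)


def bootstrap_ci(decisions: pd.DataFrame, metric: str,
                 frac: float = 0.8, n: int = 100, seed: int = 0,
                 replace: bool = False,
                 truth_column: str = "label",
                 predicted_column: str = "predicted") -> ConfidenceInterval:
    """Subsampling confidence interval for one metric of a decisions table.

    Draws ``n`` resamples of ``floor(frac * N)`` rows (without replacement
    by default) with a seeded generator, recomputes the metric on each, and
    builds the interval from the resample mean and standard deviation.
    Resamples on which the metric is undefined (a class missing) are skipped
    with a warning and counted in the result.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    if n < 2:
        raise ValueError("need at least 2 resamples")
    rng = np.random.default_rng(seed)
    N = len(decisions)
    m = int(frac * N)
    if m < 1:
        raise ValueError("resample size is zero; increase frac")
    values = []
    skipped = 0
    for _ in range(n):
        idx = rng.choice(N, size=m, replace=replace)
        sub = decisions.iloc[idx]
        val = confusion_metrics(count_confusion(
            sub, truth_column, predicted_column))[metric]
        if val is None:
            skipped += 1
            continue
        values.append(val)
    if skipped:
        warnings.warn(f"{skipped}/{n} resamples had an undefined {metric} "
                      "and were skipped")
    if not values:
        raise ValueError(f"metric {metric} undefined on every resample")
    arr = np.asarray(values)
    M = float(arr.mean())
    sigma = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    ci = interval_from_moments(M, sigma, n)
    return ConfidenceInterval(M=M, sigma=sigma, n=n, low=ci.low, high=ci.high,
                              seed=seed, skipped_resamples=skipped)


def evaluate_decisions(decisions: pd.DataFrame,
                       ci: bool = True, frac: float = 0.8, n: int = 100,
                       seed: int = 0) -> MetricReport:
    """Full metric report (optionally with CIs) for a decisions table."""
    counts = count_confusion(decisions)
    report = confusion_metrics(counts)
    if ci:
        for name in METRIC_NAMES:
            if report[name] is None:
                continue
            report.intervals[name] = bootstrap_ci(
                decisions, name, frac=frac, n=n, seed=seed)
    return report
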