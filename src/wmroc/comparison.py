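"""Model-comparison metrics and cohort-level inference.

AIC = 2k + 2*NLL and BIC = k*ln(n) + 2*NLL, with n the participant's total
number of Bernoulli trials.  Matched model pairs (equal parameter counts) may
be compared on raw NLL, where AIC/BIC/NLL rankings coincide.  Cohort-level
inference is a two-sided one-sample t test of the per-participant metric
differences against zero, at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data import ValidationError
from .fitting import FitResult

TIE_EPS = 1e-9
ALPHA = 0.05
METRICS = ("aic", "bic", "nll")


def aic(nll: float, k: int) -> float:
    return 2.0 * k + 2.0 * nll


def bic(nll: float, k: int, n_trials: int) -> float:
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    return k * float(np.log(n_trials)) + 2.0 * nll


@dataclass(frozen=True)
class ComparisonRow:
    """One participant's metric difference for one model pair (a minus b)."""

    participant_id: str
    spec_a: "object"
    spec_b: "object"
    metric_name: str
    delta_metric: float
    winner: str  # "a" | "b" | "tie"


@dataclass(frozen=True)
class CohortComparison:
    """Cohort-level evidence for one model pair under one metric."""

    rows: tuple[ComparisonRow, ...]
    summed_delta: float
    t_statistic: float
    df: int
    p_value: float
    decision: str  # "favors_a" | "favors_b" | "inconclusive"


def compare_pair(fit_a: FitResult, fit_b: FitResult, metric_name: str,
                 participant_id: str = "") -> ComparisonRow:
    """Metric difference (a minus b); negative favors a.

    Raw-NLL comparison is only meaningful for equal parameter counts and is
    rejected otherwise.
    """
    metric_name = metric_name.lower()
    if metric_name not in METRICS:
        raise ValueError(f"unknown metric {metric_name!r}")
    if metric_name == "nll" and fit_a.k != fit_b.k:
        raise ValidationError(
            f"NLL comparison requires equal parameter counts (got {fit_a.k} vs {fit_b.k})"
        )
    delta = fit_a.metric(metric_name) - fit_b.metric(metric_name)
    if abs(delta) <= TIE_EPS:
        winner = "tie"
    else:
        winner = "a" if delta < 0 else "b"
    return ComparisonRow(
        participant_id=participant_id,
        spec_a=fit_a.spec,
        spec_b=fit_b.spec,
        metric_name=metric_name,
        delta_metric=float(delta),
        winner=winner,
    )


def _one_sample_t(deltas: np.ndarray) -> tuple[float, int, float]:
    """t statistic, df, and two-sided p for mean(deltas) == 0.

    A zero-variance sample has an undefined t; the sign of the (common) value
    decides: p = 0 when the mean is nonzero, p = 1 when all deltas are zero.
    """
    n = len(deltas)
    df = n - 1
    sd = float(np.std(deltas, ddof=1))
    mean = float(np.mean(deltas))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(mean)) * np.inf, df, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def cohort_inference(rows: Sequence[ComparisonRow], alpha: float = ALPHA) -> CohortComparison:
    """Two-sided one-sample t test of the metric deltas against zero."""
    if len(rows) < 2:
        raise ValidationError("cohort inference requires >= 2 participants")
    deltas = np.array([r.delta_metric for r in rows], dtype=float)
    t, df, p = _one_sample_t(deltas)
    mean = float(np.mean(deltas))
    if p < alpha and mean != 0.0:
        decision = "favors_a" if mean < 0 else "favors_b"
    else:
        decision = "inconclusive"
    return CohortComparison(
        rows=tuple(rows),
        summed_delta=float(np.sum(deltas)),
        t_statistic=t,
        df=df,
        p_value=p,
        decision=decision,
    )
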