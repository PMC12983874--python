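"""Model-assessment metrics for misclassification estimates.

The central quantity is the average absolute loss of model-based rates
against observed row-conditional rates,

    loss = sum_{s,i,j} |est[s,i,j] - obs[s,i,j]| / Obs,

summed over cells whose (country, reference cause) row is observed, with Obs
the number of such cells.  Uncertainty quantification is scored with the
proper (Winkler) interval score at level alpha, and two models are compared
by percent loss reduction and the share of cells with strictly smaller
absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import ObservedRates, ValidationError


@dataclass(frozen=True)
class ModelComparison:
    """Pairwise model comparison (model A vs reference model B)."""

    loss_model_a: float
    loss_model_b: float
    percent_reduction: float       # 100 * (loss_b - loss_a) / loss_b
    share_cells_improved: float    # strict inequality; ties not improved
    interval_score_a: float        # averages over observed cells
    interval_score_b: float
    interval_score_reduction: float
    share_intervals_improved: float


def _observed_cells(est: np.ndarray, obs: ObservedRates):
    est = np.asarray(est, dtype=float)
    if est.shape != obs.rates.shape:
        raise ValidationError(
            f"estimate shape {est.shape} does not match observed rates "
            f"{obs.rates.shape}")
    cell_mask = np.repeat(obs.mask[:, :, None], obs.rates.shape[2], axis=2)
    if not cell_mask.any():
        raise ValidationError("no observed cells")
    return est[cell_mask], obs.rates[cell_mask], cell_mask


def average_absolute_loss(est: np.ndarray, obs: ObservedRates) -> float:
    """Mean absolute deviation from observed rates over observed cells.

    ``est`` is an (S, C, C) stack of model-based matrices aligned with the
    observed-rate container.  A cell (s, i, j) enters when row (s, i) has at
    least one observed death; the divisor Obs is the number of such cells.
    """
    e, o, _ = _observed_cells(est, obs)
    return float(np.abs(e - o).mean())


def interval_score(lower, upper, x, alpha: float = 0.05):
    """Proper (Winkler) interval score; lower is better.

    width + (2/alpha) * undershoot + (2/alpha) * overshoot.  Accepts scalars
    or broadcastable arrays.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    x = np.asarray(x, dtype=float)
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if np.any(lower > upper):
        raise ValidationError("interval lower bound exceeds upper bound")
    score = ((upper - lower)
             + (2.0 / alpha) * np.maximum(lower - x, 0.0)
             + (2.0 / alpha) * np.maximum(x - upper, 0.0))
    return float(score) if score.ndim == 0 else score


def compare_models(est_a: np.ndarray, est_b: np.ndarray, obs: ObservedRates,
                   intervals_a: Optional[tuple] = None,
                   intervals_b: Optional[tuple] = None,
                   alpha: float = 0.05) -> ModelComparison:
    """Compare two misclassification models against observed rates.

    ``intervals_*`` are optional (lower, upper) pairs of (S, C, C) arrays of
    credible bounds; when omitted the interval summaries are NaN.
    percent_reduction is positive when model A is closer to the observed
    rates than model B.
    """
    ea, o, mask = _observed_cells(est_a, obs)
    eb, _, _ = _observed_cells(est_b, obs)
    err_a = np.abs(ea - o)
    err_b = np.abs(eb - o)
    loss_a = float(err_a.mean())
    loss_b = float(err_b.mean())
    pct = 100.0 * (loss_b - loss_a) / loss_b if loss_b > 0 else 0.0
    share = float(np.mean(err_a < err_b))

    is_a = is_b = is_red = share_is = float("nan")
    if intervals_a is not None and intervals_b is not None:
        sa = interval_score(np.asarray(intervals_a[0])[mask],
                            np.asarray(intervals_a[1])[mask], o, alpha)
        sb = interval_score(np.asarray(intervals_b[0])[mask],
                            np.asarray(intervals_b[1])[mask], o, alpha)
        is_a = float(sa.mean())
        is_b = float(sb.mean())
        is_red = 100.0 * (is_b - is_a) / is_b if is_b > 0 else 0.0
        share_is = float(np.mean(sa < sb))
    return ModelComparison(loss_a, loss_b, pct, share, is_a, is_b,
                           is_red, share_is)


def ci_coverage(replicate_intervals, truths) -> float:
    """Fraction of replicates whose interval contains the truth.

    ``replicate_intervals`` is a sequence of (lower, upper) pairs aligned
    with ``truths``.
    """
    intervals = list(replicate_intervals)
    truths = np.asarray(truths, dtype=float)
    if len(intervals) == 0:
        raise ValidationError("no replicates")
    if len(intervals) != truths.shape[0]:
        raise ValidationError("intervals and truths differ in length")
    lo = np.asarray([iv[0] for iv in intervals], dtype=float)
    hi = np.asarray([iv[1] for iv in intervals], dtype=float)
    return float(np.mean((truths >= lo) & (truths <= hi)))


def comparison_report(est_a: np.ndarray, est_b: np.ndarray,
                      obs: ObservedRates,
                      intervals_a: Optional[tuple] = None,
                      intervals_b: Optional[tuple] = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Tidy per-cell report over observed cells."""
    labels = obs.cause_map.labels
    rows = []
    for s, country in enumerate(obs.countries):
        for i in np.flatnonzero(obs.mask[s]):
            for j in range(len(labels)):
                rec = {
                    "country": country,
                    "ref_cause": labels[i],
                    "va_cause": labels[j],
                    "observed_rate": obs.rates[s, i, j],
                    "est_a": est_a[s, i, j],
                    "est_b": est_b[s, i, j],
                }
                rec["abs_err_a"] = abs(rec["est_a"] - rec["observed_rate"])
                rec["abs_err_b"] = abs(rec["est_b"] - rec["observed_rate"])
                if intervals_a is not None:
                    rec["interval_score_a"] = interval_score(
                        intervals_a[0][s, i, j], intervals_a[1][s, i, j],
                        obs.rates[s, i, j], alpha)
                if intervals_b is not None:
                    rec["interval_score_b"] = interval_score(
                        intervals_b[0][s, i, j], intervals_b[1][s, i, j],
                        obs.rates[s, i, j], alpha)
                rows.append(rec)
    return pd.DataFrame(rows)
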