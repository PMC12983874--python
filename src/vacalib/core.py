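"""Core containers for cause-of-death misclassification analysis.

Everything downstream (misclassification modelling, calibration, evaluation)
shares these types: an ordered cause map, paired (reference cause, VA cause)
count matrices per country, row-stochastic misclassification matrices, VA-only
count vectors, and posterior CSMF summaries.  The cause-map order is the
canonical axis order for every matrix and vector in the package; serialized
artifacts always carry the cause list so axes cannot silently drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

ROW_SUM_TOL = 1e-9


class VacalibError(Exception):
    """Base class for package errors."""


class ValidationError(VacalibError):
    """Invalid input data or configuration."""


class SamplerError(VacalibError):
    """MCMC failure that cannot be downgraded to a warning."""


# ---------------------------------------------------------------------------
# cause maps
# ---------------------------------------------------------------------------

#: Broad neonatal (0-27 days) cause grouping used in under-five VA surveillance.
NEONATE6_LABELS = (
    "congenital_malformation",
    "pneumonia",
    "sepsis_meningitis_inf",
    "ipre",
    "prematurity",
    "other",
)

#: Broad child (1-59 months) cause grouping.
CHILD9_LABELS = (
    "malaria",
    "pneumonia",
    "diarrhea",
    "severe_malnutrition",
    "hiv",
    "injury",
    "neonatal_causes",
    "other_infections",
    "other",
)


@dataclass(frozen=True)
class CauseMap:
    """Ordered list of cause labels defining the canonical axis order.

    Parameters
    ----------
    labels
        Unique cause names; their order fixes rows/columns of every matrix.
    age_group
        Tag such as ``"neonate"``, ``"child"`` or ``"custom"``.
    other_label
        Name of the residual 'other' category, if the map has one.  The
        'other' cause is never calibrated and is removed (with row
        renormalization) before calibration.
    """

    labels: tuple[str, ...]
    age_group: str = "custom"
    other_label: Optional[str] = None

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValidationError("cause map needs at least 2 labels")
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate cause labels in {labels}")
        if self.other_label is not None and self.other_label not in labels:
            raise ValidationError(
                f"other_label {self.other_label!r} not among labels"
            )

    @property
    def n_causes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown cause label {label!r}") from None

    def without_other(self) -> "CauseMap":
        """The map with the 'other' category removed."""
        if self.other_label is None:
            return self
        labels = tuple(l for l in self.labels if l != self.other_label)
        return CauseMap(labels, self.age_group, None)

    def to_dict(self) -> dict:
        return {
            "age_group": self.age_group,
            "labels": list(self.labels),
            "other_label": self.other_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CauseMap":
        return cls(tuple(d["labels"]), d.get("age_group", "custom"),
                   d.get("other_label"))


def make_cause_map(labels: Sequence[str], age_group: str = "custom",
                   other_label: Optional[str] = None) -> CauseMap:
    """Build a validated :class:`CauseMap`."""
    return CauseMap(tuple(labels), age_group, other_label)


_PRESETS = {
    "neonate6": CauseMap(NEONATE6_LABELS, "neonate", "other"),
    "child9": CauseMap(CHILD9_LABELS, "child", "other"),
}


def cause_map_preset(name: str) -> CauseMap:
    """Return a packaged preset: ``"neonate6"`` (6 causes) or ``"child9"`` (9)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# count containers
# ---------------------------------------------------------------------------

def _as_count_array(x, shape, what: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.shape != shape:
        raise ValidationError(f"{what}: expected shape {shape}, got {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"{what}: counts must be integers")
        arr = np.round(arr).astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValidationError(f"{what}: counts must be nonnegative")
    return arr


@dataclass(frozen=True)
class PairedCauseCounts:
    """Per-country C x C contingency counts of (reference cause, VA cause).

    ``counts[s, i, j]`` is the number of deaths in country ``s`` with
    reference cause ``i`` that the algorithm classified as cause ``j``.
    """

    cause_map: CauseMap
    countries: tuple[str, ...]
    counts: np.ndarray  # (S, C, C) int64

    def __post_init__(self) -> None:
        countries = tuple(self.countries)
        object.__setattr__(self, "countries", countries)
        if len(set(countries)) != len(countries):
            raise ValidationError("duplicate country names")
        C = self.cause_map.n_causes
        arr = _as_count_array(self.counts, (len(countries), C, C),
                              "paired counts")
        object.__setattr__(self, "counts", arr)

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    def pooled(self) -> np.ndarray:
        """Counts summed over countries, shape (C, C)."""
        return self.counts.sum(axis=0)

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MisclassMatrix:
    """Row-stochastic misclassification matrix Phi.

    Entry (i, j) is the probability the algorithm assigns cause j when the
    reference cause is i; the diagonal entries are sensitivities and the
    off-diagonal entries false-negative rates.
    """

    cause_map: CauseMap
    values: np.ndarray  # (C, C) float

    def __post_init__(self) -> None:
        C = self.cause_map.n_causes
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (C, C):
            raise ValidationError(
                f"misclassification matrix: expected ({C}, {C}), got {vals.shape}"
            )
        if (vals < -ROW_SUM_TOL).any() or (vals > 1 + ROW_SUM_TOL).any():
            raise ValidationError("matrix entries must lie in [0, 1]")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9, rtol=0):
            raise ValidationError("matrix rows must each sum to 1")
        object.__setattr__(self, "values", vals)

    @property
    def sensitivities(self) -> np.ndarray:
        return np.diag(self.values)


@dataclass(frozen=True)
class ObservedRates:
    """Empirical row-conditional misclassification rates per country.

    A row (country, reference cause) is "observed" when at least one paired
    death carries that reference cause there; unobserved rows are masked out
    and carry NaN.
    """

    cause_map: CauseMap
    countries: tuple[str, ...]
    rates: np.ndarray  # (S, C, C), NaN on masked-out rows
    mask: np.ndarray   # (S, C) bool, True where row observed

    def __post_init__(self) -> None:
        object.__setattr__(self, "countries", tuple(self.countries))
        rates = np.asarray(self.rates, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        S, C = len(self.countries), self.cause_map.n_causes
        if rates.shape != (S, C, C) or mask.shape != (S, C):
            raise ValidationError("observed-rate arrays have wrong shape")
        sums = np.nansum(rates, axis=2)
        if not np.allclose(sums[mask], 1.0, atol=1e-9, rtol=0):
            raise ValidationError("observed rows must sum to 1")
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "mask", mask)

    @property
    def n_observed_cells(self) -> int:
        return int(self.mask.sum()) * self.cause_map.n_causes


@dataclass(frozen=True)
class VAOnlyCounts:
    """Counts of VA-predicted causes for one algorithm (no reference cause)."""

    cause_map: CauseMap
    algorithm: str
    counts: np.ndarray  # (C,) int64

    def __post_init__(self) -> None:
        C = self.cause_map.n_causes
        arr = _as_count_array(self.counts, (C,), f"VA counts [{self.algorithm}]")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def drop_other(self) -> "VAOnlyCounts":
        """Exclude deaths VA-classified as 'other' (those are not calibrated)."""
        cm = self.cause_map
        if cm.other_label is None:
            return self
        keep = [k for k, l in enumerate(cm.labels) if l != cm.other_label]
        return VAOnlyCounts(cm.without_other(), self.algorithm,
                            self.counts[keep])


@dataclass(frozen=True)
class CSMFEstimate:
    """Posterior summary of a cause-specific mortality fraction vector."""

    cause_map: CauseMap
    mean: np.ndarray             # (C,)
    draws: np.ndarray            # (n_draws, C); may be empty (0, C)
    lower95: np.ndarray          # (C,)
    upper95: np.ndarray          # (C,)

    def __post_init__(self) -> None:
        C = self.cause_map.n_causes
        mean = np.asarray(self.mean, dtype=float)
        draws = np.asarray(self.draws, dtype=float).reshape(-1, C)
        lo = np.asarray(self.lower95, dtype=float)
        hi = np.asarray(self.upper95, dtype=float)
        if mean.shape != (C,) or lo.shape != (C,) or hi.shape != (C,):
            raise ValidationError("CSMF summary vectors have wrong shape")
        if abs(mean.sum() - 1.0) > 1e-9:
            raise ValidationError("CSMF mean must sum to 1")
        if draws.size and not np.allclose(draws.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("CSMF draws must each sum to 1")
        if (lo > hi + 1e-12).any() or (lo < -1e-12).any() or (hi > 1 + 1e-12).any():
            raise ValidationError("invalid credible bounds")
        for name, v in (("mean", mean), ("draws", draws),
                        ("lower95", lo), ("upper95", hi)):
            object.__setattr__(self, name, v)

    @classmethod
    def from_draws(cls, cause_map: CauseMap, draws: np.ndarray) -> "CSMFEstimate":
        draws = np.asarray(draws, dtype=float)
        mean = draws.mean(axis=0)
        mean = mean / mean.sum()
        lo = np.quantile(draws, 0.025, axis=0)
        hi = np.quantile(draws, 0.975, axis=0)
        return cls(cause_map, mean, draws, lo, hi)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def observed_rates(data: PairedCauseCounts) -> ObservedRates:
    """Row-conditional empirical rates per country.

    For country s and reference cause i with total n_si >= 1,
    ``rate[s, i, j] = counts[s, i, j] / n_si``; rows with no deaths are
    masked out (NaN).
    """
    totals = data.counts.sum(axis=2)  # (S, C)
    mask = totals >= 1
    rates = np.full(data.counts.shape, np.nan)
    with np.errstate(invalid="ignore"):
        rates[mask] = data.counts[mask] / totals[mask][:, None]
    return ObservedRates(data.cause_map, data.countries, rates, mask)


def uncalibrated_csmf(va: VAOnlyCounts) -> CSMFEstimate:
    """Raw CSMF estimate q_hat_j = x_j / n with conjugate uncertainty.

    The point estimate is the empirical VA-predicted fraction.  Uncertainty
    comes from the multinomial posterior under a flat Dirichlet(1, ..., 1)
    prior: each marginal is Beta(1 + x_j, C - 1 + n - x_j), and the bounds
    are equal-tailed 95% quantiles.  No draws are stored.
    """
    x = va.counts
    n = va.total
    if n == 0:
        raise ValidationError("cannot estimate a CSMF from zero VA records")
    C = va.cause_map.n_causes
    q = x / n
    a = 1.0 + x
    b = (C + n) - a
    lo = stats.beta.ppf(0.025, a, b)
    hi = stats.beta.ppf(0.975, a, b)
    return CSMFEstimate(va.cause_map, q, np.empty((0, C)), lo, hi)


def drop_other_renormalize(m: MisclassMatrix) -> MisclassMatrix:
    """Remove the 'other' row/column of Phi and renormalize remaining rows.

    Calibration is not performed for the residual 'other' category, so its
    row and column are deleted and each remaining row is rescaled to sum to
    one, keeping the matrix a valid conditional distribution over the C-1
    retained causes.
    """
    cm = m.cause_map
    if cm.other_label is None:
        raise ValidationError("cause map has no 'other' category to drop")
    k = cm.index(cm.other_label)
    keep = [i for i in range(cm.n_causes) if i != k]
    sub = m.values[np.ix_(keep, keep)]
    row_sums = sub.sum(axis=1)
    if (row_sums <= ROW_SUM_TOL).any():
        bad = np.asarray(keep)[row_sums <= ROW_SUM_TOL]
        labels = [cm.labels[i] for i in bad]
        raise ValidationError(
            f"rows {labels} place all mass on 'other'; renormalization undefined"
        )
    return MisclassMatrix(cm.without_other(), sub / row_sums[:, None])


def drop_other_renormalize_draws(draws: np.ndarray, cause_map: CauseMap
                                 ) -> np.ndarray:
    """Vectorized :func:`drop_other_renormalize` over a stack of draws."""
    if cause_map.other_label is None:
        return np.asarray(draws, dtype=float)
    k = cause_map.index(cause_map.other_label)
    keep = [i for i in range(cause_map.n_causes) if i != k]
    sub = np.asarray(draws, dtype=float)[:, keep, :][:, :, keep]
    sums = sub.sum(axis=2)
    if (sums <= ROW_SUM_TOL).any():
        raise ValidationError("a draw places all row mass on 'other'")
    return sub / sums[..., None]


def warn(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=2)
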