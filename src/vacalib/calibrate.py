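"""Modular VA-calibration: recover true CSMFs from VA-only counts.

VA-predicted cause fractions q relate to the true cause-specific mortality
fractions p through the calibration equation ``q_j = sum_i phi_ij p_i``,
where Phi is the algorithm's misclassification matrix.  Calibration inverts
this relationship in a Bayesian model,

    p ~ Dirichlet(delta, ..., delta)
    Phi ~ informative prior (from stored misclassification posteriors)
    x ~ Multinomial(n, Phi^T p),

so that no access to the paired reference/VA data is needed — only the
stored misclassification estimates.  Recovery is well posed provided Phi is
non-singular; the condition number of the posterior-mean Phi^T is reported
and gated.

Sampling is an exact data-augmentation Gibbs scheme.  Each VA-classified
death with predicted cause j is assigned a latent true cause i with
probability proportional to ``p_i phi_ij``; given the latent true-cause
counts, p is conjugate Dirichlet, and so is each row of Phi under the
``dirichlet_rows`` prior.  Stored-draw priors (``draw_resampling``) are
updated by an independence Metropolis step that proposes uniformly from the
stored draws, preserving cross-cell dependence.

The residual 'other' cause is never calibrated: deaths VA-classified as
'other' are excluded and Phi is row-renormalized over the remaining causes
before inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core import (
    CauseMap,
    CSMFEstimate,
    MisclassMatrix,
    ValidationError,
    VAOnlyCounts,
    drop_other_renormalize_draws,
    uncalibrated_csmf,
)

PRIOR_FORMS = ("dirichlet_rows", "draw_resampling", "point_mass")

ALPHA0_MIN = 1.0
ALPHA0_MAX = 1e6


@dataclass(frozen=True)
class MisclassPrior:
    """Informative prior on a misclassification matrix.

    Exactly one representation is populated depending on ``form``:
    per-row Dirichlet parameters (``alphas``), a bank of stored posterior
    draws (``draws``), or a single fixed matrix (``matrix``).
    """

    cause_map: CauseMap
    form: str
    matrix: Optional[np.ndarray] = None    # (C, C)
    alphas: Optional[np.ndarray] = None    # (C, C), strictly positive
    draws: Optional[np.ndarray] = None     # (n, C, C)

    def __post_init__(self) -> None:
        if self.form not in PRIOR_FORMS:
            raise ValidationError(f"unknown prior form {self.form!r}")
        C = self.cause_map.n_causes
        if self.form == "point_mass":
            if self.matrix is None:
                raise ValidationError("point_mass prior needs a matrix")
            MisclassMatrix(self.cause_map, self.matrix)  # validates
        elif self.form == "dirichlet_rows":
            al = np.asarray(self.alphas, dtype=float)
            if al.shape != (C, C) or (al <= 0).any():
                raise ValidationError(
                    "dirichlet_rows parameters must be positive, shape (C, C)")
            object.__setattr__(self, "alphas", al)
        else:  # draw_resampling
            dr = np.asarray(self.draws, dtype=float)
            if dr.ndim != 3 or dr.shape[1:] != (C, C):
                raise ValidationError("draws must have shape (n, C, C)")
            object.__setattr__(self, "draws", dr)

    def mean_matrix(self) -> np.ndarray:
        if self.form == "point_mass":
            return np.asarray(self.matrix, dtype=float)
        if self.form == "dirichlet_rows":
            return self.alphas / self.alphas.sum(axis=1, keepdims=True)
        return self.draws.mean(axis=0)


def build_informative_prior(
    draws: Union[Sequence[MisclassMatrix], np.ndarray],
    form: str = "dirichlet_rows",
    cause_map: Optional[CauseMap] = None,
    drop_other: bool = True,
) -> MisclassPrior:
    """Package stored misclassification draws as a calibration prior.

    ``dirichlet_rows`` moment-matches each row: the Dirichlet mean is set to
    the draw mean m, and the concentration to the average over causes of
    ``m_j (1 - m_j) / Var_j - 1``, capped to [1, 1e6].  ``draw_resampling``
    stores the draws themselves; ``point_mass`` keeps the single (or mean)
    matrix.  If the draws carry an 'other' category and ``drop_other`` is
    set, it is removed with row renormalization first.
    """
    if isinstance(draws, np.ndarray):
        if cause_map is None:
            raise ValidationError("cause_map required with an array of draws")
        arr = np.asarray(draws, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
    else:
        draws = list(draws)
        if not draws:
            raise ValidationError("need at least one draw")
        cause_map = cause_map or draws[0].cause_map
        arr = np.stack([d.values for d in draws])
    if drop_other and cause_map.other_label is not None:
        arr = drop_other_renormalize_draws(arr, cause_map)
        cause_map = cause_map.without_other()

    if form == "point_mass":
        return MisclassPrior(cause_map, "point_mass",
                             matrix=arr.mean(axis=0))
    if form == "draw_resampling":
        return MisclassPrior(cause_map, "draw_resampling", draws=arr)
    if form != "dirichlet_rows":
        raise ValidationError(f"unknown prior form {form!r}")
    if arr.shape[0] < 2:
        raise ValidationError("dirichlet_rows moment matching needs >= 2 draws")

    C = cause_map.n_causes
    alphas = np.empty((C, C))
    for i in range(C):
        m = arr[:, i, :].mean(axis=0)
        v = arr[:, i, :].var(axis=0, ddof=1)
        valid = (v > 1e-12) & (m > 1e-12) & (m < 1 - 1e-12)
        if valid.any():
            a0 = float(np.mean(m[valid] * (1 - m[valid]) / v[valid] - 1.0))
        else:
            a0 = ALPHA0_MAX
            warnings.warn(
                f"zero-variance draws in row {cause_map.labels[i]!r}; "
                f"concentration capped at {ALPHA0_MAX:g}",
                UserWarning, stacklevel=2)
        a0 = float(np.clip(a0, ALPHA0_MIN, ALPHA0_MAX))
        alphas[i] = np.maximum(a0 * m, 1e-4)
    return MisclassPrior(cause_map, "dirichlet_rows", alphas=alphas)


# ---------------------------------------------------------------------------
# settings / results
# ---------------------------------------------------------------------------

@dataclass
class CalibrationSettings:
    """Gibbs-sampler settings for CSMF calibration."""

    seed: int
    n_iter: int = 4000
    n_burn: int = 1000
    n_draws: int = 2000
    p_prior: float = 1.0           # flat Dirichlet concentration on p
    cond_warn: float = 1e3
    cond_error: float = 1e8


@dataclass
class CalibrationResult:
    """Calibrated and uncalibrated CSMF estimates with diagnostics."""

    calibrated: CSMFEstimate
    uncalibrated: CSMFEstimate
    condition_number: float
    diagnostics: dict
    seed: int

    @property
    def cause_map(self) -> CauseMap:
        return self.calibrated.cause_map


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _align_counts(va: VAOnlyCounts, prior: MisclassPrior) -> VAOnlyCounts:
    if va.cause_map.labels == prior.cause_map.labels:
        return va
    reduced = va.drop_other()
    if reduced.cause_map.labels == prior.cause_map.labels:
        return reduced
    raise ValidationError(
        f"cause maps do not align: VA {va.cause_map.labels} vs prior "
        f"{prior.cause_map.labels}")


def calibrate_single(va: VAOnlyCounts, prior: MisclassPrior,
                     settings: CalibrationSettings) -> CalibrationResult:
    """Calibrate one algorithm's VA-only counts against its prior."""
    return calibrate_ensemble([va], [prior], settings)


def calibrate_ensemble(vas: Sequence[VAOnlyCounts],
                       priors: Sequence[MisclassPrior],
                       settings: CalibrationSettings) -> CalibrationResult:
    """Joint calibration across algorithms sharing one true CSMF.

    Each algorithm contributes an independent multinomial likelihood for its
    VA counts given the shared p (a working likelihood over aggregate
    counts); the posterior for p integrates all algorithms' misclassification
    priors, reducing the risk of relying on a single inaccurate algorithm.
    """
    if not vas:
        raise ValidationError("need at least one algorithm")
    if len(vas) != len(priors):
        raise ValidationError("one prior per algorithm required")
    vas = [_align_counts(v, pr) for v, pr in zip(vas, priors)]
    cm = priors[0].cause_map
    for pr in priors[1:]:
        if pr.cause_map.labels != cm.labels:
            raise ValidationError("cause maps differ across algorithms")
    if all(v.total == 0 for v in vas):
        raise ValidationError("no VA records to calibrate")
    for pr in priors:
        cond0 = np.linalg.cond(pr.mean_matrix().T)
        if cond0 >= settings.cond_error:
            raise ValidationError(
                f"misclassification matrix is numerically singular "
                f"(condition number {cond0:.3g}); calibration is ill posed")

    rng = np.random.default_rng(settings.seed)
    p_draws, phi_means, accept = _gibbs(
        [v.counts for v in vas], priors, settings, rng)

    cond = max(float(np.linalg.cond(m.T)) for m in phi_means)
    if cond > settings.cond_warn:
        warnings.warn(
            f"posterior-mean misclassification matrix is ill conditioned "
            f"(condition number {cond:.3g}); calibrated CSMFs may be "
            "unstable", UserWarning, stacklevel=2)

    calibrated = CSMFEstimate.from_draws(cm, p_draws)
    total = np.sum([v.counts for v in vas], axis=0)
    uncal = uncalibrated_csmf(
        VAOnlyCounts(cm, "+".join(v.algorithm for v in vas), total))
    diagnostics = {
        "n_iter": settings.n_iter,
        "n_burn": settings.n_burn,
        "algorithms": [v.algorithm for v in vas],
        "n_records": [int(v.total) for v in vas],
        "phi_accept_rate": accept,
        "condition_numbers": [float(np.linalg.cond(m.T)) for m in phi_means],
    }
    return CalibrationResult(calibrated, uncal, cond, diagnostics,
                             settings.seed)


def _gibbs(xs: list[np.ndarray], priors: Sequence[MisclassPrior],
           settings: CalibrationSettings, rng: np.random.Generator):
    """Data-augmentation Gibbs sampler shared by single and ensemble modes.

    Returns kept p draws, per-algorithm posterior-mean matrices, and the
    independence-Metropolis acceptance rate per algorithm (NaN when the
    prior form needs no Metropolis step).
    """
    K = len(xs)
    C = priors[0].cause_map.n_causes
    delta = settings.p_prior

    phis = [pr.mean_matrix().copy() for pr in priors]
    draw_idx = [0] * K
    total = np.sum(xs, axis=0).astype(float)
    p = (total + 1.0) / (total.sum() + C)

    n_keep = settings.n_iter - settings.n_burn
    if n_keep <= 0:
        raise ValidationError("n_iter must exceed n_burn")
    kept = np.empty((n_keep, C))
    phi_sums = [np.zeros((C, C)) for _ in range(K)]
    prop_count = np.zeros(K)
    acc_count = np.zeros(K)

    for it in range(settings.n_iter):
        m_latent = []
        for k in range(K):
            M = np.zeros((C, C))
            x = xs[k]
            phi = phis[k]
            for j in np.flatnonzero(x):
                w = p * phi[:, j]
                tot = w.sum()
                if tot <= 0:
                    w = np.full(C, 1.0 / C)
                else:
                    w = w / tot
                M[:, j] = rng.multinomial(int(x[j]), w)
            m_latent.append(M)

        p = rng.dirichlet(delta + np.sum([M.sum(axis=1) for M in m_latent],
                                         axis=0))

        for k in range(K):
            pr, M = priors[k], m_latent[k]
            if pr.form == "dirichlet_rows":
                for i in range(C):
                    phis[k][i] = rng.dirichlet(pr.alphas[i] + M[i])
            elif pr.form == "draw_resampling":
                prop_count[k] += 1
                n_bank = pr.draws.shape[0]
                j_new = int(rng.integers(0, n_bank))
                cur = np.log(np.maximum(phis[k], 1e-300))
                new = np.log(np.maximum(pr.draws[j_new], 1e-300))
                log_r = float(np.sum(M * (new - cur)))
                if np.log(rng.random()) < log_r:
                    phis[k] = pr.draws[j_new].copy()
                    draw_idx[k] = j_new
                    acc_count[k] += 1
            # point_mass: fixed

        if it >= settings.n_burn:
            kept[it - settings.n_burn] = p
            for k in range(K):
                phi_sums[k] += phis[k]

    if n_keep > settings.n_draws:
        idx = np.sort(rng.choice(n_keep, size=settings.n_draws, replace=False))
        kept = kept[idx]
    phi_means = [s / n_keep for s in phi_sums]
    accept = [float(acc_count[k] / prop_count[k]) if prop_count[k] else
              float("nan") for k in range(K)]
    return kept, phi_means, accept
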