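"""Hierarchical Bayesian estimation of VA misclassification matrices.

Model
-----
Each row i of the misclassification matrix is generated by two latent
mechanisms:

* *intrinsic accuracy* ``a_i`` — the probability the algorithm identifies the
  true cause by design, and
* *pull* ``b`` — a probability vector over causes describing where
  predictions land when the algorithm fails, independent of the true cause.

Default parameterization (pull mass may land on the true cause, so the
sensitivity is ``a_i + (1 - a_i) b_i``)::

    phi_ij = a_i * 1{i = j} + (1 - a_i) * b_j

An alternative that renormalizes the pull over the off-diagonal causes is
available via ``FitSettings.parameterization = "pull_off_diagonal"``.

The country-specific extension puts the mechanism on link scales,

    logit(a_si) = alpha_i + u_si,      b_s = softmax(beta + v_s),

with the last pull coordinate fixed at zero for identifiability, and places a
horseshoe (global-local continuous shrinkage) prior on the country deviations:

    u_si ~ N(0, (lambda_a * psi_si)^2),   v_sj ~ N(0, (lambda_b * omega_sj)^2),

with half-Cauchy(0, 1) global scales lambda and local scales psi, omega.
With homogeneous data the scales collapse toward zero and every country
shrinks to the pooled matrix; with strong heterogeneity and enough data the
local scales release individual deviations.  Rows are multinomial given the
reference cause.

Sampling uses an ensemble MCMC (differential-evolution moves) over a
non-centered parameterization, with raw deviations ``u_tilde ~ N(0, 1)``
scaled by the sampled shrinkage scales.  Convergence diagnostics (split
R-hat, bulk ESS) are computed on the retained ensemble and reported;
violations raise warnings, never silent failures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import emcee
import numpy as np
from scipy.special import expit, logit

from .core import (
    CauseMap,
    MisclassMatrix,
    PairedCauseCounts,
    SamplerError,
    ValidationError,
)

ALPHA_SD = 1.5  # prior sd of global logit-accuracies
BETA_SD = 1.5   # prior sd of global log-pull weights

_LOG_HALF_CAUCHY_CONST = float(np.log(2.0 / np.pi))


# ---------------------------------------------------------------------------
# accuracy / pull mechanism
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccuracyPull:
    """Latent mechanism (intrinsic accuracy ``a``, pull simplex ``b``)."""

    a: np.ndarray  # (C,) in [0, 1]
    b: np.ndarray  # (C,) simplex

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or b.shape != a.shape:
            raise ValidationError("a and b must be 1-d vectors of equal length")
        if (a < 0).any() or (a > 1).any():
            raise ValidationError("intrinsic accuracies must lie in [0, 1]")
        if (b < 0).any() or abs(b.sum() - 1.0) > 1e-9:
            raise ValidationError("pull must be a probability vector")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)


def accuracy_pull_to_matrix(ap: AccuracyPull,
                            cause_map: Optional[CauseMap] = None,
                            parameterization: str = "pull_on_true"
                            ) -> MisclassMatrix:
    """Misclassification matrix implied by an accuracy/pull mechanism.

    ``pull_on_true``: phi_ij = a_i 1{i=j} + (1 - a_i) b_j (rows sum to 1 by
    the identity a_i + (1 - a_i) sum_j b_j = 1).  ``pull_off_diagonal``
    renormalizes the pull over causes other than the true one.
    """
    C = ap.a.size
    if cause_map is None:
        cause_map = CauseMap(tuple(f"cause_{k + 1}" for k in range(C)))
    if cause_map.n_causes != C:
        raise ValidationError("cause map size does not match mechanism size")
    values = _mechanism_matrix(ap.a[None, :], ap.b[None, :],
                               parameterization)[0]
    return MisclassMatrix(cause_map, values)


def _mechanism_matrix(a: np.ndarray, b: np.ndarray,
                      parameterization: str) -> np.ndarray:
    """Vectorized mechanism -> matrix map.

    ``a``, ``b`` have shape (..., C); the result has shape (..., C, C).
    """
    C = a.shape[-1]
    eye = np.eye(C)
    if parameterization == "pull_on_true":
        phi = (a[..., :, None] * eye
               + (1.0 - a[..., :, None]) * b[..., None, :])
    elif parameterization == "pull_off_diagonal":
        off = b[..., None, :] / np.maximum(1.0 - b[..., :, None], 1e-12)
        phi = (1.0 - a[..., :, None]) * off
        diag_idx = np.arange(C)
        phi[..., diag_idx, diag_idx] = a
    else:
        raise ValidationError(
            f"unknown parameterization {parameterization!r}")
    return phi


# ---------------------------------------------------------------------------
# settings / posterior containers
# ---------------------------------------------------------------------------

@dataclass
class FitSettings:
    """Ensemble-MCMC settings for the misclassification model.

    ``n_steps`` is the total chain length per walker; the first ``n_burn``
    steps are discarded, and ``n_draws`` parameter vectors are subsampled
    from the retained ensemble.  The walker count defaults to roughly twice
    the parameter dimension.
    """

    seed: int
    n_steps: int = 2000
    n_burn: int = 1000
    n_draws: int = 1000
    n_walkers: Optional[int] = None
    parameterization: str = "pull_on_true"
    alpha_sd: float = ALPHA_SD
    beta_sd: float = BETA_SD
    rhat_gate: float = 1.01
    ess_gate: float = 400.0
    check_diagnostics: bool = True


@dataclass
class MisclassPosterior:
    """Posterior draws of misclassification matrices.

    ``country_draws[d, s]`` is draw d of country s's matrix; ``pooled_draws``
    are the matrices implied by the global accuracy/pull parameters alone,
    and ``other_draws`` are predictive matrices for a country outside the
    data, centred on the pooled matrix with spread governed by the fitted
    heterogeneity.  The model-based estimate of a matrix is the posterior
    mean of its draws; intervals are equal-tailed.
    """

    cause_map: CauseMap
    countries: tuple[str, ...]
    country_draws: np.ndarray        # (n_draws, S, C, C)
    pooled_draws: np.ndarray         # (n_draws, C, C)
    other_draws: np.ndarray          # (n_draws, C, C)
    hyper_draws: dict                # alpha, beta, log_lambda_a, log_lambda_b
    diagnostics: dict
    settings: FitSettings
    homogeneous: bool

    @property
    def n_draws(self) -> int:
        return self.country_draws.shape[0]

    def country_index(self, name: str) -> int:
        try:
            return self.countries.index(name)
        except ValueError:
            raise ValidationError(f"unknown country {name!r}") from None

    def country_mean(self, name: str) -> MisclassMatrix:
        s = self.country_index(name)
        return _mean_matrix(self.cause_map, self.country_draws[:, s])

    def pooled_mean(self) -> MisclassMatrix:
        return _mean_matrix(self.cause_map, self.pooled_draws)

    def other_mean(self) -> MisclassMatrix:
        return _mean_matrix(self.cause_map, self.other_draws)

    def country_matrices(self, name: str) -> list[MisclassMatrix]:
        s = self.country_index(name)
        return [MisclassMatrix(self.cause_map, v)
                for v in self.country_draws[:, s]]

    def means_by_country(self) -> np.ndarray:
        """(S, C, C) array of posterior-mean matrices, row-renormalized."""
        m = self.country_draws.mean(axis=0)
        return m / m.sum(axis=2, keepdims=True)


def _mean_matrix(cause_map: CauseMap, draws: np.ndarray) -> MisclassMatrix:
    m = draws.mean(axis=0)
    return MisclassMatrix(cause_map, m / m.sum(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# log posteriors (vectorized over walkers)
# ---------------------------------------------------------------------------

def _log_half_cauchy_logscale(x: np.ndarray) -> np.ndarray:
    """Log-density of log(s) where s ~ half-Cauchy(0, 1), summed over axis -1."""
    # density of s: (2/pi) / (1 + s^2); with s = e^x the Jacobian adds +x
    return np.sum(_LOG_HALF_CAUCHY_CONST + x - np.logaddexp(0.0, 2.0 * x),
                  axis=-1)


def _softmax_last(eta: np.ndarray) -> np.ndarray:
    eta = eta - eta.max(axis=-1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=-1, keepdims=True)


class _HomogeneousModel:
    """Pooled accuracy/pull model: theta = [alpha (C), beta (C-1)]."""

    def __init__(self, counts: np.ndarray, settings: FitSettings):
        self.counts = counts  # (C, C), summed over countries
        self.C = counts.shape[0]
        self.ndim = 2 * self.C - 1
        self.settings = settings

    def unpack(self, theta: np.ndarray):
        C = self.C
        alpha = theta[..., :C]
        beta = np.concatenate(
            [theta[..., C:], np.zeros(theta.shape[:-1] + (1,))], axis=-1)
        return alpha, beta

    def matrices(self, theta: np.ndarray) -> np.ndarray:
        alpha, beta = self.unpack(theta)
        return _mechanism_matrix(expit(alpha), _softmax_last(beta),
                                 self.settings.parameterization)

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        alpha, beta = self.unpack(theta)
        s = self.settings
        lp = (-0.5 * np.sum((alpha / s.alpha_sd) ** 2, axis=-1)
              - 0.5 * np.sum((beta[..., :-1] / s.beta_sd) ** 2, axis=-1))
        phi = self.matrices(theta)
        loglik = np.einsum("ij,wij->w", self.counts,
                           np.log(np.maximum(phi, 1e-300)))
        return lp + loglik

    def initial(self, rng: np.random.Generator, n_walkers: int) -> np.ndarray:
        center = _empirical_start(self.counts, self.settings)
        jitter = rng.normal(0.0, 0.15, size=(n_walkers, self.ndim))
        return center[None, :] + jitter


class _CountrySpecificModel:
    """Hierarchical model with horseshoe-shrunk country deviations.

    theta = [alpha (C), beta (C-1), u_tilde (S*C), v_tilde (S*(C-1)),
             log_lambda_a, log_lambda_b, log_psi (S*C), log_omega (S*(C-1))]

    Non-centered: u = lambda_a * psi * u_tilde with u_tilde ~ N(0, 1).
    """

    def __init__(self, counts: np.ndarray, settings: FitSettings):
        self.counts = counts  # (S, C, C)
        self.S, self.C = counts.shape[0], counts.shape[1]
        S, C = self.S, self.C
        sizes = [C, C - 1, S * C, S * (C - 1), 1, 1, S * C, S * (C - 1)]
        self.splits = np.cumsum(sizes)[:-1]
        self.ndim = int(np.sum(sizes))
        self.settings = settings

    def unpack(self, theta: np.ndarray):
        parts = np.split(theta, self.splits, axis=-1)
        (alpha, beta_free, ut, vt, lla, llb, lpsi, lomega) = parts
        lead = theta.shape[:-1]
        S, C = self.S, self.C
        return {
            "alpha": alpha,
            "beta_free": beta_free,
            "u_tilde": ut.reshape(lead + (S, C)),
            "v_tilde": vt.reshape(lead + (S, C - 1)),
            "log_lambda_a": lla[..., 0],
            "log_lambda_b": llb[..., 0],
            "log_psi": lpsi.reshape(lead + (S, C)),
            "log_omega": lomega.reshape(lead + (S, C - 1)),
        }

    def _ab(self, p: dict):
        """Country-level accuracy (., S, C) and pull (., S, C)."""
        lam_a = np.exp(np.clip(p["log_lambda_a"], -40.0, 40.0))
        lam_b = np.exp(np.clip(p["log_lambda_b"], -40.0, 40.0))
        u = (lam_a[..., None, None]
             * np.exp(np.clip(p["log_psi"], -40.0, 40.0)) * p["u_tilde"])
        v = (lam_b[..., None, None]
             * np.exp(np.clip(p["log_omega"], -40.0, 40.0)) * p["v_tilde"])
        a = expit(p["alpha"][..., None, :] + u)
        beta = np.concatenate(
            [p["beta_free"], np.zeros(p["beta_free"].shape[:-1] + (1,))],
            axis=-1)
        v_full = np.concatenate([v, np.zeros(v.shape[:-1] + (1,))], axis=-1)
        b = _softmax_last(beta[..., None, :] + v_full)
        return a, b

    def matrices(self, theta: np.ndarray) -> np.ndarray:
        p = self.unpack(theta)
        a, b = self._ab(p)
        return _mechanism_matrix(a, b, self.settings.parameterization)

    def pooled_matrices(self, theta: np.ndarray) -> np.ndarray:
        p = self.unpack(theta)
        beta = np.concatenate(
            [p["beta_free"], np.zeros(p["beta_free"].shape[:-1] + (1,))],
            axis=-1)
        return _mechanism_matrix(expit(p["alpha"]), _softmax_last(beta),
                                 self.settings.parameterization)

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        p = self.unpack(theta)
        s = self.settings
        lp = (-0.5 * np.sum((p["alpha"] / s.alpha_sd) ** 2, axis=-1)
              - 0.5 * np.sum((p["beta_free"] / s.beta_sd) ** 2, axis=-1)
              - 0.5 * np.sum(p["u_tilde"] ** 2, axis=(-1, -2))
              - 0.5 * np.sum(p["v_tilde"] ** 2, axis=(-1, -2)))
        lp += _log_half_cauchy_logscale(p["log_lambda_a"][..., None])
        lp += _log_half_cauchy_logscale(p["log_lambda_b"][..., None])
        lp += _log_half_cauchy_logscale(
            p["log_psi"].reshape(p["log_psi"].shape[:-2] + (-1,)))
        lp += _log_half_cauchy_logscale(
            p["log_omega"].reshape(p["log_omega"].shape[:-2] + (-1,)))
        a, b = self._ab(p)
        phi = _mechanism_matrix(a, b, s.parameterization)
        loglik = np.einsum("sij,wsij->w", self.counts,
                           np.log(np.maximum(phi, 1e-300)))
        return lp + loglik

    def initial(self, rng: np.random.Generator, n_walkers: int) -> np.ndarray:
        pooled = self.counts.sum(axis=0)
        global_start = _empirical_start(pooled, self.settings)
        S, C = self.S, self.C
        center = np.zeros(self.ndim)
        center[: 2 * C - 1] = global_start
        i0 = self.splits[3]  # start of log_lambda_a
        center[i0] = center[i0 + 1] = np.log(0.3)
        scale = np.full(self.ndim, 0.3)
        scale[: 2 * C - 1] = 0.15
        idx_ut = slice(self.splits[1], self.splits[3])
        scale[idx_ut] = 0.5
        return center[None, :] + rng.normal(0.0, 1.0,
                                            (n_walkers, self.ndim)) * scale


def _empirical_start(pooled: np.ndarray, settings: FitSettings) -> np.ndarray:
    """Moment-style starting point for (alpha, beta_free) from pooled counts."""
    C = pooled.shape[0]
    row_tot = pooled.sum(axis=1)
    diag_prop = (np.diag(pooled) + 0.5) / (row_tot + 1.0)
    col_off = pooled.sum(axis=0) - np.diag(pooled) + 0.5
    b_hat = col_off / col_off.sum()
    if settings.parameterization == "pull_on_true":
        a_hat = (diag_prop - b_hat) / np.maximum(1.0 - b_hat, 1e-6)
    else:
        a_hat = diag_prop
    a_hat = np.clip(a_hat, 0.05, 0.95)
    beta_free = np.log(b_hat[:-1] / b_hat[-1])
    return np.concatenate([logit(a_hat), np.clip(beta_free, -4, 4)])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _run_ensemble(model, settings: FitSettings, rng: np.random.Generator):
    """Run the ensemble sampler; return (flat draws, diagnostics)."""
    ndim = model.ndim
    n_walkers = settings.n_walkers or max(2 * ndim + 2, 48)
    if n_walkers % 2:
        n_walkers += 1
    p0 = model.initial(rng, n_walkers)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, model.log_prob,
                                    vectorize=True, moves=moves)
    seed = int(rng.integers(0, 2**31 - 1))
    sampler._random = np.random.RandomState(seed)
    sampler.run_mcmc(p0, settings.n_steps, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain()[settings.n_burn:]  # (steps, walkers, ndim)
    if chain.size == 0:
        raise SamplerError("no post-burn-in draws; increase n_steps")
    diagnostics = _diagnostics(chain, settings)
    flat = chain.reshape(-1, ndim)
    idx = rng.choice(flat.shape[0], size=min(settings.n_draws, flat.shape[0]),
                     replace=False)
    return flat[np.sort(idx)], diagnostics


def _diagnostics(chain: np.ndarray, settings: FitSettings) -> dict:
    """Split R-hat and bulk ESS over the retained ensemble.

    The walker ensemble is folded into four pseudo-chains so the statistics
    follow the usual (chain, draw) layout.
    """
    import arviz as az

    steps, walkers, ndim = chain.shape
    g = walkers // 4 * 4
    # group walkers into 4 pseudo-chains, each walker trajectory contiguous
    pseudo = (chain[:, :g, :]
              .transpose(1, 0, 2)
              .reshape(4, (g // 4) * steps, ndim))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(pseudo)
        rhat = az.rhat(ds)["x"].values
        ess = az.ess(ds)["x"].values
    out = {
        "max_rhat": float(np.nanmax(rhat)),
        "min_ess": float(np.nanmin(ess)),
        "rhat": rhat,
        "ess": ess,
        "converged": bool(np.nanmax(rhat) < settings.rhat_gate
                          and np.nanmin(ess) > settings.ess_gate),
    }
    if settings.check_diagnostics and not out["converged"]:
        warnings.warn(
            f"sampler diagnostics outside gates (max R-hat "
            f"{out['max_rhat']:.3f}, min bulk ESS {out['min_ess']:.0f}); "
            "treat estimates with care or increase n_steps",
            UserWarning, stacklevel=3)
    return out


def _check_data(data: PairedCauseCounts) -> None:
    if data.total() == 0:
        raise ValidationError("paired data contain no deaths")


def fit_homogeneous(data: PairedCauseCounts,
                    settings: FitSettings) -> MisclassPosterior:
    """Pooled (homogeneous) fit: one matrix shared by every country.

    Counts are summed over countries and each row of the summed matrix is
    multinomial with probabilities from the accuracy/pull mechanism.  The
    pooled draws are replicated as every country's estimate.
    """
    _check_data(data)
    rng = np.random.default_rng(settings.seed)
    model = _HomogeneousModel(data.pooled().astype(float), settings)
    draws, diagnostics = _run_ensemble(model, settings, rng)
    phi = model.matrices(draws)  # (n, C, C)
    alpha, beta = model.unpack(draws)
    n, S = phi.shape[0], data.n_countries
    country = np.broadcast_to(phi[:, None], (n, S) + phi.shape[1:]).copy()
    return MisclassPosterior(
        cause_map=data.cause_map,
        countries=data.countries,
        country_draws=country,
        pooled_draws=phi,
        other_draws=phi.copy(),
        hyper_draws={"alpha": alpha, "beta_free": beta[..., :-1]},
        diagnostics=diagnostics,
        settings=settings,
        homogeneous=True,
    )


def fit_country_specific(data: PairedCauseCounts,
                         settings: FitSettings) -> MisclassPosterior:
    """Country-specific hierarchical fit with continuous shrinkage.

    Returns per-country draws, pooled draws (global mechanism), and
    other-country predictive draws for a country outside the data.  A country
    with few or no deaths contributes little likelihood, so its posterior
    shrinks toward the pooled estimate; with no deaths at all it coincides
    with the other-country predictive distribution.
    """
    _check_data(data)
    rng = np.random.default_rng(settings.seed)
    model = _CountrySpecificModel(data.counts.astype(float), settings)
    draws, diagnostics = _run_ensemble(model, settings, rng)
    country_phi = model.matrices(draws)       # (n, S, C, C)
    pooled_phi = model.pooled_matrices(draws)  # (n, C, C)
    p = model.unpack(draws)
    hyper = {
        "alpha": p["alpha"],
        "beta_free": p["beta_free"],
        "log_lambda_a": p["log_lambda_a"],
        "log_lambda_b": p["log_lambda_b"],
    }
    other_phi = _draw_new_country(hyper, settings, rng)
    return MisclassPosterior(
        cause_map=data.cause_map,
        countries=data.countries,
        country_draws=country_phi,
        pooled_draws=pooled_phi,
        other_draws=other_phi,
        hyper_draws=hyper,
        diagnostics=diagnostics,
        settings=settings,
        homogeneous=False,
    )


def _draw_new_country(hyper: dict, settings: FitSettings,
                      rng: np.random.Generator) -> np.ndarray:
    """Predictive matrices for an unseen country, one per posterior draw.

    New-country deviations are drawn from the fitted hierarchical
    distribution: fresh half-Cauchy local scales and standard-normal raw
    deviations, scaled by each draw's global shrinkage scales.
    """
    alpha = hyper["alpha"]
    beta_free = hyper["beta_free"]
    n, C = alpha.shape
    lam_a = np.exp(hyper["log_lambda_a"])
    lam_b = np.exp(hyper["log_lambda_b"])
    psi = np.abs(rng.standard_cauchy((n, C)))
    omega = np.abs(rng.standard_cauchy((n, C - 1)))
    u = lam_a[:, None] * psi * rng.standard_normal((n, C))
    v = lam_b[:, None] * omega * rng.standard_normal((n, C - 1))
    a = expit(alpha + u)
    beta = np.concatenate([beta_free + v, np.zeros((n, 1))], axis=-1)
    b = _softmax_last(beta)
    return _mechanism_matrix(a, b, settings.parameterization)


def sample_other_country(post: MisclassPosterior, n_draws: int,
                         seed: int) -> list[MisclassMatrix]:
    """Draw predictive misclassification matrices for a new country.

    Centred on the pooled matrix; the spread grows with the fitted
    cross-country heterogeneity.  On a homogeneous-only fit there is no
    heterogeneity model, so pooled draws are returned with a warning.
    """
    rng = np.random.default_rng(seed)
    if post.homogeneous:
        warnings.warn("homogeneous fit has no heterogeneity model; "
                      "returning pooled draws", UserWarning, stacklevel=2)
        idx = rng.integers(0, post.pooled_draws.shape[0], size=n_draws)
        return [MisclassMatrix(post.cause_map, v)
                for v in post.pooled_draws[idx]]
    n_post = post.hyper_draws["alpha"].shape[0]
    idx = rng.integers(0, n_post, size=n_draws)
    hyper = {k: v[idx] for k, v in post.hyper_draws.items()}
    phi = _draw_new_country(hyper, post.settings, rng)
    return [MisclassMatrix(post.cause_map, v) for v in phi]
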