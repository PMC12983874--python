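"""Synthetic multi-country paired and VA-only cause-of-death data.

The generators mirror the data-generating assumptions of the estimation
model: each algorithm has a global accuracy/pull mechanism; countries
deviate on the link scales (logit accuracy, log pull) with independent
Normal(0, eta^2) perturbations, so ``eta`` directly controls cross-country
heterogeneity (eta = 0 gives identical matrices everywhere).  Paired data
draw each reference-cause row as a multinomial from the country matrix;
VA-only data first draw each death's true cause from the true CSMF p, then
each algorithm's predicted cause from its matrix row — algorithms are
conditionally independent given the true cause, so the VA margins follow
the calibration equation q = Phi^T p.

One master seed expands deterministically into per-stage substreams, so a
scenario is fully reproducible while stages stay independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import expit, logit

from .core import (
    CauseMap,
    PairedCauseCounts,
    ValidationError,
    VAOnlyCounts,
    cause_map_preset,
)
from .misclass import AccuracyPull, _mechanism_matrix, _softmax_last


def _default_accuracy(C: int) -> np.ndarray:
    # spans the low-to-high sensitivity regimes seen in practice (~0.2-0.8)
    return np.linspace(0.8, 0.2, C)


def _default_pull(C: int) -> np.ndarray:
    w = np.arange(C, 0, -1.0)
    return w / w.sum()


def _default_csmf(C: int) -> np.ndarray:
    w = np.arange(C, 0, -1.0)
    return w / w.sum()


@dataclass
class ScenarioConfig:
    """Configuration of one synthetic study scenario.

    Defaults describe a mid-sized multi-country study: 4 causes, 4 countries,
    500 paired deaths per (country, reference cause), 5000 VA-only records,
    moderate heterogeneity eta = 0.3, one algorithm.  ``a``/``b``/``p`` may
    be a single vector shared by all algorithms or one vector per algorithm
    (shape (K, C)) for ``a`` and ``b``.
    """

    cause_map: Union[str, CauseMap] = "custom4"
    n_countries: int = 4
    n_per_row: Union[int, np.ndarray] = 500     # scalar or (S, C)
    heterogeneity: float = 0.3                  # eta >= 0
    accuracy: Optional[np.ndarray] = None       # (C,) or (K, C)
    pull: Optional[np.ndarray] = None           # (C,) or (K, C)
    csmf: Optional[np.ndarray] = None           # (C,)
    n_va_records: int = 5000
    n_algorithms: int = 1
    parameterization: str = "pull_on_true"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cause_map, str):
            if self.cause_map.startswith("custom"):
                C = int(self.cause_map.removeprefix("custom"))
                self.cause_map = CauseMap(
                    tuple(f"cause_{k + 1}" for k in range(C)))
            else:
                self.cause_map = cause_map_preset(self.cause_map)
        C = self.cause_map.n_causes
        if self.heterogeneity < 0:
            raise ValidationError("heterogeneity must be >= 0")
        if self.n_countries < 1 or self.n_algorithms < 1:
            raise ValidationError("need >= 1 country and >= 1 algorithm")
        K = self.n_algorithms
        self.accuracy = self._per_algo(self.accuracy, _default_accuracy(C), C)
        self.pull = self._per_algo(self.pull, _default_pull(C), C)
        if self.csmf is None:
            self.csmf = _default_csmf(C)
        self.csmf = np.asarray(self.csmf, dtype=float)
        if self.csmf.shape != (C,) or abs(self.csmf.sum() - 1) > 1e-9 \
                or (self.csmf < 0).any():
            raise ValidationError("csmf must be a length-C probability vector")
        n = np.asarray(self.n_per_row)
        if n.ndim == 0:
            n = np.full((self.n_countries, C), int(n))
        if n.shape != (self.n_countries, C) or (n < 0).any():
            raise ValidationError("n_per_row must be scalar or (S, C) >= 0")
        self.n_per_row = n.astype(np.int64)
        for k in range(K):
            AccuracyPull(self.accuracy[k], self.pull[k])  # validates

    def _per_algo(self, value, default, C: int) -> np.ndarray:
        K = self.n_algorithms
        if value is None:
            value = default
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 1:
            arr = np.broadcast_to(arr, (K, C)).copy()
        if arr.shape != (K, C):
            raise ValidationError(f"expected shape ({K}, {C}), got {arr.shape}")
        return arr

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(f"country_{s + 1}" for s in range(self.n_countries))

    @property
    def algorithms(self) -> tuple[str, ...]:
        return tuple(f"algo_{k + 1}" for k in range(self.n_algorithms))

    def substream(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage random substream from the master seed."""
        stages = {"mechanism": 0, "paired": 1, "va_only": 2}
        root = np.random.SeedSequence(self.seed)
        return np.random.default_rng(root.spawn(3)[stages[stage]])


@dataclass
class SyntheticTruth:
    """Known truth of a scenario plus (optionally) realized datasets."""

    config: ScenarioConfig
    mechanisms: list[list[AccuracyPull]]   # [algorithm][country]
    matrices: np.ndarray                   # (K, S, C, C)
    csmf: np.ndarray                       # (C,)
    paired: Optional[list[PairedCauseCounts]] = None   # per algorithm
    va_only: Optional[list[VAOnlyCounts]] = None       # per algorithm


def gen_true_mechanism(cfg: ScenarioConfig) -> SyntheticTruth:
    """Draw true per-country mechanisms and matrices for every algorithm.

    Country deviations u_si, v_sj ~ Normal(0, eta^2) are applied through the
    same links as the model (logit for accuracy, log with softmax for pull,
    last pull coordinate pinned at zero), so eta = 0 reproduces the global
    matrix in every country exactly.
    """
    rng = cfg.substream("mechanism")
    C = cfg.cause_map.n_causes
    S, K, eta = cfg.n_countries, cfg.n_algorithms, cfg.heterogeneity
    mechanisms: list[list[AccuracyPull]] = []
    mats = np.empty((K, S, C, C))
    for k in range(K):
        alpha = logit(np.clip(cfg.accuracy[k], 1e-9, 1 - 1e-9))
        beta = np.log(np.maximum(cfg.pull[k], 1e-12))
        beta = beta - beta[-1]
        u = rng.normal(0.0, eta, size=(S, C)) if eta > 0 else np.zeros((S, C))
        v = np.zeros((S, C))
        if eta > 0:
            v[:, :-1] = rng.normal(0.0, eta, size=(S, C - 1))
        a = expit(alpha[None, :] + u)
        b = _softmax_last(beta[None, :] + v)
        mats[k] = _mechanism_matrix(a, b, cfg.parameterization)
        mechanisms.append([AccuracyPull(a[s], b[s]) for s in range(S)])
    return SyntheticTruth(cfg, mechanisms, mats, cfg.csmf.copy())


def gen_paired_counts(cfg: ScenarioConfig, truth: SyntheticTruth
                      ) -> list[PairedCauseCounts]:
    """Draw paired (reference, VA) counts: one multinomial row per
    (algorithm, country, reference cause) with the scenario's sample sizes."""
    rng = cfg.substream("paired")
    C = cfg.cause_map.n_causes
    out = []
    for k in range(cfg.n_algorithms):
        counts = np.zeros((cfg.n_countries, C, C), dtype=np.int64)
        for s in range(cfg.n_countries):
            for i in range(C):
                n = int(cfg.n_per_row[s, i])
                if n:
                    counts[s, i] = rng.multinomial(n, truth.matrices[k, s, i])
        out.append(PairedCauseCounts(cfg.cause_map, cfg.countries, counts))
    truth.paired = out
    return out


def gen_va_only(cfg: ScenarioConfig, truth: SyntheticTruth,
                country: int = 0) -> list[VAOnlyCounts]:
    """Draw VA-only counts from the true CSMF through each algorithm.

    Each death's reference cause is drawn from p; every algorithm then
    predicts a cause from its (given country's) matrix row for that cause,
    conditionally independently across algorithms.  Marginally each
    algorithm's counts are Multinomial(n, Phi_k^T p).
    """
    rng = cfg.substream("va_only")
    C = cfg.cause_map.n_causes
    ref_counts = rng.multinomial(cfg.n_va_records, truth.csmf)
    out = []
    for k, name in enumerate(cfg.algorithms):
        va = np.zeros(C, dtype=np.int64)
        for i in range(C):
            if ref_counts[i]:
                va += rng.multinomial(int(ref_counts[i]),
                                      truth.matrices[k, country, i])
        out.append(VAOnlyCounts(cfg.cause_map, name, va))
    truth.va_only = out
    return out


def simulate_scenario(cfg: ScenarioConfig) -> SyntheticTruth:
    """Full scenario: mechanisms, paired counts, VA-only counts."""
    truth = gen_true_mechanism(cfg)
    gen_paired_counts(cfg, truth)
    gen_va_only(cfg, truth)
    return truth
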