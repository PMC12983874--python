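"""Serialization of counts, cause maps, and misclassification inventories.

The durable exchange format is the *inventory* JSON: posterior draws and
means of misclassification matrices resolved by country, plus pooled and
other-country entries, together with the cause map, seed, and sampler
metadata.  Calibration consumes this file (or any file matching the schema),
which is what makes calibration possible without access to the paired data.
All matrices are stored row-major with the cause list adjacent, so axis
order cannot drift; numbers are serialized at full double precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    CauseMap,
    PairedCauseCounts,
    ValidationError,
    VAOnlyCounts,
    warn,
)
from .misclass import MisclassPosterior

SCHEMA_VERSION = 1
_ROW_TOL = 1e-6

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# cause maps
# ---------------------------------------------------------------------------

def read_cause_map(path: PathLike) -> CauseMap:
    with open(path) as fh:
        return CauseMap.from_dict(json.load(fh))


def write_cause_map(cm: CauseMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(cm.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# long-format paired counts CSV
# ---------------------------------------------------------------------------

PAIRED_COLUMNS = ("country", "ref_cause", "va_cause", "count")


def read_paired_counts(path: PathLike, cause_map: CauseMap
                       ) -> PairedCauseCounts:
    """Read long-format paired counts (country, ref_cause, va_cause, count).

    Combinations absent from the file are zero.  Unknown cause labels,
    negative/non-integer counts, and duplicated (country, ref, va) rows are
    rejected with the offending row named.
    """
    df = pd.read_csv(path)
    missing = set(PAIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        warn(f"{path}: no data rows; returning all-zero counts")
        return PairedCauseCounts(cause_map, (),
                                 np.zeros((0, cause_map.n_causes,
                                           cause_map.n_causes), dtype=int))
    dup = df.duplicated(subset=["country", "ref_cause", "va_cause"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate row (country={row['country']}, "
            f"ref_cause={row['ref_cause']}, va_cause={row['va_cause']})")
    countries = tuple(dict.fromkeys(df["country"].astype(str)))
    C = cause_map.n_causes
    counts = np.zeros((len(countries), C, C), dtype=np.int64)
    cidx = {c: k for k, c in enumerate(countries)}
    for _, row in df.iterrows():
        i = cause_map.index(str(row["ref_cause"]))
        j = cause_map.index(str(row["va_cause"]))
        n = row["count"]
        if float(n) != int(n) or int(n) < 0:
            raise ValidationError(
                f"{path}: invalid count {n!r} in row "
                f"(country={row['country']}, ref_cause={row['ref_cause']}, "
                f"va_cause={row['va_cause']})")
        counts[cidx[str(row["country"])], i, j] = int(n)
    return PairedCauseCounts(cause_map, countries, counts)


def write_paired_counts(data: PairedCauseCounts, path: PathLike) -> None:
    """Write nonzero cells in long format (lossless with read_paired_counts)."""
    labels = data.cause_map.labels
    rows = [
        {"country": country, "ref_cause": labels[i], "va_cause": labels[j],
         "count": int(data.counts[s, i, j])}
        for s, country in enumerate(data.countries)
        for i, j in zip(*np.nonzero(data.counts[s]))
    ]
    pd.DataFrame(rows, columns=list(PAIRED_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VA-only counts CSV
# ---------------------------------------------------------------------------

VA_COLUMNS = ("algorithm", "va_cause", "count")


def read_va_counts(path: PathLike, cause_map: CauseMap
                   ) -> dict[str, VAOnlyCounts]:
    """Read VA-only counts keyed by algorithm (columns algorithm, va_cause,
    count); unlisted causes are zero."""
    df = pd.read_csv(path)
    missing = set(VA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, VAOnlyCounts] = {}
    for algo, grp in df.groupby("algorithm", sort=False):
        if grp.duplicated(subset=["va_cause"]).any():
            raise ValidationError(
                f"{path}: duplicate va_cause for algorithm {algo}")
        counts = np.zeros(cause_map.n_causes, dtype=np.int64)
        for _, row in grp.iterrows():
            counts[cause_map.index(str(row["va_cause"]))] = int(row["count"])
        out[str(algo)] = VAOnlyCounts(cause_map, str(algo), counts)
    return out


def write_va_counts(vas: list[VAOnlyCounts], path: PathLike) -> None:
    rows = [
        {"algorithm": va.algorithm, "va_cause": label, "count": int(n)}
        for va in vas
        for label, n in zip(va.cause_map.labels, va.counts)
    ]
    pd.DataFrame(rows, columns=list(VA_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# misclassification inventory JSON
# ---------------------------------------------------------------------------

@dataclass
class Inventory:
    """In-memory image of an inventory file."""

    algorithm: str
    age_group: str
    cause_map: CauseMap
    countries: dict[str, np.ndarray]   # name -> (n_draws, C, C)
    pooled: np.ndarray
    other: np.ndarray
    sampler: dict
    seed: int
    homogeneous: bool = False

    def draws_for(self, country: str) -> np.ndarray:
        """Draws for a country, falling back to 'other' when unlisted."""
        if country in self.countries:
            return self.countries[country]
        warn(f"inventory has no entry for {country!r}; "
             "falling back to the other-country estimate")
        return self.other


def _matrix_block(draws: np.ndarray) -> dict:
    return {
        "draws": np.asarray(draws, dtype=float).tolist(),
        "mean": np.asarray(draws, dtype=float).mean(axis=0).tolist(),
    }


def write_inventory(post: MisclassPosterior, path: PathLike,
                    algorithm: str = "algorithm") -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "algorithm": algorithm,
        "age_group": post.cause_map.age_group,
        "cause_map": post.cause_map.to_dict(),
        "countries": {
            name: _matrix_block(post.country_draws[:, s])
            for s, name in enumerate(post.countries)
        },
        "pooled": _matrix_block(post.pooled_draws),
        "other": _matrix_block(post.other_draws),
        "sampler": {
            "engine": "emcee-ensemble",
            "n_steps": post.settings.n_steps,
            "n_burn": post.settings.n_burn,
            "n_draws": post.settings.n_draws,
            "parameterization": post.settings.parameterization,
            "homogeneous": post.homogeneous,
            "max_rhat": post.diagnostics.get("max_rhat"),
            "min_ess": post.diagnostics.get("min_ess"),
        },
        "seed": post.settings.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _validated_draws(block: dict, C: int, what: str) -> np.ndarray:
    draws = np.asarray(block["draws"], dtype=float)
    if draws.ndim != 3 or draws.shape[1:] != (C, C):
        raise ValidationError(f"inventory {what}: draws must be (n, {C}, {C})")
    sums = draws.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=_ROW_TOL, rtol=0):
        worst = float(np.abs(sums - 1.0).max())
        raise ValidationError(
            f"inventory {what}: matrix rows must sum to 1 "
            f"(worst deviation {worst:.3g})")
    return draws


def read_inventory(path: PathLike) -> Inventory:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"{path}: unsupported inventory schema version {version!r}")
    for key in ("cause_map", "countries", "pooled", "other"):
        if key not in payload:
            raise ValidationError(f"{path}: missing inventory field {key!r}")
    cm = CauseMap.from_dict(payload["cause_map"])
    C = cm.n_causes
    countries = {
        name: _validated_draws(block, C, f"country {name!r}")
        for name, block in payload["countries"].items()
    }
    return Inventory(
        algorithm=payload.get("algorithm", "algorithm"),
        age_group=payload.get("age_group", cm.age_group),
        cause_map=cm,
        countries=countries,
        pooled=_validated_draws(payload["pooled"], C, "pooled"),
        other=_validated_draws(payload["other"], C, "other"),
        sampler=payload.get("sampler", {}),
        seed=int(payload.get("seed", 0)),
        homogeneous=bool(payload.get("sampler", {}).get("homogeneous", False)),
    )


# ---------------------------------------------------------------------------
# calibration result JSON / CSV
# ---------------------------------------------------------------------------

def calibration_payload(result, algorithm: str) -> dict:
    cal, unc = result.calibrated, result.uncalibrated
    return {
        "algorithm": algorithm,
        "cause_map": cal.cause_map.to_dict(),
        "mean": cal.mean.tolist(),
        "lower95": cal.lower95.tolist(),
        "upper95": cal.upper95.tolist(),
        "uncalibrated": {
            "mean": unc.mean.tolist(),
            "lower95": unc.lower95.tolist(),
            "upper95": unc.upper95.tolist(),
        },
        "condition_number": result.condition_number,
        "diagnostics": {k: v for k, v in result.diagnostics.items()},
        "seed": result.seed,
    }


def calibration_table(results: dict[str, "object"]) -> pd.DataFrame:
    """Tidy per-cause table over a dict of algorithm -> CalibrationResult."""
    rows = []
    for algo, res in results.items():
        cm = res.calibrated.cause_map
        for k, label in enumerate(cm.labels):
            rows.append({
                "algorithm": algo,
                "cause": label,
                "calibrated_mean": res.calibrated.mean[k],
                "calibrated_lower95": res.calibrated.lower95[k],
                "calibrated_upper95": res.calibrated.upper95[k],
                "uncalibrated_mean": res.uncalibrated.mean[k],
                "uncalibrated_lower95": res.uncalibrated.lower95[k],
                "uncalibrated_upper95": res.uncalibrated.upper95[k],
            })
    return pd.DataFrame(rows)
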