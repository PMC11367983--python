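"""Reading and writing the delimited-text formats the package consumes.

Observation tables are plain CSV with a required header::

    species,study_id,ndfa_pct,aboveground_n_kg_ha,seed_n_kg_ha,root_factor

``study_id`` and ``root_factor`` may be blank.  Ndfa and theta are always
carried in percent in files; decimal point, comma separator, UTF-8.
Structured results (estimates, comparisons) are written as JSON and embed
the seed and configuration needed to regenerate them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .balances import BalanceKind, LegumeObservation
from .distributions import BetaParams, GammaParams
from .errors import ValidationError
from .priors import PriorSet

__all__ = [
    "OBSERVATION_COLUMNS",
    "read_observations",
    "write_observations",
    "read_nhi",
    "write_prior_table",
    "read_prior_table",
    "write_results_json",
]

OBSERVATION_COLUMNS = [
    "species",
    "study_id",
    "ndfa_pct",
    "aboveground_n_kg_ha",
    "seed_n_kg_ha",
    "root_factor",
]
_REQUIRED = ["species", "ndfa_pct", "aboveground_n_kg_ha", "seed_n_kg_ha"]
_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless for field data


def read_observations(path: str | Path) -> list[LegumeObservation]:
    """Read and validate an observation CSV.

    Raises :class:`~ndfa.errors.ValidationError` naming missing columns,
    or listing offending rows (1-based data line numbers) when records
    fail validation.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    observations: list[LegumeObservation] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        try:
            rf = row.get("root_factor", None)
            sid = row.get("study_id", None)
            observations.append(
                LegumeObservation(
                    species=str(row["species"]),
                    ndfa_pct=float(row["ndfa_pct"]),
                    aboveground_n=float(row["aboveground_n_kg_ha"]),
                    seed_n=float(row["seed_n_kg_ha"]),
                    root_factor=None if rf is None or pd.isna(rf) else float(rf),
                    study_id=None if sid is None or pd.isna(sid) else str(sid),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i + 1}: {exc}")
    if problems:
        raise ValidationError(f"{path}: invalid rows:\n" + "\n".join(problems))
    return observations


def write_observations(
    observations: list[LegumeObservation], path: str | Path, header_note: str = ""
) -> None:
    """Write observations in the standard CSV schema.

    ``header_note`` (e.g. the generating seed/config) is embedded as a
    ``#`` comment line that readers skip.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "species": [o.species for o in observations],
            "study_id": [o.study_id for o in observations],
            "ndfa_pct": [o.ndfa_pct for o in observations],
            "aboveground_n_kg_ha": [o.aboveground_n for o in observations],
            "seed_n_kg_ha": [o.seed_n for o in observations],
            "root_factor": [o.root_factor for o in observations],
        }
    )
    with path.open("w", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_nhi(path: str | Path) -> pd.DataFrame:
    """Read an NHI sample table with columns ``species`` and ``nhi``."""
    df = pd.read_csv(Path(path), comment="#")
    missing = [c for c in ("species", "nhi") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    return df


def write_prior_table(priors: list[PriorSet], path: str | Path, header_note: str = "") -> None:
    """Serialize prior sets to CSV, one row per (species, balance kind)."""
    rows = [
        {
            "species": p.species,
            "kind": p.balance_kind.value,
            "theta_alpha": p.theta_prior.alpha,
            "theta_beta": p.theta_prior.beta,
            "beta1_shape": p.beta1_prior.shape,
            "beta1_rate": p.beta1_prior.rate,
            "sigma_shape": p.sigma_prior.shape,
            "sigma_rate": p.sigma_prior.rate,
        }
        for p in priors
    ]
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        pd.DataFrame(rows).to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_prior_table(path: str | Path) -> list[PriorSet]:
    """Read back a prior table written by :func:`write_prior_table`."""
    df = pd.read_csv(Path(path), comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(
            PriorSet(
                theta_prior=BetaParams(row["theta_alpha"], row["theta_beta"]),
                species=str(row["species"]),
                balance_kind=BalanceKind(row["kind"]),
                beta1_prior=GammaParams(row["beta1_shape"], row["beta1_rate"]),
                sigma_prior=GammaParams(row["sigma_shape"], row["sigma_rate"]),
            )
        )
    return out


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, BalanceKind):
        return obj.value
    return obj


def write_results_json(payload: dict, path: str | Path) -> None:
    """Write a structured result dictionary as UTF-8 JSON."""
    Path(path).write_text(
        json.dumps(_jsonable(payload), indent=2) + "\n", encoding="utf-8"
    )
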