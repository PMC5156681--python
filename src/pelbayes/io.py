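"""Trial-table CSV I/O and flat YAML config handling.

A trial table is a pandas DataFrame with the columns in
``pelbayes.simulate.TRIAL_COLUMNS``: condition label, number of lines,
semicolon-joined pitches (empty for dark rows), line length in degrees
(empty for dark rows), reported PEL in degrees, trial index and seed
provenance.  ``read_trials`` validates the header and every angle field,
reporting the offending row number; ``write_trials(read_trials(p))`` is an
identity.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .core import GaussianBelief, ModelParams
from .simulate import TRIAL_COLUMNS, ExperimentDesign

__all__ = ["read_trials", "write_trials", "load_config", "params_from_config", "design_from_config"]


class TrialTableError(ValueError):
    """Malformed trial table (missing columns, bad angles, empty file)."""


def _check_pitches(raw: object, n_lines: int, row: int) -> None:
    text = "" if raw is None or (isinstance(raw, float) and math.isnan(raw)) else str(raw).strip()
    if n_lines == 0:
        if text:
            raise TrialTableError(f"row {row}: dark trial has pitches {text!r}")
        return
    tokens = text.split(";") if text else []
    if len(tokens) != n_lines:
        raise TrialTableError(
            f"row {row}: expected {n_lines} pitch(es), got {text!r}"
        )
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            raise TrialTableError(f"row {row}: non-numeric pitch {tok!r} in {text!r}") from None


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises :class:`TrialTableError` naming the first bad row; row numbers
    count data rows from 1 (the header is row 0).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"condition_id": str, "pitches": str})
    except pd.errors.EmptyDataError:
        raise TrialTableError(f"{path}: empty trial table (no header)") from None
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    if df.empty:
        raise TrialTableError(f"{path}: trial table has a header but no rows")

    df["pitches"] = df["pitches"].fillna("")
    for col in ("n_lines", "trial_idx", "seed"):
        if not pd.api.types.is_integer_dtype(df[col]):
            try:
                df[col] = df[col].astype(int)
            except (ValueError, TypeError):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                row = int(bad[0]) + 1 if len(bad) else 1
                raise TrialTableError(f"{path}: row {row}: non-integer {col}") from None
    for col in ("length_deg", "reported_pel_deg"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise TrialTableError(
                f"{path}: row {int(bad[0]) + 1}: non-numeric {col} {df[col].iloc[bad[0]]!r}"
            )
        df[col] = coerced
    bad_pel = df.index[df["reported_pel_deg"].isna()]
    if len(bad_pel):
        raise TrialTableError(f"{path}: row {int(bad_pel[0]) + 1}: missing reported_pel_deg")

    for idx, rec in enumerate(df.itertuples(index=False), start=1):
        _check_pitches(rec.pitches, int(rec.n_lines), idx)
        if int(rec.n_lines) > 0 and math.isnan(rec.length_deg):
            raise TrialTableError(f"{path}: row {idx}: line trial missing length_deg")

    return df[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV (degrees as decimal numbers)."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialTableError(f"cannot write trial table: missing columns {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a flat key/value YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of keys to values")
    return cfg


def params_from_config(cfg: dict[str, Any]) -> ModelParams:
    """Build observer parameters from config keys.

    Recognized keys: ``prior_mean``, ``prior_sd``, and either ``sigma_vi``
    (mapping of line length to std) or ``sigma_vl``.
    """
    prior = GaussianBelief(
        mean=float(cfg["prior_mean"]), variance=float(cfg["prior_sd"]) ** 2
    )
    if "sigma_vi" in cfg and "sigma_vl" in cfg:
        raise ValueError("config sets both sigma_vi and sigma_vl; choose one")
    if "sigma_vi" in cfg:
        sigma_vi = {float(k): float(v) for k, v in cfg["sigma_vi"].items()}
        return ModelParams(prior=prior, sigma_vi=sigma_vi)
    if "sigma_vl" in cfg:
        return ModelParams(prior=prior, sigma_vl=float(cfg["sigma_vl"]))
    raise ValueError("config must set sigma_vi (per-length map) or sigma_vl")


def design_from_config(cfg: dict[str, Any]) -> ExperimentDesign:
    """Build an experiment design from config keys (defaults preserved)."""
    kwargs: dict[str, Any] = {}
    if "dark_trials" in cfg:
        kwargs["dark_trials"] = int(cfg["dark_trials"])
    if "trials_per_condition" in cfg:
        kwargs["trials_per_condition"] = int(cfg["trials_per_condition"])
    if "pitch_grid" in cfg:
        kwargs["pitch_grid"] = tuple(float(p) for p in cfg["pitch_grid"])
    if "lengths" in cfg:
        kwargs["lengths"] = tuple(float(l) for l in cfg["lengths"])
    if "two_line_conditions" in cfg:
        kwargs["two_line_conditions"] = tuple(
            (float(a), float(b)) for a, b in cfg["two_line_conditions"]
        )
    if "seed" in cfg:
        kwargs["seed"] = int(cfg["seed"])
    return ExperimentDesign(**kwargs)
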