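"""Prediction-error metrics and Bayesian vs Matin-Li comparison tables."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import LineStimulus, ModelParams, predict_pel
from .matin_li import MatinLiParams, predict_pel_matin_li

__all__ = ["standard_error_of_estimate", "ComparisonResult", "compare_models"]


def standard_error_of_estimate(
    predicted: Sequence[float],
    observed: Sequence[float],
    *,
    ddof: int = 0,
) -> float:
    """Standard error of estimation between predictions and observations.

    Computed as sqrt(sum((obs - pred)^2) / (n - ddof)).  The default
    ``ddof=0`` is the population RMSE convention; ``ddof=2`` gives the
    regression convention.  Nonnegative, zero iff the prediction is perfect,
    and invariant to row order.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.size != obs.size:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {obs.size} observations")
    if pred.size == 0:
        raise ValueError("cannot score empty prediction lists")
    if pred.size - ddof <= 0:
        raise ValueError(f"need more than {ddof} points for ddof={ddof}")
    return float(np.sqrt(np.sum((obs - pred) ** 2) / (pred.size - ddof)))


def _parse_pitches(raw: object) -> list[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return []
    text = str(raw).strip()
    if not text:
        return []
    return [float(tok) for tok in text.split(";")]


@dataclass(frozen=True)
class ComparisonResult:
    """Per-condition predictions of both models plus aggregate SEE.

    ``see`` maps model name to SEE over the rows where that model makes a
    prediction (the Matin-Li model makes none for dark rows, which have no
    line length).
    """

    table: pd.DataFrame
    see: dict[str, float]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_models(
    trials: pd.DataFrame,
    bayes: ModelParams,
    ml: MatinLiParams,
    *,
    per_trial: bool = False,
    ddof: int = 0,
) -> ComparisonResult:
    """Score the Bayesian and Matin-Li models side by side on a trial table.

    By default predictions are scored against condition-mean observed PEL
    (one row per condition); ``per_trial=True`` scores every trial.  Rows
    with lines but no line length are rejected.
    """
    if trials.empty:
        return ComparisonResult(
            table=pd.DataFrame(
                columns=[
                    "condition_id", "n_lines", "pitches", "length_deg",
                    "n_trials", "observed_pel_deg", "bayes_pred_deg", "matin_li_pred_deg",
                ]
            ),
            see={"bayes": math.nan, "matin_li": math.nan},
        )

    bad = trials[(trials["n_lines"] > 0) & (trials["length_deg"].isna())]
    if not bad.empty:
        raise ValueError(
            f"{len(bad)} line trials are missing length_deg (e.g. condition "
            f"{bad.iloc[0]['condition_id']!r})"
        )

    rows = []
    grouped = trials.groupby("condition_id", sort=False)
    for cond, grp in grouped:
        n_lines = int(grp["n_lines"].iloc[0])
        pitches = _parse_pitches(grp["pitches"].iloc[0])
        length = float(grp["length_deg"].iloc[0]) if n_lines > 0 else math.nan

        if n_lines == 0:
            bayes_pred = bayes.prior.mean
            ml_pred = math.nan
        else:
            stimuli = [LineStimulus(p, length) for p in pitches]
            bayes_pred = predict_pel(stimuli, bayes)
            ml_pred = predict_pel_matin_li(pitches, length, ml)

        if per_trial:
            for _, trial in grp.iterrows():
                rows.append(
                    {
                        "condition_id": cond,
                        "n_lines": n_lines,
                        "pitches": grp["pitches"].iloc[0],
                        "length_deg": length,
                        "n_trials": 1,
                        "observed_pel_deg": float(trial["reported_pel_deg"]),
                        "bayes_pred_deg": bayes_pred,
                        "matin_li_pred_deg": ml_pred,
                    }
                )
        else:
            rows.append(
                {
                    "condition_id": cond,
                    "n_lines": n_lines,
                    "pitches": grp["pitches"].iloc[0],
                    "length_deg": length,
                    "n_trials": len(grp),
                    "observed_pel_deg": float(grp["reported_pel_deg"].mean()),
                    "bayes_pred_deg": bayes_pred,
                    "matin_li_pred_deg": ml_pred,
                }
            )

    table = pd.DataFrame(rows)
    see: dict[str, float] = {}
    for model, col in (("bayes", "bayes_pred_deg"), ("matin_li", "matin_li_pred_deg")):
        scored = table.dropna(subset=[col])
        see[model] = (
            standard_error_of_estimate(
                scored[col], scored["observed_pel_deg"], ddof=ddof
            )
            if not scored.empty
            else math.nan
        )
    return ComparisonResult(table=table, see=see)
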