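"""Calibrate observer parameters from behavioral PEL data.

The body prior comes from dark-condition settings (sample mean and std).
Visual likelihood variances come from the slope of mean PEL on pitch in
single-line sweeps: for a Bayesian observer that slope is

    m = sigma_b^2 / (sigma_b^2 + sigma_v^2),

so the visual variance follows as sigma_v^2 = |sigma_b^2 / m - sigma_b^2|.
The absolute value covers empirical slopes above 1, which are inconsistent
with the Gaussian-fusion reading (a warning is emitted, never a silent
clamp).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GaussianBelief, ModelParams

__all__ = [
    "SlopeFit",
    "CalibrationResult",
    "fit_dark_prior",
    "fit_single_line_slope",
    "variance_from_slope",
    "slope_from_variances",
    "sigma_vl_from_length",
    "calibrate_trials",
]


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of mean PEL on line pitch for a single-line sweep."""

    slope: float
    intercept: float
    residual_std: float
    n_points: int

    @property
    def bayes_consistent(self) -> bool:
        """Whether the slope admits a Gaussian-fusion reading (0 < m < 1)."""
        return 0.0 < self.slope < 1.0


def fit_dark_prior(settings: Sequence[float]) -> GaussianBelief:
    """Body prior from dark-condition PEL settings.

    Returns the sample mean and sample standard deviation (ddof=1) as
    (mu_b, sigma_b).  Constant settings produce a degenerate zero-variance
    belief and a warning.
    """
    x = np.asarray(settings, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 dark settings, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dark settings must be finite")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        warnings.warn("dark settings are constant; prior std is degenerate (0)", stacklevel=2)
    return GaussianBelief(mean=float(np.mean(x)), variance=sd * sd)


def fit_single_line_slope(
    pitches: Sequence[float], mean_pel: Sequence[float]
) -> SlopeFit:
    """Ordinary least-squares regression of mean PEL on line pitch."""
    x = np.asarray(pitches, dtype=float)
    y = np.asarray(mean_pel, dtype=float)
    if x.size != y.size:
        raise ValueError(f"pitches ({x.size}) and mean_pel ({y.size}) differ in length")
    if x.size < 2:
        raise ValueError("need at least 2 points to fit a slope")
    if np.ptp(x) == 0:
        raise ValueError("all pitches identical; slope is undefined")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    dof = x.size - 2
    resid_std = float(np.sqrt(np.sum((y - fitted) ** 2) / dof)) if dof > 0 else 0.0
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_std=resid_std,
        n_points=int(x.size),
    )


def variance_from_slope(m: float, prior_var: float) -> float:
    """Visual likelihood variance implied by a single-line slope.

    sigma_v^2 = |sigma_b^2 / m - sigma_b^2|.  A slope of 0 means the visual
    cue had no measurable effect and raises; a slope above 1 triggers a
    warning because the absolute value then masks a sign inversion.
    """
    if prior_var <= 0:
        raise ValueError(f"prior variance must be positive, got {prior_var}")
    if m == 0:
        raise ValueError("slope is 0: visual cue had no measurable effect on PEL")
    if m > 1 or m < 0:
        warnings.warn(
            f"slope m={m} outside (0, 1); absolute value applied but the fit is "
            "inconsistent with Gaussian prior-likelihood fusion",
            stacklevel=2,
        )
    return abs(prior_var / m - prior_var)


def slope_from_variances(prior_var: float, visual_var: float) -> float:
    """Predicted single-line slope m = sigma_b^2 / (sigma_b^2 + sigma_v^2)."""
    if prior_var <= 0 or visual_var <= 0:
        raise ValueError("variances must be positive")
    return prior_var / (prior_var + visual_var)


def sigma_vl_from_length(sigma_vi: float, length_deg: float) -> float:
    """Length-free noise constant: sigma_vl = sigma_vi * sqrt(l)."""
    if sigma_vi <= 0 or length_deg <= 0:
        raise ValueError("sigma_vi and length must be positive")
    return sigma_vi * math.sqrt(length_deg)


@dataclass(frozen=True)
class CalibrationResult:
    """Full calibration of the observer model from a trial table.

    ``slopes`` maps line length to the single-line :class:`SlopeFit` used to
    derive its likelihood std; ``implied_intercepts`` gives the model-implied
    intercept (1 - m) * mu_b for each length, reported alongside the fitted
    intercept because the two need not agree in empirical data.
    """

    prior: GaussianBelief
    slopes: Mapping[float, SlopeFit]
    params: ModelParams

    @property
    def sigma_vi(self) -> dict[float, float]:
        assert self.params.sigma_vi is not None
        return dict(self.params.sigma_vi)

    @property
    def implied_intercepts(self) -> dict[float, float]:
        return {
            length: (1.0 - fit.slope) * self.prior.mean
            for length, fit in self.slopes.items()
        }


def calibrate_trials(trials: pd.DataFrame, *, raw: bool = False) -> CalibrationResult:
    """Run the full calibration pipeline on a trial table.

    Dark rows (``n_lines == 0``) give the prior; single-line rows give, per
    line length, an OLS slope of condition-mean PEL on pitch (``raw=True``
    regresses on individual trials instead of condition means) from which the
    likelihood std follows via :func:`variance_from_slope`.
    """
    dark = trials.loc[trials["n_lines"] == 0, "reported_pel_deg"]
    if dark.size < 2:
        raise ValueError("calibration needs at least 2 dark trials")
    prior = fit_dark_prior(dark.to_numpy())

    single = trials[trials["n_lines"] == 1]
    if single.empty:
        raise ValueError("calibration needs single-line trials")

    slopes: dict[float, SlopeFit] = {}
    sigma_map: dict[float, float] = {}
    for length, grp in single.groupby("length_deg"):
        pitch = grp["pitches"].astype(float)
        if raw:
            fit = fit_single_line_slope(pitch.to_numpy(), grp["reported_pel_deg"].to_numpy())
        else:
            means = grp.assign(pitch=pitch).groupby("pitch")["reported_pel_deg"].mean()
            fit = fit_single_line_slope(means.index.to_numpy(), means.to_numpy())
        slopes[float(length)] = fit
        sigma_map[float(length)] = math.sqrt(variance_from_slope(fit.slope, prior.variance))

    params = ModelParams(prior=prior, sigma_vi=sigma_map)
    return CalibrationResult(prior=prior, slopes=slopes, params=params)
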