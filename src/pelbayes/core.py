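"""Gaussian fusion core for perceived-eye-level (PEL) prediction.

Perceived eye level is modeled as the posterior of a Bayesian observer who
combines an internally generated Gaussian "body" prior over elevation
(proprioceptive/vestibular, measured in darkness) with one Gaussian visual
likelihood per pitched illuminated line.  A line pitched by ``theta`` degrees
is read, under the geometric interpretation, as a vertical line seen from an
eye level shifted by ``theta``; the per-line likelihood is therefore centered
on the pitch itself, N(theta_i, sigma_vi^2).

All angles are signed degrees of elevation with 0 at true eye level and
positive upward.  All internal arithmetic is carried out on variances
(deg^2); standard deviations appear only at the API surface.

Two noise parameterizations are supported:

* a per-length map ``length -> sigma_vi`` (one calibrated visual noise per
  line length), the default prediction path; and
* a single length-free constant ``sigma_vl`` with the scaling
  ``sigma_vi = sigma_vl / sqrt(l)``, which treats each unit of line length
  as an independent sample and allows extrapolation to unseen lengths (and
  mixed-length displays) at the cost of an independence assumption that
  becomes questionable for long lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "GaussianBelief",
    "LineStimulus",
    "ModelParams",
    "combine_gaussians",
    "visual_likelihood",
    "predict_pel",
    "predict_pel_varying",
    "a_of_l",
    "posterior",
]


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian belief over eye-level elevation.

    Parameters
    ----------
    mean : float
        Location in signed degrees of elevation.
    variance : float
        Spread in deg^2.  ``math.inf`` marks an explicitly uninformative
        belief (zero precision); ``0.0`` marks a degenerate point belief
        (infinite precision), which can arise from constant calibration
        data and is flagged by the calibration routines.
    """

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"belief mean must be finite, got {self.mean}")
        if math.isnan(self.variance) or self.variance < 0:
            raise ValueError(f"belief variance must be >= 0, got {self.variance}")

    @classmethod
    def uninformative(cls) -> "GaussianBelief":
        """A flat belief contributing zero precision to any fusion."""
        return cls(mean=0.0, variance=math.inf)

    @property
    def is_informative(self) -> bool:
        return math.isfinite(self.variance)

    @property
    def precision(self) -> float:
        """Inverse variance in deg^-2 (0 for uninformative beliefs)."""
        if math.isinf(self.variance):
            return 0.0
        if self.variance == 0.0:
            return math.inf
        return 1.0 / self.variance

    @property
    def std(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class LineStimulus:
    """One pitched illuminated line.

    ``pitch_deg`` is the signed pitch angle theta (positive pitch pulls the
    perceived eye level upward); ``length_deg`` is the angular length of the
    line, used to resolve its visual noise.
    """

    pitch_deg: float
    length_deg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pitch_deg):
            raise ValueError(f"pitch must be finite, got {self.pitch_deg}")
        if not (self.length_deg > 0 and math.isfinite(self.length_deg)):
            raise ValueError(f"line length must be positive, got {self.length_deg}")


@dataclass(frozen=True)
class ModelParams:
    """Bayesian observer parameters: body prior plus visual noise model.

    Exactly one of ``sigma_vi`` (map from line length in degrees to the
    per-length likelihood std, degrees) and ``sigma_vl`` (length-free noise
    constant, degrees * sqrt(degrees)) must be provided.
    """

    prior: GaussianBelief
    sigma_vi: Mapping[float, float] | None = None
    sigma_vl: float | None = None

    def __post_init__(self) -> None:
        if (self.sigma_vi is None) == (self.sigma_vl is None):
            raise ValueError("exactly one of sigma_vi (per-length map) and sigma_vl must be set")
        if self.sigma_vi is not None:
            for length, sd in self.sigma_vi.items():
                if not (length > 0 and sd > 0):
                    raise ValueError(f"sigma_vi map entries must be positive, got {length}: {sd}")
        if self.sigma_vl is not None and not (self.sigma_vl > 0):
            raise ValueError(f"sigma_vl must be positive, got {self.sigma_vl}")

    @property
    def uses_length_scaling(self) -> bool:
        return self.sigma_vl is not None

    def sigma_for_length(self, length_deg: float) -> float:
        """Visual likelihood std (degrees) for a line of the given length."""
        if self.sigma_vl is not None:
            return self.sigma_vl / math.sqrt(length_deg)
        assert self.sigma_vi is not None
        for known, sd in self.sigma_vi.items():
            if math.isclose(known, length_deg, rel_tol=1e-9, abs_tol=1e-9):
                return sd
        known_lengths = sorted(self.sigma_vi)
        raise KeyError(
            f"no calibrated sigma_vi for line length {length_deg} deg "
            f"(known lengths: {known_lengths}); set sigma_vl to enable "
            "length scaling"
        )

    @property
    def k(self) -> float:
        """Noise-to-prior variance ratio k = sigma_vl^2 / sigma_b^2.

        Only defined on the length-scaled path; governs how fast the prior's
        pull a(l) decays with line length and number of lines.
        """
        if self.sigma_vl is None:
            raise ValueError("k requires the length-scaled noise model (sigma_vl)")
        return self.sigma_vl**2 / self.prior.variance


def combine_gaussians(beliefs: Sequence[GaussianBelief]) -> GaussianBelief:
    """Fuse Gaussian beliefs by multiplying their densities.

    The product of Gaussian densities is (after normalization) Gaussian with
    precision equal to the sum of the input precisions and mean equal to the
    precision-weighted average of the input means.  Uninformative inputs
    contribute zero precision and drop out.

    Raises
    ------
    ValueError
        If ``beliefs`` is empty, or every input is uninformative, or two
        degenerate (zero-variance) inputs disagree on the mean.
    """
    if len(beliefs) == 0:
        raise ValueError("cannot combine an empty list of beliefs")

    degenerate = [b for b in beliefs if b.variance == 0.0]
    if degenerate:
        mean = degenerate[0].mean
        if any(not math.isclose(b.mean, mean, abs_tol=1e-12) for b in degenerate[1:]):
            raise ValueError("conflicting zero-variance beliefs cannot be combined")
        return GaussianBelief(mean=mean, variance=0.0)

    total_precision = sum(b.precision for b in beliefs)
    if total_precision == 0.0:
        raise ValueError("all beliefs are uninformative; fusion carries no information")
    mean = sum(b.precision * b.mean for b in beliefs) / total_precision
    return GaussianBelief(mean=mean, variance=1.0 / total_precision)


def _line_likelihood(stim: LineStimulus, params: ModelParams) -> GaussianBelief:
    sd = params.sigma_for_length(stim.length_deg)
    return GaussianBelief(mean=stim.pitch_deg, variance=sd * sd)


def visual_likelihood(stimuli: Sequence[LineStimulus], params: ModelParams) -> GaussianBelief:
    """Composite visual likelihood from one or more pitched lines.

    Equals the Gaussian fusion of the per-line likelihoods
    N(theta_i, sigma_vi^2).  For n lines of a common length this reduces to
    mean(theta_i) with variance sigma_vi^2 / n.
    """
    if len(stimuli) == 0:
        raise ValueError("visual likelihood requires at least one stimulus")
    return combine_gaussians([_line_likelihood(s, params) for s in stimuli])


def posterior(stimuli: Sequence[LineStimulus], params: ModelParams) -> GaussianBelief:
    """Full posterior belief (mean and variance) over eye level.

    Fuses the body prior with the composite visual likelihood; with no
    stimuli the posterior is the prior itself.  The posterior variance never
    exceeds the prior's or the composite likelihood's.
    """
    if len(stimuli) == 0:
        return params.prior
    return combine_gaussians([params.prior, visual_likelihood(stimuli, params)])


def predict_pel(stimuli: Sequence[LineStimulus], params: ModelParams) -> float:
    """Predicted mean PEL (degrees) on the per-length path.

    With the per-length noise map all stimuli must share one line length
    (the constant-length simplification); mixed-length displays must go
    through :func:`predict_pel_varying` with the length-scaled noise model.
    """
    if len(stimuli) >= 2 and not params.uses_length_scaling:
        lengths = {s.length_deg for s in stimuli}
        if len(lengths) > 1:
            raise ValueError(
                "mixed line lengths with the per-length noise map; use "
                "predict_pel_varying with sigma_vl for varying lengths"
            )
    return posterior(stimuli, params).mean


def predict_pel_varying(stimuli: Sequence[LineStimulus], params: ModelParams) -> float:
    """Predicted mean PEL for lines of (possibly) differing lengths.

    Substitutes the per-line variance sigma_vl^2 / l_i into the general
    precision-weighted fusion.  Requires the length-scaled noise model; for
    equal lengths it agrees with :func:`predict_pel` when
    sigma_vi = sigma_vl / sqrt(l).
    """
    if not params.uses_length_scaling:
        raise ValueError("predict_pel_varying requires sigma_vl (length-scaled noise)")
    return posterior(stimuli, params).mean


def a_of_l(length_deg: float, n: int, params: ModelParams) -> float:
    """Residual pull of the body prior, a(l) = mu_b / (1 + n*l/k).

    ``k = sigma_vl^2 / sigma_b^2``.  Shrinks in magnitude as the number of
    lines ``n`` or the line length grows (the visual evidence overwhelms the
    prior); equals mu_b at n = 0.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if not (length_deg > 0):
        raise ValueError(f"length must be positive, got {length_deg}")
    return params.prior.mean / (1.0 + n * length_deg / params.k)
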