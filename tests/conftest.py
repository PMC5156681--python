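"""Shared fixtures: published parameter sets and a brute-force fusion oracle."""

import numpy as np
import pytest

from pelbayes import GaussianBelief, ModelParams

# Published observer parameters (dark prior + per-length likelihood stds).
PRIOR_MEAN = -0.622
PRIOR_SD = 2.08
SIGMA_SHORT = 5.12  # 12 deg line
SIGMA_LONG = 3.01  # 64 deg line
SHORT_LEN = 12.0
LONG_LEN = 64.0


@pytest.fixture
def published_params() -> ModelParams:
    return ModelParams(
        prior=GaussianBelief(mean=PRIOR_MEAN, variance=PRIOR_SD**2),
        sigma_vi={SHORT_LEN: SIGMA_SHORT, LONG_LEN: SIGMA_LONG},
    )


def grid_fusion(means, variances, lo=-90.0, hi=90.0, step=0.001):
    """Brute-force oracle: numerically integrate the product of Gaussian
    densities over [lo, hi] and return the mean/variance of the normalized
    product.  Independent of the closed-form path it is used to check.
    """
    x = np.arange(lo, hi + step, step)
    log_p = np.zeros_like(x)
    for m, v in zip(means, variances):
        log_p -= (x - m) ** 2 / (2.0 * v)
    p = np.exp(log_p - log_p.max())
    z = np.trapezoid(p, x)
    mean = np.trapezoid(x * p, x) / z
    var = np.trapezoid((x - mean) ** 2 * p, x) / z
    return mean, var
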