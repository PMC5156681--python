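"""The Matin-Li behavioral model of perceived eye level.

An empirically fitted description of PEL under n pitched lines of a common
length l:

    PEL = a + k1 * sum(theta_i) / (k2 / l + n)

with per-length offset ``a`` (degrees) and shared constants ``k1``
(dimensionless gain) and ``k2`` (degrees, so k2/l is dimensionless).  Used
here purely as a comparison baseline; refitting k1/k2 from new data is out
of scope (the constants are inputs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = ["MatinLiParams", "MATIN_LI_REFERENCE", "predict_pel_matin_li"]


@dataclass(frozen=True)
class MatinLiParams:
    """Constants of the Matin-Li model.

    ``a`` maps line length (degrees) to the per-length offset; ``k1`` and
    ``k2`` are shared across lengths.
    """

    a: Mapping[float, float]
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.k2 > 0):
            raise ValueError(f"k2 must be positive, got {self.k2}")

    def a_for_length(self, length_deg: float) -> float:
        for known, value in self.a.items():
            if math.isclose(known, length_deg, rel_tol=1e-9, abs_tol=1e-9):
                return value
        raise KeyError(
            f"no offset a for line length {length_deg} deg (known: {sorted(self.a)})"
        )


#: Published constants fitted to the original two-length data set
#: (short 12 deg / long 64 deg lines).
MATIN_LI_REFERENCE = MatinLiParams(a={12.0: -0.29, 64.0: -4.61}, k1=0.51, k2=19.44)


def predict_pel_matin_li(
    pitches: Sequence[float], length_deg: float, params: MatinLiParams
) -> float:
    """Evaluate PEL = a + k1 * sum(theta_i) / (k2/l + n).

    ``n`` is the number of pitches.  With no pitches (dark) the prediction
    is the offset ``a`` alone.  The model is linear in sum(theta_i) with
    slope k1 / (k2/l + n).
    """
    if not (length_deg > 0):
        raise ValueError(f"line length must be positive, got {length_deg}")
    n = len(pitches)
    a = params.a_for_length(length_deg)
    if n == 0:
        return a
    return a + params.k1 * sum(pitches) / (params.k2 / length_deg + n)
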