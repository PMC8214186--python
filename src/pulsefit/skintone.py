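"""Skin pigmentation via the individual typology angle (ITA).

ITA is computed from the CIELAB lightness L* and yellow-blue axis b* of a
spectrocolorimetry measurement:

    ITA = arctan((L* - 50) / b*) × 180 / 3.14159   (degrees)

and classified into the six conventional groups (very light ... dark) using
the cutoff chain 55° / 41° / 28° / 10° / -30°.  The 180/3.14159 constant is
kept verbatim by default so outputs match the conventional arithmetic
digit-for-digit; ``exact_pi=True`` switches to the true π.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .config import DEFAULT_ITA_CUTOFFS, ITA_CATEGORIES
from .errors import ValidationError

DEGREES_PER_RADIAN_APPROX = 180.0 / 3.14159


def compute_ita(L_star: float, b_star: float, exact_pi: bool = False) -> float:
    """Individual typology angle in degrees from CIELAB L* and b*.

    b* <= 0 can occur on instrument noise; the two-argument arctangent then
    resolves the angle toward the ±90° limits by the sign of L*-50 (with a
    warning), instead of dividing by a non-positive b*.
    """
    scale = 180.0 / math.pi if exact_pi else DEGREES_PER_RADIAN_APPROX
    if b_star > 0:
        return math.atan((L_star - 50.0) / b_star) * scale
    if b_star == 0 and L_star == 50.0:
        raise ValidationError("ITA undefined at L*=50, b*=0")
    warnings.warn(
        f"b*={b_star:g} <= 0: resolving ITA via two-argument arctangent",
        stacklevel=2,
    )
    return math.atan2(L_star - 50.0, b_star) * scale


def classify_ita(ita: float, cutoffs: tuple[float, ...] = DEFAULT_ITA_CUTOFFS) -> str:
    """Map an ITA in degrees to its six-group skin-tone category.

    Boundary convention: a value strictly above a cutoff belongs to the
    lighter category; the cutoff value itself to the darker one (e.g. 55°
    is 'light', 55.01° is 'very light').
    """
    if not math.isfinite(ita):
        raise ValidationError("ITA must be finite")
    for cutoff, category in zip(cutoffs, ITA_CATEGORIES):
        if ita > cutoff:
            return category
    return ITA_CATEGORIES[-1]


@dataclass(frozen=True)
class ItaMeasurement:
    """One spectrocolorimetry reading with its derived angle and category."""

    L_star: float
    b_star: float
    ita_degrees: float
    category: str

    @classmethod
    def from_lab(cls, L_star: float, b_star: float,
                 cutoffs: tuple[float, ...] = DEFAULT_ITA_CUTOFFS,
                 exact_pi: bool = False) -> "ItaMeasurement":
        ita = compute_ita(L_star, b_star, exact_pi=exact_pi)
        return cls(L_star, b_star, ita, classify_ita(ita, cutoffs))
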