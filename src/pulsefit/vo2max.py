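"""VO2max estimation from field-test results.

Two submaximal/field protocols are supported:

* 3-minute step test (Tecumseh protocol): stepping at 24 steps/min on an
  8-inch step for 3 minutes; VO2max is predicted from the heart-beat count
  in the 30-60 s recovery window (HB3060) together with age and sex.
* 12-minute run test (Cooper protocol): VO2max is an affine function of the
  distance covered in 12 minutes (d12, meters).

Both regressions are affine with coefficients held in configuration
(config.StepCoefficients / config.RunCoefficients), each carrying a source
citation.  VO2max is in mL·kg⁻¹·min⁻¹ throughout; rounding happens only at
presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import RunCoefficients, StepCoefficients
from .errors import InsufficientDataError, ValidationError
from .ppg import HrWindowEstimate

# Plausibility bounds (warnings, not errors)
HB3060_BOUNDS = (22.5, 105.0)      # 45-210 bpm sustained over half a minute
D12_BOUNDS = (500.0, 6000.0)       # meters; guards a km-vs-m confusion


@dataclass(frozen=True)
class StepTestResult:
    hb3060: float
    age: float
    sex: int
    vo2max: float


@dataclass(frozen=True)
class RunTestResult:
    d12: float
    vo2max: float


def hb3060_from_windows(estimates: list[HrWindowEstimate], test_end: float) -> float:
    """Heart beats between 30 and 60 s after the step test ends.

    The 10-s analysis windows do not align with the 30-60 s counting
    interval, so HB3060 is the overlap-weighted mean of the valid fused HR
    over [test_end+30, test_end+60], converted to beats over the half minute.
    """
    t_lo, t_hi = test_end + 30.0, test_end + 60.0
    weights, rates = [], []
    for e in estimates:
        if not e.valid or e.fused_hr_bpm is None:
            continue
        overlap = min(e.window_end, t_hi) - max(e.window_start, t_lo)
        if overlap > 0:
            weights.append(overlap)
            rates.append(e.fused_hr_bpm)
    if not weights:
        raise InsufficientDataError(
            "no valid heart-rate window overlaps the 30-60 s recovery interval"
        )
    mean_bpm = float(np.average(rates, weights=weights))
    return mean_bpm * 0.5  # bpm over half a minute -> beats


def vo2max_step(hb3060: float, age: float, sex: int,
                coeffs: StepCoefficients = StepCoefficients()) -> float:
    """Step-test VO2max from recovery beats, age and sex (0 male, 1 female)."""
    if sex not in (0, 1):
        raise ValidationError(f"sex must be 0 (male) or 1 (female), got {sex!r}")
    if hb3060 <= 0:
        raise ValidationError("hb3060 must be positive")
    if not (HB3060_BOUNDS[0] <= hb3060 <= HB3060_BOUNDS[1]):
        warnings.warn(
            f"HB3060={hb3060:g} outside plausible range {HB3060_BOUNDS} "
            "(45-210 bpm over half a minute)", stacklevel=2,
        )
    vo2 = (coeffs.intercept + coeffs.hb3060_coef * hb3060
           + coeffs.age_coef * age + coeffs.sex_coef * sex)
    if vo2 <= 0:
        warnings.warn(f"non-physiological VO2max {vo2:g} mL/kg/min", stacklevel=2)
    return float(vo2)


def vo2max_run(d12: float, coeffs: RunCoefficients = RunCoefficients()) -> float:
    """Run-test VO2max from the 12-minute distance in meters."""
    if d12 <= 0:
        raise ValidationError("d12 must be a positive distance in meters")
    if not (D12_BOUNDS[0] <= d12 <= D12_BOUNDS[1]):
        warnings.warn(
            f"d12={d12:g} m outside plausible range {D12_BOUNDS}; "
            "check units (meters expected)", stacklevel=2,
        )
    return float((d12 - coeffs.distance_offset) / coeffs.distance_scale)


def step_test_result(hb3060: float, age: float, sex: int,
                     coeffs: StepCoefficients = StepCoefficients()) -> StepTestResult:
    return StepTestResult(hb3060, age, sex, vo2max_step(hb3060, age, sex, coeffs))


def run_test_result(d12: float,
                    coeffs: RunCoefficients = RunCoefficients()) -> RunTestResult:
    return RunTestResult(d12, vo2max_run(d12, coeffs))
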