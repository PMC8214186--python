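"""Central configuration for every tunable the estimators expose.

All defaults are documented in docs/methods.md; anything read from a JSON
config file is validated against the same bounds the owning module enforces.
Coefficient sets carry a mandatory, non-empty ``source`` citation string.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ConfigurationError


@dataclass(frozen=True)
class HrConfig:
    """Parameters of the windowed-autocorrelation heart-rate estimator.

    hr_min/hr_max bound the physiological search range in beats per minute;
    band is the zero-phase band-pass in Hz; peak_threshold is the spurious-peak
    magnitude cutoff relative to the lag-0 autocorrelation; confidence_cutoff
    is the QC validity threshold on the fused confidence score.
    """

    hr_min: float = 45.0
    hr_max: float = 210.0
    band: tuple[float, float] = (0.6, 4.0)
    filter_order: int = 4
    window_seconds: float = 10.0
    confidence_cutoff: float = 0.5
    peak_threshold: float = 0.25
    target_rate: float | None = None  # None -> resample at the series' nominal rate

    def __post_init__(self) -> None:
        if not (0 < self.hr_min < self.hr_max):
            raise ConfigurationError(
                f"require 0 < hr_min < hr_max, got {self.hr_min}, {self.hr_max}"
            )
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ConfigurationError(f"band must satisfy 0 < low < high, got {self.band}")
        if not (0 <= self.confidence_cutoff <= 1):
            raise ConfigurationError("confidence_cutoff must lie in [0, 1]")
        if not (0 <= self.peak_threshold <= 1):
            raise ConfigurationError("peak_threshold must lie in [0, 1]")
        if self.window_seconds <= 0:
            raise ConfigurationError("window_seconds must be positive")


@dataclass(frozen=True)
class StepCoefficients:
    """Affine coefficients of the step-test VO2max regression.

    vo2max = intercept + hb3060_coef*HB3060 + age_coef*age + sex_coef*sex
    with sex coded 0 for male, 1 for female.  The default set is Milligan's
    Tecumseh-family equation; ``source`` is mandatory so alternative sets
    remain traceable.
    """

    intercept: float = 83.477
    hb3060_coef: float = -0.586
    age_coef: float = -0.404
    sex_coef: float = -7.030
    source: str = (
        "Milligan (2013), Tecumseh 3-min step test regression on HB3060/age/sex"
    )

    def __post_init__(self) -> None:
        if not self.source:
            raise ConfigurationError("StepCoefficients.source must be non-empty")


@dataclass(frozen=True)
class RunCoefficients:
    """Affine coefficients of the 12-minute-run VO2max equation.

    vo2max = (d12 - distance_offset) / distance_scale, d12 in meters.
    Defaults are Cooper's original equation: (d12 - 504.9) / 44.73.
    """

    distance_offset: float = 504.9
    distance_scale: float = 44.73
    source: str = "Cooper (1968), JAMA 203:201-204, 12-minute field run test"

    def __post_init__(self) -> None:
        if self.distance_scale == 0:
            raise ConfigurationError("distance_scale must be nonzero")
        if not self.source:
            raise ConfigurationError("RunCoefficients.source must be non-empty")


@dataclass(frozen=True)
class SavgolParams:
    """Savitzky-Golay smoothing parameters for GPS trajectories (1 Hz)."""

    window_samples: int = 9
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window_samples % 2 == 0 or self.window_samples <= self.polyorder:
            raise ConfigurationError(
                "window_samples must be odd and greater than polyorder"
            )


# Individual typology angle category boundaries, degrees, lightest first.
# A value strictly above a cutoff belongs to the lighter category; the cutoff
# itself belongs to the darker-adjacent interval.
DEFAULT_ITA_CUTOFFS: tuple[float, ...] = (55.0, 41.0, 28.0, 10.0, -30.0)
ITA_CATEGORIES: tuple[str, ...] = (
    "very light",
    "light",
    "intermediate",
    "tan",
    "brown",
    "dark",
)


@dataclass(frozen=True)
class RunConfig:
    """Bundle of every configurable, serializable to/from JSON."""

    hr: HrConfig = field(default_factory=HrConfig)
    step: StepCoefficients = field(default_factory=StepCoefficients)
    run: RunCoefficients = field(default_factory=RunCoefficients)
    savgol: SavgolParams = field(default_factory=SavgolParams)
    ita_cutoffs: tuple[float, ...] = DEFAULT_ITA_CUTOFFS
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"config file is not valid JSON: {exc}") from exc
        kwargs = {}
        if "hr" in payload:
            hr = dict(payload["hr"])
            if "band" in hr:
                hr["band"] = tuple(hr["band"])
            kwargs["hr"] = HrConfig(**hr)
        if "step" in payload:
            kwargs["step"] = StepCoefficients(**payload["step"])
        if "run" in payload:
            kwargs["run"] = RunCoefficients(**payload["run"])
        if "savgol" in payload:
            kwargs["savgol"] = SavgolParams(**payload["savgol"])
        if "ita_cutoffs" in payload:
            kwargs["ita_cutoffs"] = tuple(payload["ita_cutoffs"])
        if "seed" in payload:
            kwargs["seed"] = payload["seed"]
        return cls(**kwargs)
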