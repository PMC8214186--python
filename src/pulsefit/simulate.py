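"""Synthetic data generators with known ground truth.

Every estimator in the package can be exercised offline against signals
whose true heart rate, path length or variance components are known
analytically.  Each generator is a pure function of its spec, including the
seed, so outputs are bitwise reproducible.

The PPG generator emulates a flash-illuminated fingertip capture: a
phase-continuous quasi-periodic pulse (optionally harmonic-rich, the hard
case for autocorrelation fundamental selection), per-channel gain (a crude
surrogate for skin tone and device optics), low-frequency baseline drift,
additive sensor noise, and an intensity offset into a 0-255-like range.
The heart-rate profile is either constant or a mono-exponential recovery
curve, the standard first-order model of post-exercise heart-rate decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .gps import DisplacementTrack, EARTH_RADIUS_M
from .ppg import ChannelSeries


@dataclass(frozen=True)
class ConstantHR:
    bpm: float

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(t, dtype=float), self.bpm)

    @property
    def max_bpm(self) -> float:
        return self.bpm


@dataclass(frozen=True)
class RecoveryHR:
    """Mono-exponential post-exercise recovery: asymptote + (start−asymptote)·e^(−t/τ)."""

    start_bpm: float
    asymptote_bpm: float
    tau_seconds: float

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.asymptote_bpm + (self.start_bpm - self.asymptote_bpm) * np.exp(
            -t / self.tau_seconds
        )

    @property
    def max_bpm(self) -> float:
        return max(self.start_bpm, self.asymptote_bpm)


# amplitude of each harmonic relative to the fundamental, index 0 = fundamental
SINUSOID = (1.0,)
HARMONIC_RICH = (1.0, 0.4)


@dataclass(frozen=True)
class PpgSimSpec:
    """Specification of one synthetic fingertip-PPG capture.

    channel_gains scale the pulse amplitude per channel (red, green, blue);
    noise_sd is the per-channel additive white-noise SD in intensity units;
    drift adds a slow sinusoidal baseline (amplitude, frequency Hz).
    """

    duration: float = 60.0
    rate: float = 60.0
    hr_profile: ConstantHR | RecoveryHR = field(default_factory=lambda: ConstantHR(75.0))
    harmonics: tuple[float, ...] = HARMONIC_RICH
    channel_gains: tuple[float, float, float] = (1.0, 1.0, 0.3)
    pulse_amplitude: float = 10.0
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_freq: float = 0.05
    baseline: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ConfigurationError("duration and rate must be positive")
        nyq_needed = 2.0 * self.hr_profile.max_bpm / 60.0 * len(self.harmonics)
        if self.rate < nyq_needed:
            raise ConfigurationError(
                f"rate {self.rate} Hz below the Nyquist requirement "
                f"{nyq_needed:g} Hz for the highest harmonic"
            )


def simulate_ppg(spec: PpgSimSpec, window_seconds: float = 10.0):
    """Generate a capture and the true mean HR of each full analysis window.

    Returns (ChannelSeries, true_window_hr) where true_window_hr[i] is the
    time-average of the instantaneous HR over window i.  The oscillator is
    phase-continuous: phase(t) = 2π/60 · ∫ hr(u) du.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    hr_t = spec.hr_profile.rate_at(t)
    # cumulative phase via trapezoidal integration of the instantaneous rate
    inst_freq = hr_t / 60.0
    phase = 2.0 * math.pi * np.concatenate(
        [[0.0], np.cumsum((inst_freq[1:] + inst_freq[:-1]) / 2.0) / spec.rate]
    )
    pulse = np.zeros(n)
    for i, amp in enumerate(spec.harmonics, start=1):
        pulse += amp * np.sin(i * phase)
    drift = spec.drift_amplitude * np.sin(2.0 * math.pi * spec.drift_freq * t)
    chans = {}
    for gain, name in zip(spec.channel_gains, ("red", "green", "blue")):
        noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0
        chans[name] = spec.baseline + gain * spec.pulse_amplitude * pulse + drift + noise
    series = ChannelSeries(timestamps=t, nominal_rate=spec.rate, **chans)
    n_per = int(round(window_seconds * spec.rate))
    n_win = n // n_per
    true_hr = np.array([
        hr_t[i * n_per:(i + 1) * n_per].mean() for i in range(n_win)
    ])
    return series, true_hr


@dataclass(frozen=True)
class TrackSimSpec:
    """Specification of one synthetic 1 Hz GPS displacement record."""

    shape: str = "line"                 # line | circle | waypoints
    speed: float = 2.0                  # m/s
    duration: float = 720.0             # s
    jitter_sd: float = 0.0              # meters per position coordinate
    dialect: str = "meters"
    anchor: tuple[float, float] | None = None
    radius: float = 100.0               # circle radius, m
    waypoints: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed < 0 or self.jitter_sd < 0:
            raise ConfigurationError("speed and jitter_sd must be non-negative")
        if self.dialect == "degrees" and self.anchor is None:
            raise ConfigurationError("degrees dialect requires an anchor")
        if self.dialect not in ("meters", "degrees"):
            raise ConfigurationError(f"unknown dialect {self.dialect!r}")


def _waypoint_positions(waypoints: np.ndarray, speed: float, n: int) -> np.ndarray:
    """Positions at 1 s intervals along a piecewise-linear waypoint path."""
    seg = np.diff(waypoints, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.minimum(np.arange(n) * speed, cum[-1])
    xs = np.interp(s, cum, waypoints[:, 0])
    ys = np.interp(s, cum, waypoints[:, 1])
    return np.column_stack([xs, ys])


def simulate_track(spec: TrackSimSpec):
    """Generate a displacement track of known true length.

    Returns (DisplacementTrack, true_length_m).  Noiseless positions are laid
    out at 1 Hz along the requested shape, iid Gaussian jitter is added per
    position, and consecutive differences are encoded in the requested
    dialect.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration)) + 1  # positions at t = 0..duration
    tsec = np.arange(n, dtype=float)
    if spec.shape == "line":
        pos = np.column_stack([spec.speed * tsec, np.zeros(n)])
        true_len = spec.speed * spec.duration
    elif spec.shape == "circle":
        omega = spec.speed / spec.radius
        theta = omega * tsec
        pos = spec.radius * np.column_stack([np.cos(theta), np.sin(theta)])
        true_len = spec.speed * spec.duration
    elif spec.shape == "waypoints":
        if spec.waypoints is None or len(spec.waypoints) < 2:
            raise ConfigurationError("waypoints shape needs >= 2 waypoints")
        wp = np.asarray(spec.waypoints, dtype=float)
        pos = _waypoint_positions(wp, spec.speed, n)
        true_len = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    else:
        raise ConfigurationError(f"unknown shape {spec.shape!r}")
    if spec.jitter_sd > 0:
        pos = pos + rng.normal(0.0, spec.jitter_sd, pos.shape)
    disp = np.diff(pos, axis=0)
    if spec.dialect == "meters":
        track = DisplacementTrack("meters", disp)
    else:
        lat0 = spec.anchor[0]  # type: ignore[index]
        phi0 = math.radians(lat0)
        dlat = np.degrees(disp[:, 1] / EARTH_RADIUS_M)
        dlon = np.degrees(disp[:, 0] / (EARTH_RADIUS_M * math.cos(phi0)))
        track = DisplacementTrack("degrees", np.column_stack([dlat, dlon]),
                                  anchor=spec.anchor)
    return track, float(true_len)


def simulate_agreement_cohort(n_subjects: int, repeats: int, subject_sd: float,
                              error_sd: float, bias: float = 0.0, seed: int = 0,
                              mean: float = 40.0):
    """Subject × repeat matrix with known variance components.

    value = mean + subject effect (SD subject_sd) + bias + noise (SD error_sd).
    Returns (matrix, true_icc) with
    true_icc = subject_sd² / (subject_sd² + error_sd²).
    """
    if n_subjects < 2 or repeats < 2:
        raise ConfigurationError("need >= 2 subjects and >= 2 repeats")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, subject_sd, (n_subjects, 1))
    noise = rng.normal(0.0, error_sd, (n_subjects, repeats))
    matrix = mean + bias + subj + noise
    denom = subject_sd ** 2 + error_sd ** 2
    true_icc = 1.0 if denom == 0 else subject_sd ** 2 / denom
    return matrix, float(true_icc)
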