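"""Heart-rate estimation from camera channel-mean time series.

A fingertip video capture is reduced on-device to the per-frame mean pixel
intensity of each color channel; those three time series are the only input.
The estimator resamples them to a uniform grid, band-pass filters and
mean-centers them, splits them into fixed-length analysis windows, and in
each window estimates the pulse period from the peak structure of the
normalized autocorrelation function (ACF).  A confidence score — the
normalized ACF magnitude at the selected fundamental lag — drives both
channel fusion (red vs green, maximum confidence wins) and quality control
(windows below the cutoff are flagged invalid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import HrConfig
from .errors import ConfigurationError, InsufficientDataError, ValidationError

CHANNELS = ("red", "green", "blue")


@dataclass
class ChannelSeries:
    """Timestamped per-frame mean red/green/blue intensities.

    timestamps are seconds since capture start (strictly increasing);
    nominal_rate is the camera frame rate in Hz (target 60).
    """

    timestamps: np.ndarray
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    nominal_rate: float = 60.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        for name in CHANNELS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.timestamps.shape:
                raise ValidationError(
                    f"channel '{name}' length {arr.size} != timestamps {self.timestamps.size}"
                )
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be positive")
        diffs = np.diff(self.timestamps)
        if np.any(diffs <= 0):
            bad = np.flatnonzero(diffs <= 0) + 1
            raise ValidationError(
                f"timestamps must be strictly increasing; offending indices {bad[:10].tolist()}"
            )

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if len(self) else 0.0

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise ValidationError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass
class AcfResult:
    """Normalized autocorrelation of one single-channel window.

    acf_values[0] == 1 after normalization; candidate_peaks are the
    (integer lag, normalized magnitude) local maxima inside the physiological
    lag band that survive the spurious-peak magnitude threshold.
    fundamental_lag is the sub-sample-refined lag of the strongest candidate,
    or None when no candidate survives.
    """

    lags: np.ndarray
    acf_values: np.ndarray
    candidate_peaks: list[tuple[int, float]]
    fundamental_lag: float | None
    lag_bounds: tuple[int, int]

    @property
    def fundamental_magnitude(self) -> float:
        """Normalized ACF at the (integer) fundamental lag; 0 if absent."""
        if self.fundamental_lag is None:
            return 0.0
        k = int(round(self.fundamental_lag))
        k = min(max(k, 0), self.acf_values.size - 1)
        return float(self.acf_values[k])

    @property
    def peak_ratio(self) -> float:
        """Magnitude ratio of the fundamental peak to the next candidate peak.

        Diagnostic alternative quality measure; >= 1 by construction and
        unbounded (infinite when the fundamental is the only candidate).
        """
        if self.fundamental_lag is None or not self.candidate_peaks:
            return 0.0
        mags = sorted((m for _, m in self.candidate_peaks), reverse=True)
        if len(mags) < 2:
            return math.inf
        return mags[0] / mags[1] if mags[1] > 0 else math.inf


@dataclass
class HrWindowEstimate:
    """Per-window heart-rate estimate with per-channel and fused confidence."""

    window_start: float
    window_end: float
    hr_bpm: dict = field(default_factory=dict)        # channel -> bpm or None
    confidence: dict = field(default_factory=dict)    # channel -> [0, 1]
    fused_hr_bpm: float | None = None
    fused_confidence: float = 0.0
    source_channel: str = "none"
    valid: bool = False


def resample_uniform(series: ChannelSeries, target_rate: float | None = None) -> ChannelSeries:
    """Linearly interpolate all channels onto a uniform time grid.

    Camera timestamps jitter; downstream filtering assumes uniform sampling.
    The grid runs from the first to the last timestamp at 1/target_rate
    spacing (default: the series' nominal rate).
    """
    if target_rate is None:
        target_rate = series.nominal_rate
    if target_rate <= 0:
        raise ConfigurationError("target_rate must be positive")
    if len(series) < 2:
        raise ValidationError("need at least 2 samples to resample")
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    n = int(math.floor((t1 - t0) * target_rate)) + 1
    grid = t0 + np.arange(n) / target_rate
    chans = {
        name: np.interp(grid, series.timestamps, series.channel(name))
        for name in CHANNELS
    }
    return ChannelSeries(timestamps=grid, nominal_rate=target_rate, **chans)


def preprocess(series: ChannelSeries, band: tuple[float, float] = (0.6, 4.0),
               order: int = 4) -> ChannelSeries:
    """Zero-phase band-pass filter and mean-center each channel.

    Expects uniform sampling (run resample_uniform first). The default
    0.6-4.0 Hz band covers the 45-210 bpm search range with margin.
    """
    lo, hi = band
    nyq = series.nominal_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ConfigurationError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({nyq:g} Hz)"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=series.nominal_rate,
                        output="sos")
    chans = {}
    for name in CHANNELS:
        x = series.channel(name)
        y = signal.sosfiltfilt(sos, x - np.mean(x))
        chans[name] = y - np.mean(y)
    return ChannelSeries(timestamps=series.timestamps.copy(),
                         nominal_rate=series.nominal_rate, **chans)


def split_windows(series: ChannelSeries, window_seconds: float = 10.0) -> list[ChannelSeries]:
    """Split into consecutive non-overlapping windows of window_seconds.

    A trailing partial window is discarded.  Raises InsufficientDataError
    when not even one full window fits.
    """
    n_per = int(round(window_seconds * series.nominal_rate))
    n_win = len(series) // n_per
    if n_win == 0:
        raise InsufficientDataError(
            f"capture of {series.duration:.1f} s is shorter than one "
            f"{window_seconds:g} s analysis window"
        )
    out = []
    for i in range(n_win):
        sl = slice(i * n_per, (i + 1) * n_per)
        out.append(ChannelSeries(
            timestamps=series.timestamps[sl].copy(),
            red=series.red[sl].copy(), green=series.green[sl].copy(),
            blue=series.blue[sl].copy(), nominal_rate=series.nominal_rate,
        ))
    return out


def _biased_acf(x: np.ndarray) -> np.ndarray:
    """Biased (1/N) autocorrelation, normalized so lag 0 equals 1."""
    n = x.size
    # FFT-based full autocorrelation; biased estimator divides by N uniformly,
    # which tapers long lags and regularizes peak selection.
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / n
    if acf[0] <= 0:
        return np.zeros(n)
    return acf / acf[0]


def lag_bounds(rate: float, hr_min: float, hr_max: float, n: int) -> tuple[int, int]:
    """Integer lag search band [shortest, longest] for the HR range.

    Inclusive of the boundary periods: the short-lag edge uses floor so that
    hr_max remains representable when its period is a non-integer sample
    count; sub-sample refinement recovers the fractional part.
    """
    lag_lo = max(1, int(math.floor(rate * 60.0 / hr_max)))
    lag_hi = int(math.ceil(rate * 60.0 / hr_min))
    lag_hi = min(lag_hi, n - 2)
    return lag_lo, lag_hi


def _parabolic_refine(y: np.ndarray, k: int) -> float:
    """Sub-sample peak location by quadratic interpolation around index k."""
    if k <= 0 or k >= y.size - 1:
        return float(k)
    denom = y[k - 1] - 2.0 * y[k] + y[k + 1]
    if denom == 0:
        return float(k)
    delta = 0.5 * (y[k - 1] - y[k + 1]) / denom
    return float(k) + float(np.clip(delta, -0.5, 0.5))


def compute_acf(window: np.ndarray, rate: float, hr_min: float = 45.0,
                hr_max: float = 210.0, peak_threshold: float = 0.25) -> AcfResult:
    """Normalized ACF of one window with physiological peak selection.

    Candidate peaks are local maxima of the normalized ACF whose lag lies in
    the band implied by [hr_min, hr_max] and whose magnitude is at least
    peak_threshold of the lag-0 magnitude (spurious-peak filter).  The
    fundamental is the maximum-magnitude candidate, refined to sub-sample
    precision; an absent fundamental is a valid outcome, not an error.
    """
    x = np.asarray(window, dtype=float)
    n = x.size
    lag_lo, lag_hi = lag_bounds(rate, hr_min, hr_max, n)
    if lag_hi < lag_lo:
        raise InsufficientDataError(
            "window too short for the requested heart-rate search band"
        )
    acf = _biased_acf(x)
    lags = np.arange(n)
    if not np.any(acf):  # constant window: zero-energy, no periodicity
        return AcfResult(lags, acf, [], None, (lag_lo, lag_hi))
    peaks, _ = signal.find_peaks(acf)
    peaks = peaks[(peaks >= lag_lo) & (peaks <= lag_hi)]
    candidates = [(int(k), float(acf[k])) for k in peaks if acf[k] >= peak_threshold]
    if not candidates:
        return AcfResult(lags, acf, [], None, (lag_lo, lag_hi))
    best_lag = max(candidates, key=lambda p: p[1])[0]
    refined = _parabolic_refine(acf, best_lag)
    return AcfResult(lags, acf, candidates, refined, (lag_lo, lag_hi))


def confidence_score(acf: AcfResult) -> float:
    """Quality score in [0, 1]: normalized ACF magnitude at the fundamental.

    The ACF maximum sits at lag 0 and equals 1 after normalization, so the
    fundamental-peak magnitude is directly the 'relative magnitude to the
    maxima'.  0 when no fundamental survived the spurious-peak filter.
    """
    if acf.fundamental_lag is None:
        return 0.0
    return float(np.clip(acf.fundamental_magnitude, 0.0, 1.0))


def estimate_window_hr(window: ChannelSeries, config: HrConfig = HrConfig()) -> HrWindowEstimate:
    """Estimate HR for one preprocessed analysis window with channel fusion.

    Red and green are estimated independently; the fused estimate comes from
    the channel with maximum confidence (green preferred on exact ties —
    hemoglobin absorbs most strongly at green wavelengths).  Blue is computed
    for diagnostics but never fused.  The estimate is valid when the fused
    confidence reaches the QC cutoff.
    """
    rate = window.nominal_rate
    est = HrWindowEstimate(
        window_start=float(window.timestamps[0]),
        window_end=float(window.timestamps[-1] + 1.0 / rate),
    )
    for name in CHANNELS:
        acf = compute_acf(window.channel(name), rate, config.hr_min, config.hr_max,
                          config.peak_threshold)
        conf = confidence_score(acf)
        if acf.fundamental_lag is not None and acf.fundamental_lag > 0:
            hr = rate * 60.0 / acf.fundamental_lag
            hr = float(np.clip(hr, config.hr_min, config.hr_max))
        else:
            hr = None
        est.hr_bpm[name] = hr
        est.confidence[name] = conf
    # fusion over red/green only; green wins ties deterministically
    fusable = [(est.confidence[c], c) for c in ("green", "red")
               if est.hr_bpm[c] is not None]
    if fusable:
        conf, chan = max(fusable, key=lambda p: p[0])
        est.fused_hr_bpm = est.hr_bpm[chan]
        est.fused_confidence = conf
        est.source_channel = chan
        est.valid = conf >= config.confidence_cutoff
    return est


def hr_timecourse(series: ChannelSeries, config: HrConfig = HrConfig()) -> list[HrWindowEstimate]:
    """Full pipeline: resample, filter, window, estimate each window.

    Invalid windows are retained in the output but flagged; use
    retained_fraction() for the QC summary.
    """
    uniform = resample_uniform(series, config.target_rate)
    filtered = preprocess(uniform, config.band, config.filter_order)
    windows = split_windows(filtered, config.window_seconds)
    return [estimate_window_hr(w, config) for w in windows]


def retained_fraction(estimates: list[HrWindowEstimate]) -> float:
    """Fraction of analysis windows passing the confidence cutoff."""
    if not estimates:
        return 0.0
    return sum(e.valid for e in estimates) / len(estimates)


def mean_valid_hr(estimates: list[HrWindowEstimate]) -> float:
    """Mean fused HR over valid windows (e.g. a 20-s resting capture).

    Raises InsufficientDataError when no window is valid.
    """
    vals = [e.fused_hr_bpm for e in estimates if e.valid and e.fused_hr_bpm is not None]
    if not vals:
        raise InsufficientDataError("no valid heart-rate windows to aggregate")
    return float(np.mean(vals))
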