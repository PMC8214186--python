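"""Method-agreement statistics for paired physiological measurements.

Implements the validation toolbox for comparing a test measurement against a
reference: Lin's concordance correlation coefficient (penalizing both
correlation loss and location/scale shift), Bland-Altman bias and 95% limits
of agreement, single-measure two-way absolute-agreement ICC for test-retest
reliability, absolute percent error, and the confidence-cutoff retention
curve used for windowed-measurement quality control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InsufficientDataError, ValidationError

ICC_VARIANT = "ICC(2,1) two-way random, single measure, absolute agreement"


@dataclass
class PairedMeasurements:
    """Same-unit (reference, test) measurement pairs."""

    reference: np.ndarray
    test: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if self.reference.shape != self.test.shape or self.reference.ndim != 1:
            raise ValidationError("reference and test must be equal-length vectors")
        if self.reference.size < 2:
            raise ValidationError("need at least 2 pairs")
        if not (np.all(np.isfinite(self.reference)) and np.all(np.isfinite(self.test))):
            raise ValidationError("measurements must be finite")

    def __len__(self) -> int:
        return self.reference.size


@dataclass
class AgreementReport:
    lin_ccc: float
    pearson_r: float
    ba_bias: float
    ba_loa: tuple[float, float]
    mean_percent_error: float
    sd_percent_error: float
    n: int
    icc: float | None = None
    icc_variant: str = ICC_VARIANT

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ba"] = {"bias": d.pop("ba_bias"), "loa": list(d.pop("ba_loa"))}
        d["percent_error"] = {"mean": d.pop("mean_percent_error"),
                              "sd": d.pop("sd_percent_error")}
        return d


def lin_ccc(pairs: PairedMeasurements, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2·cov(x,y) / (var(x) + var(y) + (mean x − mean y)²), using
    population (1/n) moments as in Lin's original formulation;
    ``sample_moments=True`` switches to n−1 denominators.
    """
    x, y = pairs.reference, pairs.test
    ddof = 1 if sample_moments else 0
    vx, vy = np.var(x, ddof=ddof), np.var(y, ddof=ddof)
    dmean = np.mean(x) - np.mean(y)
    denom = vx + vy + dmean ** 2
    if denom == 0:
        raise InsufficientDataError(
            "Lin concordance undefined: both vectors constant with equal means"
        )
    cov = np.mean((x - np.mean(x)) * (y - np.mean(y)))
    if ddof:
        cov *= len(pairs) / (len(pairs) - 1)
    return float(2.0 * cov / denom)


def pearson_r(pairs: PairedMeasurements) -> float:
    x, y = pairs.reference, pairs.test
    if np.var(x) == 0 or np.var(y) == 0:
        raise InsufficientDataError("Pearson r undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def bland_altman(pairs: PairedMeasurements):
    """Bias and 95% limits of agreement of the paired differences.

    Returns (bias, (lower, upper), means, differences); differences are
    test − reference, limits are bias ± 1.96 × sample SD (n−1), and the
    (mean, difference) points are returned for plotting.
    """
    d = pairs.test - pairs.reference
    m = (pairs.test + pairs.reference) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd), m, d


def percent_error(pairs: PairedMeasurements):
    """Absolute percent error per pair and its summary.

    100·|test − reference| / reference; pairs with a zero reference are
    excluded with a warning.  Returns (per_pair, mean, sd); a signed variant
    is available via ``signed_percent_error``.
    """
    mask = pairs.reference != 0
    if not np.all(mask):
        warnings.warn(
            f"excluding {int(np.sum(~mask))} pair(s) with zero reference",
            stacklevel=2,
        )
    if not np.any(mask):
        raise InsufficientDataError("no pairs with nonzero reference")
    pe = 100.0 * np.abs(pairs.test[mask] - pairs.reference[mask]) / pairs.reference[mask]
    return pe, float(np.mean(pe)), float(np.std(pe, ddof=1)) if pe.size > 1 else 0.0


def signed_percent_error(pairs: PairedMeasurements) -> np.ndarray:
    mask = pairs.reference != 0
    return 100.0 * (pairs.test[mask] - pairs.reference[mask]) / pairs.reference[mask]


def icc_test_retest(measurements: np.ndarray) -> float:
    """Single-measure two-way absolute-agreement ICC from a subject × repeat matrix.

    Computed from the mean-squares decomposition of the two-way layout:
    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n).
    Rows (subjects) containing missing repeats (NaN) are dropped listwise
    with a warning.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise ValidationError("measurements must be a 2-D subject × repeat matrix")
    complete = ~np.any(np.isnan(m), axis=1)
    if not np.all(complete):
        warnings.warn(
            f"dropping {int(np.sum(~complete))} subject(s) with missing repeats",
            stacklevel=2,
        )
        m = m[complete]
    n, k = m.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need >= 2 subjects and >= 2 repeats")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise InsufficientDataError("ICC undefined: zero total variability")
    return float((msr - mse) / denom)


def retention_curve(confidences: np.ndarray, cutoffs: np.ndarray) -> np.ndarray:
    """Fraction of windows with confidence >= cutoff, per cutoff.

    Non-increasing in the cutoff and equal to 1 at cutoff 0 (confidences are
    bounded to [0, 1]).
    """
    c = np.asarray(confidences, dtype=float)
    if c.size == 0:
        raise ValidationError("empty confidence vector")
    if np.any((c < 0) | (c > 1)):
        raise ValidationError("confidences must lie in [0, 1]")
    cuts = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    return np.array([np.mean(c >= t) for t in cuts])


def agreement_report(pairs: PairedMeasurements,
                     retest: np.ndarray | None = None) -> AgreementReport:
    """One-call summary: CCC, Pearson, Bland-Altman, percent error, optional ICC."""
    bias, loa, _, _ = bland_altman(pairs)
    _, pe_mean, pe_sd = percent_error(pairs)
    icc = icc_test_retest(retest) if retest is not None else None
    return AgreementReport(
        lin_ccc=lin_ccc(pairs), pearson_r=pearson_r(pairs),
        ba_bias=bias, ba_loa=loa,
        mean_percent_error=pe_mean, sd_percent_error=pe_sd,
        n=len(pairs), icc=icc,
    )


def bland_altman_plot(pairs: PairedMeasurements, out_path: str) -> None:
    """Write a Bland-Altman figure (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bias, (lo, hi), means, diffs = bland_altman(pairs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=12, alpha=0.7)
    for y, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="crimson", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (test − reference)")
    ax.set_title(f"bias {bias:.3g}, LoA [{lo:.3g}, {hi:.3g}]")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
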