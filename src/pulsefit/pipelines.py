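"""End-to-end compositions of the estimation stages.

The step-test pipeline chains camera-PPG heart-rate estimation, recovery
beat counting (HB3060) and the step-test VO2max regression into one call,
mirroring what the smartphone protocol computes from a single 60-second
post-exercise fingertip capture.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .errors import InsufficientDataError
from .ppg import ChannelSeries, HrWindowEstimate, hr_timecourse, retained_fraction
from .vo2max import StepTestResult, hb3060_from_windows, vo2max_step


@dataclass
class StepTestReport:
    result: StepTestResult
    estimates: list[HrWindowEstimate]
    retained_fraction: float

    def summary(self) -> dict:
        return {
            "hb3060": self.result.hb3060,
            "age": self.result.age,
            "sex": self.result.sex,
            "vo2max": round(self.result.vo2max, 1),
            "n_windows": len(self.estimates),
            "retained_fraction": self.retained_fraction,
        }


def run_step_test(capture: ChannelSeries, test_end: float, age: float, sex: int,
                  config: RunConfig = RunConfig()) -> StepTestReport:
    """Estimate step-test VO2max from a post-exercise fingertip capture.

    ``test_end`` is the time stepping stopped, on the capture's clock; the
    capture must cover the [test_end+30, test_end+60] recovery interval with
    at least one valid window, else InsufficientDataError.
    """
    t_lo, t_hi = test_end + 30.0, test_end + 60.0
    if capture.timestamps[0] > t_lo or capture.timestamps[-1] < t_hi - 1.0 / capture.nominal_rate:
        raise InsufficientDataError(
            f"capture [{capture.timestamps[0]:.1f}, {capture.timestamps[-1]:.1f}] s "
            f"does not cover the recovery interval [{t_lo:.0f}, {t_hi:.0f}] s"
        )
    estimates = hr_timecourse(capture, config.hr)
    hb = hb3060_from_windows(estimates, test_end)
    vo2 = vo2max_step(hb, age, sex, config.step)
    return StepTestReport(
        result=StepTestResult(hb, age, sex, vo2),
        estimates=estimates,
        retained_fraction=retained_fraction(estimates),
    )
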