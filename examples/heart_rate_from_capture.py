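"""Estimate heart rate from a synthetic fingertip camera capture.

Generates a 60-second capture whose true pulse rate is 72 bpm, runs the
windowed-autocorrelation estimator, and prints one line per 10-second
analysis window: the fused heart rate, the channel it came from, and the
confidence score that gates quality control (windows below 0.5 would be
discarded).
"""

from pulsefit import ConstantHR, HrConfig, PpgSimSpec, hr_timecourse
from pulsefit import retained_fraction, simulate_ppg

spec = PpgSimSpec(duration=60.0, hr_profile=ConstantHR(72.0), noise_sd=2.0, seed=42)
series, true_hr = simulate_ppg(spec)

estimates = hr_timecourse(series, HrConfig())
print("window   true_hr   est_hr  source  confidence  valid")
for i, (est, truth) in enumerate(zip(estimates, true_hr)):
    print(f"{i:>6}   {truth:7.1f}  {est.fused_hr_bpm:7.1f}  {est.source_channel:>6}"
          f"  {est.fused_confidence:10.3f}  {est.valid}")
print(f"retained fraction at cutoff 0.5: {retained_fraction(estimates):.2f}")
print("each row is one 10-s window; est_hr within ~1 bpm of true_hr means the")
print("autocorrelation picked the pulse period, not a harmonic or noise peak")
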