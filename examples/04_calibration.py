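"""Hazard-ratio calibration: from all-stage survival to T1 monthly mortality.

Builds a synthetic all-stage survival target for one biomarker class (the
mixture-of-exponentials model plus 1% multiplicative noise), fits the baseline
monthly hazard by least squares, and reads off the stage-1 monthly
cancer-specific death probability for every class on the hazard-ratio ladder.
"""

from t1crc_cea import (
    ClassId, HazardRatios, StageMix, default_parameter_set,
    fit_baseline_hazard, t1_class_rates,
)
from t1crc_cea.synthetic import make_target_curve

hrs = HazardRatios()          # class HRs 1.94/1.00/1.11/1.48/2.48; stage HRs 1/2.11/7.99/52.2
mix = StageMix({1: 0.3, 2: 0.3, 3: 0.25, 4: 0.15})   # synthetic stage-at-diagnosis mix

target = make_target_curve(h0=0.0028, hrs=hrs, cls=ClassId.class0, mix=mix,
                           noise_sd=0.01, seed=11)
fit = fit_baseline_hazard(target, hrs, ClassId.class0, mix)
print(f"fitted baseline hazard h0 = {fit.h0:.6f}/mo (truth 0.002800), "
      f"residual SSE = {fit.residual:.2e}")

rates = t1_class_rates(fit.h0, hrs)
print("implied stage-1 (T1) monthly CRC mortality per class:")
for cls, rate in sorted(rates.items(), key=lambda kv: kv[1]):
    print(f"  {cls.value:7s} {rate:.6f}")

packaged = default_parameter_set()
print("\npackaged (published) class rates, for comparison:")
for cls in rates:
    print(f"  {cls.value:7s} {packaged.biomarker_class(cls).monthly_crc_mortality:.4f}")

print(
    "\nReading: the fitted ladder preserves the class hazard ratios exactly; "
    "the packaged rates are the published calibration and are never "
    "overwritten by this pipeline."
)
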