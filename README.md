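# icgflow

Indicator-dilution kinetics for dynamic indocyanine-green (ICG)
fluorescence imaging of limb perfusion.

After an intravenous ICG bolus, a near-infrared camera records the
fluorescence of a hand or foot as a time series (the targeted protocol:
120 frames of 768 × 512 px at 5-s intervals for 10 min). The transit of
the dye through each pixel encodes local hemodynamics. `icgflow` turns
such image stacks into vascular tracer parameters and group-level
statistics, for researchers studying peripheral perfusion — in
particular the distinct blood-flow signatures of diabetic patients with
and without microvascular complications.

For each baseline-subtracted time–intensity curve *I(t)* the package
computes

- **I_max** — maximum net fluorescence, a regional blood-volume surrogate;
- **T_rising** — time from curve onset to I_max;
- **BFI** = I_max / T_rising — the rising-slope blood flow index;
- **MTT** = ∫ t·I(t) dt / ∫ I(t) dt — mean transit time as the first
  temporal moment of the net curve (indicator-dilution reading);
- **AUC** = ∫ I(t) dt — net area under the curve, a second volume surrogate.

Around that core it provides digit/dorsum region analysis (digits proxy
peripheral arterial input, the dorsum proxies microvascular flow),
rigid-drift motion QC with the ">1 cm within the first 3 min" exclusion
rule, rest/post cuff-stimulation response pairing, one-way ANOVA with
Bonferroni post hoc plus chi-square group comparisons, and a calibrated
synthetic bolus-transit generator whose three groups (C control,
D diabetes, M diabetes with complications) reproduce published
foot-table kinetics — so the entire pipeline is testable end to end
with no clinical data.

## Worked example

```python
import numpy as np
from icgflow import CurveModelParams, model_curve, extract_params

params = CurveModelParams(baseline=100.0, arrival=60.0, amplitude=1000.0,
                          rise_time=40.0, washout_tau=120.0,
                          plateau_fraction=0.3)
times = np.arange(120) * 5.0            # the 5-s acquisition grid
kp = extract_params(model_curve(params, times))
print(kp.i_max, kp.t_rising, kp.bfi, kp.mtt)
```

prints

```
1000.0 30.0 33.333333333333336 282.2044835412881
```

I_max recovers the generator amplitude exactly (a frame lands on the
apex); the onset is detected at 70 s — the curve crosses 10 % of its
smoothed net peak between the 60-s arrival and the 100-s apex — giving
T_rising 30 s and BFI 33.3 A.U./s; the window-limited first moment puts
the mean transit at 282 s. The scripts in `examples/` walk through the
other capabilities one by one (parameter maps, motion QC, cohort
statistics, stimulation response) and print what each number means.

Higher-level entry points: `generate_cohort(...)` simulates a full
study cohort; `Cohort.region_table()` extracts per-limb region
parameters; `run_pipeline(manifest, loader)` chains QC → extraction →
response pairing → statistics over any manifest of stacks on disk
(multi-page TIFF + YAML sidecar) or in memory.

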