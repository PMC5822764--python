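"""Extract vascular tracer parameters from one time-intensity curve.

Builds a noiseless bolus-transit curve (baseline 100 A.U., dye arriving
at 60 s, peaking 1000 A.U. above baseline 40 s later) sampled on the
acquisition protocol's 5-s grid, and extracts the tracer parameters.
"""

import numpy as np

from icgflow import CurveModelParams, extract_params, model_curve

params = CurveModelParams(
    baseline=100.0,      # pre-bolus fluorescence, A.U.
    arrival=60.0,        # dye arrival, s
    amplitude=1000.0,    # true net peak (I_max), A.U.
    rise_time=40.0,      # onset-to-peak span, s
    washout_tau=120.0,   # washout time constant, s
    plateau_fraction=0.3,  # recirculation plateau as a fraction of peak
)

times = np.arange(120) * 5.0  # 120 frames at 5-s intervals (10 min)
curve = model_curve(params, times)
kp = extract_params(curve)

print(f"baseline   {kp.baseline:8.1f} A.U.   (pre-bolus level)")
print(f"onset      {kp.onset_time:8.1f} s      (curve leaves baseline)")
print(f"peak       {kp.peak_time:8.1f} s")
print(f"I_max      {kp.i_max:8.1f} A.U.   (net peak, blood-volume surrogate)")
print(f"T_rising   {kp.t_rising:8.1f} s      (onset to peak)")
print(f"BFI        {kp.bfi:8.2f} A.U./s (I_max / T_rising, inflow-rate surrogate)")
print(f"MTT        {kp.mtt:8.1f} s      (first temporal moment of the net curve)")
print(f"AUC        {kp.auc:8.0f} A.U.*s (net area, second volume surrogate)")
print(f"valid      {kp.valid} ({kp.reason})")
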