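"""Forward-simulate and refit one PET voxel with the Sokoloff model.

A time-activity curve is generated for known microparameters from a
Feng-type arterial input, frame-averaged onto the 41-frame schedule,
noise is added, and the voxel is refitted. The fitted rates should land
close to the truth, and the derived Ki = K1 k3/(k2+k3) even closer (it
is the best-identified combination).
"""

import numpy as np

from dualkin import SokoloffParams, TimeCurve, feng_aif, fit_sokoloff_voxel, sokoloff_forward
from dualkin.phantom import pet_frame_schedule

sched = pet_frame_schedule()
t = np.arange(0.0, 3601.0)
aif = TimeCurve(t, feng_aif(t, delay_s=10.0))

truth = SokoloffParams(k1=0.15, k2=0.30, k3=0.05, vb=0.10)
clean = sokoloff_forward(truth, aif, None, None, schedule=sched)

rng = np.random.default_rng(0)
noisy = TimeCurve(sched.midpoints, clean + rng.standard_normal(41) * 0.03 * clean.max())

fit, diag = fit_sokoloff_voxel(noisy, aif, schedule=sched)
print("          truth    fitted")
for name, tv, fv in zip(
    ("K1", "k2", "k3", "vb"), truth.as_array(), fit.as_array()
):
    print(f"{name:>6}   {tv:7.4f}  {fv:8.4f}")
print(f"{'Ki':>6}   {truth.ki:7.4f}  {fit.ki:8.4f}   (net influx constant, 1/min)")
print(f"fit rRMSE {diag.rrmse:.2f}% over {sched.n_frames} frames "
      f"(3% added noise; converged={diag.converged})")
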