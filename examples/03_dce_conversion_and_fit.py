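"""SPGR signal conversion and an extended Tofts voxel fit.

A tissue gadolinium concentration curve is generated from the Parker
population plasma input, rendered as SPGR signal with a known
pre-contrast T10, converted back to concentration with the inverse
signal equation, and fitted. The conversion is an exact algebraic
inverse, so on clean data the fit recovers the truth.
"""

import numpy as np

from dualkin import (
    SPGRAcquisition,
    TimeCurve,
    ToftsParams,
    fit_tofts_voxel,
    parker_aif,
    signal_to_concentration,
    spgr_signal,
    tofts_forward,
)
from dualkin.phantom import dce_frame_schedule

acq = SPGRAcquisition()  # TR 3.46 ms, 15 deg, r 3.4 /s/mM, Hct 0.45
sched = dce_frame_schedule()
mids = sched.midpoints
cp = TimeCurve(mids, parker_aif(mids, delay_s=30.0))

truth = ToftsParams(ktrans=0.25, ve=0.35, vp=0.06)
ct_true = tofts_forward(truth, cp)
signal = spgr_signal(ct_true, acq, t10_s=1.4, s0=500.0)
print(f"baseline signal {signal[0]:.1f} (S0=500), peak {signal.max():.1f} "
      f"at {mids[signal.argmax()]:.0f} s")

recovered, valid = signal_to_concentration(
    TimeCurve(mids, signal), acq, t10_s=1.4, s0=500.0
)
print(f"conversion max |error| {np.abs(recovered.values - ct_true).max():.2e} mM "
      f"({valid.sum()}/{valid.size} samples invertible)")

fit, diag = fit_tofts_voxel(recovered, cp)
print("            truth    fitted")
for name, tv, fv in zip(("Ktrans", "ve", "vp"), truth.as_array(), fit.as_array()):
    print(f"{name:>8}   {tv:6.3f}  {fv:8.4f}")
print(f"{'Kep':>8}   {truth.kep:6.3f}  {fit.kep:8.4f}   (= Ktrans/ve, 1/min)")
print(f"fit rRMSE {diag.rrmse:.3f}%")
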