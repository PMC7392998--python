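"""SPGR signal conversion and extended Tofts DCE-MRI kinetics.

The measured spoiled-gradient-echo (SPGR) signal is converted to
gadolinium concentration through the steady-state SPGR signal equation,
using the pre-contrast relaxation time T10 of each voxel, the sequence
TR and flip angle, and the contrast-agent relaxivity; the arterial curve
is additionally divided by (1 - Hct) to express it as a plasma
concentration. Tissue concentration curves are then fitted voxel-wise to
the extended Tofts model

    Ct(t) = vp * Cp(t) + Ktrans * int_0^t Cp(u) exp(-Kep (t-u)) du

with transfer constant Ktrans (1/min), extravascular-extracellular
fraction ve, plasma fraction vp and efflux constant Kep = Ktrans/ve.
The convolution is evaluated with the exact recursive scheme for a
piecewise-linear plasma curve on a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .imaging import DynamicImage, EmptyMaskError, TimeCurve, VoxelMask
from .pet_model import FitDiagnostics, summarize_maps

__all__ = [
    "ToftsParams",
    "SPGRAcquisition",
    "spgr_signal",
    "signal_to_concentration",
    "tofts_forward",
    "fit_tofts_voxel",
    "fit_dce_maps",
    "detect_bolus_arrival",
]

DCE_PARAM_NAMES = ("Ktrans", "ve", "Kep", "vp")

DEFAULT_INIT = (0.1, 0.2, 0.02)  # Ktrans 1/min, ve, vp
DEFAULT_BOUNDS = ((0.0, 1e-3, 0.0), (5.0, 1.0, 1.0))


@dataclass(frozen=True)
class ToftsParams:
    """Microparameters of the extended Tofts model."""

    ktrans: float  # 1/min
    ve: float  # unitless EES fraction
    vp: float  # unitless plasma fraction

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("Ktrans must be >= 0")
        if not 0.0 <= self.ve <= 1.0 or not 0.0 <= self.vp <= 1.0:
            raise ValueError("ve and vp must be in [0, 1]")
        if self.ve == 0 and self.ktrans > 0:
            raise ValueError("ve = 0 with Ktrans > 0 leaves Kep undefined")

    @property
    def kep(self) -> float:
        """Efflux constant Ktrans/ve in 1/min (0 when Ktrans = 0)."""
        return self.ktrans / self.ve if self.ve > 0 else 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.ktrans, self.ve, self.vp])


@dataclass(frozen=True)
class SPGRAcquisition:
    """Constants of the 3D fast SPGR DCE acquisition.

    Defaults follow a 3 T protocol with Dotarem: TR 3.46 ms, flip angle
    15 degrees, relaxivity 3.4 /s/mM, hematocrit 0.45.
    """

    tr_s: float = 3.46e-3
    flip_deg: float = 15.0
    relaxivity: float = 3.4  # 1/s/mM
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("TR must be > 0")
        if not 0.0 < self.flip_deg < 90.0:
            raise ValueError("flip angle must be in (0, 90) degrees")
        if self.relaxivity <= 0:
            raise ValueError("relaxivity must be > 0")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must be in (0, 1)")

    @property
    def cos_alpha(self) -> float:
        return float(np.cos(np.deg2rad(self.flip_deg)))


def spgr_signal(conc, acq: SPGRAcquisition, t10_s: float, s0: float):
    """Steady-state SPGR signal for a given gadolinium concentration.

    ``R1(t) = 1/T10 + r * C(t)`` and the signal is normalised so that
    zero concentration gives exactly the pre-contrast signal ``s0``.
    """
    conc = np.asarray(conc, dtype=float)
    if t10_s <= 0 or s0 <= 0:
        raise ValueError("T10 and S0 must be > 0")
    ca = acq.cos_alpha
    e0 = np.exp(-acq.tr_s / t10_s)
    e1 = np.exp(-acq.tr_s * (1.0 / t10_s + acq.relaxivity * conc))
    return s0 * (1.0 - e1) / (1.0 - ca * e1) * (1.0 - ca * e0) / (1.0 - e0)


def signal_to_concentration(
    signal: TimeCurve,
    acq: SPGRAcquisition,
    t10_s: float,
    s0: float,
    plasma_correct: bool = False,
) -> tuple[TimeCurve, np.ndarray]:
    """Invert the SPGR signal equation to gadolinium concentration (mM).

    With ``B(t) = (S(t)/S0) * (1-E)/(1 - cos(a) E)`` and
    ``E = exp(-TR/T10)``,

        C(t) = -1/(r*TR) * [ TR/T10 + ln( (B-1) / (B cos(a) - 1) ) ]

    optionally multiplied by ``1/(1-Hct)`` (``plasma_correct``) to turn a
    whole-blood concentration into a plasma concentration — applied to
    the arterial curve, not to tissue, by default conventions upstream.

    Samples where the log argument is non-positive (signal outside the
    invertible range) are flagged invalid and set to NaN; the second
    return value is the per-sample validity mask.
    """
    if s0 <= 0:
        raise ValueError("S0 must be > 0")
    if t10_s <= 0:
        raise ValueError("T10 must be > 0")
    ca = acq.cos_alpha
    e0 = np.exp(-acq.tr_s / t10_s)
    b = (signal.values / s0) * (1.0 - e0) / (1.0 - ca * e0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (b - 1.0) / (b * ca - 1.0)
        valid = np.isfinite(ratio) & (ratio > 0) & (signal.values > 0)
        conc = np.where(
            valid,
            -1.0 / (acq.relaxivity * acq.tr_s) * (acq.tr_s / t10_s + np.log(ratio)),
            np.nan,
        )
    if plasma_correct:
        conc = conc / (1.0 - acq.hematocrit)
    return TimeCurve(times=signal.times.copy(), values=conc), valid


def _tofts_conv_py(cp, dt, kep):
    # Exact discrete convolution of a piecewise-linear cp with
    # exp(-kep t) on a uniform grid of spacing dt; kep in 1/s.
    n = cp.shape[0]
    out = np.zeros(n)
    a = kep * dt
    if a < 1e-8:
        # trapezoid limit
        w_prev = 0.5 * dt
        w_next = 0.5 * dt
        e = 1.0
    else:
        e = np.exp(-a)
        w_next = dt * (1.0 / a - (1.0 - e) / (a * a))
        w_prev = dt * ((1.0 - e) / a - (1.0 / a - (1.0 - e) / (a * a)))
    acc = 0.0
    for i in range(n - 1):
        acc = e * acc + w_prev * cp[i] + w_next * cp[i + 1]
        out[i + 1] = acc
    return out


try:  # pragma: no cover
    from numba import njit

    _tofts_conv = njit(cache=True)(_tofts_conv_py)
except ImportError:  # pragma: no cover
    _tofts_conv = _tofts_conv_py


def tofts_forward(params: ToftsParams, cp: TimeCurve, times=None) -> np.ndarray:
    """Extended Tofts tissue concentration curve.

    ``cp`` must be sampled on a uniform grid; the convolution with the
    efflux exponential is evaluated with the exact recursion for a
    piecewise-linear plasma curve. With ``times`` given, the result is
    linearly interpolated onto them; otherwise it is returned on the
    ``cp`` grid.
    """
    tgrid = cp.times
    dts = np.diff(tgrid)
    if dts.size and not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("tofts_forward requires a uniformly sampled cp")
    dt = float(dts[0]) if dts.size else 1.0
    kep_s = params.kep / 60.0
    conv = _tofts_conv(cp.values, dt, kep_s)
    ct = params.vp * cp.values + (params.ktrans / 60.0) * conv
    if times is None:
        return ct
    return np.interp(np.asarray(times, float), tgrid, ct)


def fit_tofts_voxel(
    ct: TimeCurve,
    cp: TimeCurve,
    init=DEFAULT_INIT,
    bounds=DEFAULT_BOUNDS,
    valid: np.ndarray | None = None,
    min_valid: int = 10,
) -> tuple[ToftsParams, FitDiagnostics]:
    """Bounded nonlinear least-squares fit of one tissue curve.

    ``valid`` masks out samples whose signal-to-concentration conversion
    failed; they are excluded from the residual (and from the rRMSE
    computed downstream). Fewer than ``min_valid`` usable samples flags
    the voxel invalid instead of raising.
    """
    if valid is None:
        valid = np.isfinite(ct.values)
    else:
        valid = np.asarray(valid, bool) & np.isfinite(ct.values)
    if valid.sum() < min_valid:
        return (
            ToftsParams(0.0, DEFAULT_BOUNDS[0][1], 0.0),
            FitDiagnostics(valid=False, message="too few valid samples"),
        )
    meas = ct.values

    def residuals(p):
        model = tofts_forward(ToftsParams(*p), cp)
        return (model - meas)[valid]

    sol = least_squares(
        residuals,
        x0=np.asarray(init, float),
        bounds=(np.asarray(bounds[0], float), np.asarray(bounds[1], float)),
        method="trf",
        x_scale=np.array([0.1, 0.2, 0.05]),
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
    )
    params = ToftsParams(*np.clip(sol.x, bounds[0], bounds[1]))
    fitted = tofts_forward(params, cp)
    norm_meas = np.linalg.norm(meas[valid])
    rrmse = (
        100.0 * np.linalg.norm((meas - fitted)[valid]) / norm_meas
        if norm_meas > 0
        else np.nan
    )
    diag = FitDiagnostics(
        valid=True,
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        residual_norm=float(np.linalg.norm((meas - fitted)[valid])),
        rrmse=float(rrmse),
        message=sol.message,
    )
    return params, diag


def detect_bolus_arrival(aif_signal: TimeCurve, n_baseline: int = 5) -> int:
    """Index of the first sample of the bolus upslope on an AIF signal.

    The first ``n_baseline`` samples define the pre-contrast baseline;
    arrival is the first sample exceeding baseline + max(5 SD, 2% of the
    baseline mean), which stays robust when the baseline is noiseless.
    """
    v = aif_signal.values
    if v.size <= n_baseline:
        raise ValueError("curve too short for baseline estimation")
    base = v[:n_baseline]
    thresh = base.mean() + max(5.0 * base.std(), 0.02 * abs(base.mean()), 1e-12)
    above = np.nonzero(v > thresh)[0]
    if above.size == 0:
        raise ValueError("no detectable bolus on the arterial curve")
    return int(above[0])


def fit_dce_maps(
    img: DynamicImage,
    tumor_mask: VoxelMask,
    aif_mask: VoxelMask,
    t10_map: np.ndarray,
    acq: SPGRAcquisition = SPGRAcquisition(),
    init=DEFAULT_INIT,
    bounds=DEFAULT_BOUNDS,
    max_invalid_frac: float = 0.2,
    tissue_plasma_correct: bool = False,
) -> tuple[dict, dict, pd.DataFrame, TimeCurve]:
    """Voxel-wise extended Tofts fit over a tumor mask.

    Per voxel: S0 is estimated as the mean signal over the pre-bolus
    frames (bolus arrival detected on the arterial VOI curve), the
    signal is converted to concentration (tissue curves without the
    hematocrit factor by default; ``tissue_plasma_correct=True`` gives
    the literal everywhere-corrected variant), and the concentration
    curve is fitted. Voxels whose conversion drops more than
    ``max_invalid_frac`` of the samples are flagged missing.

    Returns ``(maps, diagnostics, summary, cp)`` where ``cp`` is the
    plasma input curve derived from the arterial VOI.
    """
    from .imaging import extract_voi_curve

    if tumor_mask.n_voxels == 0:
        raise EmptyMaskError("fit_dce_maps: empty tumor mask")
    aif_signal = extract_voi_curve(img, aif_mask)
    arrival = detect_bolus_arrival(aif_signal)
    pre = max(arrival - 1, 1)  # frames used for S0, a one-frame safety margin

    t10_blood = float(np.mean(np.asarray(t10_map)[aif_mask.data]))
    s0_blood = float(aif_signal.values[:pre].mean())
    cp, cp_valid = signal_to_concentration(
        aif_signal, acq, t10_blood, s0_blood, plasma_correct=True
    )
    if not cp_valid.all():
        # non-invertible blood samples: fall back to zero concentration
        cp = TimeCurve(cp.times, np.where(cp_valid, cp.values, 0.0))
    if np.nanmax(cp.values) <= 0:
        raise ValueError("arterial curve shows no detectable bolus")

    shape = img.shape3d
    maps = {name: np.full(shape, np.nan) for name in DCE_PARAM_NAMES}
    diag_maps = {
        "rrmse": np.full(shape, np.nan),
        "converged": np.zeros(shape, dtype=bool),
        "valid": np.zeros(shape, dtype=bool),
    }
    t10_arr = np.asarray(t10_map, dtype=float)
    for ix, iy, iz in np.argwhere(tumor_mask.data):
        sig = TimeCurve(img.schedule.midpoints, img.data[ix, iy, iz, :])
        s0 = float(sig.values[:pre].mean())
        if s0 <= 0 or not np.all(np.isfinite(sig.values)):
            continue
        ct, valid = signal_to_concentration(
            sig, acq, float(t10_arr[ix, iy, iz]), s0,
            plasma_correct=tissue_plasma_correct,
        )
        if (~valid).mean() > max_invalid_frac:
            continue
        params, diag = fit_tofts_voxel(ct, cp, init=init, bounds=bounds, valid=valid)
        if not diag.valid:
            continue
        vals = (params.ktrans, params.ve, params.kep, params.vp)
        for name, val in zip(DCE_PARAM_NAMES, vals):
            maps[name][ix, iy, iz] = val
        diag_maps["rrmse"][ix, iy, iz] = diag.rrmse
        diag_maps["converged"][ix, iy, iz] = diag.converged
        diag_maps["valid"][ix, iy, iz] = True

    summary = summarize_maps(maps, tumor_mask)
    return maps, diag_maps, summary, cp
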