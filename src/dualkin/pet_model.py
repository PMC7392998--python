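"""Irreversible two-tissue-compartment (Sokoloff) FDG model.

Forward simulation and voxel-wise nonlinear least-squares fitting of the
classic FDG model

    dCf/dt = K1*Cp - (k2 + k3)*Cf
    dCb/dt = k3*Cf
    C(t)   = (1 - vb) * (Cf + Cb) + vb * Cwb

with transport constants K1 (mL/min/mL) and k2 (1/min), phosphorylation
rate k3 (1/min) and fractional blood volume vb. The net influx constant
Ki = K1*k3/(k2+k3) and the metabolic rate of glucose
MRGlu = Ki * glycaemia / LC are derived; the lumped constant LC defaults
to 1, the convention in oncology where the true LC is unknown, which
makes MRGlu a plain multiple of Ki.

The ODE system is integrated with an explicit second-order Runge-Kutta
(Heun) scheme on a fixed internal grid with the input function linearly
interpolated onto it, and the modeled activity is averaged within each
acquisition frame window, since frame lengths span 10-300 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .aif import frame_average
from .imaging import DynamicImage, EmptyMaskError, FrameSchedule, TimeCurve, VoxelMask

__all__ = [
    "SokoloffParams",
    "FitDiagnostics",
    "sokoloff_forward",
    "fit_sokoloff_voxel",
    "compute_ki_mrglu",
    "fit_pet_maps",
]

PET_PARAM_NAMES = ("K1", "k2", "k3", "vb", "Ki", "MRGlu")

DEFAULT_INIT = (0.1, 0.1, 0.05, 0.05)
DEFAULT_BOUNDS = ((0.0, 0.0, 0.0, 0.0), (5.0, 5.0, 5.0, 1.0))


def _rk2_2tc_py(cp, dt, k1, beta, k3):
    # Heun's method on the linear two-compartment system; cp sampled on
    # the uniform internal grid. Rates in 1/s, k1 in mL/s/mL.
    n = cp.shape[0]
    ct = np.zeros(n)
    cf = 0.0
    cb = 0.0
    for i in range(n - 1):
        d1f = k1 * cp[i] - beta * cf
        d1b = k3 * cf
        cf_e = cf + dt * d1f
        d2f = k1 * cp[i + 1] - beta * cf_e
        d2b = k3 * cf_e
        cf = cf + 0.5 * dt * (d1f + d2f)
        cb = cb + 0.5 * dt * (d1b + d2b)
        ct[i + 1] = cf + cb
    return ct


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _rk2_2tc = njit(cache=True)(_rk2_2tc_py)
except ImportError:  # pragma: no cover
    _rk2_2tc = _rk2_2tc_py


@dataclass(frozen=True)
class SokoloffParams:
    """Microparameters of the irreversible FDG compartment model."""

    k1: float  # mL/min/mL, plasma-to-tissue transport (K1)
    k2: float  # 1/min, tissue-to-plasma efflux
    k3: float  # 1/min, phosphorylation
    vb: float  # unitless fractional blood volume

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0.0 <= self.vb <= 1.0:
            raise ValueError("vb must be in [0, 1]")

    @property
    def ki(self) -> float:
        """Net influx constant K1*k3/(k2+k3), in 1/min (0 when k3 = 0)."""
        ki, _ = compute_ki_mrglu(self.k1, self.k2, self.k3, glycaemia=1.0, lc=1.0)
        return ki

    def mrglu(self, glycaemia: float, lc: float = 1.0) -> float:
        """Metabolic rate of glucose, Ki * glycaemia / LC."""
        _, mrglu = compute_ki_mrglu(self.k1, self.k2, self.k3, glycaemia, lc)
        return mrglu

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.vb])


@dataclass
class FitDiagnostics:
    """Bookkeeping for one voxel-wise nonlinear fit."""

    valid: bool
    converged: bool = False
    n_iter: int = 0
    residual_norm: float = np.nan
    rrmse: float = np.nan
    message: str = ""


def compute_ki_mrglu(
    k1: float, k2: float, k3: float, glycaemia: float, lc: float = 1.0
) -> tuple[float, float]:
    """Derive (Ki, MRGlu) from the fitted microparameters.

    Ki = K1*k3/(k2+k3); MRGlu = Ki * glycaemia / LC. When k2+k3 = 0 the
    ratio is taken as 0 if k3 = 0 (no phosphorylation, no influx) and is
    an error otherwise.
    """
    if glycaemia <= 0:
        raise ValueError("glycaemia must be > 0")
    if lc <= 0:
        raise ValueError("lumped constant must be > 0")
    if k2 + k3 <= 0:
        if k3 == 0:
            return 0.0, 0.0
        raise ValueError("Ki undefined: k2 + k3 = 0 with k3 > 0")
    ki = k1 * k3 / (k2 + k3)
    return ki, ki * glycaemia / lc


class _ForwardModel:
    """Precomputed machinery for repeated forward evaluations on one AIF."""

    def __init__(
        self,
        aif: TimeCurve,
        whole_blood: TimeCurve,
        t_end: float,
        dt: float = 1.0,
    ) -> None:
        self.dt = float(dt)
        self.grid = np.arange(0.0, t_end + dt, dt)
        self.cp = np.interp(self.grid, aif.times, aif.values, left=0.0)
        self.cwb = np.interp(self.grid, whole_blood.times, whole_blood.values, left=0.0)

    def tissue(self, k1, k2, k3, vb) -> np.ndarray:
        """Model curve on the internal grid, rates given in per-minute."""
        ct = _rk2_2tc(self.cp, self.dt, k1 / 60.0, (k2 + k3) / 60.0, k3 / 60.0)
        return (1.0 - vb) * ct + vb * self.cwb

    def at(self, params, times: np.ndarray) -> np.ndarray:
        model = self.tissue(*params)
        return np.interp(times, self.grid, model)

    def frame_averaged(self, params, schedule: FrameSchedule) -> np.ndarray:
        model = self.tissue(*params)
        return frame_average(self.grid, model, schedule)


def sokoloff_forward(
    params: SokoloffParams,
    aif: TimeCurve,
    whole_blood: TimeCurve | None,
    times,
    schedule: FrameSchedule | None = None,
    dt: float = 1.0,
) -> np.ndarray:
    """Modeled tissue activity for one voxel.

    With ``schedule`` given, returns the within-frame average of the
    continuous model for every frame (``times`` is then ignored);
    otherwise the continuous model is evaluated at ``times`` (seconds).
    ``whole_blood`` defaults to the AIF itself, i.e. an uncorrected
    whole-blood image-derived input.
    """
    if whole_blood is None:
        whole_blood = aif
    if schedule is None:
        times = np.asarray(times, dtype=float)
        t_end = float(times.max())
    else:
        t_end = schedule.ends[-1]
    if t_end > aif.times[-1] + dt:
        raise ValueError("requested times extend beyond the AIF support")
    fm = _ForwardModel(aif, whole_blood, t_end, dt)
    p = (params.k1, params.k2, params.k3, params.vb)
    if schedule is not None:
        return fm.frame_averaged(p, schedule)
    return fm.at(p, times)


def fit_sokoloff_voxel(
    tac: TimeCurve,
    aif: TimeCurve,
    whole_blood: TimeCurve | None = None,
    init=DEFAULT_INIT,
    bounds=DEFAULT_BOUNDS,
    schedule: FrameSchedule | None = None,
    dt: float = 1.0,
    weights: np.ndarray | None = None,
) -> tuple[SokoloffParams, FitDiagnostics]:
    """Bounded nonlinear least-squares fit of one time-activity curve.

    Residuals are unweighted by default (``weights`` can supply e.g.
    frame-duration weights). A TAC that is all-zero or contains
    non-finite samples is flagged invalid rather than raising, so map
    fitting can skip it cleanly.
    """
    values = tac.values
    if not np.all(np.isfinite(values)) or not np.any(values != 0):
        return (
            SokoloffParams(0.0, 0.0, 0.0, 0.0),
            FitDiagnostics(valid=False, message="all-zero or non-finite TAC"),
        )
    if whole_blood is None:
        whole_blood = aif
    t_end = schedule.ends[-1] if schedule is not None else float(tac.times.max())
    fm = _ForwardModel(aif, whole_blood, t_end, dt)
    w = np.ones_like(values) if weights is None else np.asarray(weights, float)

    if schedule is not None:
        predict = lambda p: fm.frame_averaged(p, schedule)
    else:
        predict = lambda p: fm.at(p, tac.times)

    def residuals(p):
        return w * (predict(p) - values)

    sol = least_squares(
        residuals,
        x0=np.asarray(init, float),
        bounds=(np.asarray(bounds[0], float), np.asarray(bounds[1], float)),
        method="trf",
        x_scale=np.array([0.1, 0.1, 0.05, 0.05]),
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
    )
    params = SokoloffParams(*np.clip(sol.x, bounds[0], bounds[1]))
    fitted = predict(sol.x)
    norm_meas = np.linalg.norm(values)
    diag = FitDiagnostics(
        valid=True,
        converged=bool(sol.success),
        n_iter=int(sol.nfev),
        residual_norm=float(np.linalg.norm(fitted - values)),
        rrmse=float(100.0 * np.linalg.norm(values - fitted) / norm_meas),
        message=sol.message,
    )
    return params, diag


def fit_pet_maps(
    img: DynamicImage,
    tumor_mask: VoxelMask,
    aif: TimeCurve,
    whole_blood: TimeCurve | None = None,
    glycaemia: float = 1.0,
    lc: float = 1.0,
    init=DEFAULT_INIT,
    bounds=DEFAULT_BOUNDS,
    dt: float = 1.0,
) -> tuple[dict, dict, pd.DataFrame]:
    """Voxel-wise Sokoloff fit over a tumor mask.

    Returns ``(maps, diagnostics, summary)``: parametric 3D maps for K1,
    k2, k3, vb, Ki and MRGlu with NaN outside the mask and at invalid
    voxels; diagnostic maps (``rrmse``, ``converged``, ``valid``); and a
    per-parameter median/IQR summary table.
    """
    if tumor_mask.n_voxels == 0:
        raise EmptyMaskError("fit_pet_maps: empty tumor mask")
    if whole_blood is None:
        whole_blood = aif
    schedule = img.schedule
    fm = _ForwardModel(aif, whole_blood, schedule.ends[-1], dt)
    shape = img.shape3d
    maps = {name: np.full(shape, np.nan) for name in PET_PARAM_NAMES}
    diag_maps = {
        "rrmse": np.full(shape, np.nan),
        "converged": np.zeros(shape, dtype=bool),
        "valid": np.zeros(shape, dtype=bool),
    }
    lo = np.asarray(DEFAULT_BOUNDS[0] if bounds is None else bounds[0], float)
    hi = np.asarray(DEFAULT_BOUNDS[1] if bounds is None else bounds[1], float)

    idx = np.argwhere(tumor_mask.data)
    for ix, iy, iz in idx:
        values = img.data[ix, iy, iz, :]
        if not np.all(np.isfinite(values)) or not np.any(values != 0):
            continue
        sol = least_squares(
            lambda p: fm.frame_averaged(p, schedule) - values,
            x0=np.asarray(init, float),
            bounds=(lo, hi),
            method="trf",
            x_scale=np.array([0.1, 0.1, 0.05, 0.05]),
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
        )
        k1, k2, k3, vb = np.clip(sol.x, lo, hi)
        ki, mrglu = compute_ki_mrglu(k1, k2, k3, glycaemia, lc)
        for name, val in zip(PET_PARAM_NAMES, (k1, k2, k3, vb, ki, mrglu)):
            maps[name][ix, iy, iz] = val
        fitted = fm.frame_averaged(sol.x, schedule)
        diag_maps["rrmse"][ix, iy, iz] = 100.0 * np.linalg.norm(
            values - fitted
        ) / np.linalg.norm(values)
        diag_maps["converged"][ix, iy, iz] = bool(sol.success)
        diag_maps["valid"][ix, iy, iz] = True

    summary = summarize_maps(maps, tumor_mask)
    return maps, diag_maps, summary


def summarize_maps(maps: dict, mask: VoxelMask) -> pd.DataFrame:
    """Median and IQR of each parametric map over the mask (valid voxels)."""
    rows = []
    for name, vol in maps.items():
        vals = vol[mask.data]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append((name, np.nan, np.nan, np.nan, 0))
            continue
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        rows.append((name, q50, q25, q75, vals.size))
    return pd.DataFrame(
        rows, columns=["parameter", "median", "iqr_lo", "iqr_hi", "n_voxels"]
    )
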