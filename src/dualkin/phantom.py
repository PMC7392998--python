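"""Digital tumor phantom with known dual-modality kinetic ground truth.

Generates paired dynamic FDG-PET and DCE-MRI series on a common 2 mm
isotropic grid from per-voxel ground-truth Sokoloff and extended Tofts
parameter maps, so every downstream stage of the analysis (IDIF
extraction, voxel-wise fitting, fit-quality tables, correlation
analysis) can be validated against a known answer.

The default phantom emulates the regional decoupling pattern reported in
aggressive lung tumors: a perfused, vascularized rim with modest
phosphorylation, and a hypoperfused, poorly vascularized core (low
Ktrans, vp and vb) with high metabolic enzymatic activity (high k3) — a
hypoxia-like profile. An aorta-like cylinder carries the arterial curve
so that image-derived input-function extraction is exercised
realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .aif import feng_aif, frame_average, parker_aif
from .dce_model import SPGRAcquisition, ToftsParams, spgr_signal, tofts_forward
from .imaging import DynamicImage, FrameSchedule, TimeCurve, VoxelMask
from .pet_model import SokoloffParams, _ForwardModel, compute_ki_mrglu

__all__ = [
    "Region",
    "PhantomSpec",
    "GroundTruth",
    "pet_frame_schedule",
    "dce_frame_schedule",
    "default_phantom_spec",
    "build_phantom",
    "simulate_pet",
    "simulate_dce",
]


def pet_frame_schedule() -> FrameSchedule:
    """The 41-frame, 1-hour dynamic PET histogramming schedule.

    12 x 10 s, 12 x 20 s, 4 x 60 s, 5 x 120 s, 8 x 300 s.
    """
    durations = np.concatenate(
        [np.full(12, 10.0), np.full(12, 20.0), np.full(4, 60.0),
         np.full(5, 120.0), np.full(8, 300.0)]
    )
    return FrameSchedule.from_durations(durations)


def dce_frame_schedule(n_frames: int = 120, frame_s: float = 3.03) -> FrameSchedule:
    """The uniform DCE schedule: 120 frames of 3.03 s each."""
    return FrameSchedule.from_durations(np.full(n_frames, frame_s))


@dataclass
class Region:
    """One ellipsoidal kinetic region with homogeneous ground truth."""

    name: str
    center_mm: tuple  # (x, y, z)
    radii_mm: tuple  # semi-axes
    pet: tuple  # (K1, k2, k3, vb)
    dce: tuple  # (Ktrans, ve, vp)
    t10_s: float = 1.4

    def __post_init__(self) -> None:
        SokoloffParams(*self.pet)  # validates physiological bounds
        p = ToftsParams(*self.dce)
        if p.ve + p.vp > 1.0:
            raise ValueError(f"region {self.name}: ve + vp must be <= 1")

    def membership(self, coords_mm: np.ndarray) -> np.ndarray:
        d = (coords_mm - np.asarray(self.center_mm)) / np.asarray(self.radii_mm)
        return (d**2).sum(axis=-1) <= 1.0


@dataclass
class PhantomSpec:
    """Complete description of one synthetic dual-modality phantom.

    The first region is the tumor envelope; later regions override
    earlier ones inside it (explicit resolution order) and must lie
    within the envelope. Noise: PET frames get zero-mean Gaussian noise
    with variance ``pet_noise_scale**2 * mean / duration`` (a
    pseudo-Poisson surrogate for reconstructed count noise); DCE frames
    get additive Gaussian noise with SD ``dce_noise_frac * S0``.
    """

    shape: tuple = (48, 48, 16)
    voxel_size_mm: float = 2.0
    regions: list = field(default_factory=list)
    aorta_center_mm: tuple = (20.0, 20.0)
    aorta_radius_mm: float = 14.0
    aorta_voi_radius_mm: float = 6.0
    aorta_voi_z_mm: tuple = (8.0, 24.0)
    t10_blood_s: float = 1.66
    t10_background_s: float = 1.2
    s0: float = 500.0
    pet_noise_scale: float = 1.5  # kBq/mL * sqrt(s / kBq/mL) pseudo-Poisson scale
    dce_noise_frac: float = 0.02
    jitter_frac: float = 0.05  # within-region multiplicative parameter jitter
    glycaemia: float = 1.0  # g/L
    lumped_constant: float = 1.0
    pet_bolus_delay_s: float = 10.0
    dce_bolus_delay_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            return
        if len(self.shape) != 3 or self.voxel_size_mm <= 0:
            raise ValueError("invalid grid definition")
        extent = np.asarray(self.shape) * self.voxel_size_mm
        for r in self.regions:
            if np.any(np.asarray(r.center_mm) - np.asarray(r.radii_mm) < 0) or np.any(
                np.asarray(r.center_mm) + np.asarray(r.radii_mm) > extent
            ):
                raise ValueError(f"region {r.name} extends outside the grid")

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        doc = yaml.safe_load(Path(path).read_text())
        regions = [Region(**{**r, "center_mm": tuple(r["center_mm"]),
                             "radii_mm": tuple(r["radii_mm"]),
                             "pet": tuple(r["pet"]), "dce": tuple(r["dce"])})
                   for r in doc.pop("regions")]
        doc = {k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()}
        return cls(regions=regions, **doc)


@dataclass
class GroundTruth:
    """Per-voxel ground-truth maps plus phantom geometry and input curves."""

    spec: PhantomSpec
    pet_maps: dict  # K1, k2, k3, vb, Ki, MRGlu -> 3D arrays (NaN outside tumor)
    dce_maps: dict  # Ktrans, ve, Kep, vp -> 3D arrays
    t10_map: np.ndarray
    tumor_mask: VoxelMask
    aorta_mask: VoxelMask
    aorta_voi_mask: VoxelMask
    region_labels: np.ndarray  # 0 background, 1.. per region

    @property
    def voxel_size(self) -> np.ndarray:
        return np.full(3, self.spec.voxel_size_mm)


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Two-region rim/core phantom with a hypoxia-like anticorrelated core.

    Rim: well perfused and vascularized, moderate phosphorylation.
    Core: hypoperfused and poorly vascularized (low Ktrans, vp, vb) with
    high phosphorylation rate (high k3) — so k3 varies inversely with
    Ktrans, vp and vb across the tumor. Roughly 500 tumor voxels on a
    48 x 48 x 16 grid at 2 mm isotropic.
    """
    rim = Region(
        name="rim",
        center_mm=(62.0, 48.0, 16.0),
        radii_mm=(12.0, 10.0, 8.0),
        pet=(0.15, 0.30, 0.05, 0.10),
        dce=(0.25, 0.35, 0.06),
        t10_s=1.4,
    )
    core = Region(
        name="core",
        center_mm=(62.0, 48.0, 16.0),
        radii_mm=(6.0, 5.0, 4.0),
        pet=(0.08, 0.25, 0.15, 0.03),
        dce=(0.06, 0.25, 0.015),
        t10_s=1.4,
    )
    return PhantomSpec(regions=[rim, core], seed=seed)


def _voxel_centers_mm(shape, voxel_size) -> np.ndarray:
    axes = [(np.arange(n) + 0.5) * voxel_size for n in shape]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return grid


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Assign per-voxel ground-truth parameters from the region geometry.

    Deterministic given ``spec.seed``. Within-region heterogeneity is a
    seeded multiplicative log-normal jitter of relative SD
    ``jitter_frac`` applied independently per parameter, clipped to the
    physiological bounds (ve + vp rescaled when their sum would exceed
    0.95).
    """
    if not spec.regions:
        raise ValueError("phantom spec has no regions")
    coords = _voxel_centers_mm(spec.shape, spec.voxel_size_mm)
    labels = np.zeros(spec.shape, dtype=int)
    envelope = spec.regions[0].membership(coords)
    for i, region in enumerate(spec.regions, start=1):
        inside = region.membership(coords)
        if i > 1 and np.any(inside & ~envelope):
            raise ValueError(f"region {region.name} extends outside the tumor envelope")
        labels[inside] = i

    rng = np.random.default_rng(spec.seed)
    pet_names = ("K1", "k2", "k3", "vb")
    dce_names = ("Ktrans", "ve", "vp")
    pet_maps = {n: np.full(spec.shape, np.nan) for n in pet_names}
    dce_maps = {n: np.full(spec.shape, np.nan) for n in dce_names}
    for i, region in enumerate(spec.regions, start=1):
        vox = labels == i
        nv = int(vox.sum())
        for names, maps, base in ((pet_names, pet_maps, region.pet),
                                  (dce_names, dce_maps, region.dce)):
            for name, value in zip(names, base):
                if spec.jitter_frac > 0:
                    sigma = np.sqrt(np.log1p(spec.jitter_frac**2))
                    jitter = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=nv)
                else:
                    jitter = np.ones(nv)
                maps[name][vox] = value * jitter
    # enforce fraction bounds after jitter
    pet_maps["vb"] = np.clip(pet_maps["vb"], 0.0, 1.0)
    for n in ("ve", "vp"):
        dce_maps[n] = np.clip(dce_maps[n], 0.0, 1.0)
    total = dce_maps["ve"] + dce_maps["vp"]
    over = total > 0.95
    for n in ("ve", "vp"):
        dce_maps[n][over] *= 0.95 / total[over]

    tumor = labels > 0
    ki = np.full(spec.shape, np.nan)
    mrglu = np.full(spec.shape, np.nan)
    kep = np.full(spec.shape, np.nan)
    for ix, iy, iz in np.argwhere(tumor):
        ki_v, mr_v = compute_ki_mrglu(
            pet_maps["K1"][ix, iy, iz], pet_maps["k2"][ix, iy, iz],
            pet_maps["k3"][ix, iy, iz], spec.glycaemia, spec.lumped_constant,
        )
        ki[ix, iy, iz] = ki_v
        mrglu[ix, iy, iz] = mr_v
    ve = dce_maps["ve"]
    kep[tumor] = dce_maps["Ktrans"][tumor] / ve[tumor]
    pet_maps["Ki"] = ki
    pet_maps["MRGlu"] = mrglu
    dce_full = {"Ktrans": dce_maps["Ktrans"], "ve": ve, "Kep": kep, "vp": dce_maps["vp"]}

    t10 = np.full(spec.shape, spec.t10_background_s)
    for i, region in enumerate(spec.regions, start=1):
        t10[labels == i] = region.t10_s

    xy = coords[..., :2]
    aorta = ((xy - np.asarray(spec.aorta_center_mm)) ** 2).sum(axis=-1) <= (
        spec.aorta_radius_mm**2
    )
    z = coords[..., 2]
    voi = (
        ((xy - np.asarray(spec.aorta_center_mm)) ** 2).sum(axis=-1)
        <= spec.aorta_voi_radius_mm**2
    ) & (z >= spec.aorta_voi_z_mm[0]) & (z <= spec.aorta_voi_z_mm[1])
    if np.any(aorta & tumor):
        raise ValueError("aorta overlaps the tumor; adjust the geometry")
    t10[aorta] = spec.t10_blood_s

    vs = np.full(3, spec.voxel_size_mm)
    return GroundTruth(
        spec=spec,
        pet_maps=pet_maps,
        dce_maps=dce_full,
        t10_map=t10,
        tumor_mask=VoxelMask(tumor, vs),
        aorta_mask=VoxelMask(aorta, vs),
        aorta_voi_mask=VoxelMask(voi, vs),
        region_labels=labels,
    )


def simulate_pet(
    gt: GroundTruth,
    schedule: FrameSchedule | None = None,
    noise_scale: float | None = None,
    seed: int | None = None,
    dt: float = 1.0,
) -> DynamicImage:
    """Forward-simulate the dynamic PET series from the ground truth.

    Each tumor voxel's frame value is the within-frame average of the
    continuous Sokoloff model driven by the Feng arterial curve; aorta
    voxels carry the (frame-averaged) arterial curve itself so IDIF
    extraction is exercised; the background is zero. Noise is zero-mean
    Gaussian with variance ``noise_scale**2 * mean / duration`` per
    frame (``noise_scale=0`` gives the noiseless series). Deterministic
    given the seed.
    """
    spec = gt.spec
    schedule = schedule or pet_frame_schedule()
    noise_scale = spec.pet_noise_scale if noise_scale is None else noise_scale
    seed = spec.seed if seed is None else seed

    t_end = schedule.ends[-1]
    grid = np.arange(0.0, t_end + dt, dt)
    cp_curve = TimeCurve(grid, feng_aif(grid, delay_s=spec.pet_bolus_delay_s))
    fm = _ForwardModel(cp_curve, cp_curve, t_end, dt)
    cp_frames = frame_average(grid, cp_curve.values, schedule)

    data = np.zeros(spec.shape + (schedule.n_frames,))
    data[gt.aorta_mask.data, :] = cp_frames
    for ix, iy, iz in np.argwhere(gt.tumor_mask.data):
        p = (
            gt.pet_maps["K1"][ix, iy, iz], gt.pet_maps["k2"][ix, iy, iz],
            gt.pet_maps["k3"][ix, iy, iz], gt.pet_maps["vb"][ix, iy, iz],
        )
        data[ix, iy, iz, :] = fm.frame_averaged(p, schedule)

    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_scale * np.sqrt(np.maximum(data, 0.0) / schedule.durations)
        data = data + rng.standard_normal(data.shape) * sd
    return DynamicImage(
        data=data, voxel_size=np.full(3, spec.voxel_size_mm),
        schedule=schedule, units="kBq/mL",
    )


def simulate_dce(
    gt: GroundTruth,
    schedule: FrameSchedule | None = None,
    acq: SPGRAcquisition = SPGRAcquisition(),
    noise_frac: float | None = None,
    seed: int | None = None,
) -> DynamicImage:
    """Forward-simulate the DCE signal series from the ground truth.

    Tissue voxels follow the extended Tofts concentration driven by the
    Parker plasma curve, converted to SPGR signal with the voxel's T10;
    aorta voxels carry the whole-blood gadolinium concentration
    ``Cp * (1 - Hct)``. Additive Gaussian noise of SD
    ``noise_frac * S0``; deterministic given the seed.
    """
    spec = gt.spec
    schedule = schedule or dce_frame_schedule()
    noise_frac = spec.dce_noise_frac if noise_frac is None else noise_frac
    seed = spec.seed + 1 if seed is None else seed

    mids = schedule.midpoints
    cp = TimeCurve(mids, parker_aif(mids, delay_s=spec.dce_bolus_delay_s))

    data = np.full(spec.shape + (schedule.n_frames,), spec.s0, dtype=float)
    blood_conc = cp.values * (1.0 - acq.hematocrit)
    data[gt.aorta_mask.data, :] = spgr_signal(
        blood_conc, acq, spec.t10_blood_s, spec.s0
    )
    bg = ~gt.aorta_mask.data & ~gt.tumor_mask.data
    data[bg, :] = spgr_signal(0.0, acq, spec.t10_background_s, spec.s0)
    for ix, iy, iz in np.argwhere(gt.tumor_mask.data):
        params = ToftsParams(
            gt.dce_maps["Ktrans"][ix, iy, iz], gt.dce_maps["ve"][ix, iy, iz],
            gt.dce_maps["vp"][ix, iy, iz],
        )
        ct = tofts_forward(params, cp)
        data[ix, iy, iz, :] = spgr_signal(
            ct, acq, float(gt.t10_map[ix, iy, iz]), spec.s0
        )

    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.standard_normal(data.shape) * (noise_frac * spec.s0)
    return DynamicImage(
        data=data, voxel_size=np.full(3, spec.voxel_size_mm),
        schedule=schedule, units="arbitrary-signal",
    )
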