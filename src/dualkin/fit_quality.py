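"""Voxel-wise curve-fitting error metric and binned summary tables.

Fit quality is quantified by the relative root mean square error

    rRMSE = 100 * ||measured - fitted||_2 / ||measured||_2   (percent)

and summarized per tumor and modality as median (IQR) plus the fraction
of voxels in three bins: rRMSE <= 20%, 20% < rRMSE <= 45%, and > 45%.
Quartiles use the linear-interpolation (type-7) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["rrmse", "bin_fit_errors", "FitQualityTable", "fit_quality_report"]

BIN_EDGES = (20.0, 45.0)


def rrmse(measured, estimated) -> float:
    """Relative RMS error between a measured and a fitted curve, in percent.

    Scale-invariant: rescaling both curves by the same nonzero factor
    leaves it unchanged. The measured curve must have nonzero norm.
    """
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if measured.shape != estimated.shape:
        raise ValueError("curves must have equal length")
    denom = np.linalg.norm(measured)
    if denom == 0:
        raise ValueError("measured signal has zero norm; rRMSE undefined")
    return float(100.0 * np.linalg.norm(measured - estimated) / denom)


@dataclass
class FitQualityTable:
    """One modality's per-tumor fit-quality summary row."""

    modality: str  # "PET" | "DCE"
    median: float
    iqr_lo: float
    iqr_hi: float
    frac_le20: float  # percent of voxels
    frac_20_45: float
    frac_gt45: float
    n_voxels: int

    def as_dict(self) -> dict:
        return dict(
            modality=self.modality, median=self.median,
            iqr_lo=self.iqr_lo, iqr_hi=self.iqr_hi,
            frac_le20=self.frac_le20, frac_20_45=self.frac_20_45,
            frac_gt45=self.frac_gt45, n_voxels=self.n_voxels,
        )


def bin_fit_errors(values, modality: str = "") -> FitQualityTable:
    """Median, IQR and the three bin fractions of a set of rRMSE values.

    Bin boundaries are 20 and 45 percent, lower-inclusive (a value of
    exactly 20 falls in the first bin). Fractions are percentages and
    always partition to 100.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite rRMSE values to summarize")
    q25, q50, q75 = np.percentile(values, [25, 50, 75])  # type-7 linear
    n = values.size
    le20 = float((values <= BIN_EDGES[0]).sum()) / n * 100.0
    mid = float(((values > BIN_EDGES[0]) & (values <= BIN_EDGES[1])).sum()) / n * 100.0
    gt45 = float((values > BIN_EDGES[1]).sum()) / n * 100.0
    return FitQualityTable(
        modality=modality, median=float(q50), iqr_lo=float(q25), iqr_hi=float(q75),
        frac_le20=le20, frac_20_45=mid, frac_gt45=gt45, n_voxels=int(n),
    )


def fit_quality_report(
    pet_diag: dict, dce_diag: dict, tumor_id: str = "phantom"
) -> tuple[FitQualityTable, FitQualityTable, pd.DataFrame]:
    """Summarize per-voxel rRMSE maps of both modalities.

    ``pet_diag`` / ``dce_diag`` are the diagnostics dictionaries emitted
    by the map-fitting routines (with an ``rrmse`` 3D array). Returns
    the two summary tables plus a long-format per-voxel frame suitable
    for distribution plots and export.
    """
    tables = []
    frames = []
    for modality, diag in (("PET", pet_diag), ("DCE", dce_diag)):
        vals = np.asarray(diag["rrmse"])
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"{modality}: no valid voxels to summarize")
        tables.append(bin_fit_errors(vals, modality=modality))
        frames.append(
            pd.DataFrame(
                {"tumor_id": tumor_id, "modality": modality, "rrmse": vals}
            )
        )
    long = pd.concat(frames, ignore_index=True)
    return tables[0], tables[1], long


def tables_to_frame(tables, tumor_id: str = "phantom") -> pd.DataFrame:
    """Stack fit-quality tables into the export CSV layout."""
    rows = []
    for t in tables:
        d = t.as_dict()
        d["tumor_id"] = tumor_id
        rows.append(d)
    cols = ["tumor_id", "modality", "median", "iqr_lo", "iqr_hi",
            "frac_le20", "frac_20_45", "frac_gt45", "n_voxels"]
    return pd.DataFrame(rows)[cols]
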