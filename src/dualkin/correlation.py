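"""Voxel-wise Spearman correlation of PET and DCE microparameters.

For one tumor, every unordered pair among the PET parameters
{K1, k2, k3, vb, MRGlu} and DCE parameters {Ktrans, ve, Kep, vp} —
10 PET-PET, 6 DCE-DCE and 20 PET-DCE pairs, 36 in all — is correlated
across voxels with the Spearman rank coefficient after z-score outlier
cleaning (|z| > 3), with a seeded paired percentile bootstrap (default
1000 resamples) for the 95% confidence interval. A pair is significant
when its CI excludes zero, and |rs| is classified as low (< 0.4),
moderate (0.4 to 0.7 inclusive) or high (> 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .imaging import VoxelMask

__all__ = [
    "CorrelationRecord",
    "zscore_clean",
    "spearman_rs",
    "bootstrap_ci",
    "classify_strength",
    "correlation_matrix",
    "records_to_frame",
    "PET_PARAMS",
    "DCE_PARAMS",
]

PET_PARAMS = ("K1", "k2", "k3", "vb", "MRGlu")
DCE_PARAMS = ("Ktrans", "ve", "Kep", "vp")

Z_CUTOFF = 3.0
STRENGTH_LOW, STRENGTH_HIGH = 0.4, 0.7


@dataclass
class CorrelationRecord:
    """One parameter pair's correlation result for one tumor."""

    pair: str  # e.g. "k3-Ktrans"
    pair_class: str  # "PET-PET" | "DCE-DCE" | "PET-DCE"
    rs: float
    ci_low: float
    ci_high: float
    n_voxels: int
    significant: bool
    strength: str  # "low" | "moderate" | "high"
    n_outliers: int = 0


def zscore_clean(
    table: pd.DataFrame, columns=None, cutoff: float = Z_CUTOFF
) -> tuple[pd.DataFrame, pd.Series]:
    """Standardize each parameter and drop voxels with any |z| > cutoff.

    ``columns`` restricts the cleaning to a subset (e.g. the two
    parameters of the pair under analysis — the default pairwise mode).
    Returns the cleaned table and a per-column report of the fraction
    removed because of that column. A zero-variance column cannot be
    standardized and raises, so its pairs can be flagged not-computable
    by the caller.
    """
    cols = list(table.columns if columns is None else columns)
    if len(table) < 10:
        raise ValueError("need at least 10 voxels for outlier cleaning")
    keep = np.ones(len(table), dtype=bool)
    removed_frac = {}
    for c in cols:
        x = table[c].to_numpy(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance parameter {c!r}: pairs not computable")
        z = (x - x.mean()) / sd
        bad = np.abs(z) > cutoff
        removed_frac[c] = float(bad.mean())
        keep &= ~bad
    return table.loc[keep], pd.Series(removed_frac, name="removed_frac")


def spearman_rs(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks. Constant input leaves the coefficient
    undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _spearman_rows(xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Row-wise Spearman coefficients of two (m, n) matrices."""
    rx = rankdata(xb, axis=1)
    ry = rankdata(yb, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", rx, ry)
    den = np.sqrt(
        np.einsum("ij,ij->i", rx, rx) * np.einsum("ij,ij->i", ry, ry)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_ci(
    x, y, n_boot: int = 1000, seed: int | None = 0, ci: float = 95.0
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the Spearman coefficient.

    Voxels are resampled in pairs with replacement; the 2.5th and 97.5th
    percentiles of the resampled coefficient distribution bound the 95%
    interval. Degenerate resamples (zero rank variance in either
    variable) are redrawn. Deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 pairs for a bootstrap CI")
    rng = np.random.default_rng(seed)
    rs_boot = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        m = n_boot - filled
        idx = rng.integers(0, n, size=(m, n))
        vals = _spearman_rows(x[idx], y[idx])
        good = np.isfinite(vals)
        take = vals[good]
        rs_boot[filled : filled + take.size] = take
        filled += take.size
    lo, hi = np.percentile(rs_boot, [(100 - ci) / 2, 100 - (100 - ci) / 2])
    return float(lo), float(hi)


def classify_strength(rs: float) -> str:
    """Correlation strength class of |rs|: low < 0.4 <= moderate <= 0.7 < high."""
    a = abs(rs)
    if a > 1.0 + 1e-12:
        raise ValueError("|rs| cannot exceed 1")
    if a < STRENGTH_LOW:
        return "low"
    if a <= STRENGTH_HIGH:
        return "moderate"
    return "high"


def correlation_matrix(
    pet_maps: dict,
    dce_maps: dict,
    tumor_mask: VoxelMask,
    n_boot: int = 1000,
    seed: int = 0,
    clean_mode: str = "pairwise",
) -> list[CorrelationRecord]:
    """All 36 pairwise voxel-wise correlations for one tumor.

    ``clean_mode="pairwise"`` (default) removes |z| > 3 outliers per
    parameter pair, so each record may use a slightly different voxel
    subset; ``"global"`` removes outliers on all nine parameters at once
    and uses one common subset. Records are ordered PET-PET, DCE-DCE,
    then PET-DCE. Each pair's bootstrap uses an independent stream
    derived from ``seed``.
    """
    for name in PET_PARAMS:
        if name not in pet_maps:
            raise ValueError(f"missing PET map {name!r}")
    for name in DCE_PARAMS:
        if name not in dce_maps:
            raise ValueError(f"missing DCE map {name!r}")
    mask = tumor_mask.data
    cols = {}
    for name in PET_PARAMS:
        cols[name] = np.asarray(pet_maps[name])[mask]
    for name in DCE_PARAMS:
        cols[name] = np.asarray(dce_maps[name])[mask]
    table = pd.DataFrame(cols).dropna()
    if len(table) < 10:
        raise ValueError("fewer than 10 jointly valid voxels")

    if clean_mode == "global":
        base_table, _ = zscore_clean(table)
    elif clean_mode != "pairwise":
        raise ValueError(f"unknown clean_mode {clean_mode!r}")

    pairs = (
        [(a, b, "PET-PET") for a, b in combinations(PET_PARAMS, 2)]
        + [(a, b, "DCE-DCE") for a, b in combinations(DCE_PARAMS, 2)]
        + [(a, b, "PET-DCE") for a in PET_PARAMS for b in DCE_PARAMS]
    )
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(pairs))
    records = []
    for (a, b, klass), child in zip(pairs, child_seeds):
        if clean_mode == "pairwise":
            try:
                sub, report = zscore_clean(table, columns=[a, b])
            except ValueError:
                records.append(
                    CorrelationRecord(
                        pair=f"{a}-{b}", pair_class=klass, rs=np.nan,
                        ci_low=np.nan, ci_high=np.nan, n_voxels=0,
                        significant=False, strength="low",
                    )
                )
                continue
        else:
            sub = base_table
        x = sub[a].to_numpy(float)
        y = sub[b].to_numpy(float)
        n_out = len(table) - len(sub)
        try:
            rs = spearman_rs(x, y)
        except ValueError:
            records.append(
                CorrelationRecord(
                    pair=f"{a}-{b}", pair_class=klass, rs=np.nan,
                    ci_low=np.nan, ci_high=np.nan, n_voxels=len(sub),
                    significant=False, strength="low", n_outliers=n_out,
                )
            )
            continue
        lo, hi = bootstrap_ci(x, y, n_boot=n_boot, seed=child)
        records.append(
            CorrelationRecord(
                pair=f"{a}-{b}", pair_class=klass, rs=rs, ci_low=lo, ci_high=hi,
                n_voxels=len(sub), significant=bool(lo > 0 or hi < 0),
                strength=classify_strength(rs), n_outliers=n_out,
            )
        )
    return records


def records_to_frame(records, tumor_id: str = "phantom") -> pd.DataFrame:
    """Long-format export of correlation records."""
    return pd.DataFrame(
        [
            dict(
                tumor_id=tumor_id, pair=r.pair, pair_class=r.pair_class, rs=r.rs,
                ci_low=r.ci_low, ci_high=r.ci_high, n=r.n_voxels,
                significant=r.significant, strength=r.strength,
                n_outliers=r.n_outliers,
            )
            for r in records
        ]
    )
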