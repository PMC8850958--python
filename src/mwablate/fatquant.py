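"""ROI-based liver fat quantification from fat-fraction volumes.

Emulates the clinical reading protocol: circular in-plane regions of
interest (1 cm diameter by default) are placed on transverse slices, fully
inside the liver and strictly avoiding large vessels; the per-ROI mean fat
percentages are aggregated into a cohort-style mean +/- SD, a probability
density histogram, and a disease-state classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .materials import DiseaseState, classify_disease
from .synthetic import FatFractionVolume

__all__ = ["ROISample", "FatStatistics", "sample_rois", "summarize",
           "rois_to_csv", "statistics_to_json"]


@dataclass(frozen=True)
class ROISample:
    """One circular in-plane ROI: voxel-center disc membership."""

    center: tuple[int, int, int]   # voxel indices (x, y, z-slice)
    diameter: float                # mm
    slice_index: int
    mean_fat: float                # percent
    n_voxels: int


@dataclass
class FatStatistics:
    n_rois: int
    mean: float                    # percent
    sd: float                      # percent, sample SD of ROI means
    histogram: tuple               # (bin edges, densities)
    state: DiseaseState
    roi_means: list = field(default_factory=list)


def _disc_offsets(diameter: float, spacing) -> np.ndarray:
    """In-plane voxel offsets whose centers lie within the ROI disc."""
    r = diameter / 2.0
    nx = int(r / spacing[0]) + 1
    ny = int(r / spacing[1]) + 1
    dx, dy = np.meshgrid(np.arange(-nx, nx + 1), np.arange(-ny, ny + 1), indexing="ij")
    keep = (dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 <= r ** 2
    return np.column_stack([dx[keep], dy[keep]])


def sample_rois(
    vol: FatFractionVolume,
    n: int = 40,
    diameter: float = 10.0,
    min_spacing: float | None = None,
    seed: int = 0,
    max_attempts_per_roi: int = 2000,
) -> list[ROISample]:
    """Place ``n`` circular ROIs by seeded rejection sampling.

    Each ROI disc lies fully inside the liver mask, does not intersect the
    vessel mask, and its center is at least ``min_spacing`` mm (default: one
    diameter) from every previously accepted center (3D world distance).
    Deterministic for a given seed.  Raises with the achievable count when
    placement is infeasible within the attempt budget.
    """
    if n < 1:
        raise ValueError("need n >= 1 ROIs")
    min_spacing = diameter if min_spacing is None else min_spacing
    offsets = _disc_offsets(diameter, vol.spacing)
    allowed = vol.liver_mask & ~vol.vessel_mask
    cand = np.argwhere(allowed)
    if len(cand) == 0:
        raise RuntimeError("no candidate voxels: liver mask is empty or fully vesselled "
                           "(placed 0 ROIs)")
    rng = np.random.default_rng(seed)
    sp = np.asarray(vol.spacing)
    nx, ny, _ = vol.values.shape

    rois: list[ROISample] = []
    centers_world: list[np.ndarray] = []
    budget = n * max_attempts_per_roi
    while len(rois) < n and budget > 0:
        budget -= 1
        cx, cy, cz = cand[rng.integers(len(cand))]
        xs = cx + offsets[:, 0]
        ys = cy + offsets[:, 1]
        if xs.min() < 0 or ys.min() < 0 or xs.max() >= nx or ys.max() >= ny:
            continue
        if not allowed[xs, ys, cz].all():
            continue
        cw = np.array([cx, cy, cz]) * sp
        if centers_world and np.min(np.linalg.norm(np.array(centers_world) - cw, axis=1)) < min_spacing:
            continue
        vals = vol.values[xs, ys, cz]
        rois.append(ROISample(center=(int(cx), int(cy), int(cz)), diameter=diameter,
                              slice_index=int(cz), mean_fat=float(vals.mean()),
                              n_voxels=int(len(vals))))
        centers_world.append(cw)
    if len(rois) < n:
        raise RuntimeError(
            f"infeasible ROI placement: requested {n}, placed {len(rois)} "
            f"within the attempt budget")
    return rois


def summarize(rois: list[ROISample], bin_width: float = 1.0) -> FatStatistics:
    """Aggregate ROI means into cohort statistics.

    Returns the mean and sample SD of the per-ROI means, a normalized
    probability-density histogram of the ROI means (densities integrate to
    one), and the disease-state classification of the mean.
    """
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs to summarize")
    means = np.array([r.mean_fat for r in rois])
    lo = np.floor(means.min() / bin_width) * bin_width
    hi = np.ceil(means.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    dens, edges = np.histogram(means, bins=edges, density=True)
    return FatStatistics(
        n_rois=len(rois), mean=float(means.mean()), sd=float(means.std(ddof=1)),
        histogram=(edges, dens), state=classify_disease(float(means.mean())),
        roi_means=means.tolist(),
    )


def rois_to_csv(rois: list[ROISample], path: str | Path) -> None:
    pd.DataFrame([{
        "x": r.center[0], "y": r.center[1], "z": r.center[2],
        "slice": r.slice_index, "diameter_mm": r.diameter,
        "mean_fat_percent": r.mean_fat, "n_voxels": r.n_voxels,
    } for r in rois]).to_csv(path, index=False)


def statistics_to_json(stats: FatStatistics, path: str | Path) -> None:
    edges, dens = stats.histogram
    Path(path).write_text(json.dumps({
        "n_rois": stats.n_rois,
        "mean_fat_percent": stats.mean,
        "sd_fat_percent": stats.sd,
        "disease_index": stats.state.index,
        "disease_label": stats.state.label,
        "histogram_edges": list(edges),
        "histogram_density": list(dens),
    }, indent=2))
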