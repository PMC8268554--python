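"""Reconstruction error metrics and the grid analysis path.

Provides the analysis chain applied to reconstructed conductivity-change
maps: interpolation of per-element fields to the rectilinear grid, the
1.2 cm cubic spatial-averaging filter, sliding-histogram statistics binned
every 1 % of the true change, and per-tissue / overall error tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .bioheat import ThermalGrid
from .mesh import TetMesh
from .tissues import TissueTable

__all__ = [
    "MetricsReport",
    "rasterize",
    "box_filter",
    "interpolate_and_filter",
    "sliding_histogram",
    "error_stats",
]


@dataclass
class MetricsReport:
    """Error statistics over an evaluation mask.

    ``overall`` is (mean, std); ``per_tissue`` and ``bins`` are DataFrames;
    ``meta`` records mask size, seeds and any run metadata.
    """

    overall: tuple
    per_tissue: pd.DataFrame
    bins: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def max_abs_bin_mean(self) -> float:
        return float(np.abs(self.bins["mean"]).max()) if len(self.bins) else float("nan")

    @property
    def max_bin_std(self) -> float:
        return float(self.bins["std"].max()) if len(self.bins) else float("nan")


def rasterize(mesh: TetMesh, values: np.ndarray, grid: ThermalGrid) -> np.ndarray:
    """Nearest-element-centroid interpolation of an element field to a grid.

    Voxels outside the grid mask are set to NaN.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.centroids)
    pts = grid.voxel_centers()
    inside = grid.mask.ravel()
    out = np.full(len(pts), np.nan)
    _, nearest = tree.query(pts[inside])
    out[inside] = np.asarray(values, dtype=float)[nearest]
    return out.reshape(grid.shape)


def box_filter(values: np.ndarray, mask: np.ndarray, spacing: float,
               edge: float = 0.012) -> np.ndarray:
    """Cubic moving-average filter of the given edge length (m).

    Averages are renormalized near the boundary so masked-out voxels do not
    dilute the field; output is NaN outside the mask.
    """
    size = max(1, int(round(edge / spacing)))
    if size <= 1:
        out = values.astype(float).copy()
        out[~mask] = np.nan
        return out
    filled = np.where(mask, values, 0.0)
    num = uniform_filter(filled, size=size, mode="constant")
    den = uniform_filter(mask.astype(float), size=size, mode="constant")
    out = np.full(values.shape, np.nan)
    ok = mask & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def interpolate_and_filter(mesh: TetMesh, values: np.ndarray, grid: ThermalGrid,
                           edge: float = 0.012) -> np.ndarray:
    """Element field -> grid -> 1.2 cm cubic average (the analysis path)."""
    if edge < grid.spacing:
        raise ValueError("filter edge must be at least the grid spacing")
    return box_filter(rasterize(mesh, values, grid), grid.mask, grid.spacing, edge)


def sliding_histogram(true_values: np.ndarray, errors: np.ndarray,
                      bin_width: float = 1.0, min_count: int = 5) -> pd.DataFrame:
    """Mean and std of the error binned every ``bin_width`` of the true value.

    Bins are contiguous intervals of the observed true-value range; bins
    with fewer than ``min_count`` samples are dropped.
    """
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(errors, dtype=float)
    ok = np.isfinite(t) & np.isfinite(e)
    t, e = t[ok], e[ok]
    if len(t) == 0:
        return pd.DataFrame(columns=["bin_center", "mean", "std", "count"])
    lo = np.floor(t.min() / bin_width) * bin_width
    idx = np.floor((t - lo) / bin_width).astype(int)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        if sel.sum() < min_count:
            continue
        rows.append({
            "bin_center": lo + (b + 0.5) * bin_width,
            "mean": float(e[sel].mean()),
            "std": float(e[sel].std()),
            "count": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def error_stats(
    delta_rec: np.ndarray,
    delta_true: np.ndarray,
    labels: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    table: Optional[TissueTable] = None,
    bin_width: float = 1.0,
    weights: Optional[np.ndarray] = None,
    meta: Optional[dict] = None,
) -> MetricsReport:
    """Error tables for a reconstructed vs true field (same units).

    Statistics are computed over ``mask`` only (default: all finite
    entries).  The same machinery serves conductivity-change errors (%) and
    temperature errors (degC).
    """
    rec = np.asarray(delta_rec, dtype=float).ravel()
    tru = np.asarray(delta_true, dtype=float).ravel()
    if mask is None:
        mask = np.ones(rec.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool).ravel() & np.isfinite(rec) & np.isfinite(tru)
    if not np.any(mask):
        raise ValueError("empty evaluation mask")
    err = rec - tru

    w = None if weights is None else np.asarray(weights, dtype=float).ravel()[mask]
    em = err[mask]
    if w is None:
        overall = (float(em.mean()), float(em.std()))
    else:
        mu = float(np.average(em, weights=w))
        overall = (mu, float(np.sqrt(np.average((em - mu) ** 2, weights=w))))

    rows = []
    if labels is not None:
        lab = np.asarray(labels).ravel()
        for tid in np.unique(lab[mask]):
            sel = mask & (lab == tid)
            name = table.name_of(int(tid)) if table is not None else str(tid)
            rows.append({"tissue": name, "mean": float(err[sel].mean()),
                         "std": float(err[sel].std()), "count": int(sel.sum())})
    per_tissue = pd.DataFrame(rows)
    bins = sliding_histogram(tru[mask], err[mask], bin_width=bin_width)
    return MetricsReport(overall, per_tissue, bins, meta or {})
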