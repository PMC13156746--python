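"""Nucleotide-cleft definition and convex-hull volume.

The cleft is defined per frame as all residues with any heavy atom
within 8 Å of any cleft ligand atom (ADP, inorganic phosphate, Mg).
A convex hull over the alpha-carbons of the selected residues gives the
pocket-size statistic; its end-to-end extents are reported in the
protomer axis frame so the X/Y/Z directions are comparable across
frames and systems.  An all-heavy-atom hull is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from actintools.geometry import AxisFrame, build_axis_frame, subdomain_centroids
from actintools.model_io import ProtomerView, SubdomainScheme, Trajectory

__all__ = [
    "CleftFrameResult",
    "select_cleft_residues",
    "convex_hull_volume",
    "cleft_extents",
    "median_hull_frame",
    "running_average",
    "cleft_series",
]


@dataclass
class CleftFrameResult:
    selected_residues: list[tuple[str, int]]
    hull_vertices: np.ndarray
    volume_A3: float
    extent_x_A: float
    extent_y_A: float
    extent_z_A: float
    centroid: np.ndarray
    degenerate: bool = False


def select_cleft_residues(
    coords: np.ndarray,
    view: ProtomerView,
    ligand_indices: Sequence[int] | None = None,
    cutoff_A: float = 8.0,
) -> list[int]:
    """Residue numbers with any heavy atom within the cutoff of any
    ligand atom (heavy atoms on both sides)."""
    lig_idx = (
        np.asarray(view.ligand_indices)
        if ligand_indices is None
        else np.asarray(ligand_indices)
    )
    if lig_idx.size == 0:
        raise ValueError("no ligand atoms: the cleft is defined by its ligands")
    lig = coords[lig_idx]
    selected: list[int] = []
    for num in view.residue_numbers:
        idx = np.asarray(view.heavy_indices[num])
        if idx.size == 0:
            continue
        pts = coords[idx]
        d2 = np.sum((pts[:, None, :] - lig[None, :, :]) ** 2, axis=2)
        if d2.min() <= cutoff_A**2:
            selected.append(num)
    return selected


def convex_hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """3D convex-hull volume (Å³); degenerate inputs (< 4 points or
    coplanar) return (0.0, True) instead of raising."""
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        return 0.0, True
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0, True
    return float(hull.volume), False


def cleft_extents(
    hull_vertices: np.ndarray, axis_frame: AxisFrame
) -> tuple[float, float, float]:
    """Max − min of the vertex coordinates expressed in the protomer
    axis frame."""
    if len(hull_vertices) == 0:
        raise ValueError("no hull vertices")
    local = axis_frame.to_local(np.asarray(hull_vertices, dtype=float))
    ext = local.max(axis=0) - local.min(axis=0)
    return float(ext[0]), float(ext[1]), float(ext[2])


def median_hull_frame(volumes: Sequence[float]) -> int:
    """Index of the frame carrying the (lower) median volume.

    The lower median guarantees a real frame exists to extract a
    structure from; among ties the lowest frame index wins.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size == 0:
        raise ValueError("empty volume series")
    target = np.sort(volumes, kind="stable")[(volumes.size - 1) // 2]
    return int(np.flatnonzero(volumes == target)[0])


def running_average(series: Sequence[float], window: int) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges."""
    if window <= 0:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if window > len(s):
        raise ValueError("window exceeds series length")
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def analyze_cleft_frame(
    coords: np.ndarray,
    view: ProtomerView,
    scheme: SubdomainScheme,
    cutoff_A: float = 8.0,
    all_heavy_hull: bool = False,
    ligand_indices: Sequence[int] | None = None,
) -> CleftFrameResult:
    """Full per-frame cleft analysis: selection, hull volume, extents."""
    selected = select_cleft_residues(coords, view, ligand_indices, cutoff_A)
    if all_heavy_hull:
        idx = [i for n in selected for i in view.heavy_indices[n]]
    else:
        idx = [view.ca_indices[n] for n in selected if n in view.ca_indices]
    pts = coords[np.asarray(idx, dtype=int)] if idx else np.empty((0, 3))
    volume, degenerate = convex_hull_volume(pts)
    frame = build_axis_frame(subdomain_centroids(coords, view, scheme))
    if len(pts):
        ex, ey, ez = cleft_extents(pts, frame)
        centroid = pts.mean(axis=0)
    else:
        ex = ey = ez = 0.0
        centroid = np.zeros(3)
    return CleftFrameResult(
        selected_residues=[(view.chain_id, n) for n in selected],
        hull_vertices=pts,
        volume_A3=volume,
        extent_x_A=ex,
        extent_y_A=ey,
        extent_z_A=ez,
        centroid=centroid,
        degenerate=degenerate,
    )


def cleft_series(
    traj: Trajectory,
    view: ProtomerView,
    scheme: SubdomainScheme,
    cutoff_A: float = 8.0,
    all_heavy_hull: bool = False,
) -> pd.DataFrame:
    """Per-frame cleft volume and axis-frame extents.

    Columns: frame, time_ns, volume_A3, extent_x_A, extent_y_A,
    extent_z_A, n_selected, degenerate.
    """
    rows = []
    for i in range(traj.n_frames):
        res = analyze_cleft_frame(
            traj.frames[i], view, scheme, cutoff_A, all_heavy_hull
        )
        rows.append(
            {
                "frame": i,
                "time_ns": float(traj.times_ns[i]),
                "volume_A3": res.volume_A3,
                "extent_x_A": res.extent_x_A,
                "extent_y_A": res.extent_y_A,
                "extent_z_A": res.extent_z_A,
                "n_selected": len(res.selected_residues),
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
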