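"""Conformational clustering, PCA and Gibbs free-energy landscapes.

Clustering follows the GROMOS (Daura) procedure with a 1.5 Å (0.15 nm)
pairwise fit-RMSD cutoff: count neighbors within the cutoff, promote
the frame with the largest neighborhood to cluster representative,
remove the cluster, repeat.  Ties break toward the lowest frame index
so output is deterministic.

PCA is an eigendecomposition of the 3N×3N coordinate covariance after
iterative superposition to the mean (computed through the thin SVD of
the centered coordinate matrix).  Free-energy landscapes convert a 2D
histogram over principal-component projections into
ΔG = −k_B·T·ln(P/P_max) (kJ/mol) at the simulation temperature (310 K);
local minima below a depth threshold are located on the grid and each
gets a nearest-frame representative for structure extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from actintools.ensemble import _iterative_mean_fit, superpose
from actintools.model_io import Trajectory

__all__ = [
    "ClusterResult",
    "PCAResult",
    "FELGrid",
    "KB_KJ_PER_MOL_K",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "pca",
    "extreme_structures",
    "combined_pca",
    "free_energy_landscape",
]

KB_KJ_PER_MOL_K = 0.008314462618  # Boltzmann constant, kJ/(mol*K)


@dataclass
class ClusterResult:
    assignments: np.ndarray  # frame -> cluster id (0 = largest)
    representatives: list[int]  # cluster id -> central frame index
    sizes: list[int]  # ordered by descending size

    def __post_init__(self) -> None:
        if sum(self.sizes) != len(self.assignments):
            raise ValueError("cluster sizes must sum to the frame count")
        if any(b > a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("clusters must be ordered by descending size")

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def top(self, k: int) -> list[int]:
        """Representative frame indices of the k most common conformations."""
        return self.representatives[:k]


@dataclass
class PCAResult:
    mean_coords: np.ndarray  # flattened 3N
    eigenvectors: np.ndarray  # components x 3N, orthonormal rows
    eigenvalues: np.ndarray  # non-increasing, A^2
    projections: np.ndarray  # frames x components, centered

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("negative eigenvalue")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


@dataclass
class FELGrid:
    bin_edges_pc1: np.ndarray
    bin_edges_pc2: np.ndarray
    probability: np.ndarray
    delta_g_kj_mol: np.ndarray
    occupied: np.ndarray  # mask of non-empty bins
    minima: list[dict] = field(default_factory=list)
    temperature_K: float = 310.0


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------


def pairwise_rmsd_matrix(
    frames: np.ndarray, selection: np.ndarray
) -> np.ndarray:
    """Symmetric matrix of pairwise least-squares-fit RMSDs on the
    selection (the GROMOS convention of per-pair fitting)."""
    n = frames.shape[0]
    sel = np.asarray(selection)
    sub = frames[:, sel, :]
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = superpose(sub[j], sub[i])
            m[i, j] = m[j, i] = r
    return m


def gromos_cluster(
    traj: Trajectory | np.ndarray,
    selection: np.ndarray,
    cutoff_A: float = 1.5,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """GROMOS/Daura neighbor-counting clustering at a fit-RMSD cutoff.

    The cutoff default is the 0.15 nm convention, stored as 1.5 Å
    (coordinates are Å everywhere internally).
    """
    frames = traj.frames if isinstance(traj, Trajectory) else np.asarray(traj)
    n = frames.shape[0]
    if n == 0:
        raise ValueError("empty trajectory")
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(frames, selection)
    adj = rmsd_matrix <= cutoff_A
    np.fill_diagonal(adj, True)

    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    clusters: list[tuple[int, np.ndarray]] = []
    while remaining.any():
        counts = (adj & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        rep = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(adj[rep] & remaining)
        clusters.append((rep, members))
        remaining[members] = False

    # order clusters by descending size, ties by representative index
    order = sorted(
        range(len(clusters)), key=lambda c: (-len(clusters[c][1]), clusters[c][0])
    )
    reps: list[int] = []
    sizes: list[int] = []
    for new_id, c in enumerate(order):
        rep, members = clusters[c]
        assignments[members] = new_id
        reps.append(rep)
        sizes.append(len(members))
    return ClusterResult(assignments=assignments, representatives=reps, sizes=sizes)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def _pca_of_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD-based PCA of a centered (frames x 3N) matrix."""
    n = x.shape[0]
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    projections = x @ vt.T
    # fixed sign convention: largest-magnitude component positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            projections[:, k] = -projections[:, k]
    return vt, eigenvalues, projections


def pca(traj: Trajectory | np.ndarray, selection: np.ndarray) -> PCAResult:
    """Coordinate-covariance PCA on a selection after iterative
    superposition of all frames to their mean."""
    frames = traj.frames if isinstance(traj, Trajectory) else np.asarray(traj)
    if frames.shape[0] < 2:
        raise ValueError("PCA needs at least 2 frames")
    sel = np.asarray(selection)
    fitted = _iterative_mean_fit(frames, sel, iterations=2)
    sub = fitted[:, sel, :].reshape(frames.shape[0], -1)
    mean = sub.mean(axis=0)
    vt, eigenvalues, projections = _pca_of_matrix(sub - mean)
    return PCAResult(
        mean_coords=mean,
        eigenvectors=vt,
        eigenvalues=eigenvalues,
        projections=projections,
    )


def extreme_structures(
    result: PCAResult,
    component: int = 0,
    quantile: float | None = None,
) -> dict:
    """Structures at the extremes of one principal component.

    Default mode returns the frame indices at the minimum and maximum
    projection; with ``quantile`` the extremes are reconstructed as
    mean ± the projection quantile along the eigenvector.
    """
    if component >= len(result.eigenvalues):
        raise ValueError(f"component {component} does not exist")
    proj = result.projections[:, component]
    if quantile is None:
        return {
            "mode": "frames",
            "low_frame": int(np.argmin(proj)),
            "high_frame": int(np.argmax(proj)),
        }
    q = float(np.quantile(np.abs(proj), quantile))
    vec = result.eigenvectors[component]
    return {
        "mode": f"reconstruction(q={quantile})",
        "low_coords": (result.mean_coords - q * vec).reshape(-1, 3),
        "high_coords": (result.mean_coords + q * vec).reshape(-1, 3),
    }


def combined_pca(
    traj_a: Trajectory | np.ndarray,
    traj_b: Trajectory | np.ndarray,
    selection: np.ndarray,
) -> tuple[PCAResult, np.ndarray, np.ndarray]:
    """PCA of the concatenated trajectory with each input projected
    separately on the common eigenvectors.

    This mirrors combining crosslinked and control runs into one long
    trajectory to obtain shared vectors of motion, then projecting each
    system along them to build comparable free-energy landscapes.
    """
    fa = traj_a.frames if isinstance(traj_a, Trajectory) else np.asarray(traj_a)
    fb = traj_b.frames if isinstance(traj_b, Trajectory) else np.asarray(traj_b)
    if fa.shape[1:] != fb.shape[1:]:
        raise ValueError("trajectories must share a topology")
    combined = np.concatenate([fa, fb], axis=0)
    result = pca(combined, selection)
    na = fa.shape[0]
    return result, result.projections[:na], result.projections[na:]


# ---------------------------------------------------------------------------
# Free-energy landscapes
# ---------------------------------------------------------------------------


def free_energy_landscape(
    proj1: np.ndarray,
    proj2: np.ndarray,
    bins: int = 32,
    temperature_K: float = 310.0,
    minima_depth_kj_mol: float | None = None,
    min_basin_separation_bins: int = 2,
) -> FELGrid:
    """Gibbs free-energy landscape over two projection coordinates.

    ΔG = −k_B·T·ln(P/P_max); the most-populated bin sits at exactly 0.
    Empty bins carry the maximum finite ΔG plus a 1 kJ/mol penalty and
    are excluded from the minima search.  Minima are 8-connected local
    minima below the depth threshold (default: half the finite range),
    thinned so that no two survive within the basin-separation radius
    (Chebyshev distance); each keeps the frame nearest its bin center.
    """
    proj1 = np.asarray(proj1, dtype=float)
    proj2 = np.asarray(proj2, dtype=float)
    if proj1.size == 0 or proj1.shape != proj2.shape:
        raise ValueError("projections must be equal-length and non-empty")
    h, ex, ey = np.histogram2d(proj1, proj2, bins=bins)
    p = h / h.sum()
    occupied = p > 0
    kt = KB_KJ_PER_MOL_K * temperature_K
    dg = np.full_like(p, np.nan)
    with np.errstate(divide="ignore"):
        dg[occupied] = -kt * np.log(p[occupied] / p.max())
    max_finite = np.nanmax(dg) if np.isfinite(dg).any() else 0.0
    dg[~occupied] = max_finite + 1.0

    if minima_depth_kj_mol is None:
        minima_depth_kj_mol = 0.5 * max_finite if max_finite > 0 else 0.0

    nx, ny = dg.shape
    candidates: list[tuple[float, int, int]] = []
    for i in range(nx):
        for j in range(ny):
            if not occupied[i, j] or dg[i, j] > minima_depth_kj_mol:
                continue
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < ny and dg[a, b] < dg[i, j]:
                        is_min = False
            if is_min:
                candidates.append((float(dg[i, j]), i, j))
    candidates.sort()
    kept: list[tuple[float, int, int]] = []
    for g, i, j in candidates:
        if all(
            max(abs(i - ki), abs(j - kj)) >= min_basin_separation_bins
            for _, ki, kj in kept
        ):
            kept.append((g, i, j))

    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])
    minima = []
    for g, i, j in kept:
        d2 = (proj1 - cx[i]) ** 2 + (proj2 - cy[j]) ** 2
        minima.append(
            {
                "bin": (i, j),
                "delta_g_kj_mol": g,
                "pc1": float(cx[i]),
                "pc2": float(cy[j]),
                "representative_frame": int(np.argmin(d2)),
            }
        )
    return FELGrid(
        bin_edges_pc1=ex,
        bin_edges_pc2=ey,
        probability=p,
        delta_g_kj_mol=dg,
        occupied=occupied,
        minima=minima,
        temperature_K=temperature_K,
    )
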