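"""Superposition-based ensemble statistics and difference maps.

Everything here is built on the optimal least-squares rigid fit
(Kabsch): per-frame RMSD, per-residue RMSF about the iteratively
superposed mean, radius of gyration, per-residue RMSD maps and their
control − PBM differences, residue-RMSD Pearson correlation matrices,
time-averaged residue–target distance maps, hydrogen-bond counting,
dihedral series and Shrake–Rupley solvent-accessible surface areas.

Sign convention for delta maps follows the comparative study design:
difference = control − PBM, so negative values mean the crosslinked
system moves more.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from actintools.model_io import ProtomerView, Trajectory

__all__ = [
    "PerResidueMap",
    "HBondCriteria",
    "DihedralSeries",
    "superpose",
    "apply_fit",
    "rmsd_series",
    "rmsf",
    "delta_rmsf",
    "radius_of_gyration",
    "per_residue_rmsd",
    "difference_map",
    "rmsd_correlation_matrix",
    "residue_distance_map",
    "distance_difference_map",
    "hydrogen_bonds",
    "dihedral",
    "dihedral_series",
    "angle_histogram",
    "sasa",
    "VDW_RADII",
]

ResidueKey = tuple[str, int]


@dataclass
class PerResidueMap:
    """Scalar per-residue values keyed by (chain, residue_number)."""

    values: dict[ResidueKey, float]
    label: str = ""
    units: str = "A"

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for residue {k}")

    def __getitem__(self, key: ResidueKey) -> float:
        return self.values[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.values

    def keys(self):
        return self.values.keys()

    def as_array(self, keys: Sequence[ResidueKey] | None = None) -> np.ndarray:
        keys = list(self.values) if keys is None else list(keys)
        return np.array([self.values[k] for k in keys])


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria (GROMACS-style defaults):
    donor–acceptor distance ≤ 3.5 Å and hydrogen–donor–acceptor angle
    deviation ≤ 30°."""

    donor_acceptor_max_A: float = 3.5
    angle_max_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.donor_acceptor_max_A <= 0 or self.angle_max_deg <= 0:
            raise ValueError("hydrogen-bond criteria must be positive")


@dataclass
class DihedralSeries:
    residue: ResidueKey
    angle_kind: str  # phi, psi, chi1, chi2
    values_deg: np.ndarray

    def __post_init__(self) -> None:
        self.values_deg = np.asarray(self.values_deg, dtype=float)
        if np.any((self.values_deg <= -180.0) | (self.values_deg > 180.0)):
            raise ValueError("dihedral values must lie in (-180, 180]")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------


def superpose(
    mobile: np.ndarray, reference: np.ndarray, selection: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid fit of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits the reference on the
    selection.  The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    a = mobile[sel]
    b = reference[sel]
    if len(a) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    # collinearity check: rank of the centered coordinates
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cb - rot @ ca
    fitted = a @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_fit(coords: np.ndarray, rot: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return coords @ rot.T + trans


def _superpose_trajectory(
    frames: np.ndarray, reference: np.ndarray, sel: np.ndarray
) -> np.ndarray:
    out = np.empty_like(frames)
    for i in range(frames.shape[0]):
        rot, trans, _ = superpose(frames[i], reference, sel)
        out[i] = apply_fit(frames[i], rot, trans)
    return out


def _iterative_mean_fit(
    frames: np.ndarray, sel: np.ndarray, iterations: int = 2
) -> np.ndarray:
    """Superpose all frames to their evolving mean structure."""
    fitted = _superpose_trajectory(frames, frames[0], sel)
    for _ in range(iterations):
        mean = fitted.mean(axis=0)
        fitted = _superpose_trajectory(fitted, mean, sel)
    return fitted


# ---------------------------------------------------------------------------
# RMSD / RMSF / Rg
# ---------------------------------------------------------------------------


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    fit_selection: np.ndarray,
    measure_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference after fitting on ``fit_selection``.

    The measure selection defaults to the fit selection; measuring a
    ligand after fitting on the protein gives ligand-displacement RMSD.
    """
    fit_selection = np.asarray(fit_selection)
    if fit_selection.size == 0:
        raise ValueError("empty fit selection")
    measure = fit_selection if measure_selection is None else np.asarray(
        measure_selection
    )
    if measure.size == 0:
        raise ValueError("empty measure selection")
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        rot, trans, _ = superpose(traj.frames[i], reference, fit_selection)
        fitted = apply_fit(traj.frames[i][measure], rot, trans)
        out[i] = np.sqrt(np.mean(np.sum((fitted - reference[measure]) ** 2, axis=1)))
    return out


def replicate_mean_series(series: Sequence[np.ndarray]) -> np.ndarray:
    """Average per-frame statistics across replicates (statistics are
    computed per replicate then averaged, not on the concatenation)."""
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValueError("replicates must have equal frame counts to average")
    return np.mean(np.stack(series), axis=0)


def rmsf(
    traj: Trajectory, view: ProtomerView, label: str = "RMSF"
) -> PerResidueMap:
    """Per-residue alpha-carbon RMSF about the time-average structure,
    after iterative superposition (2 rounds) to the mean."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ca = view.ca_array()
    fitted = _iterative_mean_fit(traj.frames, ca, iterations=2)
    pos = fitted[:, ca, :]
    mean = pos.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((pos - mean) ** 2, axis=2), axis=0))
    keys = [(view.chain_id, n) for n in view.residue_numbers]
    return PerResidueMap(dict(zip(keys, map(float, fluct))), label=label)


def delta_rmsf(control: PerResidueMap, pbm: PerResidueMap) -> PerResidueMap:
    """control − PBM; negative values mean the crosslinked system is more
    flexible."""
    return difference_map(control, pbm, label="dRMSF (control - PBM)")


def radius_of_gyration(
    traj: Trajectory,
    selection: np.ndarray,
    masses: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted radius of gyration per frame (unit masses by
    default, which is exact for single-element selections)."""
    selection = np.asarray(selection)
    pos = traj.frames[:, selection, :]
    m = np.ones(len(selection)) if masses is None else np.asarray(masses, float)
    m = m / m.sum()
    com = np.einsum("fas,a->fs", pos, m)
    d2 = np.sum((pos - com[:, None, :]) ** 2, axis=2)
    return np.sqrt(np.einsum("fa,a->f", d2, m))


# ---------------------------------------------------------------------------
# Per-residue maps
# ---------------------------------------------------------------------------


def per_residue_rmsd(
    structures: Sequence[np.ndarray],
    reference: np.ndarray,
    view: ProtomerView,
    label: str = "per-residue RMSD",
) -> PerResidueMap:
    """Per-residue RMSD to a reference, averaged over the given
    structures (e.g. the top-20 cluster representatives), after a global
    alpha-carbon fit per structure."""
    ca = view.ca_array()
    acc = np.zeros(len(view.residue_numbers))
    for coords in structures:
        rot, trans, _ = superpose(coords, reference, ca)
        fitted = apply_fit(coords, rot, trans)
        for j, num in enumerate(view.residue_numbers):
            idx = np.asarray(view.atom_indices[num])
            d2 = np.sum((fitted[idx] - reference[idx]) ** 2, axis=1)
            acc[j] += np.sqrt(np.mean(d2))
    acc /= len(structures)
    keys = [(view.chain_id, n) for n in view.residue_numbers]
    return PerResidueMap(dict(zip(keys, map(float, acc))), label=label)


def difference_map(
    a: PerResidueMap, b: PerResidueMap, label: str = "difference"
) -> PerResidueMap:
    """A − B on the key intersection (antisymmetric by construction)."""
    common = [k for k in a.values if k in b.values]
    if not common:
        raise ValueError("maps share no residue keys")
    return PerResidueMap(
        {k: a.values[k] - b.values[k] for k in common}, label=label, units=a.units
    )


def rmsd_correlation_matrix(
    traj: Trajectory, view: ProtomerView
) -> tuple[np.ndarray, list[ResidueKey]]:
    """Pearson correlation of per-residue displacement-from-start series.

    Frames are fitted to frame 0 on all alpha-carbons; each residue's
    series is its CA distance to the t = 0 position.  Zero-variance
    series yield NaN rows/columns (missing, not 0).
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames for correlations")
    ca = view.ca_array()
    fitted = _superpose_trajectory(traj.frames, traj.frames[0], ca)
    pos = fitted[:, ca, :]
    disp = np.linalg.norm(pos - pos[0], axis=2)  # frames x residues
    centered = disp - disp.mean(axis=0)
    std = centered.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = centered / std
        corr = (normed.T @ normed) / disp.shape[0]
    corr[std == 0, :] = np.nan
    corr[:, std == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0, out=corr)
    keys = [(view.chain_id, n) for n in view.residue_numbers]
    return corr, keys


def residue_distance_map(
    traj: Trajectory,
    view: ProtomerView,
    target_indices: np.ndarray,
    cutoff_A: float = 10.0,
    use_ca: bool = False,
    label: str = "distance to target",
) -> PerResidueMap:
    """Time-averaged minimum heavy-atom distance from each residue to a
    target atom set, restricted to residues whose average distance is
    within the cutoff."""
    target_indices = np.asarray(target_indices)
    sums = np.zeros(len(view.residue_numbers))
    for i in range(traj.n_frames):
        tgt = traj.frames[i][target_indices]
        for j, num in enumerate(view.residue_numbers):
            idx = (
                [view.ca_indices[num]]
                if use_ca
                else view.heavy_indices[num]
            )
            pts = traj.frames[i][np.asarray(idx)]
            d = np.sqrt(
                np.sum((pts[:, None, :] - tgt[None, :, :]) ** 2, axis=2)
            )
            sums[j] += d.min()
    avg = sums / traj.n_frames
    values = {
        (view.chain_id, num): float(avg[j])
        for j, num in enumerate(view.residue_numbers)
        if avg[j] <= cutoff_A
    }
    return PerResidueMap(values, label=label)


def distance_difference_map(
    control: PerResidueMap, pbm: PerResidueMap
) -> PerResidueMap:
    """control − PBM distance difference: positive means the residue sits
    closer to the target in the crosslinked system."""
    return difference_map(control, pbm, label="d(distance) (control - PBM)")


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def hydrogen_bonds(
    traj: Trajectory,
    donors: Sequence[tuple[int, int | None]],
    acceptors: Sequence[int],
    criteria: HBondCriteria | None = None,
    distance_bin_A: float = 0.1,
    angle_bin_deg: float = 5.0,
) -> dict:
    """Count donor–H···acceptor contacts per frame.

    ``donors`` is a list of (donor_heavy_index, hydrogen_index) pairs;
    a missing hydrogen (None) activates a distance-only criterion,
    flagged in the output.  Returns the per-frame count series plus
    pooled distance and angle histograms.
    """
    criteria = criteria or HBondCriteria()
    if not donors or not len(acceptors):
        warnings.warn("no donors or acceptors given; empty hydrogen-bond result")
        return {
            "counts": np.zeros(traj.n_frames, dtype=int),
            "distances_A": np.array([]),
            "angles_deg": np.array([]),
            "distance_histogram": (np.array([]), np.array([])),
            "angle_histogram": (np.array([]), np.array([])),
            "distance_only": False,
        }
    acceptors = np.asarray(acceptors)
    counts = np.zeros(traj.n_frames, dtype=int)
    dists: list[float] = []
    angles: list[float] = []
    distance_only = any(h is None for _, h in donors)
    for i in range(traj.n_frames):
        coords = traj.frames[i]
        acc = coords[acceptors]
        for d_idx, h_idx in donors:
            dpos = coords[d_idx]
            dd = np.linalg.norm(acc - dpos, axis=1)
            for j in np.flatnonzero(dd <= criteria.donor_acceptor_max_A):
                if acceptors[j] == d_idx:
                    continue
                if h_idx is None:
                    counts[i] += 1
                    dists.append(float(dd[j]))
                    continue
                hpos = coords[h_idx]
                v1 = hpos - dpos
                v2 = acc[j] - dpos
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2)
                )
                dev = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if dev <= criteria.angle_max_deg:
                    counts[i] += 1
                    dists.append(float(dd[j]))
                    angles.append(dev)
    dists_arr = np.array(dists)
    angles_arr = np.array(angles)

    def _hist(data: np.ndarray, width: float):
        if data.size == 0:
            return np.array([]), np.array([])
        lo = np.floor(data.min() / width) * width
        hi = np.ceil(data.max() / width) * width + width
        edges = np.arange(lo, hi + width / 2, width)
        h, e = np.histogram(data, bins=edges)
        return h, e

    return {
        "counts": counts,
        "distances_A": dists_arr,
        "angles_deg": angles_arr,
        "distance_histogram": _hist(dists_arr, distance_bin_A),
        "angle_histogram": _hist(angles_arr, angle_bin_deg),
        "distance_only": distance_only,
        "criteria": criteria,
    }


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

# side-chain dihedral atom names per residue type (chi1/chi2 only)
CHI_ATOMS: dict[str, dict[str, tuple[str, str, str, str]]] = {
    "ARG": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD")},
    "HIS": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "ND1")},
    "LYS": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD")},
    "GLU": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD")},
    "GLN": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD")},
    "MET": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "SD")},
    "LEU": {"chi1": ("N", "CA", "CB", "CG"), "chi2": ("CA", "CB", "CG", "CD1")},
    "SER": {"chi1": ("N", "CA", "CB", "OG")},
    "CYS": {"chi1": ("N", "CA", "CB", "SG")},
    "THR": {"chi1": ("N", "CA", "CB", "OG1")},
}


def dihedral(p0, p1, p2, p3) -> float:
    """Signed (IUPAC) dihedral angle in degrees for four points."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def dihedral_series(
    traj: Trajectory, view: ProtomerView, residue_number: int, kind: str
) -> DihedralSeries:
    """Per-frame phi/psi/chi1/chi2 dihedral for one residue.

    Backbone phi/psi use the preceding/following residue's atoms;
    chi angles use the residue-type table (missing atoms — e.g. chi2 of
    Ser — are a named error).
    """
    protomer = view.protomer
    res = protomer.residue(residue_number)

    def _atom_index(resnum: int, name: str) -> int:
        r = protomer.residue(resnum)
        for flat, a in zip(view.atom_indices[resnum], r.atoms):
            if a.name == name:
                return flat
        raise ValueError(
            f"{kind} of {res.name}{residue_number}: missing atom "
            f"{name!r} in residue {resnum}"
        )

    if kind == "phi":
        quad = [
            _atom_index(residue_number - 1, "C"),
            _atom_index(residue_number, "N"),
            _atom_index(residue_number, "CA"),
            _atom_index(residue_number, "C"),
        ]
    elif kind == "psi":
        quad = [
            _atom_index(residue_number, "N"),
            _atom_index(residue_number, "CA"),
            _atom_index(residue_number, "C"),
            _atom_index(residue_number + 1, "N"),
        ]
    elif kind in ("chi1", "chi2"):
        table = CHI_ATOMS.get(res.name.upper(), {})
        if kind not in table:
            raise ValueError(
                f"{kind} undefined for residue type {res.name} "
                f"({res.name}{residue_number})"
            )
        quad = [_atom_index(residue_number, n) for n in table[kind]]
    else:
        raise ValueError(f"unknown dihedral kind {kind!r}")

    vals = np.array(
        [
            dihedral(*(traj.frames[i][q] for q in quad))
            for i in range(traj.n_frames)
        ]
    )
    return DihedralSeries(
        residue=(view.chain_id, residue_number), angle_kind=kind, values_deg=vals
    )


def angle_histogram(
    series: DihedralSeries, bin_deg: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)
    return np.histogram(series.values_deg, bins=edges)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

# single-atom van der Waals radii (Å) used for surface areas
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "MG": 1.73, "F": 1.47, "CL": 1.75,
}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into their principal-axes frame.

    The Fibonacci lattice is fixed in space, so sampling in a canonical
    molecular frame makes the surface area exactly invariant under rigid
    motions of the input (up to principal-axis degeneracy for highly
    symmetric point sets).
    """
    centered = coords - coords.mean(axis=0)
    if len(centered) < 2:
        return centered
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    local = centered @ v
    # orientation-independent signs: positive third moment along each axis
    skew = np.sum(local**3, axis=0)
    flip = np.where(skew < 0, -1.0, 1.0)
    return local * flip


def sasa(
    coords: np.ndarray,
    elements: Sequence[str],
    residue_keys: Sequence[ResidueKey] | None = None,
    probe_radius_A: float = 1.4,
    n_sphere_points: int = 960,
    radii: np.ndarray | None = None,
) -> PerResidueMap | np.ndarray:
    """Shrake–Rupley solvent-accessible surface area.

    Sphere points on each atom's solvent-expanded surface are tested for
    occlusion by neighboring atoms; the accessible fraction times the
    sphere area gives the per-atom SASA.  Sampling happens in the
    molecule's principal-axes frame so results are rigid-motion
    invariant.  When ``residue_keys`` is given, per-atom areas are
    summed per residue into a :class:`PerResidueMap` (Å²); otherwise the
    per-atom array is returned.
    """
    coords = np.asarray(coords, dtype=float)
    elements = [e.upper() for e in elements]
    if radii is None:
        unknown = sorted({e for e in elements if e not in VDW_RADII})
        if unknown:
            raise ValueError(f"no van der Waals radius for element(s): {unknown}")
        radii = np.array([VDW_RADII[e] for e in elements])
    radii = np.asarray(radii, dtype=float) + probe_radius_A
    pts = _canonical_frame(coords)
    sphere = _fibonacci_sphere(n_sphere_points)
    n = len(pts)
    per_atom = np.empty(n)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
    for i in range(n):
        neighbors = np.flatnonzero(
            (d2[i] < (radii[i] + radii) ** 2) & (np.arange(n) != i)
        )
        surface = pts[i] + radii[i] * sphere
        if neighbors.size:
            dist2 = np.sum(
                (surface[:, None, :] - pts[neighbors][None, :, :]) ** 2, axis=2
            )
            # boundary tie-break by atom index so exactly coincident
            # spheres are counted once, not zero or twice
            r2 = radii[neighbors][None, :] ** 2
            tol = 1e-9 * r2
            lower = neighbors < i
            buried = (
                (dist2 < r2 - tol)
                | ((dist2 <= r2 + tol) & lower[None, :])
            ).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    if residue_keys is None:
        return per_atom
    out: dict[ResidueKey, float] = {}
    for key, area in zip(residue_keys, per_atom):
        out[key] = out.get(key, 0.0) + float(area)
    return PerResidueMap(out, label="SASA", units="A^2")
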