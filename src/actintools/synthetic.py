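"""Synthetic actin-like protomers, filaments and trajectories with
planted, recoverable ground truth.

The generator stands in for production MD runs so every pipeline stage
can be verified against known answers:

- a 375-residue CA-only protomer whose subdomain centroids exactly
  reproduce a planted layout, built in the canonical axis frame (SD1/SD3
  on the X-axis so the frame origin is (0,0,0), SD2 toward +Z);
- cleft pseudo-ligands (ADP-like, Pi-like, Mg-like point groups)
  surrounded by a z-symmetric cage of cleft-lining residues;
- deterministic motion modes (D-loop in/out-of-plane swings, SD3→SD4
  hinge, cleft breathing, C-terminal fluctuation) plus block-correlated
  Gaussian noise with optional AR(1) memory;
- an optional C374-tethering constraint emulating a PBM crosslink.

D-loop swings are applied with subdomain-centroid compensation: the
non-D-loop SD2 residues are counter-translated so the SD2 centroid (and
hence the axis frame) is exactly unperturbed and the planted angle is
exactly recoverable.  The cleft cage is z-symmetric about the cleft
center so breathing leaves all subdomain centroids invariant.  Ground
truth carries the analytically expected descriptor series for every
planted mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from actintools.model_io import (
    AtomRecord,
    CrosslinkSpec,
    FilamentSystem,
    LigandGroup,
    LigandKind,
    Protomer,
    ProtomerRole,
    Residue,
    SubdomainScheme,
    Trajectory,
)

__all__ = [
    "ScaffoldSpec",
    "Mode",
    "NoiseSpec",
    "MotionModel",
    "CrosslinkConstraint",
    "make_scaffold",
    "make_filament",
    "generate_trajectory",
    "apply_crosslink_constraint",
    "make_community_scaffold",
    "make_crosslink_testbed",
    "fourier_amplitude",
]

DEFAULT_CENTROIDS: dict[str, tuple[float, float, float]] = {
    "SD1": (-15.0, 0.0, 0.0),
    "SD2": (-15.0, 0.0, 25.0),
    "SD3": (15.0, 0.0, 0.0),
    # SD4 sits slightly off the SD3 vertical so the SD3->SD4 tilt has a
    # nonzero baseline and hinge rotations never fold through 0 deg
    "SD4": (18.0, 0.0, 22.0),
}
DEFAULT_DLOOP_CENTROID = (-15.0, 0.0, 43.0)
DEFAULT_CLEFT_CENTER = (0.0, 0.0, 8.0)

# cleft-lining residues drawn from SD1 and SD3 (the cleft sits at the
# SD1/SD3 interface); kept z-symmetric about the cleft center
CAGE_RESIDUES: tuple[int, ...] = (
    10, 11, 12, 13, 14, 15, 16, 17, 338, 339, 340, 341,
    155, 156, 157, 158, 159, 160, 161, 162, 300, 301, 302, 303,
)


@dataclass
class ScaffoldSpec:
    n_residues: int = 375
    scheme: SubdomainScheme = field(default_factory=SubdomainScheme)
    centroid_layout: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CENTROIDS)
    )
    dloop_centroid: tuple[float, float, float] = DEFAULT_DLOOP_CENTROID
    cleft_center: tuple[float, float, float] = DEFAULT_CLEFT_CENTER
    cage_radius_A: float = 6.0
    cleft_exclusion_A: float = 13.0  # free residues stay outside this radius
    n_adp_atoms: int = 10
    n_pi_atoms: int = 4
    seed: int = 0


@dataclass
class Mode:
    """One deterministic motion mode.

    kinds: dloop_swing_in_plane / dloop_swing_out_of_plane (amplitude in
    degrees, sinusoidal), sd34_hinge (degrees, raised-cosine in [0, A]),
    cleft_breathing (amplitude = fractional z-compression, raised-cosine
    scale in [1−A, 1]), cterm_fluctuation (extra noise amplitude in Å on
    residues 370–375).
    """

    kind: str
    amplitude: float
    period_frames: int = 200

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("mode amplitude must be >= 0")
        valid = {
            "dloop_swing_in_plane",
            "dloop_swing_out_of_plane",
            "sd34_hinge",
            "cleft_breathing",
            "cterm_fluctuation",
        }
        if self.kind not in valid:
            raise ValueError(f"unknown mode kind {self.kind!r}")


@dataclass
class NoiseSpec:
    """Block-correlated Gaussian residue noise.

    Within a block the pairwise correlation is ``rho_in``; across blocks
    it is ``rho_cross`` (requires 0 ≤ rho_cross ≤ rho_in < 1).  AR(1)
    memory in time via ``ar1`` (0 = white noise).
    """

    sigma_A: float = 0.5
    blocks: list[list[int]] | None = None
    rho_in: float = 0.0
    rho_cross: float = 0.0
    ar1: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_A <= 0:
            raise ValueError("sigma must be positive")
        if not (0 <= self.rho_cross <= self.rho_in < 1):
            raise ValueError("need 0 <= rho_cross <= rho_in < 1")
        if not (-1 < self.ar1 < 1):
            raise ValueError("|AR(1) coefficient| must be < 1")


@dataclass
class CrosslinkConstraint:
    """PBM-like tether: C374 is displaced toward a cross-strand
    K191-like anchor by a restoring fraction each frame, and C-terminal
    (370–375) fluctuations are rescaled."""

    tether_residue: int = 374
    anchor_point: tuple[float, float, float] = (10.0, -12.0, -5.0)
    stiffness: float = 0.5
    cterm_amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.stiffness <= 1):
            raise ValueError("stiffness must lie in (0, 1]")


@dataclass
class MotionModel:
    modes: list[Mode] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    constraint: CrosslinkConstraint | None = None


def apply_crosslink_constraint(
    motion: MotionModel, constraint: CrosslinkConstraint
) -> MotionModel:
    """Return a copy of the motion model with the tether attached."""
    return replace(motion, constraint=constraint)


# ---------------------------------------------------------------------------
# Scaffold construction
# ---------------------------------------------------------------------------


def _dloop_offsets(n: int) -> np.ndarray:
    """Fixed arc-like D-loop shape, exactly zero-mean."""
    t = np.linspace(-1.0, 1.0, n)
    pts = np.stack(
        [4.0 * np.sin(1.2 * t), 0.8 * t, 3.0 * np.cos(1.2 * t)], axis=1
    )
    return pts - pts.mean(axis=0)


def _cage_offsets(radius: float) -> np.ndarray:
    """24 cage points in ±z pairs (z-symmetric about the cleft center)."""
    n_pairs = len(CAGE_RESIDUES) // 2
    phi = 2 * np.pi * np.arange(n_pairs) / n_pairs + 0.26
    dz = 2.0 + 3.0 * np.arange(n_pairs) / (n_pairs - 1)
    top = np.stack([radius * np.cos(phi), radius * np.sin(phi), dz], axis=1)
    bottom = top.copy()
    bottom[:, 2] *= -1
    return np.concatenate([top, bottom], axis=0)


def _ligand_points(spec: ScaffoldSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    c = np.asarray(spec.cleft_center)
    adp = c + rng.normal(0, 0.8, size=(spec.n_adp_atoms, 3))
    adp = np.clip(adp - c, -1.5, 1.5) + c
    pi = c + np.array([2.5, 0, 0]) + rng.normal(0, 0.4, size=(spec.n_pi_atoms, 3))
    mg = (c + np.array([-2.5, 0.0, 0.0]))[None, :]
    return {"ADP": adp, "Pi": pi, "Mg": mg}


def scaffold_coordinates(spec: ScaffoldSpec) -> tuple[dict[int, np.ndarray], dict]:
    """Planted CA coordinates keyed by residue number, plus ground truth.

    Subdomain centroids reproduce ``centroid_layout`` exactly: special
    residues (D-loop, cleft cage) are placed first and the free residues
    of each subdomain absorb the remainder so the unweighted CA mean
    hits the planted centroid to machine precision.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = spec.scheme
    coords: dict[int, np.ndarray] = {}

    dres = scheme.dloop_residues()
    dc = np.asarray(spec.dloop_centroid, dtype=float)
    for num, off in zip(dres, _dloop_offsets(len(dres))):
        coords[num] = dc + off

    cage_pts = np.asarray(spec.cleft_center) + _cage_offsets(spec.cage_radius_A)
    for num, pt in zip(CAGE_RESIDUES, cage_pts):
        coords[num] = pt.astype(float)

    cleft_c = np.asarray(spec.cleft_center)
    for sd, target in spec.centroid_layout.items():
        target = np.asarray(target, dtype=float)
        members = [r for r in scheme.residues_of(sd) if r <= spec.n_residues]
        fixed = [r for r in members if r in coords]
        free = [r for r in members if r not in coords]
        if not free:
            continue
        offsets = rng.normal(0, 3.0, size=(len(free), 3))
        offsets -= offsets.mean(axis=0)
        fixed_sum = (
            np.sum([coords[r] for r in fixed], axis=0)
            if fixed
            else np.zeros(3)
        )
        free_mean = (len(members) * target - fixed_sum) / len(free)
        pts = free_mean + offsets
        # keep free residues out of the cleft neighborhood so the 8 A
        # ligand selection stays confined to the planted cage
        for _ in range(3):
            rel = pts - cleft_c
            d = np.linalg.norm(rel, axis=1)
            close = d < spec.cleft_exclusion_A
            if not close.any():
                break
            pts[close] = (
                cleft_c
                + rel[close] / d[close, None] * (spec.cleft_exclusion_A + 0.5)
            )
            pts += free_mean - pts.mean(axis=0)
        for num, pt in zip(free, pts):
            coords[num] = pt

    truth = {
        "centroids": {k: np.asarray(v, float) for k, v in spec.centroid_layout.items()},
        "dloop_centroid": dc,
        "cleft_center": cleft_c,
        "cage_residues": list(CAGE_RESIDUES),
        "cage_max_dz": 5.0,
    }
    return coords, truth


def make_scaffold(
    spec: ScaffoldSpec | None = None, chain_id: str = "A"
) -> FilamentSystem:
    """Single CA-only protomer plus cleft pseudo-ligands.

    Deterministic for a given spec/seed; subdomain centroids reproduce
    the planted layout to machine precision.
    """
    spec = spec or ScaffoldSpec()
    coords, _ = scaffold_coordinates(spec)
    rng = np.random.default_rng(spec.seed + 1)
    ligs = _ligand_points(spec, rng)

    residues = []
    serial = 0
    for num in range(1, spec.n_residues + 1):
        if num not in coords:
            raise ValueError(f"subdomain scheme does not cover residue {num}")
        serial += 1
        atom = AtomRecord(
            serial=serial, name="CA", element="C", residue_number=num,
            residue_name="ALA", chain_id=chain_id, position=coords[num],
        )
        residues.append(Residue(number=num, name="ALA", atoms=[atom]))

    def _group(kind: LigandKind, resname: str, element: str, pts: np.ndarray,
               resnum: int) -> LigandGroup:
        nonlocal serial
        atoms = []
        for k, p in enumerate(pts):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial, name=f"{element}{k + 1}", element=element,
                    residue_number=resnum, residue_name=resname,
                    chain_id=chain_id, position=p,
                )
            )
        return LigandGroup(kind=kind, atoms=atoms)

    ligands = [
        _group(LigandKind.ADP, "ADP", "P", ligs["ADP"], 401),
        _group(LigandKind.PI, "PO4", "O", ligs["Pi"], 402),
        _group(LigandKind.MG, "MG", "MG", ligs["Mg"], 403),
    ]
    protomer = Protomer(chain_id=chain_id, residues=residues, ligands=ligands)
    return FilamentSystem(name="synthetic-protomer", protomers=[protomer])


# rise/twist per protomer along the filament axis (literature convention)
HELIX_RISE_A = 27.5
HELIX_TWIST_DEG = -166.7

CROSSLINK_PATTERNS: dict[str, list[tuple[int, int]]] = {
    "control": [],
    "pbm_dimer": [(1, 2), (3, 4), (5, 6)],
    "pbm_trimer": [(1, 2), (2, 3), (4, 5), (5, 6), (7, 8), (8, 9)],
}


def make_filament(
    spec: ScaffoldSpec | None = None,
    n_protomers: int = 6,
    pattern: str = "control",
) -> FilamentSystem:
    """Helical filament of protomers with a crosslink pattern.

    Patterns follow the simulated systems: 'pbm_dimer' (6 protomers,
    3 crosslinks at (1,2), (3,4), (5,6)), 'pbm_trimer' (9 protomers,
    6 crosslinks), or 'control' (none).  Donor protomers are labelled
    crosslinked-C-terminus, acceptor protomers crosslinked-K191.
    """
    if n_protomers < 2:
        raise ValueError("a filament needs at least 2 protomers")
    if pattern not in CROSSLINK_PATTERNS:
        raise ValueError(f"unknown crosslink pattern {pattern!r}")
    links = CROSSLINK_PATTERNS[pattern]
    if links and max(max(a, b) for a, b in links) > n_protomers:
        raise ValueError(
            f"pattern {pattern!r} references protomer beyond n={n_protomers}"
        )
    spec = spec or ScaffoldSpec()
    chain_ids = [str(i + 1) for i in range(n_protomers)]

    protomers = []
    for i, cid in enumerate(chain_ids):
        unit = make_scaffold(spec, chain_id=cid)
        p = unit.protomers[0]
        theta = np.radians(HELIX_TWIST_DEG * i)
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shift = np.array([0.0, 0.0, HELIX_RISE_A * i])
        for a in list(
            at for r in p.residues for at in r.atoms
        ) + [at for lig in p.ligands for at in lig.atoms]:
            a.position = rot @ a.position + shift
        protomers.append(p)

    donors = {a for a, _ in links}
    acceptors = {b for _, b in links}
    for i, p in enumerate(protomers, start=1):
        if i in donors:
            p.role = ProtomerRole.PBM_CROSSLINKED_CTERM
        elif i in acceptors:
            p.role = ProtomerRole.PBM_CROSSLINKED_K191
    crosslinks = [
        CrosslinkSpec(
            donor_chain=chain_ids[a - 1], acceptor_chain=chain_ids[b - 1]
        )
        for a, b in links
    ]
    return FilamentSystem(
        name=f"synthetic-filament-{pattern}-{n_protomers}",
        protomers=protomers,
        crosslinks=crosslinks,
    )


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------


def _rot_y(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])


def _block_noise(
    rng: np.random.Generator,
    n_frames: int,
    resnums: list[int],
    noise: NoiseSpec,
) -> np.ndarray:
    """(frames, residues, 3) correlated Gaussian noise."""
    n = len(resnums)
    block_of = np.full(n, -1)
    if noise.blocks:
        index = {r: i for i, r in enumerate(resnums)}
        for b, members in enumerate(noise.blocks):
            for r in members:
                if r in index:
                    block_of[index[r]] = b
    n_blocks = int(block_of.max()) + 1 if noise.blocks else 0

    rho_in, rho_x = noise.rho_in, noise.rho_cross
    w_global = np.sqrt(rho_x)
    w_block = np.sqrt(rho_in - rho_x)
    w_ind = np.sqrt(1.0 - rho_in)

    eps = np.empty((n_frames, n, 3))
    prev = np.zeros((n, 3))
    phi = noise.ar1
    innov_scale = np.sqrt(1.0 - phi**2) if phi else 1.0
    for t in range(n_frames):
        zg = rng.standard_normal(3)
        zb = rng.standard_normal((n_blocks, 3)) if n_blocks else None
        zi = rng.standard_normal((n, 3))
        step = w_ind * zi + w_global * zg[None, :]
        if zb is not None:
            in_block = block_of >= 0
            step[in_block] += w_block * zb[block_of[in_block]]
        if phi:
            prev = phi * prev + innov_scale * step
            eps[t] = noise.sigma_A * prev
        else:
            eps[t] = noise.sigma_A * step
    return eps


def generate_trajectory(
    system: FilamentSystem,
    motion: MotionModel,
    n_frames: int,
    seed: int,
    chain_id: str | None = None,
    scheme: SubdomainScheme | None = None,
    frame_interval_ns: float = 0.1,
) -> tuple[Trajectory, dict]:
    """Synthesize a trajectory: base coordinates + deterministic mode
    displacements + correlated noise (+ optional C374 tether).

    Returns the trajectory and a ground-truth dict with the analytically
    expected per-frame descriptor values for each planted mode
    (in/out-of-plane D-loop angle, domain tilt, cleft z-scale), the
    noise block membership and the constraint parameters.
    """
    scheme = scheme or SubdomainScheme()
    rng = np.random.default_rng(seed)
    base = system.coordinates()
    n_atoms = base.shape[0]

    protomer = system.protomers[0] if chain_id is None else system.chain(chain_id)
    # flat indices for this chain's residues (CA-only scaffolds: 1 atom each)
    flat_index: dict[int, list[int]] = {}
    pos = 0
    lig_index: list[int] = []
    for p in system.protomers:
        for r in p.residues:
            if p is protomer:
                flat_index[r.number] = list(range(pos, pos + len(r.atoms)))
            pos += len(r.atoms)
        for lig in p.ligands:
            if p is protomer:
                lig_index.extend(range(pos, pos + len(lig.atoms)))
            pos += len(lig.atoms)
    resnums = sorted(flat_index)

    dloop = [r for r in scheme.dloop_residues() if r in flat_index]
    sd2_free = [
        r for r in scheme.residues_of("SD2") if r in flat_index and r not in dloop
    ]
    sd4 = [r for r in scheme.residues_of("SD4") if r in flat_index]
    cage = [r for r in CAGE_RESIDUES if r in flat_index]
    cterm = [r for r in range(370, 376) if r in flat_index]

    def idx(nums: Sequence[int]) -> np.ndarray:
        return np.array([i for r in nums for i in flat_index[r]], dtype=int)

    dloop_idx, sd2_free_idx = idx(dloop), idx(sd2_free)
    sd4_idx, cage_idx = idx(sd4), idx(cage)
    cleft_c = np.asarray(DEFAULT_CLEFT_CENTER)

    sd3_members = [r for r in scheme.residues_of("SD3") if r in flat_index]
    sd3_centroid = (
        base[idx(sd3_members)].mean(axis=0) if sd3_members else np.zeros(3)
    )

    t_arr = np.arange(n_frames, dtype=float)
    truth: dict = {
        "modes": [(m.kind, m.amplitude, m.period_frames) for m in motion.modes],
        "blocks": motion.noise.blocks,
        "seed": seed,
    }

    # precompute per-mode schedules
    schedules: list[tuple[Mode, np.ndarray]] = []
    for m in motion.modes:
        w = 2 * np.pi * t_arr / m.period_frames
        if m.kind in ("dloop_swing_in_plane", "dloop_swing_out_of_plane"):
            theta = np.radians(m.amplitude) * np.sin(w)
        elif m.kind == "sd34_hinge":
            theta = np.radians(m.amplitude) * 0.5 * (1.0 - np.cos(w))
        elif m.kind == "cleft_breathing":
            theta = 1.0 - m.amplitude * 0.5 * (1.0 - np.cos(w))  # z scale
        else:  # cterm_fluctuation: extra noise sigma, constant
            theta = np.full(n_frames, m.amplitude)
        schedules.append((m, theta))

    # analytic ground-truth descriptor series
    if dloop:
        dc0 = base[dloop_idx].mean(axis=0)
        in0 = np.degrees(np.arctan2(dc0[0], dc0[2]))
        truth["in_plane_deg"] = np.full(n_frames, in0)
        truth["out_of_plane_deg"] = np.full(
            n_frames, np.degrees(np.arcsin(dc0[1] / np.linalg.norm(dc0)))
        )
    if sd4:
        sd4_c0 = base[sd4_idx].mean(axis=0)
        v34_0 = sd4_c0 - sd3_centroid
        a34_0 = np.degrees(
            np.arccos(np.clip(v34_0[2] / np.linalg.norm(v34_0), -1, 1))
        )
        sd2_all = idx([r for r in scheme.residues_of("SD2") if r in flat_index])
        sd1_all = idx([r for r in scheme.residues_of("SD1") if r in flat_index])
        v12 = base[sd2_all].mean(axis=0) - base[sd1_all].mean(axis=0)
        a12 = np.degrees(np.arccos(np.clip(v12[2] / np.linalg.norm(v12), -1, 1)))
        truth["tilt_deg"] = np.full(n_frames, a12 - a34_0)
    truth["cleft_z_scale"] = np.ones(n_frames)

    for m, theta in schedules:
        if m.kind == "dloop_swing_in_plane" and dloop:
            truth["in_plane_deg"] = truth["in_plane_deg"] + np.degrees(theta)
        elif m.kind == "dloop_swing_out_of_plane" and dloop:
            oop = np.empty(n_frames)
            for t in range(n_frames):
                v = _rot_x(theta[t]) @ dc0
                oop[t] = np.degrees(np.arcsin(v[1] / np.linalg.norm(v)))
            truth["out_of_plane_deg"] = oop
        elif m.kind == "sd34_hinge" and sd4:
            rotated = np.empty(n_frames)
            for t in range(n_frames):
                v = _rot_y(theta[t]) @ v34_0
                rotated[t] = np.degrees(
                    np.arccos(np.clip(v[2] / np.linalg.norm(v), -1, 1))
                )
            truth["tilt_deg"] = a12 - rotated
        elif m.kind == "cleft_breathing":
            truth["cleft_z_scale"] = theta.copy()

    noise = _block_noise(rng, n_frames, resnums, motion.noise)
    cterm_sigma_extra = 0.0
    for m, theta in schedules:
        if m.kind == "cterm_fluctuation":
            cterm_sigma_extra = m.amplitude

    constraint = motion.constraint
    if constraint is not None:
        truth["constraint"] = {
            "tether_residue": constraint.tether_residue,
            "anchor_point": list(constraint.anchor_point),
            "stiffness": constraint.stiffness,
            "cterm_amplitude_scale": constraint.cterm_amplitude_scale,
        }
        scale_rows = [
            i for i, r in enumerate(resnums) if r in cterm
        ]
        noise[:, scale_rows, :] *= constraint.cterm_amplitude_scale
    if cterm_sigma_extra > 0:
        extra_rows = [i for i, r in enumerate(resnums) if r in cterm]
        noise[:, extra_rows, :] += rng.normal(
            0, cterm_sigma_extra, size=(n_frames, len(extra_rows), 3)
        )

    res_row = {r: i for i, r in enumerate(resnums)}
    frames = np.empty((n_frames, n_atoms, 3))
    for t in range(n_frames):
        coords = base.copy()
        for m, theta in schedules:
            if m.kind == "dloop_swing_in_plane" and dloop:
                rot = _rot_y(theta[t])
                old_mean = coords[dloop_idx].mean(axis=0)
                coords[dloop_idx] = coords[dloop_idx] @ rot.T
                delta = coords[dloop_idx].mean(axis=0) - old_mean
                if len(sd2_free_idx):
                    coords[sd2_free_idx] -= (
                        len(dloop_idx) / len(sd2_free_idx)
                    ) * delta
            elif m.kind == "dloop_swing_out_of_plane" and dloop:
                rot = _rot_x(theta[t])
                old_mean = coords[dloop_idx].mean(axis=0)
                coords[dloop_idx] = coords[dloop_idx] @ rot.T
                delta = coords[dloop_idx].mean(axis=0) - old_mean
                if len(sd2_free_idx):
                    coords[sd2_free_idx] -= (
                        len(dloop_idx) / len(sd2_free_idx)
                    ) * delta
            elif m.kind == "sd34_hinge" and len(sd4_idx):
                rot = _rot_y(theta[t])
                coords[sd4_idx] = (
                    (coords[sd4_idx] - sd3_centroid) @ rot.T + sd3_centroid
                )
            elif m.kind == "cleft_breathing":
                s = theta[t]
                affected = np.concatenate([cage_idx, np.asarray(lig_index, int)]) \
                    if len(cage_idx) else np.asarray(lig_index, int)
                if len(affected):
                    coords[affected, 2] = (
                        cleft_c[2] + s * (coords[affected, 2] - cleft_c[2])
                    )
        for r in resnums:
            for i in flat_index[r]:
                coords[i] += noise[t, res_row[r]]
        if constraint is not None and constraint.tether_residue in flat_index:
            for i in flat_index[constraint.tether_residue]:
                anchor = np.asarray(constraint.anchor_point)
                coords[i] = coords[i] + constraint.stiffness * (
                    anchor - coords[i]
                )
        frames[t] = coords

    times = (t_arr + 1.0) * frame_interval_ns
    traj = Trajectory(
        topology=system,
        frames=frames,
        times_ns=times,
        provenance=[{"generator": "actintools.synthetic", "seed": seed}],
    )
    return traj, truth


def fourier_amplitude(
    series: np.ndarray, period_frames: int, phase: str = "sin"
) -> float:
    """Least-squares amplitude of a sin/cos component at a known period.

    Averaging over all frames makes this estimator robust to the
    per-frame noise that a max−min estimate would inflate.
    """
    series = np.asarray(series, dtype=float)
    t = np.arange(series.size)
    w = 2 * np.pi * t / period_frames
    basis = np.sin(w) if phase == "sin" else np.cos(w)
    x = series - series.mean()
    return float(abs(2.0 * np.mean(x * basis)))


# ---------------------------------------------------------------------------
# Purpose-built small scaffolds
# ---------------------------------------------------------------------------


def make_community_scaffold(
    n_blocks: int = 3, per_block: int = 12, spacing_A: float = 9.0, seed: int = 0
) -> tuple[FilamentSystem, list[list[int]]]:
    """CA-only residue blocks arranged as spatial clusters with sparse
    bridge contacts between consecutive blocks.

    Residues within a block sit on a 2.9 Å grid whose face diagonals
    (4.1 Å) fall inside the 4.5 Å contact cutoff with margin to spare, so every block is a
    densely connected cluster even after the |i−j| ≤ 1 sequence-neighbor
    exclusion; adjacent blocks touch only through their facing grid
    columns (the planted inter-community bridges).  Returns the system
    and the residue-number blocks (the planted community partition and
    noise blocks).
    """
    rng = np.random.default_rng(seed)
    residues = []
    blocks: list[list[int]] = []
    serial = 0
    num = 0
    grid = []
    nx = int(np.ceil(per_block / 4))
    for ix in range(nx):
        for iy in range(2):
            for iz in range(2):
                grid.append((ix * 2.9, iy * 2.9, iz * 2.9))
    grid = np.asarray(grid[:per_block])
    grid = grid - grid.mean(axis=0)
    for b in range(n_blocks):
        members = []
        center = np.array([spacing_A * b, 0.0, 0.0])
        jitter = rng.normal(0, 0.05, size=grid.shape)
        for pt in grid + center + jitter:
            num += 1
            serial += 1
            members.append(num)
            residues.append(
                Residue(
                    number=num,
                    name="ALA",
                    atoms=[
                        AtomRecord(
                            serial=serial, name="CA", element="C",
                            residue_number=num, residue_name="ALA",
                            chain_id="A", position=pt,
                        )
                    ],
                )
            )
        blocks.append(members)
    system = FilamentSystem(
        name="community-scaffold",
        protomers=[Protomer(chain_id="A", residues=residues)],
    )
    return system, blocks


def make_crosslink_testbed(seed: int = 0) -> tuple[FilamentSystem, dict]:
    """A C-terminus-to-target communication testbed.

    Four compact residue clusters sit at the corners of a square: the
    C-terminal cluster (369–373, source 370), the target cluster
    (113–117, target 116), and a peripheral detour pair (356–360 and
    130–134).  Residue 374 bridges the C-terminal and target clusters
    directly, so the shortest 370→116 communication route runs through
    it; the detour connects the same endpoints around the periphery in
    many more hops.  Tethering 374 to a distant anchor breaks its
    contacts and forces the rerouting.  Every planted contact clears the
    4.5 Å cutoff by ≥ 1.5 Å and every sequence-neighbor pair is excluded
    by numbering, verified in the test suite against a brute-force
    distance check.
    """
    rng = np.random.default_rng(seed)
    coords: dict[int, np.ndarray] = {
        # C-terminal cluster around (0, 0, 0)
        369: np.array([0.0, 2.0, 0.0]),
        370: np.array([-2.0, 0.0, 0.0]),
        371: np.array([2.0, 0.0, 0.0]),
        372: np.array([0.0, -2.0, 0.0]),
        373: np.array([0.0, 0.0, 2.0]),
        # the tethered bridge residue
        374: np.array([4.5, 0.0, 0.0]),
        # target cluster around (9, 0, 0)
        113: np.array([9.0, 2.0, 0.0]),
        114: np.array([9.0, -2.0, 0.0]),
        115: np.array([11.0, 0.0, 0.0]),
        116: np.array([7.0, 0.0, 0.0]),
        117: np.array([9.0, 4.5, 0.0]),
        # detour cluster around (0, 9, 0), entered via 356
        356: np.array([0.0, 4.5, 0.0]),
        357: np.array([-2.0, 9.0, 0.0]),
        358: np.array([0.0, 7.0, 0.0]),
        359: np.array([2.0, 9.0, 0.0]),
        360: np.array([0.0, 9.0, 2.0]),
        # detour cluster around (9, 9, 0), entered via 130, exits via 131
        130: np.array([4.5, 9.0, 0.0]),
        131: np.array([9.0, 7.0, 0.0]),
        132: np.array([7.0, 9.0, 0.0]),
        133: np.array([9.0, 11.0, 0.0]),
        134: np.array([9.0, 9.0, 2.0]),
    }
    for n in coords:
        coords[n] = coords[n] + rng.normal(0, 0.03, 3)

    residues = []
    for serial, num in enumerate(sorted(coords), start=1):
        residues.append(
            Residue(
                number=num,
                name="CYS" if num == 374 else "ALA",
                atoms=[
                    AtomRecord(
                        serial=serial, name="CA", element="C",
                        residue_number=num, residue_name="ALA", chain_id="A",
                        position=coords[num],
                    )
                ],
            )
        )
    system = FilamentSystem(
        name="crosslink-testbed",
        protomers=[Protomer(chain_id="A", residues=residues)],
    )
    info = {
        "source": ("A", 370),
        "target": ("A", 116),
        "tethered": ("A", 374),
        "anchor_point": (4.5, -25.0, 0.0),
        "blocks": [
            [369, 370, 371, 372, 373, 374],
            [113, 114, 115, 116, 117],
            [356, 357, 358, 359, 360],
            [130, 131, 132, 133, 134],
        ],
    }
    return system, info
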