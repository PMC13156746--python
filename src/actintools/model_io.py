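"""Domain model and structure/trajectory I/O.

Filaments are represented as ordered chains (protomers) of residues with
atoms; nucleotide ligands (ADP, inorganic phosphate, Mg) are attached to
their owning chain as ligand groups.  Coordinates are Å everywhere;
residue numbering is 1-based and follows the actin convention (C374,
F375, K191 are literal).  Water and ions are never read as coordinates:
they contribute only to a solvent pseudo-count used for system-ledger
arithmetic, since every analysis in the package is protein/ligand-only.

The trajectory dialect is multi-model PDB (one MODEL per frame); an
adapter for binary formats only needs to produce the same
:class:`Trajectory` contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "LigandGroup",
    "LigandKind",
    "ProtomerRole",
    "Protomer",
    "CrosslinkSpec",
    "FilamentSystem",
    "Trajectory",
    "SystemLedger",
    "SubdomainScheme",
    "PDBParseError",
    "TopologyError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "concatenate_replicates",
    "build_ledger",
]

_WATER_ION_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "NA", "CL", "K", "NA+", "CL-"}


class PDBParseError(ValueError):
    """Raised for malformed or contract-violating PDB content."""


class TopologyError(ValueError):
    """Raised when a trajectory or selection disagrees with its topology."""


class LigandKind(Enum):
    ADP = "ADP"
    PI = "Pi"
    MG = "Mg"
    HIC_TAG = "HIC_tag"
    OTHER = "other"


_LIGAND_RESNAMES = {
    "ADP": LigandKind.ADP,
    "PO4": LigandKind.PI,
    "PI": LigandKind.PI,
    "IPH": LigandKind.PI,
    "MG": LigandKind.MG,
    "HIC": LigandKind.HIC_TAG,
}


class ProtomerRole(Enum):
    PBM_CROSSLINKED_CTERM = "PBM_crosslinked_Cterm"
    PBM_CROSSLINKED_K191 = "PBM_crosslinked_K191"
    CONTROL = "control"


@dataclass
class AtomRecord:
    """One coordinate record.

    The occupancy and B-factor columns are reused as scalar output fields
    when per-residue maps are projected onto structures for visualization.
    """

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    occupancy_field: float = 1.0
    bfactor_field: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if self.residue_number < 1:
            raise ValueError(f"atom {self.name}: residue_number must be >= 1")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def ca_index(self) -> int | None:
        for i, a in enumerate(self.atoms):
            if a.name == "CA":
                return i
        return None

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number}: no atom {name!r}")


@dataclass
class LigandGroup:
    kind: LigandKind
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ligand group must contain at least one atom")


@dataclass
class Protomer:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    ligands: list[LigandGroup] = field(default_factory=list)
    role: ProtomerRole = ProtomerRole.CONTROL

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(
                f"chain {self.chain_id}: residue numbers must be strictly increasing"
            )

    def residue(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise KeyError(f"chain {self.chain_id}: no residue {number}")


@dataclass
class CrosslinkSpec:
    """A PBM-style crosslink annotation: C374 of one chain to K191 of another.

    The linker is bookkeeping plus optional pseudo-atoms, never
    parameterized chemistry.
    """

    donor_chain: str
    donor_residue: int = 374
    acceptor_chain: str = ""
    acceptor_residue: int = 191
    linker_atom_count: int = 26


@dataclass
class FilamentSystem:
    name: str = ""
    protomers: list[Protomer] = field(default_factory=list)
    crosslinks: list[CrosslinkSpec] = field(default_factory=list)
    solvent_pseudo_count: int = 0

    def __post_init__(self) -> None:
        chains = {p.chain_id for p in self.protomers}
        for xl in self.crosslinks:
            if xl.donor_chain not in chains or xl.acceptor_chain not in chains:
                raise ValueError(
                    f"crosslink {xl.donor_chain}->{xl.acceptor_chain}: "
                    "chain ids must resolve to protomers"
                )

    def chain(self, chain_id: str) -> Protomer:
        for p in self.protomers:
            if p.chain_id == chain_id:
                return p
        raise KeyError(f"no chain {chain_id!r}")

    def iter_atoms(self) -> Iterator[AtomRecord]:
        """All atoms in canonical order: per chain, residues then ligands."""
        for p in self.protomers:
            for r in p.residues:
                yield from r.atoms
            for lig in p.ligands:
                yield from lig.atoms

    @property
    def atoms(self) -> list[AtomRecord]:
        return list(self.iter_atoms())

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.iter_atoms()], dtype=float)


@dataclass
class Trajectory:
    """Frames × atoms × 3 coordinates (Å) bound to a topology."""

    topology: FilamentSystem
    frames: np.ndarray
    times_ns: np.ndarray
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] != self.times_ns.shape[0]:
            raise ValueError("times_ns length must match frame count")
        if np.any(np.diff(self.times_ns) <= 0):
            raise ValueError("times must be strictly increasing")
        n_top = self.topology.n_atoms
        if self.frames.shape[1] != n_top:
            raise TopologyError(
                f"expected {n_top} atoms per frame, found {self.frames.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class SystemLedger:
    """Atom-count bookkeeping in the style of an MD system-details table."""

    total_atoms: int
    protein_atoms: int
    protein_plus_ligand_atoms: int
    pbm_atoms: int
    water_ion_atoms: int

    def __post_init__(self) -> None:
        self.verify()

    def verify(self) -> None:
        if self.protein_plus_ligand_atoms < self.protein_atoms:
            raise ValueError("protein+ligand count below protein count")
        expected = (
            self.protein_plus_ligand_atoms + self.pbm_atoms + self.water_ion_atoms
        )
        if self.total_atoms != expected:
            raise ValueError(
                f"ledger additivity violated: total {self.total_atoms} != "
                f"{self.protein_plus_ligand_atoms} + {self.pbm_atoms} + "
                f"{self.water_ion_atoms} = {expected}"
            )

    @classmethod
    def from_components(
        cls,
        protein_plus_ligand_atoms: int,
        pbm_atoms: int,
        water_ion_atoms: int,
        protein_atoms: int | None = None,
    ) -> "SystemLedger":
        """Build a ledger from component counts; the total is computed."""
        if protein_atoms is None:
            protein_atoms = protein_plus_ligand_atoms
        return cls(
            total_atoms=protein_plus_ligand_atoms + pbm_atoms + water_ion_atoms,
            protein_atoms=protein_atoms,
            protein_plus_ligand_atoms=protein_plus_ligand_atoms,
            pbm_atoms=pbm_atoms,
            water_ion_atoms=water_ion_atoms,
        )


def _intervals(spec: object) -> list[tuple[int, int]]:
    if isinstance(spec, tuple) and len(spec) == 2 and isinstance(spec[0], int):
        return [spec]
    return [tuple(iv) for iv in spec]  # type: ignore[arg-type]


@dataclass
class SubdomainScheme:
    """Residue partition of a 375-residue actin-like protomer.

    The four subdomains follow the standard actin convention; intervals
    are inclusive on both ends.  The D-loop (DNaseI-binding loop) lives
    inside SD2.  Named elements cover the C-terminus-to-cleft
    communication route.
    """

    sd_ranges: dict[str, list[tuple[int, int]]] = field(
        default_factory=lambda: {
            "SD1": [(1, 32), (70, 144), (338, 375)],
            "SD2": [(33, 69)],
            "SD3": [(145, 180), (270, 337)],
            "SD4": [(181, 269)],
        }
    )
    dloop_range: tuple[int, int] = (38, 52)
    named_elements: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "sensor_loop": (72, 77),
            "N111_loop": (107, 112),
            "pathogenic_helix": (112, 126),
            "W_helix": (78, 91),
            "H_plug": (262, 274),
            "Pi_gate_stretch": (173, 179),
            "C_terminus": (370, 375),
        }
    )

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for sd, ivs in self.sd_ranges.items():
            for lo, hi in _intervals(ivs):
                for r in range(lo, hi + 1):
                    if r in seen:
                        raise ValueError(
                            f"residue {r} in both {seen[r]} and {sd}: "
                            "subdomain ranges must be disjoint"
                        )
                    seen[r] = sd
        lo, hi = self.dloop_range
        sd2 = set(self.residues_of("SD2"))
        if not set(range(lo, hi + 1)) <= sd2:
            raise ValueError("dloop_range must lie within SD2")
        if (lo, hi) != (38, 52):
            warnings.warn(
                f"non-default D-loop range {lo}-{hi}: the geometric D-loop "
                "convention here is 38-52 (some conventions use 38-53)",
                stacklevel=2,
            )

    def residues_of(self, sd: str) -> list[int]:
        out: list[int] = []
        for lo, hi in _intervals(self.sd_ranges[sd]):
            out.extend(range(lo, hi + 1))
        return out

    def subdomain_of(self, residue_number: int) -> str | None:
        for sd, ivs in self.sd_ranges.items():
            for lo, hi in _intervals(ivs):
                if lo <= residue_number <= hi:
                    return sd
        return None

    def dloop_residues(self) -> list[int]:
        lo, hi = self.dloop_range
        return list(range(lo, hi + 1))

    def covered(self) -> set[int]:
        out: set[int] = set()
        for sd in self.sd_ranges:
            out.update(self.residues_of(sd))
        return out


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _parse_coord_line(line: str, lineno: int) -> dict:
    try:
        return {
            "record": line[0:6].strip(),
            "serial": int(line[6:11]),
            "name": line[12:16].strip(),
            "altloc": line[16].strip(),
            "resname": line[17:20].strip(),
            "chain": line[21].strip(),
            "resnum": int(line[22:26]),
            "icode": line[26].strip(),
            "xyz": np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            ),
            "occ": float(line[54:60]) if line[54:60].strip() else 1.0,
            "bfac": float(line[60:66]) if line[60:66].strip() else 0.0,
            "element": line[76:78].strip() if len(line) >= 78 else "",
        }
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed coordinate record: {exc}")


def _guess_element(atom_name: str, resname: str) -> str:
    name = atom_name.strip()
    if resname.upper() in ("MG",):
        return "MG"
    if name[:1].isdigit():
        name = name[1:]
    return name[:1].upper() if name else "X"


def read_structure(path: str) -> FilamentSystem:
    """Read a single-model PDB file into a :class:`FilamentSystem`.

    Protein ATOM records populate chains/residues in file order; HETATM
    ligand groups are attached to their owning chain.  Water and ion
    records are counted into ``solvent_pseudo_count`` without keeping
    coordinates.  Alternate locations keep the highest-occupancy
    conformer; insertion codes are rejected (actin numbering has none).
    """
    with open(path) as fh:
        lines = fh.readlines()

    chains: dict[str, Protomer] = {}
    residue_map: dict[tuple[str, int], Residue] = {}
    ligand_map: dict[tuple[str, str, int], LigandGroup] = {}
    altloc_best: dict[tuple[str, int, str], tuple[float, AtomRecord]] = {}
    solvent = 0
    n_coord = 0

    for lineno, line in enumerate(lines, start=1):
        rec = line[0:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        f = _parse_coord_line(line, lineno)
        if f["icode"]:
            raise PDBParseError(
                f"line {lineno}: insertion code {f['icode']!r} not supported"
            )
        if f["resname"].upper() in _WATER_ION_RESNAMES:
            solvent += 1
            continue
        n_coord += 1
        element = f["element"] or _guess_element(f["name"], f["resname"])
        atom = AtomRecord(
            serial=f["serial"],
            name=f["name"],
            element=element,
            residue_number=f["resnum"],
            residue_name=f["resname"],
            chain_id=f["chain"] or "A",
            position=f["xyz"],
            occupancy_field=f["occ"],
            bfactor_field=f["bfac"],
        )
        chain_id = atom.chain_id
        if chain_id not in chains:
            chains[chain_id] = Protomer(chain_id=chain_id)

        is_ligand = rec == "HETATM" or f["resname"].upper() in _LIGAND_RESNAMES
        if is_ligand:
            key = (chain_id, f["resname"], f["resnum"])
            if key not in ligand_map:
                kind = _LIGAND_RESNAMES.get(f["resname"].upper(), LigandKind.OTHER)
                grp = LigandGroup(kind=kind, atoms=[atom])
                ligand_map[key] = grp
                chains[chain_id].ligands.append(grp)
            else:
                ligand_map[key].atoms.append(atom)
            continue

        akey = (chain_id, f["resnum"], f["name"])
        if f["altloc"]:
            prev = altloc_best.get(akey)
            if prev is None:
                altloc_best[akey] = (f["occ"], atom)
            elif f["occ"] > prev[0]:
                # replace the lower-occupancy conformer in place
                prev[1].position = atom.position
                prev[1].occupancy_field = atom.occupancy_field
                prev[1].bfactor_field = atom.bfactor_field
                altloc_best[akey] = (f["occ"], prev[1])
                continue
            else:
                continue
        elif akey in altloc_best:
            raise PDBParseError(
                f"line {lineno}: duplicate atom {f['name']!r} in "
                f"chain {chain_id} residue {f['resnum']}"
            )
        else:
            altloc_best[akey] = (f["occ"], atom)

        rkey = (chain_id, f["resnum"])
        if rkey not in residue_map:
            res = Residue(number=f["resnum"], name=f["resname"])
            residue_map[rkey] = res
            chains[chain_id].residues.append(res)
        if atom in residue_map[rkey].atoms:
            pass
        residue_map[rkey].atoms.append(atom)

    if n_coord == 0:
        raise PDBParseError("empty structure: no ATOM/HETATM coordinate records")

    system = FilamentSystem(
        name="", protomers=list(chains.values()), solvent_pseudo_count=solvent
    )
    # re-validate residue ordering after construction
    for p in system.protomers:
        Protomer(chain_id=p.chain_id, residues=p.residues)
    return system


def _format_atom_line(
    record: str, serial: int, atom: AtomRecord, bfactor: float
) -> str:
    name = atom.name
    # PDB column 13-16: 1/2-letter elements start at column 14
    if len(name) < 4 and len(atom.element) < 2:
        name = f" {name}"
    bfactor = float(np.clip(bfactor, -99.99, 999.99))
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{atom.residue_name:>3} "
        f"{atom.chain_id:1}{atom.residue_number:>4}{'':1}   "
        f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
        f"{atom.occupancy_field:6.2f}{bfactor:6.2f}          "
        f"{atom.element:>2}\n"
    )


def write_structure(
    system: FilamentSystem,
    path: str,
    scalar_field: Mapping[tuple[str, int], float] | None = None,
    coordinates: np.ndarray | None = None,
) -> None:
    """Write a PDB file; an optional per-residue scalar field goes into the
    B-factor column (residues absent from the field get 0.00).

    ``coordinates``, if given, overrides the topology's stored positions
    (used to write individual trajectory frames).
    """
    if scalar_field is not None:
        known = {
            (p.chain_id, r.number) for p in system.protomers for r in p.residues
        }
        bad = sorted(set(scalar_field) - known)
        if bad:
            raise ValueError(f"scalar_field keys not in system: {bad}")

    with open(path, "w") as fh:
        _write_structure_to(system, fh, scalar_field, coordinates)
        fh.write("END\n")


def _write_structure_to(system, fh, scalar_field, coordinates) -> None:
    atoms = system.atoms
    if coordinates is not None:
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.shape != (len(atoms), 3):
            raise ValueError(
                f"coordinates shape {coordinates.shape} != ({len(atoms)}, 3)"
            )
    serial = 0
    for p in system.protomers:
        for r in p.residues:
            for a in r.atoms:
                serial += 1
                b = 0.0
                if scalar_field is not None:
                    b = float(scalar_field.get((p.chain_id, r.number), 0.0))
                a_out = a
                if coordinates is not None:
                    a_out = AtomRecord(
                        a.serial, a.name, a.element, a.residue_number,
                        a.residue_name, a.chain_id, coordinates[serial - 1],
                        a.occupancy_field, a.bfactor_field,
                    )
                fh.write(_format_atom_line("ATOM", serial, a_out, b))
        fh.write(f"TER   {serial + 1:>5}\n")
        for lig in p.ligands:
            for a in lig.atoms:
                serial += 1
                a_out = a
                if coordinates is not None:
                    a_out = AtomRecord(
                        a.serial, a.name, a.element, a.residue_number,
                        a.residue_name, a.chain_id, coordinates[serial - 1],
                        a.occupancy_field, a.bfactor_field,
                    )
                fh.write(_format_atom_line("HETATM", serial, a_out, 0.0))


def write_trajectory(traj: "Trajectory", path: str) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    import io

    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:>4}\n")
            buf = io.StringIO()
            _write_structure_to(traj.topology, buf, None, traj.frames[i])
            fh.write(buf.getvalue())
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_trajectory(
    path: str, topology: FilamentSystem, frame_interval_ns: float = 0.1
) -> Trajectory:
    """Read a multi-model PDB as a trajectory against a known topology.

    Frames are ordered by MODEL number; times are assigned from the
    stated frame interval.  Every MODEL must carry exactly the topology's
    atom count (water/ion records are ignored, matching the topology
    reader).  The input is assumed to be pre-unwrapped (no periodic
    boundary jumps).
    """
    n_expected = topology.n_atoms
    frames: list[np.ndarray] = []
    current: list[list[float]] | None = None
    model_number = 0
    saw_model = False

    def _finish(coords: list[list[float]], model: int) -> None:
        if len(coords) != n_expected:
            raise TopologyError(
                f"model {model}: expected {n_expected} atoms, found {len(coords)}"
            )
        frames.append(np.array(coords, dtype=float))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[0:6].strip()
            if rec == "MODEL":
                saw_model = True
                model_number = int(line.split()[1]) if len(line.split()) > 1 else (
                    len(frames) + 1
                )
                current = []
            elif rec == "ENDMDL":
                if current is None:
                    raise PDBParseError(f"line {lineno}: ENDMDL without MODEL")
                _finish(current, model_number)
                current = None
            elif rec in ("ATOM", "HETATM"):
                f = _parse_coord_line(line, lineno)
                if f["resname"].upper() in _WATER_ION_RESNAMES:
                    continue
                if current is None:
                    if saw_model:
                        raise PDBParseError(
                            f"line {lineno}: coordinates outside MODEL block"
                        )
                    current = []
                current.append(list(f["xyz"]))

    if current is not None:
        _finish(current, model_number + 1 if saw_model else 1)
    if not frames:
        raise PDBParseError("empty trajectory: no frames found")

    n = len(frames)
    times = np.arange(n, dtype=float) * frame_interval_ns + frame_interval_ns
    return Trajectory(
        topology=topology,
        frames=np.stack(frames),
        times_ns=times,
        provenance=[{"source": str(path), "frames": n}],
    )


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------


def _normalize_residue_spec(
    residues: int | tuple[int, int] | Iterable | None,
) -> list[tuple[int, int]] | None:
    if residues is None:
        return None
    if isinstance(residues, int):
        return [(residues, residues)]
    if (
        isinstance(residues, tuple)
        and len(residues) == 2
        and all(isinstance(x, int) for x in residues)
    ):
        return [residues]
    out: list[tuple[int, int]] = []
    for item in residues:
        out.extend(_normalize_residue_spec(item))  # type: ignore[arg-type]
    return out


def select_atoms(
    system: FilamentSystem,
    chain: str | Sequence[str] | None = None,
    residues: int | tuple[int, int] | Iterable | None = None,
    names: str | Sequence[str] | None = None,
    heavy_only: bool = False,
    include_ligands: bool = False,
) -> np.ndarray:
    """Select atom indices (into canonical atom order) by chain, residue
    interval(s), atom names, and a heavy-only flag.

    Deterministic and order-preserving; an empty result is returned with
    a warning rather than an error.  Intervals are inclusive.
    """
    if isinstance(chain, str):
        chain = [chain]
    if chain is not None:
        known = {p.chain_id for p in system.protomers}
        missing = set(chain) - known
        if missing:
            raise KeyError(f"unknown chain(s): {sorted(missing)}")
    if isinstance(names, str):
        names = [names]
    name_set = set(names) if names is not None else None
    ivs = _normalize_residue_spec(residues)

    out: list[int] = []
    idx = 0
    for p in system.protomers:
        chain_ok = chain is None or p.chain_id in chain
        for r in p.residues:
            res_ok = ivs is None or any(lo <= r.number <= hi for lo, hi in ivs)
            for a in r.atoms:
                if (
                    chain_ok
                    and res_ok
                    and (name_set is None or a.name in name_set)
                    and (not heavy_only or a.is_heavy)
                ):
                    out.append(idx)
                idx += 1
        for lig in p.ligands:
            for a in lig.atoms:
                if (
                    include_ligands
                    and chain_ok
                    and ivs is None
                    and (name_set is None or a.name in name_set)
                    and (not heavy_only or a.is_heavy)
                ):
                    out.append(idx)
                idx += 1
    if not out:
        warnings.warn("selection matched no atoms", stacklevel=2)
    return np.array(out, dtype=int)


class ProtomerView:
    """Index bookkeeping for one chain of a system.

    Binds residue numbers to flat atom indices so per-frame coordinate
    arrays can be sliced without re-walking the topology.
    """

    def __init__(self, system: FilamentSystem, chain_id: str):
        self.system = system
        self.chain_id = chain_id
        protomer = system.chain(chain_id)
        self.protomer = protomer

        flat: dict[int, AtomRecord] = dict(enumerate(system.iter_atoms()))
        # map id(atom) -> flat index for this chain's atoms
        pos_of = {id(a): i for i, a in flat.items()}

        self.residue_numbers: list[int] = [r.number for r in protomer.residues]
        self.ca_indices: dict[int, int] = {}
        self.heavy_indices: dict[int, list[int]] = {}
        self.atom_indices: dict[int, list[int]] = {}
        for r in protomer.residues:
            self.atom_indices[r.number] = [pos_of[id(a)] for a in r.atoms]
            self.heavy_indices[r.number] = [
                pos_of[id(a)] for a in r.atoms if a.is_heavy
            ]
            ci = r.ca_index
            if ci is not None:
                self.ca_indices[r.number] = pos_of[id(r.atoms[ci])]
        self.ligand_indices: list[int] = [
            pos_of[id(a)] for lig in protomer.ligands for a in lig.atoms
        ]

    def ca_array(self, residue_numbers: Sequence[int] | None = None) -> np.ndarray:
        """Flat atom indices of alpha-carbons, ordered by residue number."""
        nums = (
            self.residue_numbers if residue_numbers is None else list(residue_numbers)
        )
        missing = [n for n in nums if n not in self.ca_indices]
        if missing:
            raise KeyError(
                f"chain {self.chain_id}: residues without alpha-carbon: {missing}"
            )
        return np.array([self.ca_indices[n] for n in nums], dtype=int)


# ---------------------------------------------------------------------------
# Trajectory utilities and ledger
# ---------------------------------------------------------------------------


def concatenate_replicates(trajectories: Sequence[Trajectory]) -> Trajectory:
    """Append replicate trajectories into one, re-offsetting times so the
    combined series is strictly increasing; replicate boundaries are
    recorded in provenance."""
    if not trajectories:
        raise ValueError("no trajectories given")
    first = trajectories[0]
    if len(trajectories) == 1:
        return first
    n_atoms = first.n_atoms
    for t in trajectories[1:]:
        if t.n_atoms != n_atoms:
            raise TopologyError(
                f"topology mismatch: {t.n_atoms} atoms vs {n_atoms}"
            )
    frames = np.concatenate([t.frames for t in trajectories], axis=0)
    times: list[np.ndarray] = []
    offset = 0.0
    boundaries: list[int] = []
    total = 0
    for t in trajectories:
        shifted = t.times_ns + offset - t.times_ns[0]
        if times:
            dt = np.median(np.diff(t.times_ns)) if t.n_frames > 1 else 1.0
            shifted = shifted + dt
        times.append(shifted)
        offset = times[-1][-1]
        total += t.n_frames
        boundaries.append(total)
    prov = [p for t in trajectories for p in t.provenance]
    prov.append({"replicate_boundaries": boundaries[:-1]})
    return Trajectory(
        topology=first.topology,
        frames=frames,
        times_ns=np.concatenate(times),
        provenance=prov,
    )


def build_ledger(system: FilamentSystem) -> SystemLedger:
    """Count atoms into the system-details ledger.

    Mg counts ligand-side; Na/Cl/water live in the solvent pseudo-count.
    The additivity invariant (total = protein+ligands + PBM + water+ions)
    holds by construction and is re-verified by the ledger itself.
    """
    protein = sum(len(r.atoms) for p in system.protomers for r in p.residues)
    ligand = sum(
        len(lig.atoms)
        for p in system.protomers
        for lig in p.ligands
        if lig.kind is not LigandKind.HIC_TAG
    )
    hic = sum(
        len(lig.atoms)
        for p in system.protomers
        for lig in p.ligands
        if lig.kind is LigandKind.HIC_TAG
    )
    protein += hic  # covalently attached tag counts with the protein
    pbm = sum(xl.linker_atom_count for xl in system.crosslinks)
    return SystemLedger(
        total_atoms=protein + ligand + pbm + system.solvent_pseudo_count,
        protein_atoms=protein,
        protein_plus_ligand_atoms=protein + ligand,
        pbm_atoms=pbm,
        water_ion_atoms=system.solvent_pseudo_count,
    )
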