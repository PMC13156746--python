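"""Shared fixtures: synthetic scaffolds and small hand-built systems."""

from __future__ import annotations

import numpy as np
import pytest

from actintools import model_io, synthetic
from actintools.model_io import (
    AtomRecord,
    FilamentSystem,
    Protomer,
    Residue,
    SubdomainScheme,
    Trajectory,
)


@pytest.fixture(scope="session")
def scheme() -> SubdomainScheme:
    return SubdomainScheme()


@pytest.fixture(scope="session")
def scaffold() -> FilamentSystem:
    return synthetic.make_scaffold()


@pytest.fixture(scope="session")
def scaffold_view(scaffold) -> model_io.ProtomerView:
    return model_io.ProtomerView(scaffold, "A")


def build_system(residue_specs, chain_id="A", name="fixture"):
    """Build a FilamentSystem from [(resnum, resname, [(atom, element, xyz), ...])]."""
    residues = []
    serial = 0
    for num, resname, atoms in residue_specs:
        recs = []
        for atom_name, element, xyz in atoms:
            serial += 1
            recs.append(
                AtomRecord(
                    serial=serial, name=atom_name, element=element,
                    residue_number=num, residue_name=resname,
                    chain_id=chain_id, position=np.asarray(xyz, dtype=float),
                )
            )
        residues.append(Residue(number=num, name=resname, atoms=recs))
    return FilamentSystem(
        name=name, protomers=[Protomer(chain_id=chain_id, residues=residues)]
    )


def make_trajectory(system, frames, dt_ns=0.1):
    frames = np.asarray(frames, dtype=float)
    times = (np.arange(frames.shape[0]) + 1) * dt_ns
    return Trajectory(topology=system, frames=frames, times_ns=times)


@pytest.fixture
def two_residue_pdb(tmp_path):
    """A minimal two-residue single-chain PDB file."""
    text = (
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00"
        "           N\n"
        "ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00"
        "           C\n"
        "ATOM      3  C   ALA A   1       2.010   1.420   0.000  1.00  0.00"
        "           C\n"
        "ATOM      4  N   GLY A   2       3.320   1.540   0.000  1.00  0.00"
        "           N\n"
        "ATOM      5  CA  GLY A   2       4.020   2.830   0.000  1.00  0.00"
        "           C\n"
        "ATOM      6  HA  GLY A   2       4.100   3.300   0.900  1.00  0.00"
        "           H\n"
        "TER       7\n"
        "END\n"
    )
    path = tmp_path / "two_res.pdb"
    path.write_text(text)
    return path


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
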