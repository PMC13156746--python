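"""Declarative comparison pipeline: crosslinked (PBM) vs control systems.

A run config names at least one PBM and one control system, each with a
topology PDB, one or more multi-model-PDB replicate trajectories and an
analysis chain.  The pipeline executes, per system: D-loop/tilt geometry
series → ensemble statistics (RMSF) → cleft volume series → GROMOS
clustering + PCA + free-energy landscape → dynamic network; then
differences every PBM system against its control counterpart (ΔRMSF,
cluster-RMSD Δ maps, unique network edges, a path table from C374 to the
standard target list).  All outputs are CSV/JSON with fixed 6-significant-
digit formatting so identical config + seed reproduces byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from actintools import cleft as cleft_mod
from actintools import conformations, ensemble, geometry, network
from actintools.model_io import (
    ProtomerView,
    SubdomainScheme,
    SystemLedger,
    Trajectory,
    concatenate_replicates,
    read_structure,
    read_trajectory,
)

logger = logging.getLogger("actintools")

__all__ = [
    "SystemConfig",
    "RunConfig",
    "ComparisonReport",
    "run_comparison",
    "path_table",
    "ledger_check",
    "DEFAULT_PATH_TARGETS",
]

# standard suboptimal-path target list: C-terminus-to-cleft connectors,
# nucleotide-dynamics residues, phosphate-release gate, N terminus and
# the SD1/SD2 interface
DEFAULT_PATH_TARGETS: tuple[int, ...] = (7, 14, 73, 88, 107, 111, 137, 161, 177, 305)
DEFAULT_PATH_SOURCE = 374


@dataclass
class SystemConfig:
    name: str
    role: str  # "PBM" | "control"
    topology: str
    trajectories: list[str]
    chain: str | None = None  # analysis chain; defaults to the first chain

    def __post_init__(self) -> None:
        if self.role not in ("PBM", "control"):
            raise ValueError(f"system {self.name}: role must be PBM or control")


@dataclass
class RunConfig:
    systems: list[SystemConfig]
    output_dir: str = "actintools_out"
    seed: int = 0
    frame_interval_ns: float = 0.1
    cleft_cutoff_A: float = 8.0
    distance_cutoff_A: float = 10.0
    cluster_cutoff_A: float = 1.5
    cluster_max_frames: int = 200
    fel_bins: int = 24
    temperature_K: float = 310.0
    network_params: network.NetworkParams = field(
        default_factory=network.NetworkParams
    )
    scheme: SubdomainScheme = field(default_factory=SubdomainScheme)

    def __post_init__(self) -> None:
        roles = {s.role for s in self.systems}
        if not {"PBM", "control"} <= roles:
            raise ValueError(
                "comparison mode needs at least one PBM and one control system"
            )
        for s in self.systems:
            for p in [s.topology, *s.trajectories]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"system {s.name}: missing {p}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        systems = [SystemConfig(**s) for s in raw.pop("systems")]
        params = raw.pop("network_params", None)
        kwargs = dict(raw)
        if params:
            kwargs["network_params"] = network.NetworkParams(**params)
        return cls(systems=systems, **kwargs)


@dataclass
class ComparisonReport:
    per_system: dict[str, dict]
    deltas: dict[str, dict]
    paths: pd.DataFrame | None
    provenance: dict


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.map(lambda v: float(f"{v:.6g}") if isinstance(v, float) else v)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    _fmt(df).to_csv(path, index=False, float_format="%.6g")


def _analyze_system(
    sys_cfg: SystemConfig, cfg: RunConfig, out: Path
) -> dict:
    logger.info("system %s: loading", sys_cfg.name)
    topology = read_structure(sys_cfg.topology)
    reps = [
        read_trajectory(p, topology, cfg.frame_interval_ns)
        for p in sys_cfg.trajectories
    ]
    traj = concatenate_replicates(reps)
    chain = sys_cfg.chain or topology.protomers[0].chain_id
    view = ProtomerView(topology, chain)

    logger.info("system %s: geometry", sys_cfg.name)
    geo = geometry.dloop_timeseries(traj, view, cfg.scheme)
    _write_csv(geo, out / f"{sys_cfg.name}_geometry.csv")

    logger.info("system %s: ensemble statistics", sys_cfg.name)
    rmsf_map = ensemble.rmsf(traj, view)
    ca = view.ca_array()
    rg = ensemble.radius_of_gyration(traj, ca)
    rmsd0 = ensemble.rmsd_series(traj, traj.frames[0], ca)

    logger.info("system %s: cleft", sys_cfg.name)
    try:
        cleft_df = cleft_mod.cleft_series(
            traj, view, cfg.scheme, cfg.cleft_cutoff_A
        )
        _write_csv(cleft_df, out / f"{sys_cfg.name}_cleft.csv")
    except ValueError:
        cleft_df = None  # topology without cleft ligands

    logger.info("system %s: clustering / PCA / FEL", sys_cfg.name)
    stride = max(1, traj.n_frames // cfg.cluster_max_frames)
    sub = traj.frames[::stride]
    clusters = conformations.gromos_cluster(sub, ca, cfg.cluster_cutoff_A)
    pca_res = conformations.pca(traj, ca)
    fel = conformations.free_energy_landscape(
        pca_res.projections[:, 0],
        pca_res.projections[:, 1],
        bins=cfg.fel_bins,
        temperature_K=cfg.temperature_K,
    )

    logger.info("system %s: network", sys_cfg.name)
    corr = network.dccm(traj, ca)
    contacts = network.contact_map(traj, view, cfg.network_params)
    keys = [(chain, n) for n in view.residue_numbers]
    net = network.build_network(corr, contacts, keys, cfg.network_params)
    betweenness = network.edge_betweenness(net)

    edge_rows = [
        {
            "i_chain": u[0], "i_res": u[1], "j_chain": v[0], "j_res": v[1],
            "correlation": net.graph[u][v]["correlation"],
            "weight": net.graph[u][v]["weight"],
            "betweenness": betweenness[tuple(sorted((u, v)))],
        }
        for u, v in net.graph.edges
    ]
    if edge_rows:
        _write_csv(pd.DataFrame(edge_rows), out / f"{sys_cfg.name}_edges.csv")

    return {
        "topology": topology,
        "trajectory": traj,
        "view": view,
        "chain": chain,
        "geometry": geo,
        "rmsf": rmsf_map,
        "rg": rg,
        "rmsd": rmsd0,
        "cleft": cleft_df,
        "clusters": clusters,
        "cluster_stride": stride,
        "pca": pca_res,
        "fel": fel,
        "network": net,
        "betweenness": betweenness,
    }


def run_comparison(config: RunConfig) -> ComparisonReport:
    """Execute the full PBM-vs-control comparison defined by a config."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    per_system: dict[str, dict] = {}
    for sys_cfg in config.systems:
        try:
            per_system[sys_cfg.name] = _analyze_system(sys_cfg, config, out)
        except Exception as exc:
            raise RuntimeError(f"system {sys_cfg.name}: {exc}") from exc

    controls = [s for s in config.systems if s.role == "control"]
    pbms = [s for s in config.systems if s.role == "PBM"]
    deltas: dict[str, dict] = {}
    paths_frames: list[pd.DataFrame] = []
    for pbm in pbms:
        ctrl = controls[min(len(deltas), len(controls) - 1)]
        a, b = per_system[ctrl.name], per_system[pbm.name]
        key = f"{ctrl.name}_vs_{pbm.name}"
        d_rmsf = ensemble.delta_rmsf(a["rmsf"], b["rmsf"])
        diff = network.network_difference(a["network"], b["network"]) if set(
            a["network"].nodes
        ) == set(b["network"].nodes) else None
        deltas[key] = {"delta_rmsf": d_rmsf, "network_difference": diff}
        rows = [
            {"chain": k[0], "residue": k[1], "delta_rmsf_A": v}
            for k, v in d_rmsf.values.items()
        ]
        _write_csv(pd.DataFrame(rows), out / f"{key}_delta_rmsf.csv")

        for name in (ctrl.name, pbm.name):
            tbl = path_table(per_system[name]["network"], per_system[name]["chain"])
            tbl.insert(0, "system", name)
            paths_frames.append(tbl)

    paths = pd.concat(paths_frames, ignore_index=True) if paths_frames else None
    if paths is not None:
        _write_csv(paths, out / "path_table.csv")

    provenance = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "systems": [
                        (s.name, s.role, s.topology, tuple(s.trajectories))
                        for s in config.systems
                    ],
                    "seed": config.seed,
                },
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest(),
        "parameters": {
            "cleft_cutoff_A": config.cleft_cutoff_A,
            "distance_cutoff_A": config.distance_cutoff_A,
            "cluster_cutoff_A": config.cluster_cutoff_A,
            "fel_bins": config.fel_bins,
            "temperature_K": config.temperature_K,
            "contact_cutoff_A": config.network_params.contact_cutoff_A,
            "occupancy_min": config.network_params.occupancy_min,
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return ComparisonReport(
        per_system=per_system, deltas=deltas, paths=paths, provenance=provenance
    )


def path_table(
    net: network.DynamicNetwork,
    chain: str,
    source_residue: int = DEFAULT_PATH_SOURCE,
    targets: tuple[int, ...] = DEFAULT_PATH_TARGETS,
) -> pd.DataFrame:
    """Shortest-path table from a source residue to the target list.

    Intermediates are listed in order starting from the source;
    disconnected pairs render as "N/A".  When the source residue is not
    a node (e.g. a terminal residue dropped from the contact graph) the
    nearest smaller-numbered node is used, mirroring the fallback from
    F375 to C374 when terminal connectivity is lost.
    """
    nodes = set(net.nodes)
    src = (chain, source_residue)
    while src not in nodes and src[1] > 1:
        src = (chain, src[1] - 1)
    rows = []
    for t in targets:
        tgt = (chain, t)
        if tgt not in nodes:
            rows.append(
                {"source": src[1], "target": t, "intermediates": "N/A",
                 "n_intermediates": -1, "total_weight": float("nan")}
            )
            continue
        result = network.suboptimal_paths(net, src, tgt)[0]
        if not result.exists:
            rows.append(
                {"source": src[1], "target": t, "intermediates": "N/A",
                 "n_intermediates": -1, "total_weight": float("nan")}
            )
        else:
            rows.append(
                {
                    "source": src[1],
                    "target": t,
                    "intermediates": "-".join(
                        str(r) for _, r in result.intermediates
                    ),
                    "n_intermediates": result.intermediate_count,
                    "total_weight": result.total_weight,
                }
            )
    return pd.DataFrame(rows)


def ledger_check(rows: list[dict]) -> pd.DataFrame:
    """Verify system-details additivity (total = protein+ligands + PBM +
    water+ions) for a list of component-count rows.

    Each row: name, protein_plus_ligand_atoms, pbm_atoms,
    water_ion_atoms, and optionally expected_total / protein_atoms.
    """
    out = []
    for row in rows:
        ledger = SystemLedger.from_components(
            protein_plus_ligand_atoms=row["protein_plus_ligand_atoms"],
            pbm_atoms=row.get("pbm_atoms", 0),
            water_ion_atoms=row["water_ion_atoms"],
            protein_atoms=row.get("protein_atoms"),
        )
        expected = row.get("expected_total")
        ok = expected is None or expected == ledger.total_atoms
        out.append(
            {
                "name": row.get("name", ""),
                "total_atoms": ledger.total_atoms,
                "protein_atoms": ledger.protein_atoms,
                "protein_plus_ligand_atoms": ledger.protein_plus_ligand_atoms,
                "pbm_atoms": ledger.pbm_atoms,
                "water_ion_atoms": ledger.water_ion_atoms,
                "expected_total": expected,
                "additivity_ok": ok,
                "delta": 0 if expected is None else ledger.total_atoms - expected,
            }
        )
    return pd.DataFrame(out)
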