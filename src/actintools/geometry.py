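"""Protomer axis-frame geometry and D-loop descriptors.

A per-frame orthonormal frame is anchored on the subdomain centroids:
the X-axis connects the SD1 and SD3 centroids, the Z-axis is the
component of the SD2 direction orthogonal to X (Gram–Schmidt), and
Y = Z × X completes a right-handed frame.  The origin is the midpoint of
the SD1/SD3 centroids.  D-loop position is reported as a signed
"in-plane" angle (within the XZ face of the protomer, positive toward
+X, i.e. the SD3 side) and a signed "out-of-plane" elevation (positive
toward +Y), plus the loop width — the distance between the centroids of
residues 38–39 and 51–52.  Domain tilt compares the SD1→SD2 and SD3→SD4
directions relative to Z.

Centroids are unweighted means of alpha-carbon positions; because the
frame is rebuilt per frame, every descriptor is invariant under rigid
motion of the whole structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from actintools.model_io import ProtomerView, SubdomainScheme, Trajectory

__all__ = [
    "AxisFrame",
    "DLoopDescriptor",
    "DescriptorSeries",
    "DegenerateFrameError",
    "subdomain_centroids",
    "build_axis_frame",
    "dloop_descriptor",
    "domain_tilt",
    "descriptor_timeseries",
    "dloop_timeseries",
]


class DegenerateFrameError(ValueError):
    """SD centroids do not define a usable frame (collinear SD2)."""


@dataclass
class AxisFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.x_axis, self.y_axis, self.z_axis):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("axes must be unit vectors")
        for a, b in ((self.x_axis, self.y_axis), (self.x_axis, self.z_axis),
                     (self.y_axis, self.z_axis)):
            if abs(float(np.dot(a, b))) > 1e-9:
                raise ValueError("axes must be mutually orthogonal")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express points in frame coordinates (x, y, z columns)."""
        rel = np.atleast_2d(points) - self.origin
        return np.stack(
            [rel @ self.x_axis, rel @ self.y_axis, rel @ self.z_axis], axis=-1
        )


@dataclass
class DLoopDescriptor:
    centroid: np.ndarray
    relative_coords: np.ndarray  # per-residue, relative to the centroid
    width_A: float
    in_plane_deg: float
    out_of_plane_deg: float


@dataclass
class DescriptorSeries:
    """A time-ordered scalar descriptor with summary statistics."""

    values: np.ndarray
    times_ns: np.ndarray
    label: str = ""
    mean: float = field(init=False)
    quartiles: tuple[float, float, float] = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(np.mean(self.values))
        q1, med, q3 = np.percentile(self.values, [25, 50, 75])
        self.quartiles = (float(q1), float(med), float(q3))


def _ca_map(
    coords: np.ndarray, view: ProtomerView, residues: list[int]
) -> np.ndarray:
    idx = view.ca_array(residues)
    return coords[idx]


def subdomain_centroids(
    coords: np.ndarray, view: ProtomerView, scheme: SubdomainScheme
) -> dict[str, np.ndarray]:
    """Unweighted mean alpha-carbon position of each subdomain's residues.

    Residues listed in the scheme but absent from the chain are an
    error only if they have no alpha-carbon; chains shorter than the
    scheme simply use the residues present.
    """
    out: dict[str, np.ndarray] = {}
    present = set(view.residue_numbers)
    for sd in scheme.sd_ranges:
        members = [r for r in scheme.residues_of(sd) if r in present]
        if not members:
            raise ValueError(f"{sd}: no residues present in chain {view.chain_id}")
        missing = [r for r in members if r not in view.ca_indices]
        if missing:
            raise ValueError(f"{sd}: residues missing alpha-carbon: {missing}")
        out[sd] = _ca_map(coords, view, members).mean(axis=0)
    return out


def build_axis_frame(centroids: Mapping[str, np.ndarray]) -> AxisFrame:
    """Construct the protomer frame from subdomain centroids.

    x = unit(SD3c − SD1c); z = unit component of (SD2c − origin)
    orthogonal to x; y = z × x; origin = midpoint of SD1c/SD3c.
    """
    sd1, sd2, sd3 = (np.asarray(centroids[k], dtype=float)
                     for k in ("SD1", "SD2", "SD3"))
    dx = sd3 - sd1
    nx = np.linalg.norm(dx)
    if nx < 1e-9:
        raise DegenerateFrameError("SD1 and SD3 centroids coincide")
    x = dx / nx
    origin = 0.5 * (sd1 + sd3)
    v2 = sd2 - origin
    z_raw = v2 - (v2 @ x) * x
    nz = np.linalg.norm(z_raw)
    if nz < 1e-9:
        raise DegenerateFrameError("SD2 centroid collinear with the SD1-SD3 line")
    z = z_raw / nz
    y = np.cross(z, x)
    return AxisFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def dloop_descriptor(
    coords: np.ndarray,
    view: ProtomerView,
    scheme: SubdomainScheme,
    axis_frame: AxisFrame,
) -> DLoopDescriptor:
    """D-loop centroid position in the protomer frame plus loop width.

    Width is the distance between the centroid of the first two D-loop
    residues (38–39) and the last two (51–52).  The in-plane angle is
    the signed angle, within the XZ plane, between Z and the XZ
    projection of (centroid − origin); out-of-plane is the elevation
    toward +Y.
    """
    dres = scheme.dloop_residues()
    ca = _ca_map(coords, view, dres)
    centroid = ca.mean(axis=0)
    rel = ca - centroid

    head = _ca_map(coords, view, dres[:2]).mean(axis=0)
    tail = _ca_map(coords, view, dres[-2:]).mean(axis=0)
    width = float(np.linalg.norm(head - tail))

    v = centroid - axis_frame.origin
    vx = float(v @ axis_frame.x_axis)
    vy = float(v @ axis_frame.y_axis)
    vz = float(v @ axis_frame.z_axis)
    in_plane = float(np.degrees(np.arctan2(vx, vz)))
    norm = np.linalg.norm(v)
    out_of_plane = float(np.degrees(np.arcsin(vy / norm))) if norm > 0 else 0.0
    return DLoopDescriptor(
        centroid=centroid,
        relative_coords=rel,
        width_A=width,
        in_plane_deg=in_plane,
        out_of_plane_deg=out_of_plane,
    )


def domain_tilt(
    coords: np.ndarray,
    view: ProtomerView,
    scheme: SubdomainScheme,
    axis_frame: AxisFrame,
    centroids: Mapping[str, np.ndarray] | None = None,
) -> float:
    """Signed difference of the SD1→SD2 and SD3→SD4 tilts relative to Z.

    Each tilt is the (unsigned) angle between the inter-centroid vector
    and the Z-axis; the returned value is tilt(SD1→SD2) − tilt(SD3→SD4)
    in degrees.
    """
    if centroids is None:
        centroids = subdomain_centroids(coords, view, scheme)
    z = axis_frame.z_axis

    def angle_to_z(v: np.ndarray) -> float:
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise ValueError("zero-length inter-centroid vector")
        return float(np.degrees(np.arccos(np.clip((v @ z) / n, -1.0, 1.0))))

    a12 = angle_to_z(centroids["SD2"] - centroids["SD1"])
    a34 = angle_to_z(centroids["SD4"] - centroids["SD3"])
    return a12 - a34


def descriptor_timeseries(
    traj: Trajectory,
    view: ProtomerView,
    scheme: SubdomainScheme,
    descriptor: Callable[[np.ndarray, ProtomerView, SubdomainScheme, AxisFrame], float],
    label: str = "",
) -> DescriptorSeries:
    """Evaluate a scalar descriptor per frame, recomputing the axis frame
    frame-wise, and attach summary statistics."""
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        coords = traj.frames[i]
        try:
            frame = build_axis_frame(subdomain_centroids(coords, view, scheme))
            values[i] = descriptor(coords, view, scheme, frame)
        except Exception as exc:
            raise RuntimeError(f"frame {i}: {exc}") from exc
    return DescriptorSeries(values=values, times_ns=traj.times_ns, label=label)


def dloop_timeseries(
    traj: Trajectory, view: ProtomerView, scheme: SubdomainScheme
) -> pd.DataFrame:
    """Per-frame D-loop width, in/out-of-plane angles and domain tilt.

    Columns: frame, time_ns, width_A, in_plane_deg, out_of_plane_deg,
    tilt_deg.  Sign convention: in-plane positive toward +X (SD3 side),
    out-of-plane positive toward +Y.
    """
    rows = []
    for i in range(traj.n_frames):
        coords = traj.frames[i]
        cents = subdomain_centroids(coords, view, scheme)
        frame = build_axis_frame(cents)
        d = dloop_descriptor(coords, view, scheme, frame)
        tilt = domain_tilt(coords, view, scheme, frame, centroids=cents)
        rows.append(
            {
                "frame": i,
                "time_ns": float(traj.times_ns[i]),
                "width_A": d.width_A,
                "in_plane_deg": d.in_plane_deg,
                "out_of_plane_deg": d.out_of_plane_deg,
                "tilt_deg": tilt,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["sign_convention"] = (
        "in_plane positive toward +X (SD3 side); out_of_plane positive toward +Y"
    )
    return df
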