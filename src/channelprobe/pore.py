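"""Pore-radius profiling, gate hydration counting, and dehydration flags.

The profiler is a deterministic, HOLE-style construction: at each position
along the pore axis the accessible radius is the largest sphere centred in
that plane that touches no atom's van der Waals surface.  In ``on-axis``
mode the sphere centre is fixed on the axis; ``in-plane-search`` mode
additionally optimizes the centre within the plane (coarse 0.5 A grid, then
Nelder-Mead refinement), which can only increase the radius.

Gate hydration follows the cylinder construction used for hydrophobic-gate
dewetting analyses: water oxygens inside a 4 A-radius cylinder whose axial
band is bounded, per frame, by the mean z of the five 9' C-beta atoms and
the mean z of the five 16' C-beta atoms.  Fewer than ``threshold`` (default
5) waters classifies the frame as dehydrated (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .constants import VDW_DEFAULT, VDW_RADII
from .model_io import Frame, SiteDefinition, Topology, Trajectory, resolve_selection


@dataclass
class PoreProfile:
    """Accessible pore radius along the channel axis."""

    z: np.ndarray            # axial coordinate grid, A (relative to origin)
    radius: np.ndarray       # accessible radius, A
    origin: np.ndarray       # axis origin point
    axis: np.ndarray         # unit axis vector
    mode: str = "on-axis"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if np.any(self.radius < 0):
            raise ValueError("radii must be non-negative")


@dataclass
class HydrationSeries:
    """Gate water count and dehydration flag per frame."""

    times: np.ndarray
    n_waters: np.ndarray
    threshold: int = 5

    @property
    def dehydrated(self) -> np.ndarray:
        return self.n_waters < self.threshold


def pore_axis(
    topology: Topology,
    frame: Frame,
    m2_site: SiteDefinition | None = None,
    fallback_z: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit channel axis through the pore-lining helices.

    For every member residue of the pore-lining (M2) site, the centroid of
    that residue's atoms over all subunits lies on the symmetry axis; the
    axis is the total-least-squares line through those ring centroids,
    oriented toward +z (extracellular side at high z by convention).  With
    ``fallback_z`` the axis is simply z through the protein centroid.
    """
    subunits = topology.subunits
    if len(subunits) < 3:
        raise ValueError("pore axis requires at least 3 subunits")
    if fallback_z:
        prot = topology.role_indices("protein")
        origin = frame.coordinates[prot].mean(axis=0)
        return origin, np.array([0.0, 0.0, 1.0])
    if m2_site is None:
        from .model_io import default_sites

        m2_site = default_sites()["M2"]
    centroids = []
    for resseq, atom_name in m2_site.members:
        pts = []
        for s in subunits:
            idx = resolve_selection(
                topology, SiteDefinition("ax", [(resseq, atom_name)]), s
            )
            pts.append(frame.coordinates[idx].mean(axis=0))
        centroids.append(np.mean(pts, axis=0))
    pts = np.asarray(centroids)
    origin = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - origin)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    return origin, axis / np.linalg.norm(axis)


def _atom_vdw(topology: Topology, indices: np.ndarray, vdw: dict | None) -> np.ndarray:
    table = dict(VDW_RADII)
    if vdw:
        table.update(vdw)
    return np.asarray(
        [table.get(topology.atoms[int(i)].element, VDW_DEFAULT) for i in indices]
    )


def pore_radius_profile(
    topology: Topology,
    frame: Frame,
    z_range: tuple[float, float],
    z_step: float = 0.5,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
    probe_optimization: str = "on-axis",
    vdw: dict | None = None,
    search_radius: float = 5.0,
) -> PoreProfile:
    """Accessible pore radius on a z grid along the axis.

    At each z the radius is ``min_i(|c - x_i| - r_vdw,i)`` over protein
    atoms, clamped at 0; ``in-plane-search`` maximizes over centre points c
    within ``search_radius`` of the axis (0.5 A coarse grid, Nelder-Mead
    refinement), which dominates the on-axis value by construction.
    """
    if z_range[0] >= z_range[1]:
        raise ValueError("empty z range")
    if probe_optimization not in ("on-axis", "in-plane-search"):
        raise ValueError(f"unknown probe_optimization {probe_optimization!r}")
    if axis is None:
        axis = pore_axis(topology, frame)
    origin, u = np.asarray(axis[0], dtype=float), np.asarray(axis[1], dtype=float)
    u = u / np.linalg.norm(u)
    prot = topology.heavy_indices("protein")
    if prot.size == 0:
        raise ValueError("no protein atoms")
    coords = frame.coordinates[prot]
    radii = _atom_vdw(topology, prot, vdw)

    # orthonormal in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)

    def accessible(center: np.ndarray) -> float:
        d = np.linalg.norm(coords - center, axis=1) - radii
        return float(d.min())

    zs = np.arange(z_range[0], z_range[1] + 1e-9, z_step)
    out = np.empty_like(zs)
    for k, z in enumerate(zs):
        c0 = origin + z * u
        best = accessible(c0)
        if probe_optimization == "in-plane-search":
            for a in np.arange(-search_radius, search_radius + 1e-9, 0.5):
                for b in np.arange(-search_radius, search_radius + 1e-9, 0.5):
                    if a * a + b * b > search_radius**2 or (a == 0 and b == 0):
                        continue
                    val = accessible(c0 + a * e1 + b * e2)
                    if val > best:
                        best = val
                        c_best = (a, b)
            # local refinement from the best coarse point
            start = np.asarray(c_best) if best > accessible(c0) else np.zeros(2)

            def neg(ab):
                if ab[0] ** 2 + ab[1] ** 2 > search_radius**2:
                    return 1e6
                return -accessible(c0 + ab[0] * e1 + ab[1] * e2)

            res = minimize(neg, start, method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-6})
            best = max(best, -res.fun)
        out[k] = max(best, 0.0)
    return PoreProfile(zs, out, origin, u, probe_optimization)


def _gate_band_and_axis(
    topology: Topology,
    frame: Frame,
    gate: SiteDefinition,
    axis: tuple[np.ndarray, np.ndarray] | None,
):
    """Axial band between the 9' and 16' C-beta ring means, plus the axis."""
    resids = sorted({r for r, _ in gate.members})
    if len(resids) != 2:
        raise ValueError("gate site must name exactly two marker residues")
    ring_coords = {}
    for resseq in resids:
        atom_name = next(a for r, a in gate.members if r == resseq)
        pts = []
        for s in topology.subunits:
            try:
                idx = resolve_selection(
                    topology, SiteDefinition("g", [(resseq, atom_name)]), s
                )
            except KeyError as exc:
                raise KeyError(
                    f"gate marker residue {resseq} ({atom_name}) missing in subunit {s}"
                ) from exc
            pts.append(frame.coordinates[idx].mean(axis=0))
        ring_coords[resseq] = np.asarray(pts)
    if axis is None:
        all_pts = np.vstack(list(ring_coords.values()))
        origin = all_pts.mean(axis=0)
        u = np.array([0.0, 0.0, 1.0])
    else:
        origin, u = np.asarray(axis[0], dtype=float), np.asarray(axis[1], dtype=float)
        u = u / np.linalg.norm(u)
    t_vals = [float(((ring_coords[r] - origin) @ u).mean()) for r in resids]
    return origin, u, min(t_vals), max(t_vals)


def hydration_count(
    topology: Topology,
    frame: Frame,
    gate: SiteDefinition | None = None,
    cylinder_radius: float = 4.0,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
) -> int:
    """Number of water oxygens inside the gate cylinder for one frame.

    The cylinder is re-measured per frame: its axial band runs between the
    mean axial coordinates of the two five-C-beta marker rings, and waters
    count when their radial distance from the axis is <= ``cylinder_radius``.
    """
    if gate is None:
        from .model_io import default_sites

        gate = default_sites()["gate"]
    waters = topology.water_oxygen_indices
    if waters.size == 0:
        raise ValueError("no waters in topology")
    origin, u, t_lo, t_hi = _gate_band_and_axis(topology, frame, gate, axis)
    rel = frame.coordinates[waters] - origin
    t = rel @ u
    radial = np.linalg.norm(rel - np.outer(t, u), axis=1)
    inside = (t >= t_lo) & (t <= t_hi) & (radial <= cylinder_radius)
    return int(inside.sum())


def hydration_series(
    traj: Trajectory,
    gate: SiteDefinition | None = None,
    cylinder_radius: float = 4.0,
    threshold: int = 5,
    stride: float | None = None,
    fixed_axis: tuple[np.ndarray, np.ndarray] | None = None,
) -> HydrationSeries:
    """Per-frame gate water count with the strict ``n < threshold``
    dehydration flag.  The cylinder is re-centred per frame unless a
    ``fixed_axis`` is supplied."""
    idx = traj.stride_indices(stride)
    times, counts = [], []
    for fi in idx:
        frame = traj.frames[fi]
        times.append(frame.time)
        counts.append(
            hydration_count(traj.topology, frame, gate, cylinder_radius, fixed_axis)
        )
    return HydrationSeries(np.asarray(times), np.asarray(counts, dtype=int), threshold)
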