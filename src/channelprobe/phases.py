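"""Ligand phase classification (aqueous / membrane / protein), phase
fractions over time, aqueous molarity, and membrane width.

Classification precedence: *protein* when any ligand atom lies within the
protein cutoff (3.5 A by default, matching the contact criterion) of any
protein heavy atom; otherwise *membrane* when the ligand centre of mass
falls between the mean phosphate planes of the two leaflets; otherwise
*aqueous*.  The membrane/aqueous boundary (mean phosphate z per leaflet,
re-measured per frame) is a package convention recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import AVOGADRO
from .model_io import Frame, Topology, Trajectory, center_of_mass, min_distance

PHASES = ("aqueous", "membrane", "protein")


@dataclass
class PhaseSeries:
    """Per-frame phase labels, counts and fractions for all ligands."""

    times: np.ndarray
    labels: np.ndarray  # (n_ligands, n_frames) of phase strings
    ligand_ids: list[tuple[str, int]]

    def counts(self) -> pd.DataFrame:
        rows = {
            phase: (self.labels == phase).sum(axis=0) for phase in PHASES
        }
        df = pd.DataFrame(rows)
        df.insert(0, "time_ps", self.times)
        return df

    def fractions(self) -> pd.DataFrame:
        df = self.counts()
        n = len(self.ligand_ids)
        for phase in PHASES:
            df[phase] = df[phase] / n
        return df


def _leaflet_z(topology: Topology, frame: Frame) -> tuple[float, float]:
    markers = [
        a.atom_index
        for a in topology.atoms
        if a.role == "lipid" and a.element == "P"
    ]
    if not markers:
        raise ValueError("no phosphate (P) marker atoms in topology")
    z = frame.coordinates[np.asarray(markers), 2]
    mid = z.mean()
    upper = z[z > mid]
    lower = z[z <= mid]
    if len(upper) == 0 or len(lower) == 0 or upper.mean() - lower.mean() < 1.0:
        raise ValueError("phosphate markers do not form two leaflets")
    return float(lower.mean()), float(upper.mean())


def membrane_bounds(topology: Topology, frame: Frame) -> tuple[float, float]:
    """(z_low, z_high) mean phosphate planes of the two leaflets."""
    return _leaflet_z(topology, frame)


def membrane_width(topology: Topology, frame: Frame) -> float:
    """Distance between the mean phosphate planes of the leaflets, A."""
    z_lo, z_hi = _leaflet_z(topology, frame)
    return z_hi - z_lo


def classify_phase(
    topology: Topology,
    frame: Frame,
    ligand_atoms: np.ndarray,
    membrane_bounds_: tuple[float, float] | None = None,
    protein_cutoff: float = 3.5,
    use_box: bool = True,
) -> str:
    """Phase of one ligand in one frame with protein > membrane > aqueous
    precedence."""
    la = np.asarray(ligand_atoms, dtype=int)
    if membrane_bounds_ is None:
        membrane_bounds_ = _leaflet_z(topology, frame)
    z_lo, z_hi = membrane_bounds_
    protein = topology.heavy_indices("protein")
    box = frame.box if use_box else None
    if protein.size and min_distance(
        frame.coordinates[la], frame.coordinates[protein], box
    ) <= protein_cutoff:
        return "protein"
    com = center_of_mass(frame.coordinates[la], topology.masses(la))
    if z_lo < com[2] < z_hi:
        return "membrane"
    return "aqueous"


def phase_fractions(
    traj: Trajectory,
    stride: float | None = None,
    protein_cutoff: float = 3.5,
) -> PhaseSeries:
    """Phase label of every ligand at every sampled frame."""
    topo = traj.topology
    ligand_ids = topo.ligand_ids
    if not ligand_ids:
        raise ValueError("topology has no ligands")
    idx = traj.stride_indices(stride)
    labels = np.empty((len(ligand_ids), len(idx)), dtype=object)
    times = np.empty(len(idx))
    for col, fi in enumerate(idx):
        frame = traj.frames[fi]
        bounds = _leaflet_z(topo, frame)
        times[col] = frame.time
        for li, lig in enumerate(ligand_ids):
            labels[li, col] = classify_phase(
                topo, frame, topo.ligand_atoms(lig), bounds, protein_cutoff
            )
    return PhaseSeries(times, labels, ligand_ids)


def aqueous_concentration(n_ligands_aqueous: int, aqueous_volume_A3: float) -> float:
    """Molar concentration in mM of n molecules in a volume given in A^3."""
    if aqueous_volume_A3 <= 0:
        raise ValueError("aqueous volume must be positive")
    if n_ligands_aqueous < 0:
        raise ValueError("ligand count must be non-negative")
    volume_litres = aqueous_volume_A3 * 1e-27
    molar = n_ligands_aqueous / (AVOGADRO * volume_litres)
    return molar * 1e3


def estimate_aqueous_volume(
    topology: Topology,
    frame: Frame,
    protein_volume_A3: float | None = None,
) -> float:
    """Approximate aqueous volume: box volume minus the membrane slab minus
    the protein's aqueous-phase excluded volume (convex-hull estimate when
    not supplied).  Explicitly approximate; clipped to [0, box volume]."""
    box_vol = float(np.prod(frame.box))
    z_lo, z_hi = _leaflet_z(topology, frame)
    slab = float(frame.box[0] * frame.box[1] * (z_hi - z_lo))
    if protein_volume_A3 is None:
        prot = topology.heavy_indices("protein")
        pts = frame.coordinates[prot]
        outside = pts[(pts[:, 2] < z_lo) | (pts[:, 2] > z_hi)]
        if len(outside) >= 4:
            from scipy.spatial import ConvexHull

            try:
                protein_volume_A3 = float(ConvexHull(outside).volume)
            except Exception:
                protein_volume_A3 = 0.0
        else:
            protein_volume_A3 = 0.0
    return float(np.clip(box_vol - slab - protein_volume_A3, 0.0, box_vol))
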