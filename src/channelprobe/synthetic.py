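"""Toy pentameric channel systems with scripted, known ground truth.

The generator builds a C5-symmetric arrangement of pseudo-helical subunits
around the z axis: a vertical pore-lining (M2) rod of pseudo-residues per
subunit, C-beta gate markers at the 9'/16' z positions, the 13-residue
intrasubunit (TM1) binding region plus the TM2 hydroxyl/amide partner atoms,
phosphate markers bounding a membrane slab, gate waters packed at a 2.8 A
exclusion, and ligand particles.  Trajectories are *scripted*, not simulated:
binding/unbinding intervals, per-subunit tilt programs, gate hydration
programs and ligand phase labels are imposed exactly, so every analysis
operation has an analytic oracle.  A Metropolis sampler over analytic 1-D
potentials provides umbrella-window samples for validating the WHAM stage.

Pseudo-atoms share a single carbon-like van der Waals radius (1.7 A) so the
pore-radius oracle is an analytic cylinder.  None of this is a physical model
of the real channel; it is a fixture generator with exact bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import BOLTZMANN_KCAL, M2_RESIDUE_RANGE, TM1_RESIDUES
from .model_io import (
    AtomRecord,
    Frame,
    SiteDefinition,
    Topology,
    Trajectory,
    default_sites,
    resolve_selection,
)

_RESNAMES = {
    119: "TYR", 120: "PRO", 121: "PHE", 197: "TYR", 201: "ILE", 202: "ILE",
    205: "MET", 206: "LYS", 222: "GLU", 233: "ILE", 240: "ILE", 242: "VAL",
    254: "TYR", 255: "THR", 258: "ILE", 307: "ASN",
}

#: shared pseudo-atom van der Waals radius (carbon-like), Angstrom
PSEUDO_VDW = 1.7

WATER_EXCLUSION = 2.8  # minimum water-water spacing in the gate, Angstrom


@dataclass
class ToyChannelSpec:
    """Geometry of the toy channel.

    ``pore_radius`` is the ring radius of the pore-lining pseudo-atoms, so the
    accessible pore radius is ``pore_radius - 1.7`` (the pseudo-atom vdW
    radius).  ``membrane_half_width`` of 18.655 A reproduces the 37.31 A
    converged membrane width used as a fixture target.
    """

    n_subunits: int = 5
    pore_radius: float = 5.0
    gate_z_range: tuple[float, float] = (-5.0, 5.0)
    membrane_half_width: float = 18.655
    n_waters_in_gate: int = 8
    n_bulk_waters: int = 20
    n_ligands: int = 5
    box: tuple[float, float, float] = (116.0, 115.0, 130.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subunits < 3:
            raise ValueError("need at least 3 subunits")
        if self.pore_radius <= 0:
            raise ValueError("pore_radius must be positive")
        if self.gate_z_range[0] >= self.gate_z_range[1]:
            raise ValueError("gate_z_range must be ordered (z_low, z_high)")


@dataclass(frozen=True)
class ScriptedBinding:
    """One scripted occupancy interval of one ligand at one site."""

    ligand: int
    site_name: str
    subunit_id: str
    t_start: float
    t_end: float


@dataclass
class EventScript:
    """Ground-truth binding script plus inter-event phase labels."""

    events: list[ScriptedBinding] = field(default_factory=list)
    unbound_phase: dict[int, str] = field(default_factory=dict)

    def phase_for(self, ligand: int) -> str:
        return self.unbound_phase.get(ligand, "aqueous")

    def validate(self, n_ligands: int, duration: float) -> None:
        per: dict[int, list[tuple[float, float]]] = {}
        for ev in self.events:
            if not 0 <= ev.ligand < n_ligands:
                raise ValueError(f"script references ligand {ev.ligand}, have {n_ligands}")
            if ev.t_end <= ev.t_start:
                raise ValueError("event interval must have t_end > t_start")
            if ev.t_start < 0 or ev.t_end > duration + 1e-9:
                raise ValueError("event interval outside trajectory span")
            per.setdefault(ev.ligand, []).append((ev.t_start, ev.t_end))
        for lig, ivals in per.items():
            ivals.sort()
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping events for ligand {lig}")


@dataclass
class AnalyticPotential:
    """Analytic 1-D potential U(z) in kcal/mol used as a WHAM oracle."""

    kind: str  # flat | harmonic | double_well
    stiffness: float = 1.0       # harmonic: U = 0.5 * stiffness * (z - center)^2
    center: float = 0.0
    barrier: float = 3.0         # double_well: barrier height at the center
    separation: float = 10.0     # double_well: distance between the two minima

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "harmonic", "double_well"):
            raise ValueError(f"unknown potential kind {self.kind!r}")
        if self.kind == "double_well" and self.barrier <= 0:
            raise ValueError("double-well barrier must be positive")

    def energy(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "flat":
            return np.zeros_like(z)
        if self.kind == "harmonic":
            return 0.5 * self.stiffness * (z - self.center) ** 2
        a = self.separation / 2.0
        return self.barrier * ((z - self.center) ** 2 - a**2) ** 2 / a**4


# ---------------------------------------------------------------------------
# channel construction
# ---------------------------------------------------------------------------

def _ring_xy(radius: float, angle: float) -> tuple[float, float]:
    return radius * math.cos(angle), radius * math.sin(angle)


def gate_packing_positions(
    z_low: float, z_high: float, ring_radius: float
) -> np.ndarray:
    """Deterministic water-oxygen positions inside the gate cylinder at the
    2.8 A exclusion.  ``ring_radius`` is the radial placement radius."""
    levels = np.arange(z_low + 1.0, z_high - 1.0 + 1e-9, WATER_EXCLUSION)
    pos: list[list[float]] = []
    for li, z in enumerate(levels):
        if ring_radius < WATER_EXCLUSION / 2:
            pos.append([0.0, 0.0, float(z)])
            continue
        k = int(math.pi / math.asin(min(1.0, (WATER_EXCLUSION / 2) / ring_radius)))
        k = max(k, 1)
        offset = (li % 2) * math.pi / k  # stagger alternate levels
        for j in range(k):
            x, y = _ring_xy(ring_radius, offset + 2 * math.pi * j / k)
            pos.append([x, y, float(z)])
    return np.asarray(pos)


def _water_ring_radius(pore_radius: float) -> float:
    return min(2.5, pore_radius - 2.5)


def build_toy_channel(spec: ToyChannelSpec) -> tuple[Topology, Frame]:
    """Construct the C_n-symmetric toy channel; returns (topology, frame).

    Raises if the requested gate waters exceed the cylinder's packing
    capacity at the 2.8 A exclusion.
    """
    atoms: list[AtomRecord] = []
    coords: list[Sequence[float]] = []
    z_low, z_high = spec.gate_z_range
    R = spec.pore_radius

    def add(name, element, resseq, resname, chain, role, xyz):
        atoms.append(AtomRecord(len(atoms), name, element, resseq, resname, chain, role))
        coords.append(xyz)

    m2_lo, m2_hi = M2_RESIDUE_RANGE
    m2_resids = list(range(m2_lo, m2_hi + 1))
    m2_z = np.linspace(z_low - 6.0, z_high + 6.0, len(m2_resids))
    tm1_extra = [r for r in TM1_RESIDUES if not m2_lo <= r <= m2_hi]

    for s in range(spec.n_subunits):
        chain = chr(ord("A") + s)
        phi = 2 * math.pi * s / spec.n_subunits
        # pore-lining M2 pseudo-helix: vertical rod of CA pseudo-atoms
        for resid, z in zip(m2_resids, m2_z):
            x, y = _ring_xy(R, phi)
            add("CA", "C", resid, _RESNAMES.get(resid, "ALA"), chain, "protein", (x, y, z))
        # gate C-beta markers at the 9'/16' z positions
        for resid, z in ((233, z_low), (240, z_high)):
            x, y = _ring_xy(R + 1.0, phi)
            add("CB", "C", resid, _RESNAMES[resid], chain, "protein", (x, y, z))
        # TM1 binding-region pseudo-residues on an outer shell
        z_spread = np.linspace(z_low - 4.0, z_high + 4.0, len(tm1_extra))
        ang_spread = np.linspace(-0.45, 0.45, len(tm1_extra))
        for resid, z, da in zip(tm1_extra, z_spread, ang_spread):
            x, y = _ring_xy(R + 7.0, phi + da)
            add("CA", "C", resid, _RESNAMES.get(resid, "ALA"), chain, "protein", (x, y, z))
        # TM2 partner atoms: Tyr-254 hydroxyl oxygen, Asn-307 amide nitrogen
        x, y = _ring_xy(R + 6.0, phi + 0.3)
        add("OH", "O", 254, "TYR", chain, "protein", (x, y, 2.0))
        x, y = _ring_xy(R + 6.0, phi - 0.3)
        add("ND2", "N", 307, "ASN", chain, "protein", (x, y, -2.0))

    # membrane: one phosphorus marker per pseudo-lipid, both leaflets
    lip_resid = 1
    grid = np.arange(-44.0, 44.1, 9.0)
    for zsign in (+1.0, -1.0):
        for gx in grid:
            for gy in grid:
                if math.hypot(gx, gy) < R + 19.0:
                    continue
                add("P", "P", lip_resid, "POPC", "M", "lipid",
                    (gx, gy, zsign * spec.membrane_half_width))
                lip_resid += 1

    # gate waters (packed) + bulk reservoir waters
    pack = gate_packing_positions(z_low, z_high, _water_ring_radius(R))
    if spec.n_waters_in_gate > len(pack):
        raise ValueError(
            f"requested {spec.n_waters_in_gate} gate waters but the cylinder holds "
            f"{len(pack)} at the {WATER_EXCLUSION} A exclusion"
        )
    wat_resid = 1
    for w in range(spec.n_waters_in_gate):
        add("O", "O", wat_resid, "HOH", "W", "water", tuple(pack[w]))
        wat_resid += 1
    for w in range(spec.n_bulk_waters):
        x, y = _ring_xy(40.0, 2 * math.pi * w / max(spec.n_bulk_waters, 1))
        add("O", "O", wat_resid, "HOH", "W", "water",
            (x, y, spec.membrane_half_width + 12.0 + 3.0 * (w % 3)))
        wat_resid += 1

    # ligands start in the aqueous phase
    for lig in range(spec.n_ligands):
        x, y = _ring_xy(36.0, 0.5 + 2 * math.pi * lig / max(spec.n_ligands, 1))
        add("O1", "O", lig + 1, "DES", "L", "ligand",
            (x, y, spec.membrane_half_width + 10.0))

    topology = Topology(atoms)
    frame = Frame(np.asarray(coords, dtype=float), np.asarray(spec.box, dtype=float), 0.0)
    return topology, frame


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------

def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _gate_band(topology: Topology, frame: Frame) -> tuple[float, float]:
    sites = default_sites()
    zs = {233: [], 240: []}
    for sub in topology.subunits:
        for resid in (233, 240):
            idx = resolve_selection(
                topology, SiteDefinition("g", [(resid, "CB")]), sub
            )
            zs[resid].append(frame.coordinates[idx, 2].mean())
    z9, z16 = float(np.mean(zs[233])), float(np.mean(zs[240]))
    return (min(z9, z16), max(z9, z16))


def _program_array(program, n_frames: int, name: str) -> np.ndarray:
    arr = np.asarray(program, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_frames, float(arr))
    if arr.shape != (n_frames,):
        raise ValueError(f"{name} must have one value per frame ({n_frames})")
    return arr


def script_trajectory(
    topology: Topology,
    base: Frame,
    script: EventScript,
    n_frames: int,
    dt: float = 1000.0,
    tilt_program: Mapping[str, Sequence[float]] | None = None,
    hydration_program: Sequence[int] | None = None,
    noise_amplitude: float = 0.0,
    seed: int = 0,
    sites: Mapping[str, SiteDefinition] | None = None,
) -> tuple[Trajectory, dict]:
    """Realize an event script as coordinates; returns (trajectory, truth).

    Ligands sit 2.5 A from the first site atom of the scripted subunit while
    bound (well inside the 3.5 A enter cutoff) and at distant aqueous or
    membrane home positions otherwise (far beyond the 5 A dissociation
    cutoff), with optional Gaussian positional noise.  Tilt programs rigidly
    rotate each subunit's pore-lining rod about its centroid; hydration
    programs repopulate the gate cylinder exactly.  The returned ``truth``
    dict is JSON-serializable ground truth for every scripted quantity.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    sites = dict(sites or default_sites())
    times = np.arange(n_frames) * dt
    ligand_ids = topology.ligand_ids
    # an event may extend one interval past the last frame (bound throughout)
    script.validate(len(ligand_ids), n_frames * dt)

    mhw = float(np.abs(
        base.coordinates[topology.role_indices("lipid"), 2]
    ).mean()) if len(topology.role_indices("lipid")) else 18.0

    # precompute bound anchor positions per (ligand-event)
    def bound_position(ev: ScriptedBinding) -> np.ndarray:
        site = sites[ev.site_name]
        idx = resolve_selection(topology, site, ev.subunit_id)
        anchor = base.coordinates[idx[0]]
        radial = np.array([anchor[0], anchor[1], 0.0])
        nrm = np.linalg.norm(radial)
        direction = -radial / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        return anchor + 2.5 * direction

    homes = {
        "aqueous": lambda k: np.array(
            [36.0 * math.cos(0.7 + 1.1 * k), 36.0 * math.sin(0.7 + 1.1 * k), mhw + 10.0]
        ),
        "membrane": lambda k: np.array(
            [36.0 * math.cos(0.7 + 1.1 * k), 36.0 * math.sin(0.7 + 1.1 * k), 0.0]
        ),
    }

    # tilt setup: per-subunit rotation of the pore-lining rod about its centroid
    tilt = {}
    if tilt_program:
        for sub, prog in tilt_program.items():
            arr = _program_array(prog, n_frames, f"tilt_program[{sub}]")
            if np.any(np.abs(arr) > 60.0):
                raise ValueError("tilt beyond 60 degrees breaks the toy geometry")
            tilt[sub] = arr
    m2 = sites.get("M2", default_sites()["M2"])
    m2_idx = {s: resolve_selection(topology, m2, s) for s in topology.subunits}
    m2_com = {s: base.coordinates[m2_idx[s]].mean(axis=0) for s in topology.subunits}

    hyd = None
    if hydration_program is not None:
        hyd = np.asarray(hydration_program, dtype=int)
        if hyd.shape != (n_frames,):
            raise ValueError("hydration_program must have one count per frame")
        z_lo, z_hi = _gate_band(topology, base)
        r_ring = _water_ring_radius(
            float(np.linalg.norm(base.coordinates[m2_idx[topology.subunits[0]][0], :2]))
        )
        pack = gate_packing_positions(z_lo, z_hi, r_ring)
        waters = topology.water_oxygen_indices
        if hyd.max(initial=0) > min(len(pack), len(waters)):
            raise ValueError(
                f"hydration program needs {hyd.max()} waters; capacity "
                f"{min(len(pack), len(waters))}"
            )

    frames: list[Frame] = []
    phase_labels = np.empty((len(ligand_ids), n_frames), dtype=object)
    for fi, t in enumerate(times):
        xyz = base.coordinates.copy()
        for lig_k in range(len(ligand_ids)):
            ev = next(
                (e for e in script.events
                 if e.ligand == lig_k and e.t_start <= t < e.t_end),
                None,
            )
            if ev is not None:
                pos = bound_position(ev)
                phase_labels[lig_k, fi] = "protein"
            else:
                phase = script.phase_for(lig_k)
                pos = homes[phase](lig_k)
                phase_labels[lig_k, fi] = phase
            if noise_amplitude > 0:
                pos = pos + rng.normal(0.0, noise_amplitude, 3)
            xyz[topology.ligand_atoms(ligand_ids[lig_k])] = pos
        for sub, prog in tilt.items():
            ang = math.radians(prog[fi])
            if abs(ang) > 1e-12:
                phi = math.atan2(m2_com[sub][1], m2_com[sub][0])
                tangent = np.array([-math.sin(phi), math.cos(phi), 0.0])
                Rm = _rotation_about(tangent, ang)
                idx = m2_idx[sub]
                xyz[idx] = (xyz[idx] - m2_com[sub]) @ Rm.T + m2_com[sub]
        if hyd is not None:
            waters = topology.water_oxygen_indices
            n_in = int(hyd[fi])
            for wi, widx in enumerate(waters):
                if wi < n_in:
                    xyz[widx] = pack[wi]
                else:
                    ang = 2 * math.pi * wi / max(len(waters), 1)
                    xyz[widx] = [42.0 * math.cos(ang), 42.0 * math.sin(ang), mhw + 14.0]
        frames.append(Frame(xyz, base.box.copy(), float(t)))

    truth = {
        "times_ps": times.tolist(),
        "dt_ps": dt,
        "seed": seed,
        "noise_amplitude": noise_amplitude,
        "events": [
            {"ligand": e.ligand, "site": e.site_name, "subunit": e.subunit_id,
             "t_start_ps": e.t_start, "t_end_ps": e.t_end,
             "residence_ns": (e.t_end - e.t_start) / 1000.0}
            for e in script.events
        ],
        "phase_labels": phase_labels.tolist(),
        "tilt_deg": {s: list(map(float, p)) for s, p in tilt.items()},
        "hydration": hyd.tolist() if hyd is not None else None,
    }
    return Trajectory(topology, frames), truth


# ---------------------------------------------------------------------------
# biased sampling over analytic potentials
# ---------------------------------------------------------------------------

def sample_windows(
    potential: AnalyticPotential,
    centers: Sequence[float],
    spring_k: float,
    n_samples: int,
    temperature: float = 298.0,
    step: float | None = None,
    burn_in: int = 1000,
    thin: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Metropolis samples from exp(-beta [U(z) + k/2 (z - z0)^2]) for every
    window centre at once; returns an (n_windows, n_samples) array.

    ``spring_k`` follows the half-k convention.  ``thin`` Metropolis updates
    are performed per recorded sample so recorded samples are nearly
    decorrelated; the proposal width defaults to ~2.4 standard deviations of
    the bias-dominated target, near the optimal random-walk acceptance.
    Deterministic for a given seed: all chains advance in lock-step from one
    random stream.
    """
    centers = np.asarray(centers, dtype=float)
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if spring_k <= 0:
        raise ValueError("spring_k must be positive")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    beta = 1.0 / (BOLTZMANN_KCAL * temperature)
    if step is None:
        step = 2.4 * math.sqrt(1.0 / (beta * spring_k))
    rng = np.random.default_rng(seed)
    n_win = len(centers)
    U = potential.energy

    z = centers.copy()
    e = U(z) + 0.5 * spring_k * (z - centers) ** 2
    out = np.empty((n_win, n_samples))
    total = burn_in + n_samples * thin
    for i in range(total):
        zp = z + rng.normal(0.0, step, n_win)
        ep = U(zp) + 0.5 * spring_k * (zp - centers) ** 2
        accept = np.log(rng.random(n_win)) < -beta * (ep - e)
        z = np.where(accept, zp, z)
        e = np.where(accept, ep, e)
        j = i - burn_in
        if j >= 0 and (j + 1) % thin == 0:
            out[:, (j + 1) // thin - 1] = z
    return out


def sample_biased_window(
    potential: AnalyticPotential,
    window_center: float,
    spring_k: float,
    n_samples: int,
    temperature: float = 298.0,
    step: float | None = None,
    burn_in: int = 1000,
    thin: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Metropolis samples of z from one harmonically biased window (see
    :func:`sample_windows`).  Deterministic for a given seed."""
    return sample_windows(
        potential, [window_center], spring_k, n_samples, temperature,
        step, burn_in, thin, seed,
    )[0]
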