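"""Structure/trajectory I/O, selections, and shared coordinate conventions.

The package represents a system as a static :class:`Topology` (atom identities
with role labels) plus one or more :class:`Frame` objects (coordinates, box,
time).  PDB and DCD reading/writing is delegated to MDAnalysis; a small
xyz-series dialect that carries per-frame box and time metadata in the comment
line is implemented here.

Conventions
-----------
* The channel/pore axis is z; by default the extracellular side is at high z.
* Distances honour the minimum-image convention under an orthorhombic box
  (membrane systems wrap in xy); pass ``box=None`` to disable.
* Residue numbering is author (PDB) numbering, 1-based.  Prime-notation
  aliases for M2 positions live in :data:`channelprobe.constants.PRIME_ALIASES`.
"""

from __future__ import annotations

import json
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .constants import ATOMIC_MASSES, MASS_DEFAULT

ROLES = ("protein", "lipid", "water", "ligand", "ion")

_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}

#: Residue-name -> role rules applied by :func:`load_structure`.
DEFAULT_ROLE_RULES: dict[str, str] = {
    **{name: "protein" for name in _AMINO_ACIDS},
    "POPC": "lipid",
    "POPE": "lipid",
    "POPG": "lipid",
    "DPPC": "lipid",
    "HOH": "water",
    "TIP3": "water",
    "WAT": "water",
    "SOL": "water",
    "DES": "ligand",
    "DFL": "ligand",
    "NA": "ion",
    "CL": "ion",
    "SOD": "ion",
    "CLA": "ion",
    "POT": "ion",
    "K": "ion",
}

_TWO_LETTER_ELEMENTS = {"NA": "Na", "CL": "Cl", "SOD": "Na", "CLA": "Cl", "POT": "K", "MG": "Mg"}


class FormatError(ValueError):
    """A structure/trajectory file could not be parsed."""


class SelectionError(KeyError):
    """A named residue/atom selection could not be resolved."""


def guess_element(atom_name: str, residue_name: str = "") -> str:
    """Guess an element symbol from a PDB atom name (fallback when the
    element column is absent)."""
    if residue_name.strip().upper() in _TWO_LETTER_ELEMENTS:
        return _TWO_LETTER_ELEMENTS[residue_name.strip().upper()]
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise FormatError(f"cannot guess element for atom name {atom_name!r}")
    return stripped[0].upper()


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the system with its static identity."""

    atom_index: int
    atom_name: str
    element: str
    residue_seq: int
    residue_name: str
    subunit_id: str
    role: str

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element, MASS_DEFAULT)


@dataclass
class Topology:
    """Static identity of the system: atoms, subunits, residue index."""

    atoms: list[AtomRecord]
    residue_index: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, a in enumerate(self.atoms):
            if a.atom_index != i:
                raise ValueError("atom_index must be contiguous from 0")
            if a.role not in ROLES:
                raise ValueError(f"unknown role {a.role!r} for atom {i}")
        if not self.residue_index:
            index: dict[tuple[str, int], list[int]] = {}
            for a in self.atoms:
                index.setdefault((a.subunit_id, a.residue_seq), []).append(a.atom_index)
            self.residue_index = {k: np.asarray(v, dtype=int) for k, v in index.items()}

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def subunits(self) -> list[str]:
        """Ordered protein chain identifiers."""
        seen: list[str] = []
        for a in self.atoms:
            if a.role == "protein" and a.subunit_id not in seen:
                seen.append(a.subunit_id)
        return seen

    def role_indices(self, role: str) -> np.ndarray:
        return np.asarray([a.atom_index for a in self.atoms if a.role == role], dtype=int)

    def heavy_indices(self, role: str | None = None) -> np.ndarray:
        return np.asarray(
            [a.atom_index for a in self.atoms
             if a.is_heavy and (role is None or a.role == role)],
            dtype=int,
        )

    @property
    def water_oxygen_indices(self) -> np.ndarray:
        """The single counting atom (oxygen) of every water molecule."""
        return np.asarray(
            [a.atom_index for a in self.atoms if a.role == "water" and a.element == "O"],
            dtype=int,
        )

    @property
    def ligand_ids(self) -> list[tuple[str, int]]:
        """Ligand molecules as ordered (subunit_id, residue_seq) keys."""
        seen: list[tuple[str, int]] = []
        for a in self.atoms:
            key = (a.subunit_id, a.residue_seq)
            if a.role == "ligand" and key not in seen:
                seen.append(key)
        return seen

    def ligand_atoms(self, ligand_id: tuple[str, int]) -> np.ndarray:
        idx = self.residue_index.get(tuple(ligand_id))
        if idx is None:
            raise SelectionError(f"no such ligand {ligand_id}")
        return idx

    def masses(self, indices: np.ndarray | None = None) -> np.ndarray:
        m = np.asarray([a.mass for a in self.atoms])
        return m if indices is None else m[np.asarray(indices, dtype=int)]

    def elements(self, indices: np.ndarray | None = None) -> list[str]:
        if indices is None:
            return [a.element for a in self.atoms]
        return [self.atoms[int(i)].element for i in np.asarray(indices, dtype=int)]


@dataclass
class Frame:
    """Coordinates (N x 3, Angstrom) + orthorhombic box (Angstrom) + time (ps)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive lengths")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered frames sharing one topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory has no frames")
        for i, f in enumerate(self.frames):
            if f.n_atoms != self.topology.n_atoms:
                raise ValueError(
                    f"frame {i}: {f.n_atoms} atoms but topology has {self.topology.n_atoms}"
                )
        times = self.times
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.asarray([f.time for f in self.frames])

    @property
    def frame_interval(self) -> float:
        """Time between the first two frames, ps."""
        if len(self.frames) < 2:
            raise ValueError("frame_interval undefined for a single frame")
        return float(self.frames[1].time - self.frames[0].time)

    @property
    def duration(self) -> float:
        return float(self.frames[-1].time - self.frames[0].time)

    def stride_indices(self, stride: float | None) -> np.ndarray:
        """Frame indices sampled every `stride` ps (all frames when None)."""
        if stride is None:
            return np.arange(len(self.frames))
        dt = self.frame_interval
        if stride < dt - 1e-9:
            raise ValueError(f"stride {stride} ps is below the frame interval {dt} ps")
        step = int(round(stride / dt))
        return np.arange(0, len(self.frames), step)


@dataclass
class SiteDefinition:
    """A named per-subunit residue set with binding cutoffs.

    ``members`` are (residue_seq, atom_name-or-None) pairs applied in every
    subunit.  The 3.5 A contact/enter cutoff and the 5 A dissociation cutoff
    follow the channel literature's contact and unbinding criteria.
    """

    name: str
    members: list[tuple[int, str | None]]
    contact_enter_cutoff: float = 3.5
    dissociation_cutoff: float = 5.0

    def __post_init__(self) -> None:
        self.members = [(int(r), a) for r, a in self.members]
        if self.contact_enter_cutoff <= 0 or self.dissociation_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if self.dissociation_cutoff < self.contact_enter_cutoff:
            raise ValueError("dissociation_cutoff must be >= contact_enter_cutoff")

    @property
    def residue_seqs(self) -> list[int]:
        return [r for r, _ in self.members]


def default_sites() -> dict[str, SiteDefinition]:
    """Built-in site definitions: TM1 (13-residue intrasubunit region), TM2
    (Tyr-254/Asn-307), the hydrophobic gate C-beta markers, and the M2 helix."""
    from .constants import M2_RESIDUE_RANGE, TM1_RESIDUES, TM2_RESIDUES

    lo, hi = M2_RESIDUE_RANGE
    return {
        "TM1": SiteDefinition("TM1", [(r, None) for r in TM1_RESIDUES]),
        "TM2": SiteDefinition("TM2", [(r, None) for r in TM2_RESIDUES]),
        "gate": SiteDefinition("gate", [(233, "CB"), (240, "CB")]),
        "M2": SiteDefinition("M2", [(r, None) for r in range(lo, hi + 1)]),
    }


# ---------------------------------------------------------------------------
# minimum-image geometry helpers
# ---------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the primary orthorhombic cell."""
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def pairwise_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> np.ndarray:
    """All pairwise minimum-image distances between coordinate sets (nA x nB)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    delta = a[:, None, :] - b[None, :, :]
    delta = minimum_image(delta, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))


def min_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> float:
    """Minimum pairwise minimum-image distance between two coordinate sets."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot compute a distance for an empty atom set")
    return float(pairwise_distances(a, b, box).min())


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    masses = np.asarray(masses, dtype=float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


# ---------------------------------------------------------------------------
# selection resolution
# ---------------------------------------------------------------------------

def resolve_selection(
    topology: Topology,
    site: SiteDefinition,
    subunit: str,
    heavy_only: bool = False,
) -> np.ndarray:
    """Atom indices of a site's member residues within one subunit.

    Members with an atom name select only that atom; otherwise all atoms of
    the residue.  Raises :class:`SelectionError` naming the missing
    (subunit, residue_seq) if a member cannot be found.
    """
    out: list[int] = []
    for resseq, atom_name in site.members:
        idx = topology.residue_index.get((subunit, resseq))
        if idx is None or len(idx) == 0:
            raise SelectionError(f"residue ({subunit!r}, {resseq}) not found for site {site.name!r}")
        chosen = list(idx)
        if atom_name is not None:
            chosen = [i for i in idx if topology.atoms[i].atom_name == atom_name]
            if not chosen:
                raise SelectionError(
                    f"atom {atom_name!r} of residue ({subunit!r}, {resseq}) not found"
                )
        if heavy_only:
            chosen = [i for i in chosen if topology.atoms[i].is_heavy]
        out.extend(chosen)
    return np.asarray(sorted(set(out)), dtype=int)


def resolve_site_all_subunits(
    topology: Topology, site: SiteDefinition, heavy_only: bool = False
) -> dict[str, np.ndarray]:
    return {s: resolve_selection(topology, site, s, heavy_only) for s in topology.subunits}


# ---------------------------------------------------------------------------
# MDAnalysis bridge
# ---------------------------------------------------------------------------

@contextmanager
def _suppress_mda_noise():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def make_mda_universe(topology: Topology, frame: Frame | None = None):
    """Build an in-memory MDAnalysis Universe mirroring the topology."""
    import MDAnalysis as mda

    n = topology.n_atoms
    residues: list[tuple[str, int, str]] = []
    atom_resindex = np.empty(n, dtype=int)
    for a in topology.atoms:
        key = (a.subunit_id, a.residue_seq, a.residue_name)
        if not residues or residues[-1] != key:
            residues.append(key)
        atom_resindex[a.atom_index] = len(residues) - 1
    seg_ids: list[str] = []
    residue_segindex = np.empty(len(residues), dtype=int)
    for ri, (chain, _, _) in enumerate(residues):
        if chain not in seg_ids:
            seg_ids.append(chain)
        residue_segindex[ri] = seg_ids.index(chain)

    with _suppress_mda_noise():
        u = mda.Universe.empty(
            n, n_residues=len(residues), n_segments=len(seg_ids),
            atom_resindex=atom_resindex, residue_segindex=residue_segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.atom_name for a in topology.atoms])
        u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
        u.add_TopologyAttr("resnames", [r[2] for r in residues])
        u.add_TopologyAttr("resids", [r[1] for r in residues])
        u.add_TopologyAttr("chainIDs", [a.subunit_id for a in topology.atoms])
        u.add_TopologyAttr("segids", seg_ids)
        u.add_TopologyAttr("record_types", ["ATOM"] * n)
        if frame is not None:
            u.atoms.positions = frame.coordinates
            u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    return u


def _prescan_pdb(path: Path) -> None:
    """Cheap line-level validation so format errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise FormatError(f"{path}:{lineno}: truncated ATOM record")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: unparseable coordinates in ATOM record"
                    ) from exc


def load_structure(
    path: str | Path,
    role_rules: Mapping[str, str] | None = None,
) -> tuple[Topology, Frame]:
    """Read a PDB structure and assign roles by residue-name rules.

    Unknown residue names with no rule raise :class:`FormatError` listing the
    names; unparseable ATOM records raise a :class:`FormatError` naming the
    line.
    """
    import MDAnalysis as mda

    path = Path(path)
    rules = dict(DEFAULT_ROLE_RULES)
    if role_rules:
        rules.update({k.upper(): v for k, v in role_rules.items()})
    _prescan_pdb(path)
    with _suppress_mda_noise():
        u = mda.Universe(str(path))
    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    try:
        chains = u.atoms.chainIDs
    except AttributeError:
        chains = u.atoms.segids
    try:
        elements = [e.capitalize() if e else "" for e in u.atoms.elements]
    except AttributeError:
        elements = [""] * len(names)

    unknown = sorted({rn.upper() for rn in resnames} - set(rules))
    if unknown:
        raise FormatError(f"no role rule for residue name(s): {', '.join(unknown)}")

    atoms = []
    for i in range(len(names)):
        elem = elements[i] or guess_element(names[i], resnames[i])
        role = rules[resnames[i].upper()]
        chain = str(chains[i]).strip()
        if role == "protein" and not chain:
            raise FormatError(f"protein atom {i} has no chain identifier")
        atoms.append(AtomRecord(i, str(names[i]), elem, int(resids[i]), str(resnames[i]), chain, role))
    topology = Topology(atoms)

    dims = u.dimensions
    box = np.asarray(dims[:3], dtype=float) if dims is not None and np.all(dims[:3] > 0) else np.array([1e6, 1e6, 1e6])
    frame = Frame(u.atoms.positions.astype(float), box, time=0.0)
    return topology, frame


def _times_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".times.json")


def write_structure(topology: Topology, frame: Frame, path: str | Path) -> None:
    path = Path(path)
    u = make_mda_universe(topology, frame)
    with _suppress_mda_noise():
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, path: str | Path, dialect: str = "multi-pdb") -> None:
    """Write a trajectory as multi-MODEL PDB (with a JSON time sidecar),
    xyz-series (box/time in the comment line), or DCD."""
    import MDAnalysis as mda

    path = Path(path)
    if dialect == "xyz-series":
        _write_xyz_series(traj, path)
        return
    u = make_mda_universe(traj.topology, traj.frames[0])
    with _suppress_mda_noise():
        with mda.Writer(str(path), n_atoms=traj.topology.n_atoms, multiframe=True) as w:
            for f in traj.frames:
                u.atoms.positions = f.coordinates
                u.dimensions = [*f.box, 90.0, 90.0, 90.0]
                u.trajectory.ts.time = f.time
                w.write(u.atoms)
    if dialect == "multi-pdb":
        _times_sidecar(path).write_text(json.dumps({"times_ps": [f.time for f in traj.frames]}))


def _write_xyz_series(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(f"{traj.topology.n_atoms}\n")
            bx, by, bz = f.box
            fh.write(f"time_ps={f.time} box={bx},{by},{bz}\n")
            for a, (x, y, z) in zip(traj.topology.atoms, f.coordinates):
                fh.write(f"{a.element} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_xyz_series(topology: Topology, path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: bad atom count at line {i + 1}") from exc
        if n != topology.n_atoms:
            raise FormatError(
                f"frame {frame_no}: {n} atoms but topology has {topology.n_atoms}"
            )
        meta = dict(kv.split("=", 1) for kv in lines[i + 1].split())
        time = float(meta["time_ps"])
        box = np.asarray([float(v) for v in meta["box"].split(",")])
        coords = np.array(
            [[float(v) for v in lines[i + 2 + j].split()[1:4]] for j in range(n)]
        )
        frames.append(Frame(coords, box, time))
        i += 2 + n
        frame_no += 1
    return frames


def load_trajectory(
    topology: Topology,
    path: str | Path,
    dialect: str = "auto",
    dt: float | None = None,
    t0: float = 0.0,
) -> Trajectory:
    """Load trajectory frames onto an existing topology.

    ``dialect`` is one of ``multi-pdb``, ``xyz-series``, ``dcd`` or ``auto``
    (by extension).  Frame times come from, in order of precedence: the JSON
    time sidecar written by :func:`write_trajectory`, an explicit ``dt``, or
    the reader's own time axis (DCD header / frame index).
    """
    path = Path(path)
    if dialect == "auto":
        dialect = {".pdb": "multi-pdb", ".xyz": "xyz-series", ".dcd": "dcd"}.get(
            path.suffix.lower(), "multi-pdb"
        )
    if dialect == "xyz-series":
        frames = _read_xyz_series(topology, path)
        if dt is not None:
            for i, f in enumerate(frames):
                f.time = t0 + i * dt
        return Trajectory(topology, frames)

    u = make_mda_universe(topology)
    with _suppress_mda_noise():
        try:
            u.load_new(str(path))
        except Exception as exc:  # atom count mismatch, framing errors
            raise FormatError(f"{path}: cannot load trajectory ({exc})") from exc
        frames = []
        for k, ts in enumerate(u.trajectory):
            if ts.positions.shape[0] != topology.n_atoms:
                raise FormatError(
                    f"frame {k}: {ts.positions.shape[0]} atoms, topology has {topology.n_atoms}"
                )
            box = (
                np.asarray(ts.dimensions[:3], dtype=float)
                if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0)
                else np.array([1e6, 1e6, 1e6])
            )
            frames.append(Frame(ts.positions.astype(float).copy(), box, time=float(ts.time)))

    sidecar = _times_sidecar(path)
    if sidecar.exists():
        times = json.loads(sidecar.read_text())["times_ps"]
        if len(times) != len(frames):
            raise FormatError(f"{sidecar}: {len(times)} times for {len(frames)} frames")
        for f, t in zip(frames, times):
            f.time = float(t)
    elif dt is not None:
        for i, f in enumerate(frames):
            f.time = t0 + i * dt
    return Trajectory(topology, frames)


def load_sites_yaml(path: str | Path) -> dict[str, SiteDefinition]:
    """Read site definitions from a YAML mapping
    ``{name: {members: [[resid, atom|null], ...], enter: A, exit: A}}``."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    sites = {}
    for name, spec in raw.items():
        sites[name] = SiteDefinition(
            name=name,
            members=[(int(m[0]), (m[1] if len(m) > 1 else None)) for m in spec["members"]],
            contact_enter_cutoff=float(spec.get("enter", 3.5)),
            dissociation_cutoff=float(spec.get("exit", 5.0)),
        )
    return sites
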