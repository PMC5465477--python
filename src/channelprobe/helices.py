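"""M2 helix tilt from four-residue turns, running averages, and backbone
RMSD via Kabsch superposition.

Tilt convention: three four-residue turns (intracellular, middle,
extracellular) are reduced to mass-weighted backbone centres of mass; the
``top`` vector runs middle -> extracellular and the ``bottom`` vector
intracellular -> middle, and each angle is measured against the membrane
normal (z by default, since the membrane is xy-planar).  The default turn
windows 222-225 / 230-233 / 237-240 span the -2'..16' region of the
pore-lining helix and are echoed in output headers as a package convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import BACKBONE_ATOM_NAMES, DEFAULT_RMSD_RANGES, DEFAULT_TILT_TURNS
from .model_io import (
    Frame,
    SiteDefinition,
    Topology,
    Trajectory,
    center_of_mass,
    resolve_selection,
)

Turns = tuple[tuple[int, int, int, int], ...]


@dataclass
class TiltSeries:
    """Per-subunit top/bottom tilt angles over time (degrees)."""

    subunit_id: str
    times: np.ndarray
    top_angle: np.ndarray
    bottom_angle: np.ndarray
    turns: Turns = DEFAULT_TILT_TURNS


def _turn_com(topology: Topology, frame: Frame, subunit: str, turn) -> np.ndarray:
    idx: list[int] = []
    for resseq in turn:
        res_atoms = resolve_selection(
            topology, SiteDefinition("turn", [(resseq, None)]), subunit
        )
        bb = [i for i in res_atoms if topology.atoms[i].atom_name in BACKBONE_ATOM_NAMES]
        if not bb:
            raise ValueError(
                f"residue ({subunit!r}, {resseq}) has no backbone atoms "
                f"({'/'.join(BACKBONE_ATOM_NAMES)})"
            )
        idx.extend(bb)
    arr = np.asarray(idx, dtype=int)
    return center_of_mass(frame.coordinates[arr], topology.masses(arr))


def _angle_deg(v: np.ndarray, n: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    n = np.asarray(n, dtype=float)
    cosang = np.dot(v, n) / (np.linalg.norm(v) * np.linalg.norm(n))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def helix_tilt(
    topology: Topology,
    frame: Frame,
    subunit: str,
    turns: Turns = DEFAULT_TILT_TURNS,
    membrane_normal: np.ndarray = (0.0, 0.0, 1.0),
) -> tuple[float, float]:
    """(top_angle, bottom_angle) in degrees for one subunit and frame."""
    if len(turns) != 3 or any(len(t) != 4 for t in turns):
        raise ValueError("turns must be three four-residue windows")
    intra, middle, extra = (
        _turn_com(topology, frame, subunit, t) for t in turns
    )
    top = _angle_deg(extra - middle, membrane_normal)
    bottom = _angle_deg(middle - intra, membrane_normal)
    return top, bottom


def tilt_series(
    traj: Trajectory,
    subunit: str,
    turns: Turns = DEFAULT_TILT_TURNS,
    membrane_normal: np.ndarray = (0.0, 0.0, 1.0),
    stride: float | None = None,
) -> TiltSeries:
    idx = traj.stride_indices(stride)
    times, tops, bots = [], [], []
    for fi in idx:
        frame = traj.frames[fi]
        top, bot = helix_tilt(traj.topology, frame, subunit, turns, membrane_normal)
        times.append(frame.time)
        tops.append(top)
        bots.append(bot)
    return TiltSeries(subunit, np.asarray(times), np.asarray(tops), np.asarray(bots), turns)


def running_average(
    values: np.ndarray,
    window: float,
    times: np.ndarray | None = None,
    mode: str = "centered",
) -> np.ndarray:
    """Centered moving mean over a uniformly sampled series.

    ``window`` is in the same units as ``times`` (ps for trajectory series);
    edges use truncated windows, so a constant series is returned unchanged
    and a linear ramp is preserved in the interior.
    """
    if mode != "centered":
        raise ValueError("only centered mode is supported")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if times is None:
        times = np.arange(n, dtype=float)
    times = np.asarray(times, dtype=float)
    if n != len(times):
        raise ValueError("values and times must have equal length")
    if n > 1:
        dt = float(times[1] - times[0])
        if window < dt:
            raise ValueError(f"window {window} is below the sampling interval {dt}")
    half = window / 2.0
    out = np.empty(n)
    lo = np.searchsorted(times, times - half, side="left")
    hi = np.searchsorted(times, times + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(n):
        out[i] = (csum[hi[i]] - csum[lo[i]]) / (hi[i] - lo[i])
    return out


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (proper rotation only).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` over the
    selection; ``rmsd`` is measured over the selection after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection, dtype=int)
    if len(sel) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    P = mobile[sel]
    Q = reference[sel]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10:
        raise ValueError("selection is collinear/degenerate; rotation is ill-defined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(((fitted - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def _range_backbone(topology: Topology, lo: int | None, hi: int | None) -> np.ndarray:
    idx = [
        a.atom_index
        for a in topology.atoms
        if a.role == "protein"
        and a.atom_name in BACKBONE_ATOM_NAMES
        and (lo is None or lo <= a.residue_seq <= hi)
    ]
    if not idx:
        raise ValueError(f"no backbone atoms in residue range {lo}-{hi}")
    return np.asarray(idx, dtype=int)


def rmsd_report(
    traj: Trajectory,
    reference: Frame,
    ranges: dict[str, tuple[int, int] | None] | None = None,
    stride: float = 100.0,
    tail: float = 20.0,
) -> pd.DataFrame:
    """Backbone RMSD vs a reference structure over named residue ranges.

    Frames are sampled every ``stride`` ps over the last ``tail`` ns; each
    range is superposed on its own backbone selection before measuring, and
    the table reports mean +/- sample SD per range in Angstrom.
    """
    if ranges is None:
        ranges = dict(DEFAULT_RMSD_RANGES)
    tail_ps = tail * 1000.0
    if tail_ps > traj.duration + 1e-9:
        raise ValueError(f"tail of {tail} ns exceeds trajectory duration")
    t_min = traj.frames[-1].time - tail_ps
    idx = [fi for fi in traj.stride_indices(stride) if traj.frames[fi].time >= t_min - 1e-9]
    if reference.n_atoms != traj.topology.n_atoms:
        raise ValueError("reference frame does not match trajectory topology")

    rows = []
    for name, rng in ranges.items():
        lo, hi = (None, None) if rng is None else rng
        sel = _range_backbone(traj.topology, lo, hi)
        vals = []
        for fi in idx:
            _, _, rmsd = kabsch_superpose(
                traj.frames[fi].coordinates, reference.coordinates, sel
            )
            vals.append(rmsd)
        rows.append({
            "range": name,
            "residues": "all" if rng is None else f"{lo}-{hi}",
            "rmsd_mean_A": float(np.mean(vals)),
            "rmsd_sd_A": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n_frames": len(vals),
        })
    return pd.DataFrame(rows)
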