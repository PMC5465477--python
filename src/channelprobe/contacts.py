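"""Ligand-channel contact probabilities, binding events, and occupancy.

A ligand is *in contact* with a residue when any ligand heavy atom lies
within the contact cutoff (default 3.5 A) of any heavy atom of the residue
(minimum-image).  A bound ligand is *judged to unbind* when its minimum
distance to the whole protein exceeds the dissociation cutoff (default 5 A);
the asymmetric enter/exit pair acts as a hysteresis that suppresses flicker.
Contact probabilities are reported per residue and subunit in percent,
aggregated across subunits with the arithmetic mean and the sample (n-1)
standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_io import (
    Frame,
    SiteDefinition,
    Trajectory,
    min_distance,
    resolve_selection,
)

log = logging.getLogger(__name__)


@dataclass
class BindingEvent:
    """One ligand's contiguous occupancy of one site in one subunit."""

    ligand_id: tuple[str, int]
    site_name: str
    subunit_id: str
    t_start: float  # ps
    t_end: float    # ps
    mean_pair_distance: float | None = None  # A, site-specific named pair
    rmsf: float | None = None                # A, bound-ligand fluctuation

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("event must have t_end > t_start")

    @property
    def residence_ns(self) -> float:
        return (self.t_end - self.t_start) / 1000.0


@dataclass
class OccupancySeries:
    """Bound-ligand count per sampled frame with series mean +/- SD."""

    site_name: str
    times: np.ndarray   # ps
    counts: np.ndarray
    sd_mode: str = "population"

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        ddof = 0 if self.sd_mode == "population" else 1
        return float(np.std(self.counts, ddof=ddof))


def residue_contact(
    frame: Frame,
    ligand_atoms: np.ndarray,
    residue_atoms: np.ndarray,
    cutoff: float = 3.5,
    use_box: bool = True,
) -> bool:
    """True iff the minimum pairwise (minimum-image) distance is <= cutoff."""
    la = np.asarray(ligand_atoms, dtype=int)
    ra = np.asarray(residue_atoms, dtype=int)
    if la.size == 0 or ra.size == 0:
        raise ValueError("contact test requires non-empty atom sets")
    box = frame.box if use_box else None
    return min_distance(frame.coordinates[la], frame.coordinates[ra], box) <= cutoff


def aggregate_subunits(values: Sequence[float]) -> tuple[float, float]:
    """Cross-subunit (mean, sample SD) of exactly five per-subunit values."""
    vals = np.asarray(values, dtype=float)
    if vals.shape != (5,):
        raise ValueError("expected exactly 5 per-subunit values")
    return float(vals.mean()), float(vals.std(ddof=1))


def _ligand_subunit_assignment(
    traj: Trajectory,
    site_atoms: dict[str, np.ndarray],
    ligand_atom_sets: dict[tuple[str, int], np.ndarray],
    frame_index: int = 0,
) -> dict[str, tuple[str, int]]:
    """Assign each subunit the nearest ligand at a reference frame; ties go
    to the first ligand in topology order and are logged."""
    frame = traj.frames[frame_index]
    assignment: dict[str, tuple[str, int]] = {}
    for sub, satoms in site_atoms.items():
        dists = []
        for lig, latoms in ligand_atom_sets.items():
            dists.append(
                (min_distance(frame.coordinates[latoms], frame.coordinates[satoms], frame.box), lig)
            )
        dists.sort(key=lambda p: p[0])
        if len(dists) > 1 and abs(dists[0][0] - dists[1][0]) < 1e-9:
            log.info("subunit %s: ligand assignment tie between %s and %s",
                     sub, dists[0][1], dists[1][1])
        assignment[sub] = dists[0][1]
    return assignment


def contact_probability(
    traj: Trajectory,
    site: SiteDefinition,
    stride: float = 1000.0,
    stop_rule: str = "until_dissociated",
    include_hydrogens: bool = False,
    use_box: bool = True,
) -> pd.DataFrame:
    """Per-residue, per-subunit contact probability table (percent).

    Each subunit is paired with its nearest ligand at the first sampled
    frame; contacts of that ligand with each member residue of the subunit
    are sampled every ``stride`` ps for the whole trajectory or, with
    ``stop_rule='until_dissociated'``, until the ligand's minimum distance to
    the whole protein exceeds the site's dissociation cutoff.  Columns are
    the subunits plus cross-subunit ``mean`` and sample ``sd``.
    """
    if len(traj) < 2:
        raise ValueError("contact probability needs at least two frames")
    if stop_rule not in ("full", "until_dissociated"):
        raise ValueError(f"unknown stop_rule {stop_rule!r}")
    idx = traj.stride_indices(stride)
    topo = traj.topology
    heavy_only = not include_hydrogens
    subunits = topo.subunits
    site_atoms = {s: resolve_selection(topo, site, s, heavy_only=heavy_only) for s in subunits}
    residue_atoms = {
        s: {
            resseq: resolve_selection(
                topo, SiteDefinition(site.name, [(resseq, None)]), s, heavy_only=heavy_only
            )
            for resseq in site.residue_seqs
        }
        for s in subunits
    }
    lig_sets = {lig: topo.ligand_atoms(lig) for lig in topo.ligand_ids}
    if heavy_only:
        heavy = set(topo.heavy_indices())
        lig_sets = {
            lig: np.asarray([i for i in atoms if i in heavy], dtype=int)
            for lig, atoms in lig_sets.items()
        }
    if not lig_sets:
        raise ValueError("topology has no ligands")
    assignment = _ligand_subunit_assignment(traj, site_atoms, lig_sets)
    protein = topo.heavy_indices("protein") if heavy_only else topo.role_indices("protein")

    hits = {s: {r: 0 for r in site.residue_seqs} for s in subunits}
    n_sampled = {s: 0 for s in subunits}
    alive = {s: True for s in subunits}
    for fi in idx:
        frame = traj.frames[fi]
        box = frame.box if use_box else None
        for s in subunits:
            if not alive[s]:
                continue
            latoms = lig_sets[assignment[s]]
            if stop_rule == "until_dissociated":
                dprot = min_distance(frame.coordinates[latoms], frame.coordinates[protein], box)
                if dprot > site.dissociation_cutoff:
                    alive[s] = False
                    continue
            n_sampled[s] += 1
            for resseq, ratoms in residue_atoms[s].items():
                d = min_distance(frame.coordinates[latoms], frame.coordinates[ratoms], box)
                if d <= site.contact_enter_cutoff:
                    hits[s][resseq] += 1

    table = {}
    for s in subunits:
        denom = max(n_sampled[s], 1)
        table[s] = [100.0 * hits[s][r] / denom for r in site.residue_seqs]
    df = pd.DataFrame(table, index=pd.Index(site.residue_seqs, name="residue_seq"))
    if len(subunits) == 5:
        stats = df.apply(lambda row: aggregate_subunits(row.values), axis=1)
        df["mean"] = [m for m, _ in stats]
        df["sd"] = [s for _, s in stats]
    return df


def detect_binding_events(
    traj: Trajectory,
    ligand_id: tuple[str, int],
    site: SiteDefinition,
    min_duration_frames: int = 2,
    pair: tuple[tuple[int, str], str] | None = None,
    sample_interval: float = 200.0,
    use_box: bool = True,
) -> list[BindingEvent]:
    """Hysteresis state machine: an event begins at the first frame where the
    ligand's minimum distance to a subunit's site atoms is <= the enter
    cutoff, and ends at the first frame where its minimum distance to the
    *whole protein* exceeds the dissociation cutoff.  Events shorter than
    ``min_duration_frames`` are discarded.  An event still open at the final
    frame is closed there.

    ``pair`` optionally names a ((residue_seq, atom_name), ligand_atom_name)
    distance pair recorded per event (e.g. Tyr-254 hydroxyl oxygen to the
    ligand's ether oxygen); bound-ligand RMSF is recorded per event using
    ``sample_interval`` ps sampling when the event spans >= 2 samples.
    """
    topo = traj.topology
    latoms = topo.ligand_atoms(ligand_id)
    subunits = topo.subunits
    site_atoms = {s: resolve_selection(topo, site, s) for s in subunits}
    protein = topo.heavy_indices("protein")

    events: list[BindingEvent] = []
    state: dict | None = None
    for fi, frame in enumerate(traj.frames):
        box = frame.box if use_box else None
        lcoords = frame.coordinates[latoms]
        if state is None:
            dists = {
                s: min_distance(lcoords, frame.coordinates[site_atoms[s]], box)
                for s in subunits
            }
            best = min(dists, key=lambda s: (dists[s], s))
            ties = [s for s in subunits if s != best and abs(dists[s] - dists[best]) < 1e-9]
            if dists[best] <= site.contact_enter_cutoff:
                if ties:
                    log.info("ligand %s: subunit tie at binding (%s vs %s)",
                             ligand_id, best, ties)
                state = {"subunit": best, "start_frame": fi, "t_start": frame.time}
        else:
            dprot = min_distance(lcoords, frame.coordinates[protein], box)
            if dprot > site.dissociation_cutoff:
                events.append(
                    _close_event(traj, ligand_id, site, state, fi, frame.time,
                                 min_duration_frames, pair, sample_interval)
                )
                state = None
    if state is not None:
        last = traj.frames[-1]
        events.append(
            _close_event(traj, ligand_id, site, state, len(traj) - 1, last.time,
                         min_duration_frames, pair, sample_interval)
        )
    return [e for e in events if e is not None]


def _close_event(traj, ligand_id, site, state, end_frame, t_end,
                 min_duration_frames, pair, sample_interval):
    n_frames = end_frame - state["start_frame"]
    if n_frames < min_duration_frames or t_end <= state["t_start"]:
        return None
    event = BindingEvent(
        ligand_id=ligand_id,
        site_name=site.name,
        subunit_id=state["subunit"],
        t_start=state["t_start"],
        t_end=t_end,
    )
    try:
        event.rmsf = bound_ligand_rmsf(traj, event, sample_interval)
    except ValueError:
        event.rmsf = None
    if pair is not None:
        event.mean_pair_distance = _event_pair_distance(traj, event, pair, sample_interval)
    return event


def _event_pair_distance(traj, event, pair, sample_interval):
    (resseq, atom_name), ligand_atom_name = pair
    topo = traj.topology
    prot = resolve_selection(
        topo, SiteDefinition("pair", [(resseq, atom_name)]), event.subunit_id
    )
    lat = topo.ligand_atoms(event.ligand_id)
    lat = np.asarray(
        [i for i in lat if topo.atoms[i].atom_name == ligand_atom_name] or list(lat),
        dtype=int,
    )
    vals = []
    for fi in _event_sample_frames(traj, event, sample_interval):
        frame = traj.frames[fi]
        vals.append(min_distance(frame.coordinates[lat], frame.coordinates[prot], frame.box))
    return float(np.mean(vals)) if vals else None


def _event_sample_frames(traj: Trajectory, event: BindingEvent, sample_interval: float):
    dt = traj.frame_interval
    step = max(int(round(sample_interval / dt)), 1)
    out = []
    for fi in range(0, len(traj), step):
        t = traj.frames[fi].time
        if event.t_start <= t < event.t_end or (t == event.t_end and fi == len(traj) - 1):
            out.append(fi)
    return out


def bound_ligand_rmsf(
    traj: Trajectory, event: BindingEvent, sample_interval: float = 200.0
) -> float:
    """RMSF of the bound ligand about its time-average structure (lab frame,
    no superposition), root-mean-squared over atoms and samples."""
    frames = _event_sample_frames(traj, event, sample_interval)
    if len(frames) < 2:
        raise ValueError("event spans fewer than 2 RMSF samples")
    latoms = traj.topology.ligand_atoms(event.ligand_id)
    coords = np.stack([traj.frames[fi].coordinates[latoms] for fi in frames])
    mean = coords.mean(axis=0)
    dev2 = ((coords - mean) ** 2).sum(axis=2)  # (n_samples, n_atoms)
    return float(np.sqrt(dev2.mean()))


def distance_series(
    traj: Trajectory,
    pair: tuple[np.ndarray, np.ndarray],
    stride: float | None = None,
    running_window: float | None = None,
    use_box: bool = True,
) -> pd.DataFrame:
    """Minimum distance between two atom selections per sampled frame.

    ``running_window`` (ps) adds a centered running mean with truncated
    edges.  Returns a DataFrame with columns ``time_ps``, ``distance_A`` and
    optionally ``running_mean_A``.
    """
    a, b = (np.asarray(p, dtype=int) for p in pair)
    if a.size == 0 or b.size == 0:
        raise ValueError("distance series selectors must be non-empty")
    idx = traj.stride_indices(stride)
    times, vals = [], []
    for fi in idx:
        frame = traj.frames[fi]
        box = frame.box if use_box else None
        times.append(frame.time)
        vals.append(min_distance(frame.coordinates[a], frame.coordinates[b], box))
    df = pd.DataFrame({"time_ps": times, "distance_A": vals})
    if running_window is not None:
        from .helices import running_average

        df["running_mean_A"] = running_average(
            np.asarray(vals), running_window, np.asarray(times)
        )
    return df


def occupancy_series(
    traj: Trajectory,
    site: SiteDefinition,
    stride: float | None = None,
    sd_mode: str = "population",
    use_box: bool = True,
) -> OccupancySeries:
    """Count of distinct ligands simultaneously bound (enter criterion, any
    subunit) at each sampled frame, with series mean and SD (population SD
    by default, matching a per-frame time-series convention)."""
    topo = traj.topology
    if not topo.ligand_ids:
        raise ValueError("topology has no ligands")
    site_atoms = {s: resolve_selection(topo, site, s) for s in topo.subunits}
    lig_sets = {lig: topo.ligand_atoms(lig) for lig in topo.ligand_ids}
    idx = traj.stride_indices(stride)
    times, counts = [], []
    for fi in idx:
        frame = traj.frames[fi]
        box = frame.box if use_box else None
        n = 0
        for latoms in lig_sets.values():
            lc = frame.coordinates[latoms]
            if any(
                min_distance(lc, frame.coordinates[sa], box) <= site.contact_enter_cutoff
                for sa in site_atoms.values()
            ):
                n += 1
        times.append(frame.time)
        counts.append(n)
    return OccupancySeries(site.name, np.asarray(times), np.asarray(counts), sd_mode)


# ---------------------------------------------------------------------------
# replicate-level event reporting
# ---------------------------------------------------------------------------

def aggregate_event_counts(per_replicate_counts: Iterable[int]) -> int:
    """Total binding events across replicate simulations."""
    counts = [int(c) for c in per_replicate_counts]
    if any(c < 0 for c in counts):
        raise ValueError("event counts must be non-negative")
    return int(sum(counts))


def combine_replicates(event_lists: Sequence[Sequence[BindingEvent]]) -> pd.DataFrame:
    """Replicate summary table: per-replicate event counts and residence
    statistics, plus an ``All`` row reported under both the event-weighted
    and replicate-weighted conventions (the two are distinguished because
    rounded published tables cannot disambiguate them)."""
    rows = []
    all_res: list[float] = []
    for i, events in enumerate(event_lists, start=1):
        res = [e.residence_ns for e in events]
        all_res.extend(res)
        rows.append({
            "replicate": str(i),
            "n_events": len(events),
            "residence_mean_ns": float(np.mean(res)) if res else np.nan,
            "residence_sd_ns": float(np.std(res, ddof=1)) if len(res) > 1 else np.nan,
        })
    total = aggregate_event_counts(r["n_events"] for r in rows)
    rows.append({
        "replicate": "All (event-weighted)",
        "n_events": total,
        "residence_mean_ns": float(np.mean(all_res)) if all_res else np.nan,
        "residence_sd_ns": float(np.std(all_res, ddof=1)) if len(all_res) > 1 else np.nan,
    })
    per_means = [r["residence_mean_ns"] for r in rows[:-1] if np.isfinite(r["residence_mean_ns"])]
    rows.append({
        "replicate": "All (replicate-weighted)",
        "n_events": total,
        "residence_mean_ns": float(np.mean(per_means)) if per_means else np.nan,
        "residence_sd_ns": float(np.std(per_means, ddof=1)) if len(per_means) > 1 else np.nan,
    })
    return pd.DataFrame(rows)
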