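"""Contact statistics, binding-event detection, residence and RMSF."""

import numpy as np
import pytest

from channelprobe import (
    BindingEvent,
    EventScript,
    Frame,
    ScriptedBinding,
    SiteDefinition,
    Trajectory,
    aggregate_event_counts,
    aggregate_subunits,
    bound_ligand_rmsf,
    combine_replicates,
    contact_probability,
    detect_binding_events,
    distance_series,
    occupancy_series,
    residue_contact,
    script_trajectory,
)
from channelprobe.model_io import AtomRecord, Topology, min_distance


def _two_atom_frame(d):
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]])
    return Frame(coords, np.array([100.0, 100.0, 100.0]))


class TestResidueContact:
    def test_boundary_is_inclusive(self):
        assert residue_contact(_two_atom_frame(3.5), [0], [1], 3.5) is True
        assert residue_contact(_two_atom_frame(3.51), [0], [1], 3.5) is False

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(5)
        box = np.array([20.0, 20.0, 20.0])
        coords = rng.uniform(0, 20, (20, 3))
        frame = Frame(coords, box)
        lig, res = np.arange(10), np.arange(10, 20)
        for cutoff in (2.0, 5.0, 8.0):
            brute = min(
                min(
                    np.linalg.norm(coords[i] - (coords[j] + s * box))
                    for s in np.array(
                        [[a, b, c] for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)]
                    )
                )
                for i in lig
                for j in res
            )
            assert residue_contact(frame, lig, res, cutoff) == (brute <= cutoff)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            residue_contact(_two_atom_frame(1.0), [], [1], 3.5)

    def test_monotone_in_cutoff(self):
        frame = _two_atom_frame(4.2)
        results = [residue_contact(frame, [0], [1], c) for c in (1.0, 4.2, 10.0)]
        assert results == sorted(results)  # False before True, never back


class TestAggregateSubunits:
    @pytest.mark.parametrize(
        "values,mean,sd",
        [
            ((10, 23, 90, 71, 14), 41.6, 36.4),   # Tyr-119
            ((23, 45, 97, 97, 43), 61.0, 34.0),   # Thr-255
            ((67, 36, 70, 88, 98), 71.8, 23.8),   # Ile-258
        ],
    )
    def test_published_rows_reproduce(self, values, mean, sd):
        m, s = aggregate_subunits(values)
        assert round(m, 1) == mean
        assert round(s, 1) == sd

    def test_equal_values_have_zero_sd(self):
        assert aggregate_subunits([50] * 5) == (50.0, 0.0)

    def test_requires_exactly_five(self):
        with pytest.raises(ValueError):
            aggregate_subunits([1, 2, 3])


class TestContactProbability:
    def test_alternating_script_gives_fifty_percent(self, toy, sites):
        _, topo, frame = toy
        events = [ScriptedBinding(0, "TM1", "A", t, t + 1000.0)
                  for t in np.arange(0.0, 10_000.0, 2000.0)]
        traj, _ = script_trajectory(topo, frame, EventScript(events=events),
                                    n_frames=10, dt=1000.0)
        table = contact_probability(traj, sites["TM1"], stride=1000.0, stop_rule="full")
        assert table.loc[242, "A"] == pytest.approx(50.0)

    def test_until_dissociated_excludes_later_frames(self, toy, sites):
        _, topo, frame = toy
        events = [ScriptedBinding(0, "TM1", "A", 0.0, 5000.0)]
        traj, _ = script_trajectory(topo, frame, EventScript(events=events),
                                    n_frames=10, dt=1000.0)
        table = contact_probability(traj, sites["TM1"], stride=1000.0,
                                    stop_rule="until_dissociated")
        assert table.loc[242, "A"] == pytest.approx(100.0)

    def test_stride_below_interval_rejected(self, bound_traj, sites):
        traj, _ = bound_traj
        with pytest.raises(ValueError, match="stride"):
            contact_probability(traj, sites["TM1"], stride=10.0)

    def test_probability_monotone_in_cutoff(self, bound_traj):
        traj, _ = bound_traj
        members = [(r, None) for r in (119, 242, 254)]
        tables = [
            contact_probability(
                traj,
                SiteDefinition("s", members, contact_enter_cutoff=c,
                               dissociation_cutoff=max(c, 5.0)),
                stride=1000.0, stop_rule="full",
            )
            for c in (2.5, 3.5, 6.0)
        ]
        for lo, hi in zip(tables, tables[1:]):
            assert (hi[["A", "B", "C", "D", "E"]].values
                    >= lo[["A", "B", "C", "D", "E"]].values - 1e-12).all()


class TestEventDetection:
    def test_hand_traced_state_machine(self, toy, sites):
        """Distance series [2,2,6,2,2,6] A at 1 ns/frame -> two 2-ns events."""
        _, topo, frame = toy
        events = [
            ScriptedBinding(0, "TM1", "A", 0.0, 2000.0),
            ScriptedBinding(0, "TM1", "A", 3000.0, 5000.0),
        ]
        traj, _ = script_trajectory(topo, frame, EventScript(events=events),
                                    n_frames=6, dt=1000.0)
        got = detect_binding_events(traj, topo.ligand_ids[0], sites["TM1"],
                                    min_duration_frames=1)
        assert [(e.t_start, e.t_end, e.residence_ns) for e in got] == [
            (0.0, 2000.0, 2.0),
            (3000.0, 5000.0, 2.0),
        ]
        assert all(e.subunit_id == "A" for e in got)

    def test_never_bound_gives_empty_list(self, toy, sites):
        _, topo, frame = toy
        traj, _ = script_trajectory(topo, frame, EventScript(), n_frames=5, dt=1000.0)
        assert detect_binding_events(traj, topo.ligand_ids[0], sites["TM1"]) == []

    def test_scripted_event_recovered_within_one_frame(self, bound_traj, sites):
        traj, truth = bound_traj
        got = detect_binding_events(traj, traj.topology.ligand_ids[0], sites["TM1"])
        assert len(got) == 1
        ev, want = got[0], truth["events"][0]
        dt = traj.frame_interval
        assert abs(ev.t_start - want["t_start_ps"]) <= dt
        assert abs(ev.t_end - want["t_end_ps"]) <= dt

    def test_residence_total_bounded_by_duration(self, bound_traj, sites):
        traj, _ = bound_traj
        events = detect_binding_events(traj, traj.topology.ligand_ids[0], sites["TM1"])
        assert sum(e.residence_ns for e in events) * 1000.0 <= traj.duration

    def test_event_count_aggregation(self):
        assert aggregate_event_counts([5, 6, 5, 8, 8]) == 32

    def test_combine_replicates_reports_both_weightings(self):
        def ev(res_ns):
            return BindingEvent(("L", 1), "TM2", "A", 0.0, res_ns * 1000.0)

        table = combine_replicates([[ev(10.0)], [ev(30.0), ev(50.0)]])
        assert table.loc[2, "replicate"] == "All (event-weighted)"
        assert table.loc[2, "n_events"] == 3
        assert table.loc[2, "residence_mean_ns"] == pytest.approx(30.0)
        assert table.loc[3, "residence_mean_ns"] == pytest.approx(25.0)


class TestBoundLigandRmsf:
    def test_static_ligand_is_zero(self, toy, sites):
        _, topo, frame = toy
        events = [ScriptedBinding(0, "TM1", "A", 0.0, 10_000.0)]
        traj, _ = script_trajectory(topo, frame, EventScript(events=events),
                                    n_frames=10, dt=1000.0, noise_amplitude=0.0)
        ev = BindingEvent(topo.ligand_ids[0], "TM1", "A", 0.0, 10_000.0)
        assert bound_ligand_rmsf(traj, ev, sample_interval=1000.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_state_fluctuation_is_half_distance(self, toy):
        """Point ligand alternating between positions d apart -> RMSF d/2."""
        _, topo, frame = toy
        lig = topo.ligand_atoms(topo.ligand_ids[0])
        frames = []
        d = 2.0
        for i in range(8):
            xyz = frame.coordinates.copy()
            xyz[lig] = [0.0, 0.0, (d / 2.0) * (-1) ** i]
            frames.append(Frame(xyz, frame.box, i * 200.0))
        traj = Trajectory(topo, frames)
        ev = BindingEvent(topo.ligand_ids[0], "TM1", "A", 0.0, 8 * 200.0)
        assert bound_ligand_rmsf(traj, ev, sample_interval=200.0) == pytest.approx(d / 2)

    def test_gaussian_noise_gives_sqrt3_sigma(self, toy):
        _, topo, frame = toy
        events = [ScriptedBinding(0, "TM1", "A", 0.0, 100_000.0)]
        traj, _ = script_trajectory(topo, frame, EventScript(events=events),
                                    n_frames=500, dt=200.0, noise_amplitude=1.0,
                                    seed=17)
        ev = BindingEvent(topo.ligand_ids[0], "TM1", "A", 0.0, 100_000.0)
        rmsf = bound_ligand_rmsf(traj, ev, sample_interval=200.0)
        assert rmsf == pytest.approx(np.sqrt(3.0), rel=0.05)

    def test_short_event_rejected(self, bound_traj):
        traj, _ = bound_traj
        ev = BindingEvent(traj.topology.ligand_ids[0], "TM1", "A", 0.0, 100.0)
        with pytest.raises(ValueError, match="2"):
            bound_ligand_rmsf(traj, ev, sample_interval=1000.0)


class TestDistanceSeries:
    def test_fixed_pair_is_constant(self, toy):
        _, topo, frame = toy
        traj, _ = script_trajectory(topo, frame, EventScript(), n_frames=5, dt=1000.0)
        a, b = [0], [1]
        expected = min_distance(
            frame.coordinates[a], frame.coordinates[b], frame.box
        )
        df = distance_series(traj, (np.array(a), np.array(b)))
        assert np.allclose(df["distance_A"], expected)

    def test_group_min_matches_brute_force(self, bound_traj):
        traj, _ = bound_traj
        topo = traj.topology
        lig = topo.ligand_atoms(topo.ligand_ids[0])
        group = np.arange(30)
        df = distance_series(traj, (group, lig), stride=10_000.0)
        for k, fi in enumerate(traj.stride_indices(10_000.0)):
            frame = traj.frames[fi]
            brute = min_distance(frame.coordinates[group], frame.coordinates[lig],
                                 frame.box)
            assert df["distance_A"].iloc[k] == pytest.approx(brute)

    def test_empty_selector_rejected(self, bound_traj):
        traj, _ = bound_traj
        with pytest.raises(ValueError):
            distance_series(traj, (np.array([], dtype=int), np.array([0])))


class TestOccupancySeries:
    def test_two_always_bound(self, toy, sites):
        _, topo, frame = toy
        events = [ScriptedBinding(i, "TM1", s, 0.0, 5000.0)
                  for i, s in ((0, "A"), (1, "B"))]
        traj, _ = script_trajectory(topo, frame, EventScript(events=events),
                                    n_frames=5, dt=1000.0)
        occ = occupancy_series(traj, sites["TM1"])
        assert occ.mean == 2.0 and occ.sd == 0.0

    def test_alternating_one_three(self, toy, sites):
        """Counts alternating 1/3 -> mean 2; population SD 1 by default."""
        _, topo, frame = toy
        events = [ScriptedBinding(0, "TM1", "A", 0.0, 10_000.0)]
        for t in np.arange(0.0, 10_000.0, 2000.0):
            events.append(ScriptedBinding(1, "TM1", "B", t, t + 1000.0))
            events.append(ScriptedBinding(2, "TM1", "C", t, t + 1000.0))
        traj, _ = script_trajectory(topo, frame, EventScript(events=events),
                                    n_frames=10, dt=1000.0)
        occ = occupancy_series(traj, sites["TM1"])
        assert occ.counts.tolist() == [3, 1] * 5
        assert occ.mean == 2.0
        assert occ.sd == 1.0
        occ_sample = occupancy_series(traj, sites["TM1"], sd_mode="sample")
        assert occ_sample.sd == pytest.approx(np.std([3, 1] * 5, ddof=1))

    def test_empty_script_mean_zero(self, toy, sites):
        _, topo, frame = toy
        traj, _ = script_trajectory(topo, frame, EventScript(), n_frames=4, dt=1000.0)
        occ = occupancy_series(traj, sites["TM1"])
        assert occ.mean == 0.0
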