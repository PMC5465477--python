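"""Helix tilt, running averages, Kabsch superposition, RMSD reports."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from channelprobe import (
    EventScript,
    Frame,
    Trajectory,
    helix_tilt,
    kabsch_superpose,
    rmsd_report,
    running_average,
    script_trajectory,
)
from channelprobe.synthetic import _rotation_about


class TestHelixTilt:
    def test_ideal_vertical_helix_is_zero(self, toy):
        _, topo, frame = toy
        for sub in topo.subunits:
            top, bottom = helix_tilt(topo, frame, sub)
            assert top == pytest.approx(0.0, abs=1e-9)
            assert bottom == pytest.approx(0.0, abs=1e-9)

    def test_ten_degree_rotation_recovered(self, toy):
        _, topo, frame = toy
        R = _rotation_about(np.array([1.0, 0.0, 0.0]), np.radians(10.0))
        rotated = Frame(frame.coordinates @ R.T, frame.box)
        for sub in topo.subunits:
            top, bottom = helix_tilt(topo, rotated, sub)
            assert top == pytest.approx(10.0, abs=0.01)
            assert bottom == pytest.approx(10.0, abs=0.01)

    def test_antiparallel_is_180(self, toy):
        _, topo, frame = toy
        flipped = Frame(frame.coordinates * [1.0, 1.0, -1.0], frame.box)
        top, bottom = helix_tilt(topo, flipped, "A")
        assert top == pytest.approx(180.0, abs=1e-9)

    def test_invariant_to_translation_and_axial_rotation(self, toy):
        _, topo, frame = toy
        ref = helix_tilt(topo, frame, "B")
        shifted = Frame(frame.coordinates + [3.0, -7.0, 11.0], frame.box)
        assert helix_tilt(topo, shifted, "B") == pytest.approx(ref, abs=1e-9)
        Rz = _rotation_about(np.array([0.0, 0.0, 1.0]), 0.9)
        spun = Frame(frame.coordinates @ Rz.T, frame.box)
        assert helix_tilt(topo, spun, "B") == pytest.approx(ref, abs=1e-9)

    def test_scripted_tilt_program_recovered(self, toy):
        _, topo, frame = toy
        prog = {"A": [0.0, 5.0, 12.5], "C": [0.0, 0.0, 30.0]}
        traj, truth = script_trajectory(topo, frame, EventScript(), n_frames=3,
                                        dt=1000.0, tilt_program=prog)
        for sub, angles in prog.items():
            for fi, want in enumerate(angles):
                top, bottom = helix_tilt(topo, traj.frames[fi], sub)
                assert top == pytest.approx(want, abs=1e-9)
                assert bottom == pytest.approx(want, abs=1e-9)


class TestRunningAverage:
    def test_constant_series_unchanged(self):
        x = np.full(20, 3.7)
        assert np.allclose(running_average(x, 5.0), x)

    def test_linear_ramp_preserved_in_interior(self):
        t = np.arange(50.0)
        x = 2.0 * t + 1.0
        out = running_average(x, 10.0, t)
        assert np.allclose(out[6:-6], x[6:-6])

    def test_matches_brute_force_window_sums(self):
        rng = np.random.default_rng(2)
        t = np.arange(30.0)
        x = rng.normal(size=30)
        window = 7.0
        out = running_average(x, window, t)
        for i in range(30):
            mask = np.abs(t - t[i]) <= window / 2
            assert out[i] == pytest.approx(x[mask].mean())

    def test_commutes_with_affine_rescaling(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=25)
        a, b = 3.0, -1.5
        assert np.allclose(
            running_average(a * x + b, 5.0), a * running_average(x, 5.0) + b
        )

    def test_window_below_interval_rejected(self):
        with pytest.raises(ValueError, match="window"):
            running_average(np.arange(5.0), 0.5, np.arange(5.0) * 2.0)


def _grid_oracle_rmsd(P, Q):
    """Brute-force best-fit RMSD via a refined rotation grid."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_for(mats):
        moved = np.einsum("nij,kj->nki", mats, Pc)
        return np.sqrt(((moved - Qc) ** 2).sum(axis=2).mean(axis=1))

    best_euler = np.zeros(3)
    width = 180.0
    best = np.inf
    for _ in range(5):
        steps = np.linspace(-width, width, 13)
        grid = np.stack(np.meshgrid(*[best_euler[i] + steps for i in range(3)],
                                    indexing="ij"), axis=-1).reshape(-1, 3)
        mats = Rotation.from_euler("xyz", grid, degrees=True).as_matrix()
        vals = rmsd_for(mats)
        k = int(np.argmin(vals))
        best = float(vals[k])
        best_euler = grid[k]
        width /= 6.0
    return best


class TestKabsch:
    def test_identity_and_rigid_copy(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(12, 3))
        _, _, rmsd0 = kabsch_superpose(P, P)
        assert rmsd0 == pytest.approx(0.0, abs=1e-12)
        R = _rotation_about(np.array([0.3, -1.0, 0.5]), 1.1)
        t = np.array([4.0, -2.0, 9.0])
        Q = P @ R.T + t
        Rk, tk, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(Rk, R, atol=1e-10)
        assert np.allclose(tk, t, atol=1e-10)

    def test_recovered_transform_inverts_applied_one(self):
        rng = np.random.default_rng(14)
        P = rng.normal(size=(8, 3))
        R = _rotation_about(rng.normal(size=3), 0.8)
        Q = P @ R.T + [1.0, 2.0, 3.0]
        Rk, tk, _ = kabsch_superpose(Q, P)
        assert np.allclose(Rk, R.T, atol=1e-10)

    def test_four_point_toy_matches_grid_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(3):
            P = rng.normal(size=(4, 3))
            Q = P.copy()
            Q[0] += rng.normal(scale=0.5, size=3)
            R = _rotation_about(rng.normal(size=3), rng.uniform(0, 2))
            Q = Q @ R.T + rng.normal(size=3)
            _, _, rmsd = kabsch_superpose(P, Q)
            assert rmsd == pytest.approx(_grid_oracle_rmsd(P, Q), abs=1e-3)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(31)
        P = rng.normal(size=(6, 3))
        Q = P + rng.normal(scale=0.3, size=(6, 3))
        _, _, ab = kabsch_superpose(P, Q)
        _, _, ba = kabsch_superpose(Q, P)
        assert ab == pytest.approx(ba, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError, match="shape"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsdReport:
    def test_reference_repeated_gives_zero(self, toy):
        _, topo, frame = toy
        frames = [Frame(frame.coordinates.copy(), frame.box, t)
                  for t in np.arange(0.0, 2100.0, 100.0)]
        traj = Trajectory(topo, frames)
        report = rmsd_report(traj, frame, stride=100.0, tail=1.0)
        assert np.allclose(report["rmsd_mean_A"], 0.0, atol=1e-12)
        assert set(report["range"]) == {"Protein", "ECD", "TMD", "Pore"}

    def test_pore_only_displacement_localizes(self, toy):
        """Deforming only pore-range residues leaves the ECD metric at zero."""
        _, topo, frame = toy
        rng = np.random.default_rng(6)
        pore_idx = [a.atom_index for a in topo.atoms
                    if a.role == "protein" and 221 <= a.residue_seq <= 244]
        frames = []
        for t in np.arange(0.0, 2100.0, 100.0):
            xyz = frame.coordinates.copy()
            xyz[pore_idx] += rng.normal(scale=0.5, size=(len(pore_idx), 3))
            frames.append(Frame(xyz, frame.box, t))
        traj = Trajectory(topo, frames)
        ranges = {"ECD-like": (119, 206), "Pore": (221, 244)}
        report = rmsd_report(traj, frame, ranges=ranges, stride=100.0, tail=1.0)
        by = report.set_index("range")
        assert by.loc["ECD-like", "rmsd_mean_A"] == pytest.approx(0.0, abs=1e-12)
        assert by.loc["Pore", "rmsd_mean_A"] > 0.1

    def test_tail_longer_than_trajectory_rejected(self, bound_traj):
        traj, _ = bound_traj
        with pytest.raises(ValueError, match="tail"):
            rmsd_report(traj, traj.frames[0], stride=1000.0, tail=10_000.0)
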