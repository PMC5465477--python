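import numpy as np
import pytest

from channelprobe import (
    EventScript,
    ScriptedBinding,
    ToyChannelSpec,
    build_toy_channel,
    default_sites,
    script_trajectory,
)


@pytest.fixture(scope="session")
def toy():
    """Default toy pentamer: (spec, topology, frame)."""
    spec = ToyChannelSpec()
    topo, frame = build_toy_channel(spec)
    return spec, topo, frame


@pytest.fixture(scope="session")
def sites():
    return default_sites()


@pytest.fixture(scope="session")
def bound_traj(toy):
    """One ligand bound to TM1 in subunit A for 50-150 ns of a 300 ns run."""
    _, topo, frame = toy
    script = EventScript(events=[ScriptedBinding(0, "TM1", "A", 50_000.0, 150_000.0)])
    traj, truth = script_trajectory(topo, frame, script, n_frames=300, dt=1000.0)
    return traj, truth


def write_minimal_pdb(path, include_hydrogen=False, bad_line=False, unknown_resname=False):
    """Hand-written 5-atom PDB (4 protein + 1 water) used by io tests."""
    def atom(serial, name, resname, chain, resid, x, y, z, element):
        return (
            f"ATOM  {serial:>5} {name:<4} {resname:>3} {chain}{resid:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}\n"
        )

    lines = ["CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1\n"]
    lines.append(atom(1, " N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"))
    lines.append(atom(2, " CA", "ALA", "A", 1, 1.5, 0.0, 0.0, "C"))
    lines.append(atom(3, " C", "ALA", "A", 1, 2.2, 1.3, 0.0, "C"))
    lines.append(atom(4, " O", "ALA", "A", 1, 3.4, 1.4, 0.0, "O"))
    if include_hydrogen:
        lines.append(atom(5, " H", "ALA", "A", 1, -0.5, 0.9, 0.0, "H"))
    resname = "XYZ" if unknown_resname else "HOH"
    lines.append(atom(6, " O", resname, "W", 2, 8.0, 8.0, 8.0, "O"))
    if bad_line:
        lines.append("ATOM      7  CA  ALA A   3      not_a_number   0.0   0.0\n")
    lines.append("END\n")
    path.write_text("".join(lines))
    return path
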