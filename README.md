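# channelprobe

Trajectory analysis for anesthetic binding and gating metrics in pentameric
ligand-gated ion channels (pLGICs).

Molecular-dynamics studies of channels such as GLIC ask a recurring set of
quantitative questions: how often does a ligand contact each binding-region
residue, when does it bind and unbind and for how long, does the pore
constrict and dewet, do the pore-lining M2 helices tilt, where do the
ligands partition (water / membrane / protein), and what free-energy
barrier does an ion face along the pore? `channelprobe` implements this
analysis pipeline as a tested, reusable library with a CLI, together with a
synthetic toy-channel generator that provides exact ground truth for every
stage — so each estimator is validated against construction, closed forms,
or brute-force oracles rather than against the simulations it is meant to
analyse.

## What it computes

* **Contact probabilities** — a ligand contacts a residue when any ligand
  heavy atom is within 3.5 Å of any residue heavy atom (minimum-image).
  Per-residue, per-subunit percentages with cross-subunit mean and sample
  (n−1) SD, sampled every 1 ns until the full duration or until the ligand
  dissociates (> 5 Å from protein).
* **Binding events** — a hysteresis state machine (enter ≤ 3.5 Å to the
  site, exit > 5 Å from the whole protein) yielding residence times,
  named-pair distances (e.g. Tyr-254 hydroxyl to the ligand ether oxygen)
  and bound-ligand RMSF about the time-average structure; per-site
  occupancy count series with mean ± SD.
* **Pore geometry** — a HOLE-style accessible-radius profile
  r(z) = max_c min_i (|c − x_i| − r_vdw,i) along the channel axis, and the
  gate hydration count: water oxygens inside a 4 Å cylinder bounded by the
  9′/16′ Cβ ring planes, with the strict n < 5 dehydration flag.
* **Helix structure** — M2 tilt angles from three four-residue turns
  (centre-of-mass vectors vs the membrane normal), centered running
  averages, Kabsch superposition, and backbone RMSD over named ranges
  (Protein / ECD 14–192 / TMD 195–315 / Pore 221–244).
* **Phase partitioning** — per-frame ligand classification with precedence
  protein > membrane > aqueous, membrane width from leaflet phosphate
  planes, and aqueous molarity n/(N_A V).
* **Free energy** — 1-D WHAM over umbrella windows with bias ½k(z − z₀)²:
  self-consistent log-space iteration to a PMF −k_B T ln P(z), zeroed at a
  reference z, with barrier-height extraction.
* **Synthetic data** — a C5-symmetric toy pentamer (pore-lining rods, gate
  Cβ markers, binding-region pseudo-residues, phosphate slab, packed gate
  waters, ligand particles) and scripted trajectories whose events, tilts,
  hydration counts and phases are known exactly; plus a seeded Metropolis
  sampler over analytic 1-D potentials for umbrella windows.

## Worked example

```python
import numpy as np
from channelprobe import (
    ToyChannelSpec, build_toy_channel, EventScript, ScriptedBinding,
    script_trajectory, detect_binding_events, default_sites,
    hydration_series, membrane_width, pore_radius_profile,
)

spec = ToyChannelSpec(n_waters_in_gate=7)
topo, frame = build_toy_channel(spec)
script = EventScript(events=[ScriptedBinding(0, "TM2", "B", 30_000.0, 110_000.0)])
traj, truth = script_trajectory(topo, frame, script, n_frames=150, dt=1000.0,
                                hydration_program=[7]*90 + [3]*60, seed=11)

events = detect_binding_events(traj, topo.ligand_ids[0], default_sites()["TM2"])
for ev in events:
    print(f"event: site={ev.site_name} subunit={ev.subunit_id} "
          f"t={ev.t_start/1000:.0f}-{ev.t_end/1000:.0f} ns "
          f"residence={ev.residence_ns:.1f} ns rmsf={ev.rmsf:.2f} A")

hyd = hydration_series(traj)
print(f"gate dehydrated fraction: {hyd.dehydrated.mean():.2f} "
      f"(first dehydrated frame at t={hyd.times[hyd.dehydrated][0]/1000:.0f} ns)")

prof = pore_radius_profile(topo, frame, (-4.0, 4.0), 1.0,
                           axis=(np.zeros(3), np.array([0.0, 0.0, 1.0])))
print(f"pore radius across gate: {prof.radius.min():.2f}-{prof.radius.max():.2f} A")
print(f"membrane width: {membrane_width(topo, frame):.2f} A")
```

prints

```
event: site=TM2 subunit=B t=30-110 ns residence=80.0 ns rmsf=0.00 A
gate dehydrated fraction: 0.40 (first dehydrated frame at t=90 ns)
pore radius across gate: 3.31-3.32 A
membrane width: 37.31 A
```

The detector recovers the scripted 80 ns occupancy of the TM2 site in
subunit B exactly (and RMSF 0, since the script is noise-free); the gate
dewets at 90 ns when the hydration program drops below five waters; the
accessible pore radius equals the analytic cylinder value (ring radius
5 Å minus the 1.7 Å pseudo-atom van der Waals radius); and the phosphate
planes at ±18.655 Å give a 37.31 Å membrane width.

The same analyses run from the shell on PDB/DCD inputs:

```sh
channelprobe simulate --out demo --n-frames 50 --seed 3
channelprobe hydration --structure demo/system.pdb \
    --trajectory demo/trajectory.pdb --out hydration.csv
channelprobe pmf --windows win0.dat --windows win1.dat ... --out pmf.csv
```

See `docs/methods.md` for the conventions (cutoffs, turn windows, axis and
leaflet definitions, WHAM settings) and for what the synthetic fixtures do
and do not establish.

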