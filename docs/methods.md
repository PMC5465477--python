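# Methods

`channelprobe` analyses molecular-dynamics trajectories of pentameric
ligand-gated ion channels (pLGICs) interacting with small hydrophobic
ligands such as volatile anesthetics. This note records the models and
conventions the package implements, the choices made where a convention had
to be fixed, and what the synthetic-data generator does and does not
emulate.

## Coordinate and distance conventions

The channel's pore axis is z, with the extracellular side at high z by
default (axis orientation is configurable, and outputs echo the convention
in their headers). All distances are minimum-image under an orthorhombic
box, since membrane systems wrap in the xy plane; every distance-based
operation takes a flag to disable wrapping for pre-unwrapped trajectories.
Residues are addressed by author (PDB) numbering; a built-in alias table
maps the pLGIC prime notation onto it (−2′ → 222, 9′ → 233, 16′ → 240).

## Contact probability

A ligand is in contact with a residue when any ligand heavy atom lies
within 3.5 Å of any heavy atom of the residue. The boundary is inclusive
(≤): the criterion must be fixed one way for reproducibility and the
inclusive choice makes the stated cutoff itself count. Heavy atoms only is
the default because the hydrogen placement of a force field is not part of
the structural signal; a flag includes hydrogens for comparison with
analyses that counted "any atom". Probabilities are reported per residue
and subunit in percent of sampled frames (default sampling every 1 ns),
either over the full trajectory or only until the ligand dissociates (first
sampled frame with minimum ligand–protein distance > 5 Å). Cross-subunit
aggregation uses the arithmetic mean and the **sample** (n − 1) standard
deviation over the five subunits; the n − 1 convention is what reproduces
published channel contact tables, and the package's acceptance suite checks
it digit-for-digit against one.

Each subunit is paired with the ligand nearest its site at the first
sampled frame. Ties are resolved to the first ligand in topology order and
logged. This matters only when several ligands crowd one subunit.

## Binding events, residence times, RMSF

Event detection is a per-(ligand, subunit) hysteresis state machine: an
event opens at the first frame where the minimum distance from the ligand
to a subunit's site atoms is ≤ the enter cutoff (3.5 Å), and closes at the
first frame where the minimum distance to the *whole protein* exceeds the
dissociation cutoff (5 Å). The asymmetric pair suppresses boundary flicker;
events shorter than 2 frames are discarded by default (both choices are
package conventions — single-frame grazing contacts are not interpretable
as occupancy at typical frame spacings). A ligand contacting two subunits
is assigned to the subunit with the minimum distance; ties are logged.
Residence is simply t_end − t_start, so on a scripted trajectory with known
intervals the detector is exact to within one frame interval per boundary.

Bound-ligand RMSF uses the time-average ligand structure over the event as
reference (samples every 0.2 ns by default), with no superposition — the
fluctuation is measured in the lab frame — and is root-mean-squared over
atoms and samples. For isotropic Gaussian positional noise of width σ the
expected value is √3·σ, which the test suite uses as a closed-form oracle.

Replicate-level event tables report the total event count plus residence
statistics under both the event-weighted and the replicate-weighted
convention, because rounded published tables cannot disambiguate which was
used.

## Pore geometry and gate hydration

The pore profiler is a deterministic HOLE-style construction. At each z
along the axis the accessible radius is max over candidate centres c of
min over protein atoms i of (|c − x_i| − r_vdw,i), clamped at zero. In
`on-axis` mode c is fixed on the axis; `in-plane-search` mode maximizes
over the plane within 5 Å of the axis using a coarse 0.5 Å grid followed by
Nelder–Mead refinement — deterministic by construction (no Monte Carlo),
and it can only increase the radius relative to on-axis. Van der Waals
radii come from a fixed element table (C 1.7, N 1.55, O 1.52, S 1.8,
H 1.2 Å, …) with a config override.

The pore axis is the total-least-squares line through the per-residue ring
centroids of the pore-lining (M2) helices: for a C5-symmetric channel each
five-subunit centroid lies on the symmetry axis exactly, which makes the
fit robust to rigid-body rotation of the whole system (recovered to < 0.1°
for a 10° rotated fixture). A fallback takes z through the protein
centroid.

Gate hydration counts water **oxygens** (one counting atom per molecule
avoids multiple counting) inside a cylinder of radius 4 Å whose axial band
is bounded by the mean axial coordinate of the five 9′ Cβ atoms and of the
five 16′ Cβ atoms. The band is re-measured every frame (the gate breathes),
and the cylinder is re-centred per frame unless a fixed axis is supplied.
Using ring means rather than per-subunit Cβ pairs is a deliberate choice
for C5 robustness. A frame is dehydrated when the count is **strictly**
fewer than the threshold (default 5): exactly five waters is hydrated.

## Helix tilt and structure comparison

M2 tilt is measured from three four-residue turns (intracellular, middle,
extracellular). Each turn is reduced to the mass-weighted centre of mass of
its backbone atoms (N, Cα, C, O); the bottom vector runs intracellular →
middle and the top vector middle → extracellular, and each is measured
against the membrane normal (z by default, configurable for tilted boxes).
The default turn windows 222–225 / 230–233 / 237–240 span the −2′..16′
region of M2; they are an explicit package convention, echoed in every
output header, since the exact choice of turns is not standardized.

Superposition is the closed-form Kabsch solution (SVD with the determinant
correction, proper rotations only); collinear selections are rejected as
degenerate. RMSD reports sample frames every 0.1 ns over the last 20 ns by
default and superpose each named range (Protein; ECD 14–192; TMD 195–315;
pore 221–244) on its own backbone selection before measuring, reporting
mean ± sample SD.

Running averages are centered moving means with truncated edge windows, so
constants are unchanged and linear ramps are preserved in the interior.

## Phase partitioning and molarity

Per frame, each ligand is classified with strict precedence
protein > membrane > aqueous: *protein* when any ligand atom lies within
3.5 Å (the contact cutoff, reused for consistency) of a protein heavy atom;
otherwise *membrane* when the ligand centre of mass sits between the mean
phosphate z planes of the two leaflets (re-measured per frame); otherwise
*aqueous*. The phosphate-plane boundary is a package convention — there is
no community-standard membrane/aqueous divider — and is recorded in output
metadata. Membrane width is the distance between the two leaflet planes,
with leaflets assigned by sign of z about the marker centroid.

Aqueous molarity is n/(N_A·V) converted to mmol/L with
N_A = 6.02214 × 10²³. The aqueous volume is user-supplied, or optionally
estimated as box volume − membrane slab − protein convex hull above the
slab; the estimate is labelled approximate and is only a rough scale for
concentration fluctuation plots.

## Umbrella sampling and WHAM

Umbrella windows carry a harmonic bias ½k(z − z₀)² with k in kcal/mol/Å²
(half-k convention; a full-k flag exists because restraint conventions
differ between MD engines). Window files are plain text: a
`# center=<z0> k=<k>` header and one z sample per line. Burn-in defaults to
discarding the first 5 % of samples per window, mirroring the common
retain-the-last-95 % protocol (e.g. keeping 9.5 ns of a 10 ns window).

`wham_solve` iterates the standard self-consistent WHAM equations in log
space (bin probabilities from bias-weighted counts, then window free-energy
constants from the unbiased distribution), with `logsumexp` throughout so
steep potentials (hundreds of kcal/mol across the range) remain stable.
Defaults: bin width 0.1 Å, tolerance 10⁻⁶ kcal/mol on the largest
per-iteration change in window constants, 10⁵ iteration cap,
k_B = 0.0019872 kcal/mol/K, T = 298 K. Adjacent windows must share at least
one occupied bin; a gap is reported naming the pair. The profile is
−k_B T ln P(z) shifted so the value at the reference z (interpolated
between bins) is exactly zero.

The validation suite reconstructs analytic potentials from 50 windows at
1 Å spacing with k = 7.17 kcal/mol/Å² and 10⁴ samples per window — the
published ion-translocation window layout at a desk-scale sample count —
and requires ≤ 0.1 kcal/mol RMSD over the central 80 % of the covered range
for flat and harmonic truths and a 3 kcal/mol double-well barrier recovered
within 0.15 kcal/mol. The statistical floor of this configuration with
independent samples is ≈ 0.06 kcal/mol, dominated by the accumulation of
window-to-window free-energy errors across 50 windows, so the criterion is
demanding but attainable with well-decorrelated samples.

## Synthetic data: what it is and is not

The toy channel is a C5-symmetric arrangement of *vertical pseudo-helical
rods* (one pseudo-atom per residue) around z: a pore-lining M2 rod per
subunit whose atoms sit at ring radius `pore_radius`, Cβ gate markers at
the 9′/16′ z positions, the 13-residue intrasubunit binding region and the
TM2 hydroxyl/amide partner atoms on outer shells, phosphate markers at
±18.655 Å (producing the 37.31 Å converged membrane width used as a
fixture), waters packed in the gate at a 2.8 Å exclusion, and single-atom
ligand particles. All pseudo-atoms share a carbon-like 1.7 Å van der Waals
radius so the pore-radius oracle is the analytic cylinder
`pore_radius − 1.7`.

Trajectories are **scripted, not simulated**: binding intervals, per-subunit
tilt programs (rigid rotation of each rod about its centroid), gate
hydration counts and ligand phase labels are imposed exactly, with optional
Gaussian positional noise on ligands, and the ground truth is serialized
alongside the frames. With zero noise every scripted quantity is recovered
exactly by the corresponding analysis; with noise, event boundaries are
recovered to within one frame interval. Seeded runs are bit-reproducible.

The umbrella-window sampler is a random-walk Metropolis chain over
U(z) + bias. The proposal width defaults to ~2.4 standard deviations of the
bias-dominated target (near-optimal random-walk scaling) and ten updates
are performed per recorded sample, so recorded samples are effectively
decorrelated; all windows advance in lock-step from one seeded stream, so
a window set is reproducible from a single integer.

None of this has physical realism: no lipid tails, no electrostatics, no
solvent structure, no protein flexibility beyond the scripted rigid
motions. Passing tests therefore demonstrate that the *measurement
operations* are correct (geometry, counting, state machines, estimators,
WHAM inversion), not that any biological conclusion holds; quantities that
require the real channel's trajectories (explored ligand volumes, actual
pore contractions, translocation barrier magnitudes, occupancy means of
specific mutants) are outside what a synthetic fixture can certify and are
deliberately not asserted anywhere.

## Numerical and degenerate-input choices

* Contact/boundary tests are inclusive (≤ cutoff).
* `aggregate_subunits` requires exactly five values; fewer is an error, not
  a silent partial mean.
* Events still open at the final frame are closed there; events shorter
  than the minimum duration are dropped, not merged.
* Empty atom selections, non-positive boxes, non-monotone frame times,
  atom-count mismatches (named by frame), unknown residue names (listed by
  name) and unparseable records (named by line) all raise immediately.
* Kabsch rejects collinear selections; the pore profiler clamps negative
  accessible radii at zero; WHAM raises on window gaps and non-convergence
  rather than returning a partial profile.

## Problem sizes used in the validation suites

Scripted-trajectory checks use 100–500 frames on a ~400-atom toy pentamer;
the WHAM suite uses 50 windows × 10⁴ samples; the hydration oracle sweeps
100 randomized fixtures. These sizes keep every oracle exact or
closed-form while exercising the full code paths end to end.
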