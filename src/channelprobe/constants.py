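"""Physical constants, element tables, and built-in channel conventions."""

from __future__ import annotations

#: Boltzmann constant in kcal/mol/K (CHARMM-style unit system).
BOLTZMANN_KCAL = 0.0019872

#: Avogadro's number, 1/mol.
AVOGADRO = 6.02214e23

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 298.0

#: Van der Waals radii in Angstrom, by element symbol. Values are the common
#: Bondi-style table used by pore profilers; override via function arguments
#: where a different table is needed.
VDW_RADII = {
    "H": 1.2,
    "D": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "F": 1.47,
    "Cl": 1.75,
    "Na": 2.27,
    "K": 2.75,
}
VDW_DEFAULT = 1.7

ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "Cl": 35.45,
    "Na": 22.990,
    "K": 39.098,
}
MASS_DEFAULT = 12.011

#: Prime-notation aliases for pore-lining (M2) positions of the GLIC channel.
#: -2' is the intracellular ring of glutamates (selectivity filter), 9' and
#: 16' bound the hydrophobic gate.
PRIME_ALIASES = {"-2'": 222, "9'": 233, "16'": 240}

#: Residues of the intrasubunit (TM1) anesthetic binding region.
TM1_RESIDUES = (119, 120, 121, 197, 201, 202, 205, 206, 242, 254, 255, 258, 307)

#: Residues of the membrane-facing TM2 site (hydroxyl / amide partners).
TM2_RESIDUES = (254, 307)

#: Pore-lining M2 helix residue span used for axis fitting and tilt turns.
M2_RESIDUE_RANGE = (222, 245)

#: Default four-residue turns (intracellular, middle, extracellular) used for
#: M2 tilt vectors. These span the -2'..16' region; they are a package
#: convention, echoed in output headers.
DEFAULT_TILT_TURNS = ((222, 223, 224, 225), (230, 231, 232, 233), (237, 238, 239, 240))

#: Named backbone-RMSD ranges (author numbering).
DEFAULT_RMSD_RANGES = {
    "Protein": None,  # all protein residues
    "ECD": (14, 192),
    "TMD": (195, 315),
    "Pore": (221, 244),
}

BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")
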