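"""Bundled van der Waals radius table.

Radii are the Bondi (1964) compilation with the common extensions used by
surface-area programs (Rowland & Taylor 1996 for halogens; alkali/alkaline
earth ions from Bondi). Values are in Angstrom and are keyed by element
symbol in title case. Callers may override any entry through the
``radii_override`` argument of the parsers, so the bundled table is a
default, not a constraint.
"""

from __future__ import annotations

# element symbol -> vdW radius (Å)
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Se": 1.90,
    "B": 1.92,
    "Li": 1.82,
    "Na": 2.27,
    "K": 2.75,
    "Rb": 3.03,
    "Cs": 3.43,
    "Mg": 1.73,
    "Ca": 2.31,
    "Sr": 2.49,
    "Ba": 2.68,
    "Mn": 2.05,
    "Fe": 2.05,
    "Co": 2.00,
    "Ni": 1.63,
    "Cu": 1.40,
    "Zn": 1.39,
    "Cd": 1.58,
    "Hg": 1.55,
}

# Residue names of common monatomic ions as deposited in the PDB.
MONATOMIC_ION_RESNAMES: frozenset[str] = frozenset(
    {
        "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU", "CU1",
        "LI", "RB", "CS", "BR", "F", "IOD", "CD", "HG", "NI", "CO", "SR",
        "BA", "PB", "AU", "AG",
    }
)

WATER_RESNAMES: frozenset[str] = frozenset(
    {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "TIP4", "SOL", "SPC"}
)

# Standard amino acids plus the frequent modified residues that still carry
# a CA atom in deposited models.
AMINO_ACID_RESNAMES: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "MSE", "SEC", "PYL",
    }
)


def vdw_radius(element: str, override: dict[str, float] | None = None) -> float | None:
    """Radius for ``element`` (any capitalisation), or None when unknown."""
    key = element.capitalize()
    if override and key in override:
        return override[key]
    return VDW_RADII.get(key)
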