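"""Component-code vocabulary for N-glycan curation.

PDB three-letter codes for the monosaccharides handled by the package, the
anomer each code declares, and the residue classes used throughout the
pipeline (which compounds count as carbohydrate, which may be parked and
restored, which are amino acids).
"""
from __future__ import annotations

#: beta-anomeric pyranoses (by declared component code)
BETA_COMPS = {"NAG", "BMA", "FUL", "BGC", "GAL", "XYP"}
#: alpha-anomeric pyranoses
ALPHA_COMPS = {"NDG", "MAN", "FUC", "GLC"}

#: all pyranose codes with a ring O5,C1..C5 this package validates and builds
PYRANOSES = BETA_COMPS | ALPHA_COMPS

#: L-sugars: in the canonical O5,C1..C5 atom order their preferred chair is
#: inverted (1C4), so the pucker pole flips (theta near 180 instead of 0).
L_SUGARS = {"FUC", "FUL"}

#: carbohydrate codes recognised when walking trees; includes chitobiose and
#: the odd inverted-chirality GlcNAc/Gal analogues occasionally deposited.
CARB_COMPS = PYRANOSES | {"CBS", "LXZ", "NGA", "GL0", "GCU", "SIA"}

#: unlinked single carbohydrates that may be temporarily deleted while
#: building; deliberately restricted to the common N-glycan residue types so
#: genuine carbohydrate ligands are never touched.
PARKABLE_COMPS = {"NAG", "NDG", "MAN", "BMA", "FUC", "FUL"}

WATER_COMPS = {"HOH", "DOD", "WAT"}

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")

#: one-letter codes for sequon scanning
ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


def declared_anomer(comp_id: str) -> str | None:
    """'alpha'/'beta' from the component code, None for non-pyranoses."""
    if comp_id in ALPHA_COMPS:
        return "alpha"
    if comp_id in BETA_COMPS:
        return "beta"
    return None


def is_carbohydrate(comp_id: str) -> bool:
    return comp_id in CARB_COMPS


def is_water(comp_id: str) -> bool:
    return comp_id in WATER_COMPS


def is_amino_acid(comp_id: str) -> bool:
    return comp_id in AMINO_ACIDS
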