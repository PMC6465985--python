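"""Idealized monosaccharide templates in a canonical chair frame.

Each supported pyranose is constructed analytically, once, from an ideal
chair ring (regular hexagon with alternating out-of-plane displacements,
which is the 4C1 chair for D-sugars in the canonical O5, C1..C5 atom order)
plus axial/equatorial substituents placed with tetrahedral geometry. The
axial/equatorial pattern per component encodes its stereochemistry
(e.g. mannose has an axial O2, galactose an axial O4, the beta anomer an
equatorial O1 in 4C1). L-sugars (FUC, FUL) are built as the mirror image of
the corresponding D-configured 6-deoxy-galactose, which simultaneously
inverts every stereocenter and turns the chair into 1C4.

The template's "O1" atom marks the glycosidic attachment direction at C1 and
is stripped when a residue is placed (it is the leaving atom of the
condensation reaction); all other heavy atoms of the residue are present.
"""
from __future__ import annotations

import functools

import numpy as np

from .geom import rotation_about_axis, tetrahedral_directions, unit
from .model import AtomRecord, ResidueRecord

RING_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")
_Z0 = 0.25
_RING_BOND = 1.52
_CO = 1.43
_CN = 1.45
_CC = 1.52

# axial/equatorial patterns, in the D-configured 4C1 frame.
# entries: substituent atom name on ring carbon -> 'ax' | 'eq'
_D_PATTERNS: dict[str, dict[str, str]] = {
    # beta-D-GlcNAc: everything equatorial
    "NAG": {"O1": "eq", "N2": "eq", "O3": "eq", "O4": "eq", "C6": "eq"},
    # alpha-D-GlcNAc
    "NDG": {"O1": "ax", "N2": "eq", "O3": "eq", "O4": "eq", "C6": "eq"},
    # beta-D-mannose: axial O2
    "BMA": {"O1": "eq", "O2": "ax", "O3": "eq", "O4": "eq", "C6": "eq"},
    # alpha-D-mannose
    "MAN": {"O1": "ax", "O2": "ax", "O3": "eq", "O4": "eq", "C6": "eq"},
    # beta-D-glucose
    "BGC": {"O1": "eq", "O2": "eq", "O3": "eq", "O4": "eq", "C6": "eq"},
    # alpha-D-glucose
    "GLC": {"O1": "ax", "O2": "eq", "O3": "eq", "O4": "eq", "C6": "eq"},
    # beta-D-galactose: axial O4
    "GAL": {"O1": "eq", "O2": "eq", "O3": "eq", "O4": "ax", "C6": "eq"},
    # beta-D-xylose: no C6
    "XYP": {"O1": "eq", "O2": "eq", "O3": "eq", "O4": "eq"},
    # 6-deoxy-D-galactose frames, mirrored below into the L-fucoses
    "_FUC_D": {"O1": "ax", "O2": "eq", "O3": "eq", "O4": "ax", "C6": "eq"},
    "_FUL_D": {"O1": "eq", "O2": "eq", "O3": "eq", "O4": "ax", "C6": "eq"},
}

#: components whose template is the mirror image of a D-configured frame
_MIRRORED = {"FUC": "_FUC_D", "FUL": "_FUL_D"}

SUPPORTED_COMPS = tuple(c for c in _D_PATTERNS if not c.startswith("_")) + tuple(_MIRRORED)


def _ideal_ring() -> dict[str, np.ndarray]:
    r = np.sqrt(_RING_BOND ** 2 - 4 * _Z0 ** 2)
    coords = {}
    for k, name in enumerate(RING_NAMES):
        t = np.radians(60.0 * k)
        coords[name] = np.array([r * np.cos(t), r * np.sin(t), _Z0 * (-1.0) ** k])
    return coords


def _substituent(coords: dict[str, np.ndarray], k: int, kind: str, length: float) -> np.ndarray:
    """Position of an axial or equatorial substituent on ring atom k."""
    center = coords[RING_NAMES[k]]
    prev_ = coords[RING_NAMES[(k - 1) % 6]]
    next_ = coords[RING_NAMES[(k + 1) % 6]]
    d1, d2 = tetrahedral_directions(center, prev_, next_)
    # axial = the direction more parallel to the ring axis (z in this frame)
    if abs(d1[2]) >= abs(d2[2]):
        ax, eq = d1, d2
    else:
        ax, eq = d2, d1
    d = ax if kind == "ax" else eq
    return center + length * d


def _build_frame(pattern: dict[str, str]) -> dict[str, np.ndarray]:
    coords = _ideal_ring()
    ring_carbon = {"O1": 1, "O2": 2, "N2": 2, "O3": 3, "O4": 4, "C6": 5}
    lengths = {"O1": _CO, "O2": _CO, "O3": _CO, "O4": _CO, "N2": _CN, "C6": _CC}
    for name, kind in pattern.items():
        coords[name] = _substituent(coords, ring_carbon[name], kind, lengths[name])
    if "C6" in coords:
        # exocyclic O6: extend from C6 away from C5, tilted toward gauche
        c5, c6 = coords["C5"], coords["C6"]
        d = unit(c6 - c5)
        axis = unit(np.cross(d, np.array([0.0, 0.0, 1.0])))
        rot = rotation_about_axis(axis, 112.0)
        if pattern is not _D_PATTERNS.get("_FUC_D") and pattern is not _D_PATTERNS.get("_FUL_D"):
            coords["O6"] = c6 + _CO * (rot @ d)
    if "N2" in coords:
        # planar acetamido group on N2
        c2, n2 = coords["C2"], coords["N2"]
        d = unit(n2 - c2)
        axis = unit(np.cross(d, np.array([0.0, 0.0, 1.0])))
        c7_dir = rotation_about_axis(axis, 122.0) @ d
        c7 = n2 + 1.33 * c7_dir
        in_plane = unit(np.cross(axis, c7_dir))
        coords["C7"] = c7
        coords["O7"] = c7 + 1.23 * unit(0.5 * c7_dir + 0.87 * in_plane)
        coords["C8"] = c7 + 1.50 * unit(0.5 * c7_dir - 0.87 * in_plane)
    return coords


@functools.lru_cache(maxsize=None)
def get_template(comp_id: str) -> dict[str, np.ndarray]:
    """Atom name -> ideal position for a supported pyranose (O1 included)."""
    if comp_id in _MIRRORED:
        frame = _build_frame(_D_PATTERNS[_MIRRORED[comp_id]])
        return {n: p * np.array([1.0, 1.0, -1.0]) for n, p in frame.items()}
    if comp_id not in _D_PATTERNS or comp_id.startswith("_"):
        raise KeyError(f"no template for component {comp_id!r}")
    return _build_frame(_D_PATTERNS[comp_id])


_ELEMENT = {"O": "O", "C": "C", "N": "N"}


def template_residue(comp_id: str, chain_id: str = "A", seq_num: int = 1,
                     b: float = 30.0, include_o1: bool = False) -> ResidueRecord:
    """A ResidueRecord built from the ideal template (in the template frame)."""
    tpl = get_template(comp_id)
    atoms = []
    for name, pos in tpl.items():
        if name == "O1" and not include_o1:
            continue
        atoms.append(AtomRecord(name=name, element=_ELEMENT[name[0]],
                                pos=pos.copy(), occ=1.0, b=b))
    return ResidueRecord(chain_id=chain_id, seq_num=seq_num, comp_id=comp_id, atoms=atoms)
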