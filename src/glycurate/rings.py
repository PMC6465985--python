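"""Pyranose ring-pucker analysis and three-tier quality status.

The Cremer-Pople decomposition expresses the out-of-plane displacements of a
six-membered ring as a total amplitude Q and spherical-polar angles
(theta, phi). With ring atoms taken in the canonical O5, C1..C5 order, a
D-pyranose in the ideal 4C1 chair gives theta = 0 and the inverted 1C4 chair
gives theta = 180. L-sugars (FUC, FUL) prefer 1C4 in this atom order, so
their ideal theta is near 180.

The three-tier status ('yes'/'check'/'no') emulates the decision surface this
pipeline consumes from carbohydrate validation: ring completeness, a chair
window on theta, and agreement of the geometric anomeric configuration at C1
with the configuration the component code declares. The theta windows
(<=30 deg chair, 30-45 deg borderline; mirrored around 180 for L-sugars) are
a convention of this package, chosen so that ideal chairs and the puckers
observed for well-built sugars fall squarely in 'yes'.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import chem
from .geom import unit
from .model import AtomRecord, ResidueRecord

RING_ATOM_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")


class IncompleteRingError(ValueError):
    """A required ring atom is missing from the residue."""


class DegeneratePuckerError(ValueError):
    """Ring geometry is degenerate (planar/collinear); theta is undefined."""


@dataclasses.dataclass
class RingPucker:
    Q: float
    theta: float | None  # degrees in [0, 180]; None when Q ~ 0
    phi: float | None    # degrees in [0, 360)

    @property
    def defined(self) -> bool:
        return self.theta is not None


@dataclasses.dataclass
class RingStatus:
    status: str  # 'yes' | 'check' | 'no'
    reasons: list[str] = dataclasses.field(default_factory=list)


def pick_ring_atoms(residue: ResidueRecord) -> list[AtomRecord]:
    """The six ring atoms in canonical order; raises if any is absent."""
    atoms = []
    missing = []
    for name in RING_ATOM_ORDER:
        a = residue.atom(name)
        if a is None:
            missing.append(name)
        else:
            atoms.append(a)
    if missing:
        raise IncompleteRingError(f"{residue}: missing ring atoms {missing}")
    return atoms


def ring_normal(coords: np.ndarray) -> np.ndarray:
    """Mean-plane normal of the Cremer-Pople construction (unit vector)."""
    coords = np.asarray(coords, dtype=float)
    center = coords.mean(axis=0)
    rel = coords - center
    n = len(coords)
    j = np.arange(n)
    r1 = (rel * np.sin(2 * np.pi * j / n)[:, None]).sum(axis=0)
    r2 = (rel * np.cos(2 * np.pi * j / n)[:, None]).sum(axis=0)
    # orientation chosen so that the ideal 4C1 chair in canonical atom order
    # (O5 displaced +z, neighbours alternating) yields theta = 0
    nvec = np.cross(r2, r1)
    nn = np.linalg.norm(nvec)
    if nn < 1e-9:
        raise DegeneratePuckerError("degenerate ring: cannot define mean plane")
    return nvec / nn


def cremer_pople(coords: np.ndarray) -> RingPucker:
    """Cremer-Pople puckering parameters for a six-membered ring.

    ``coords`` is a (6, 3) array in the canonical O5, C1..C5 order. The
    mean-plane displacements z_j sum to zero by construction. For the planar
    ring Q = 0 and theta/phi are undefined (returned as None).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (6, 3):
        raise ValueError("cremer_pople expects six ring atom positions")
    center = coords.mean(axis=0)
    rel = coords - center
    nvec = ring_normal(coords)
    z = rel @ nvec
    # assert the mean-plane property (analytic; guards against bad input)
    assert abs(z.sum()) < 1e-8

    n = 6
    j = np.arange(n)
    q2cos = np.sqrt(2.0 / n) * np.sum(z * np.cos(4 * np.pi * j / n))
    q2sin = -np.sqrt(2.0 / n) * np.sum(z * np.sin(4 * np.pi * j / n))
    q3 = np.sqrt(1.0 / n) * np.sum(z * (-1.0) ** j)
    q2 = np.hypot(q2cos, q2sin)
    Q = float(np.hypot(q2, q3))
    if Q < 1e-6:
        return RingPucker(Q=Q, theta=None, phi=None)
    theta = float(np.degrees(np.arccos(np.clip(q3 / Q, -1.0, 1.0))))
    phi = float(np.degrees(np.arctan2(q2sin, q2cos))) % 360.0
    return RingPucker(Q=Q, theta=theta, phi=phi)


def residue_pucker(residue: ResidueRecord) -> RingPucker:
    atoms = pick_ring_atoms(residue)
    return cremer_pople(np.array([a.pos for a in atoms]))


def geometric_anomer(residue: ResidueRecord,
                     substituent_pos: np.ndarray | None = None) -> str | None:
    """'alpha' or 'beta' from geometry, or None when it cannot be determined.

    The anomeric configuration is read off as the cis/trans relation, across
    the ring mean plane, between the exocyclic substituent at C1 (the
    glycosidic O/N, or O1 on an unlinked sugar) and the C5 -> C6 bond that
    defines the sugar's reference configuration: same side = beta, opposite
    side = alpha. This definition is chirality-safe, i.e. it holds for both D-
    and L-sugars. Residues without a modeled C6 (e.g. xylose) or without a
    resolvable C1 substituent return None.
    """
    try:
        atoms = pick_ring_atoms(residue)
    except IncompleteRingError:
        return None
    coords = np.array([a.pos for a in atoms])
    c1 = coords[1]
    c5 = coords[5]
    c6 = residue.atom("C6")
    if c6 is None:
        return None
    if substituent_pos is None:
        o1 = residue.atom("O1") or residue.atom("O1L")
        if o1 is None:
            return None
        substituent_pos = o1.pos
    try:
        nvec = ring_normal(coords)
    except DegeneratePuckerError:
        return None
    s_sub = float(np.dot(unit(np.asarray(substituent_pos, float) - c1), nvec))
    s_ref = float(np.dot(unit(c6.pos - c5), nvec))
    if abs(s_sub) < 1e-6 or abs(s_ref) < 1e-6:
        return None
    return "beta" if s_sub * s_ref > 0 else "alpha"


# theta windows: (chair_max, borderline_max) for D-frame sugars; L-sugars
# (FUC/FUL) use the mirrored windows around 180 degrees.
CHAIR_MAX = 30.0
BORDERLINE_MAX = 45.0


def assign_status(residue: ResidueRecord,
                  pucker: RingPucker | None,
                  expected_anomer: str | None = None,
                  substituent_pos: np.ndarray | None = None) -> RingStatus:
    """Three-tier ring quality status.

    'yes'   - complete ring, chair-region theta, anomer as declared;
    'check' - chair test fails softly (theta in the borderline band);
    'no'    - incomplete ring, undefined pucker, non-chair conformation or an
              anomer mismatch.
    """
    reasons: list[str] = []
    if pucker is None:
        return RingStatus("no", ["incomplete-ring"])
    if not pucker.defined:
        return RingStatus("no", ["undefined-pucker"])

    inverted = residue.comp_id in chem.L_SUGARS
    theta_eff = 180.0 - pucker.theta if inverted else pucker.theta
    chair_ok = theta_eff <= CHAIR_MAX
    borderline = CHAIR_MAX < theta_eff < BORDERLINE_MAX
    if not chair_ok:
        reasons.append("conformation")

    anomer_ok = True
    if expected_anomer is not None:
        observed = geometric_anomer(residue, substituent_pos)
        if observed is not None and observed != expected_anomer:
            anomer_ok = False
            reasons.append("anomer")

    if chair_ok and anomer_ok:
        return RingStatus("yes", [])
    if borderline and anomer_ok:
        return RingStatus("check", reasons or ["conformation"])
    return RingStatus("no", reasons)


def validate_residue(residue: ResidueRecord,
                     expected_anomer: str | None = None,
                     substituent_pos: np.ndarray | None = None) -> tuple[RingPucker | None, RingStatus]:
    """Convenience wrapper: pucker + status, folding missing-atom errors into 'no'."""
    try:
        pucker = residue_pucker(residue)
    except IncompleteRingError:
        return None, RingStatus("no", ["incomplete-ring"])
    except DegeneratePuckerError:
        return None, RingStatus("no", ["undefined-pucker"])
    if expected_anomer is None:
        expected_anomer = chem.declared_anomer(residue.comp_id)
    return pucker, assign_status(residue, pucker, expected_anomer, substituent_pos)
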