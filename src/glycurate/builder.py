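"""Template-based carbohydrate placement and greedy tree extension.

Single residues are placed by rigid attachment of an idealized monosaccharide
template to the parent's attachment atom: the anomeric carbon C1 is
positioned at ideal bond geometry from the parent oxygen (or the asparagine
ND2 for the root link), and a small set of candidate glycosidic torsion pairs
(phi, psi) is enumerated, each locally refined on a coarse grid. The
candidate whose atoms sit in the highest mean density wins; it is accepted
when the fit clears a (deliberately permissive) sigma threshold and does not
clash with existing atoms — the stringent density filters are applied later
by the curation pipeline.

Tree extension walks the selected tree type breadth-first over the open
attachment slots of already-present residues, placing one residue at a time
and stopping when every possibility has been attempted. Traversal order is
deterministic: core positions before branches, position 4 before 3 before 6,
fucoses last.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial import cKDTree

from .density import DensityMap
from .geom import place_atom, rotation_about_axis, torsion_deg, unit
from .model import AtomRecord, LinkRecord, ResidueKey, ResidueRecord, StructureModel
from .templates import get_template, template_residue
from .topology import GlycanEdge, GlycanTree, TreeTypeDef, TypeNode

log = logging.getLogger(__name__)

GLYCOSIDIC_BOND = 1.43       # O-C1 (and N-C1) bond length, A
GLYCOSIDIC_ANGLE = 116.0     # C1-O-C angle at the linkage oxygen, deg
LOCAL_FIT_THRESHOLD = 0.6    # sigma; permissive local gate
HARD_CLASH = 2.1             # A, to any existing non-parent atom

#: candidate glycosidic torsions; phi follows the exo-anomeric preference of
#: the anomer, psi scans the ring orientation.
PHI_CANDIDATES = {"alpha": (70.0, 90.0), "beta": (-70.0, -90.0)}
PSI_CANDIDATES = (180.0, 120.0, 60.0, -60.0, -120.0, 0.0)
REFINE_SPAN = 20.0
REFINE_STEP = 10.0


class PlacementImpossible(ValueError):
    """The parent lacks the atoms needed to attach a child residue."""


@dataclasses.dataclass
class PlacementResult:
    residue: ResidueRecord | None
    fit: float
    accepted_locally: bool
    phi: float | None = None
    psi: float | None = None


def _attachment_frame(parent: ResidueRecord, position: int | str):
    """(attachment atom, its bearer carbon, torsion reference atom)."""
    if position == "N":
        names = ("ND2", "CG", "CB")
    elif position == 6:
        names = ("O6", "C6", "C5")
    else:
        p = int(position)
        names = (f"O{p}", f"C{p}", f"C{p - 1}" if p > 1 else "O5")
    atoms = [parent.atom(n) for n in names]
    if any(a is None for a in atoms):
        raise PlacementImpossible(
            f"{parent}: missing attachment atoms {[n for n, a in zip(names, atoms) if a is None]}")
    return atoms


def _place_template(comp_id: str, ox: np.ndarray, cx: np.ndarray, ref: np.ndarray,
                    phi: float, psi: float) -> dict[str, np.ndarray]:
    """Transform the ideal template so C1 bonds the attachment atom.

    psi is the torsion C1-Ox-Cx-ref; phi is the torsion O5-C1-Ox-Cx
    (the classic glycosidic phi when ref follows the standard convention).
    """
    c1_new = place_atom(ref, cx, ox, GLYCOSIDIC_BOND, GLYCOSIDIC_ANGLE, psi)
    tpl = get_template(comp_id)
    c1_t, o1_t, o5_t = tpl["C1"], tpl["O1"], tpl["O5"]
    # rotate template so its C1->O1 direction matches C1->Ox
    v_from = unit(o1_t - c1_t)
    v_to = unit(ox - c1_new)
    axis = np.cross(v_from, v_to)
    if np.linalg.norm(axis) < 1e-9:
        rot1 = np.eye(3) if np.dot(v_from, v_to) > 0 else \
            rotation_about_axis(_any_perpendicular(v_from), 180.0)
    else:
        ang = np.degrees(np.arccos(np.clip(np.dot(v_from, v_to), -1, 1)))
        rot1 = rotation_about_axis(axis, ang)
    placed = {n: rot1 @ (p - c1_t) + c1_new for n, p in tpl.items()}
    # spin about the C1-Ox axis to set phi
    cur_phi = torsion_deg(placed["O5"], c1_new, ox, cx)
    rot2 = rotation_about_axis(ox - c1_new, phi - cur_phi)
    placed = {n: rot2 @ (p - c1_new) + c1_new for n, p in placed.items()}
    del placed["O1"]
    return placed


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    e = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, e))


_ELEMENT = {"O": "O", "C": "C", "N": "N"}


def _as_residue(comp_id: str, coords: dict[str, np.ndarray],
                chain_id: str, seq_num: int, b: float) -> ResidueRecord:
    atoms = [AtomRecord(n, _ELEMENT[n[0]], p.copy(), 1.0, b) for n, p in coords.items()]
    return ResidueRecord(chain_id, seq_num, comp_id, atoms)


def place_residue(parent: ResidueRecord, production: TypeNode | tuple,
                  map_obs: DensityMap, model: StructureModel | None = None,
                  fit_threshold: float = LOCAL_FIT_THRESHOLD,
                  exclude_keys: set[ResidueKey] | None = None,
                  b_new: float = 30.0) -> PlacementResult:
    """Best-fitting placement of one carbohydrate residue on ``parent``.

    ``production`` carries (position, comp, anomer) — a TypeNode or a plain
    (position, comp, anomer) tuple. ``map_obs`` should be sigma-normalized.
    ``model`` provides the clash environment (atoms of the parent residue and
    of residues in ``exclude_keys`` are ignored).
    """
    if isinstance(production, tuple):
        position, comp_id, anomer = production
    else:
        position, comp_id, anomer = production.position, production.comp, production.anomer
    ox_a, cx_a, ref_a = _attachment_frame(parent, position)
    ox, cx, ref = ox_a.pos, cx_a.pos, ref_a.pos

    clash_tree = None
    if model is not None:
        skip = exclude_keys or set()
        env = []
        for r in model.residues:
            if r.key in skip:
                continue
            for a in r.heavy_atoms():
                # only the attachment atom itself is covalently bonded to the
                # new residue; every other parent atom is a real clash partner
                if r.key == parent.key and a.name == ox_a.name:
                    continue
                env.append(a.pos)
        if env:
            clash_tree = cKDTree(np.array(env))

    def evaluate(phi: float, psi: float) -> tuple[float, dict[str, np.ndarray]]:
        coords = _place_template(comp_id, ox, cx, ref, phi, psi)
        pts = np.array(list(coords.values()))
        return float(np.mean(map_obs.interpolate(pts))), coords

    best = (-np.inf, None, None, None)
    for phi in PHI_CANDIDATES[anomer]:
        for psi in PSI_CANDIDATES:
            fit, coords = evaluate(phi, psi)
            if fit > best[0]:
                best = (fit, coords, phi, psi)
    # local refinement on a +-20 deg grid around the winner
    fit0, coords0, phi0, psi0 = best
    for dphi in np.arange(-REFINE_SPAN, REFINE_SPAN + 1, REFINE_STEP):
        for dpsi in np.arange(-REFINE_SPAN, REFINE_SPAN + 1, REFINE_STEP):
            if dphi == 0 and dpsi == 0:
                continue
            fit, coords = evaluate(phi0 + dphi, psi0 + dpsi)
            if fit > best[0]:
                best = (fit, coords, phi0 + dphi, psi0 + dpsi)
    fit, coords, phi, psi = best
    if coords is None:
        return PlacementResult(None, -np.inf, False)

    clash = False
    if clash_tree is not None:
        pts = np.array(list(coords.values()))
        d, _ = clash_tree.query(pts)
        clash = bool(np.min(d) < HARD_CLASH)
    accepted = bool(fit >= fit_threshold and not clash)
    residue = _as_residue(comp_id, coords, parent.chain_id, 0, b_new)
    return PlacementResult(residue, fit, accepted, phi, psi)


def _slot_order_key(typedef: TreeTypeDef, node: TypeNode) -> tuple:
    pos_rank = {"N": 0, 4: 1, 3: 2, 6: 3, 2: 4}.get(node.position, 5)
    is_fucose = node.comp in ("FUC", "FUL")
    return (int(is_fucose), typedef.node_depth(node.id), pos_rank, node.id)


def next_free_seq(model: StructureModel, chain_id: str, start: int = 401) -> int:
    used = model.used_seq_nums(chain_id)
    n = start
    while n in used:
        n += 1
    return n


def extend_tree(tree: GlycanTree, typedef: TreeTypeDef, map_obs: DensityMap,
                model: StructureModel,
                fit_threshold: float = LOCAL_FIT_THRESHOLD,
                b_new: float = 30.0) -> tuple[GlycanTree, list[ResidueRecord]]:
    """Grow a glycan tree (possibly a bare asparagine) against the density.

    Mutates ``model`` by appending accepted residues and link records, and
    returns the grown tree plus the list of newly built residues. With no
    acceptable density the tree is returned unchanged (empty growth).
    """
    from .topology import _match_tree_to_type  # local import, shared matcher

    type_root = next(n for n in typedef.nodes.values() if n.parent is None)
    filled: dict[str, ResidueKey] = {}
    if tree.root_carb is not None:
        mapping = _match_tree_to_type(tree, typedef, model)
        filled = {node_id: key for key, node_id in mapping.items()}

    asn = model.residue(tree.root_asn)
    if asn is None:
        raise PlacementImpossible(f"root asparagine {tree.root_asn} not in model")

    new_residues: list[ResidueRecord] = []

    def open_slots() -> list[TypeNode]:
        slots = []
        for node in typedef.nodes.values():
            if node.id in filled:
                continue
            if node.parent is None:
                slots.append(node)       # root NAG onto the asparagine
            elif node.parent in filled:
                slots.append(node)
        return sorted(slots, key=lambda n: _slot_order_key(typedef, n))

    attempted: set[str] = set()
    while True:
        slots = [s for s in open_slots() if s.id not in attempted]
        if not slots:
            break
        node = slots[0]
        attempted.add(node.id)
        parent_res = asn if node.parent is None else model.residue(filled[node.parent])
        try:
            result = place_residue(parent_res, node, map_obs, model,
                                   fit_threshold=fit_threshold, b_new=b_new)
        except PlacementImpossible as exc:
            log.debug("slot %s: %s", node.id, exc)
            continue
        if not result.accepted_locally:
            continue
        residue = result.residue
        residue.seq_num = next_free_seq(model, residue.chain_id)
        model.add_residue(residue)
        parent_atom = "ND2" if node.position == "N" else \
            ("O6" if node.position == 6 else f"O{node.position}")
        link = LinkRecord(
            (parent_res.chain_id, parent_res.seq_num, parent_res.ins_code, parent_atom),
            (residue.chain_id, residue.seq_num, residue.ins_code, "C1"),
            declared_distance=GLYCOSIDIC_BOND)
        model.links.append(link)
        tree.edges.append(GlycanEdge(parent=parent_res.key, child=residue.key,
                                     parent_atom=parent_atom, child_atom="C1",
                                     anomer=node.anomer, position=node.position))
        tree.nodes.append(residue.key)
        filled[node.id] = residue.key
        new_residues.append(residue)
    return tree, new_residues
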