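"""Sequon detection, glycan-tree extraction and tree-type grammars.

An N-glycosylation tree is a rooted tree of pyranose residues anchored at an
asparagine ND2 atom; edges are glycosidic linkages labelled with the parent
attachment position (N for the root link, else 2/3/4/6) and the anomeric
configuration of the child. Tree *types* (high-mannose, hybrid/complex
mammal, hybrid/complex plant) are finite template trees sharing the common
five-residue core; they are shipped as a JSON data file so the grammar is
auditable and extensible.
"""
from __future__ import annotations

import dataclasses
import json
from importlib import resources

import numpy as np

from . import chem
from .model import ResidueKey, ResidueRecord, StructureModel

DEFAULT_TREE_TYPE = "high-mannose"
TYPE_PRIORITY = ("high-mannose", "hybrid-mammal", "complex-mammal",
                 "hybrid-plant", "complex-plant")

#: maximum peptide C-N distance before two sequential residues are treated
#: as a chain break (no sequon across breaks)
CHAIN_BREAK_CN = 2.5


# -- domain types ----------------------------------------------------------

@dataclasses.dataclass
class SequonSite:
    asn: ResidueKey
    x_res: ResidueKey
    st_res: ResidueKey


@dataclasses.dataclass
class GlycanEdge:
    parent: ResidueKey
    child: ResidueKey
    parent_atom: str   # "ND2" for the root link, else "O2"/"O3"/"O4"/"O6"
    child_atom: str    # always "C1"
    anomer: str
    position: int | str  # "N" or 2/3/4/6


@dataclasses.dataclass
class GlycanTree:
    root_asn: ResidueKey
    edges: list[GlycanEdge] = dataclasses.field(default_factory=list)
    nodes: list[ResidueKey] = dataclasses.field(default_factory=list)

    def children(self, key: ResidueKey) -> list[GlycanEdge]:
        return [e for e in self.edges if e.parent == key]

    def parent_edge(self, key: ResidueKey) -> GlycanEdge | None:
        for e in self.edges:
            if e.child == key:
                return e
        return None

    def descendants(self, key: ResidueKey) -> list[ResidueKey]:
        out: list[ResidueKey] = []
        stack = [key]
        while stack:
            k = stack.pop()
            for e in self.children(k):
                out.append(e.child)
                stack.append(e.child)
        return out

    @property
    def root_carb(self) -> ResidueKey | None:
        for e in self.edges:
            if e.parent == self.root_asn:
                return e.child
        return None


@dataclasses.dataclass(frozen=True)
class TypeNode:
    id: str
    parent: str | None
    position: int | str
    comp: str
    anomer: str


@dataclasses.dataclass
class TreeTypeDef:
    name: str
    nodes: dict[str, TypeNode]
    fucose_ids: tuple[str, ...] = ()

    def children_of(self, node_id: str | None) -> list[TypeNode]:
        return [n for n in self.nodes.values() if n.parent == node_id]

    def node_depth(self, node_id: str) -> int:
        d, n = 0, self.nodes[node_id]
        while n.parent is not None:
            n = self.nodes[n.parent]
            d += 1
        return d

    def productions(self) -> set[tuple[str, int | str, str, str]]:
        """(parent comp, position, child comp, anomer) tuples of this type."""
        out = set()
        for n in self.nodes.values():
            parent_comp = "ASN" if n.parent is None else self.nodes[n.parent].comp
            out.add((parent_comp, n.position, n.comp, n.anomer))
        return out


def _coerce_pos(p) -> int | str:
    return p if p == "N" else int(p)


def load_tree_types() -> dict[str, TreeTypeDef]:
    """The five standard tree-type definitions from the packaged data file."""
    raw = json.loads(resources.files("glycurate.data").joinpath("tree_types.json").read_text())
    core = [TypeNode(d["id"], d["parent"], _coerce_pos(d["position"]), d["comp"], d["anomer"])
            for d in raw["core"]]
    defs: dict[str, TreeTypeDef] = {}
    for name, spec in raw["types"].items():
        nodes = {n.id: n for n in core}
        for d in spec["nodes"]:
            n = TypeNode(d["id"], d["parent"], _coerce_pos(d["position"]), d["comp"], d["anomer"])
            nodes[n.id] = n
        defs[name] = TreeTypeDef(name=name, nodes=nodes,
                                 fucose_ids=tuple(spec.get("fucoses", ())))
    return defs


CORE_SIZE = 5


# -- sequon detection ------------------------------------------------------

def _ordered_chain(model: StructureModel, chain_id: str) -> list[ResidueRecord]:
    return [r for r in model.chain(chain_id) if chem.is_amino_acid(r.comp_id)]


def _peptide_bonded(a: ResidueRecord, b: ResidueRecord) -> bool:
    """True when b directly follows a in the chain with no break."""
    if b.seq_num - a.seq_num != 1:
        return False
    c, n = a.atom("C"), b.atom("N")
    if c is not None and n is not None:
        return float(np.linalg.norm(c.pos - n.pos)) <= CHAIN_BREAK_CN
    return True  # fall back to numbering when backbone atoms are absent


def find_sequons(model: StructureModel) -> list[SequonSite]:
    """All modeled Asn-X-Ser/Thr sites (X anything but Pro, no chain break)."""
    sites: list[SequonSite] = []
    for chain_id in model.chain_ids():
        residues = _ordered_chain(model, chain_id)
        for i in range(len(residues) - 2):
            asn, x, st = residues[i], residues[i + 1], residues[i + 2]
            if asn.comp_id != "ASN":
                continue
            if x.comp_id == "PRO" or st.comp_id not in ("SER", "THR"):
                continue
            if not (_peptide_bonded(asn, x) and _peptide_bonded(x, st)):
                continue
            sites.append(SequonSite(asn.key, x.key, st.key))
    return sites


# -- tree extraction -------------------------------------------------------

def _link_as_parent_child(model: StructureModel, link) -> tuple | None:
    """Orient a link as (parent_key, parent_atom, child_key) or None."""
    ra = model.residue(link.atom_a[:3])
    rb = model.residue(link.atom_b[:3])
    if ra is None or rb is None:
        return None
    for (pres, patom), (cres, catom) in (((ra, link.atom_a[3]), (rb, link.atom_b[3])),
                                         ((rb, link.atom_b[3]), (ra, link.atom_a[3]))):
        if catom != "C1" or not chem.is_carbohydrate(cres.comp_id):
            continue
        if pres.comp_id == "ASN" and patom == "ND2":
            return pres.key, patom, cres.key, "N"
        if chem.is_carbohydrate(pres.comp_id) and patom.startswith("O") and len(patom) == 2:
            return pres.key, patom, cres.key, int(patom[1])
    return None


def extract_trees(model: StructureModel) -> tuple[list[GlycanTree], list[list[ResidueKey]]]:
    """Glycan trees rooted at Asn residues, plus unattached carbohydrate chains.

    Tree membership follows C1 -> Ox links transitively from each Asn root.
    A link that would close a cycle is dropped (the tree stays acyclic).
    Linked carbohydrate chains not reachable from any Asn are returned as the
    second element, one list of residue keys per connected chain.
    """
    oriented = []
    for ln in model.links:
        pc = _link_as_parent_child(model, ln)
        if pc is not None:
            oriented.append(pc)

    by_parent: dict[ResidueKey, list[tuple]] = {}
    for parent, patom, child, pos in oriented:
        by_parent.setdefault(parent, []).append((parent, patom, child, pos))

    trees: list[GlycanTree] = []
    reached: set[ResidueKey] = set()
    # deterministic order over root Asn keys
    roots = sorted({o[0] for o in oriented if o[3] == "N"})
    for asn_key in roots:
        tree = GlycanTree(root_asn=asn_key)
        visited: set[ResidueKey] = {asn_key}
        queue = [asn_key]
        while queue:
            cur = queue.pop(0)
            for parent, patom, child, pos in sorted(by_parent.get(cur, []),
                                                    key=lambda t: (str(t[3]), t[2])):
                if child in visited or child in reached:
                    continue  # would close a cycle or cross trees: drop link
                res = model.residue(child)
                anomer = chem.declared_anomer(res.comp_id) or "beta"
                tree.edges.append(GlycanEdge(parent=parent, child=child,
                                             parent_atom=patom, child_atom="C1",
                                             anomer=anomer, position=pos))
                tree.nodes.append(child)
                visited.add(child)
                queue.append(child)
        if tree.nodes:
            trees.append(tree)
            reached.update(tree.nodes)

    # unattached: carb residues participating in carb-carb links, not reached
    linked_carbs: set[ResidueKey] = set()
    adj: dict[ResidueKey, set[ResidueKey]] = {}
    for parent, patom, child, pos in oriented:
        if pos == "N":
            continue
        linked_carbs.update((parent, child))
        adj.setdefault(parent, set()).add(child)
        adj.setdefault(child, set()).add(parent)
    unattached: list[list[ResidueKey]] = []
    seen: set[ResidueKey] = set()
    for key in sorted(linked_carbs):
        if key in reached or key in seen:
            continue
        comp_keys = []
        stack = [key]
        while stack:
            k = stack.pop()
            if k in seen or k in reached:
                continue
            seen.add(k)
            comp_keys.append(k)
            stack.extend(adj.get(k, ()))
        if comp_keys:
            unattached.append(sorted(comp_keys))
    return trees, unattached


# -- tree-type selection and residue classification ------------------------

def _match_tree_to_type(tree: GlycanTree, typedef: TreeTypeDef,
                        model: StructureModel) -> dict[ResidueKey, str]:
    """Greedy root-down matching of tree residues onto type-node slots."""
    mapping: dict[ResidueKey, str] = {}
    root = tree.root_carb
    if root is None:
        return mapping
    root_res = model.residue(root)
    type_root = next((n for n in typedef.nodes.values() if n.parent is None), None)
    if root_res is None or type_root is None:
        return mapping
    if root_res.comp_id not in ("NAG", "NDG"):
        return mapping
    mapping[root] = type_root.id
    queue = [(root, type_root.id)]
    while queue:
        res_key, node_id = queue.pop(0)
        slots = typedef.children_of(node_id)
        taken: set[str] = set()
        for edge in tree.children(res_key):
            child_res = model.residue(edge.child)
            if child_res is None:
                continue
            slot = next((s for s in slots
                         if s.id not in taken and s.position == edge.position
                         and s.comp == child_res.comp_id), None)
            if slot is None:
                continue
            taken.add(slot.id)
            mapping[edge.child] = slot.id
            queue.append((edge.child, slot.id))
    return mapping


CORE_IDS = ("nag1", "nag2", "bma3", "man3", "man6")


def select_tree_type(trees: list[GlycanTree],
                     typedefs: dict[str, TreeTypeDef],
                     model: StructureModel) -> TreeTypeDef:
    """Pick the tree type used for building.

    Default is high-mannose (with fucose productions); when an existing tree
    extends beyond the shared five-residue core, the type whose template
    covers the largest number of beyond-core residues wins. Ties break in the
    order high-mannose, then mammal types, then plant types.
    """
    best_name = DEFAULT_TREE_TYPE
    best_cover = 0
    for name in TYPE_PRIORITY:
        typedef = typedefs[name]
        cover = 0
        for tree in trees:
            mapping = _match_tree_to_type(tree, typedef, model)
            cover += sum(1 for node_id in mapping.values()
                         if node_id not in CORE_IDS and node_id not in typedef.fucose_ids)
        if cover > best_cover:
            best_cover = cover
            best_name = name
    return typedefs[best_name]


def classify_residues(tree: GlycanTree, typedefs: dict[str, TreeTypeDef],
                      model: StructureModel) -> dict[ResidueKey, str]:
    """Mark each tree residue 'conforming' or 'nonstandard'.

    A residue conforms when its incoming production (parent comp, position,
    child comp, anomer) occurs in at least one of the five standard tree
    types; a nonstandard residue makes all its descendants nonstandard.
    """
    union: set[tuple[str, int | str, str, str]] = set()
    for t in typedefs.values():
        union |= t.productions()
    result: dict[ResidueKey, str] = {}
    root = tree.root_carb
    if root is None:
        return result

    def walk(key: ResidueKey, parent_ok: bool) -> None:
        edge = tree.parent_edge(key)
        res = model.residue(key)
        ok = parent_ok and res is not None and edge is not None
        if ok:
            parent_res = model.residue(edge.parent)
            parent_comp = "ASN" if edge.position == "N" else (
                parent_res.comp_id if parent_res else "")
            # NDG at the root is tolerated (it is renamed to NAG downstream)
            comp = "NAG" if (edge.position == "N" and res.comp_id == "NDG") else res.comp_id
            ok = (parent_comp, edge.position, comp,
                  chem.declared_anomer(comp) or edge.anomer) in union
        result[key] = "conforming" if ok else "nonstandard"
        for e in tree.children(key):
            walk(e.child, ok)

    walk(root, True)
    return result


def tree_summary(tree: GlycanTree, model: StructureModel) -> str:
    """One line per edge: parent -> child with linkage annotation."""
    lines = []
    for e in tree.edges:
        p = model.residue(e.parent)
        c = model.residue(e.child)
        link = "beta1-N" if e.position == "N" else \
            f"{'alpha' if e.anomer == 'alpha' else 'beta'}1-{e.position}"
        lines.append(f"{p!r} --{link}--> {c!r}")
    return "\n".join(lines)
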