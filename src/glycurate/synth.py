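"""Synthetic glycoprotein fixtures: ground-truth glycosites, observed maps
and degraded working models.

The generator builds a short idealized peptide carrying an Asn-X-Thr sequon,
attaches an ideal glycan tree using the same templates the builder uses,
synthesizes an "observed" density map from the ground truth (band-limited to
the requested resolution, sigma-normalized, plus white Gaussian noise) and
derives a working model by cropping and/or jittering the truth. Everything
is deterministic given the seed.

The peptide scaffold uses fixed ideal backbone geometry (a beta-strand-like
conformation); no Ramachandran realism is claimed — it exists to provide a
protein main chain, a sequon and a density environment.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .builder import GLYCOSIDIC_BOND, PHI_CANDIDATES, PSI_CANDIDATES, _place_template, _slot_order_key
from .density import DensityMap, calc_model_map
from .geom import place_atom
from .model import AtomRecord, LinkRecord, ResidueRecord, StructureModel
from .topology import load_tree_types

PROTEIN_B = 20.0
CARB_B = 30.0
BOX_MARGIN = 8.0

_BACKBONE = {
    "N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
    "N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.5,
    "PHI": -140.0, "PSI": 135.0, "OMEGA": 180.0,
}


def _side_chain(comp: str, n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> dict[str, np.ndarray]:
    """Idealized side-chain heavy atoms (L-configuration at CA)."""
    out: dict[str, np.ndarray] = {}
    if comp == "GLY":
        return out
    cb = place_atom(c, n, ca, 1.53, 110.5, 123.0)
    out["CB"] = cb
    if comp == "ASN":
        cg = place_atom(n, ca, cb, 1.52, 113.0, -65.0)
        out["CG"] = cg
        out["OD1"] = place_atom(ca, cb, cg, 1.23, 120.8, -60.0)
        out["ND2"] = place_atom(ca, cb, cg, 1.33, 116.4, 120.0)
    elif comp == "THR":
        out["OG1"] = place_atom(n, ca, cb, 1.43, 109.5, 60.0)
        out["CG2"] = place_atom(n, ca, cb, 1.52, 110.5, -60.0)
    elif comp == "SER":
        out["OG"] = place_atom(n, ca, cb, 1.42, 110.8, 60.0)
    elif comp == "LYS":
        out["CG"] = place_atom(n, ca, cb, 1.52, 114.0, -65.0)
    elif comp == "PRO":
        out["CG"] = place_atom(n, ca, cb, 1.50, 104.0, 30.0)
        out["CD"] = place_atom(ca, cb, out["CG"], 1.51, 105.0, -35.0)
    return out


_ELEMENT1 = {"N": "N", "C": "C", "O": "O", "S": "S"}


def build_peptide(sequence: list[str], chain_id: str = "A",
                  first_seq_num: int = 21) -> list[ResidueRecord]:
    """Idealized extended peptide with full heavy-atom side chains."""
    residues: list[ResidueRecord] = []
    bb = _BACKBONE
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([bb["N_CA"], 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, bb["CA_C"], bb["N_CA_C"], 50.0)
    for i, comp in enumerate(sequence):
        atoms = {"N": n, "CA": ca, "C": c}
        n_next = place_atom(n, ca, c, bb["C_N"], bb["CA_C_N"], bb["PSI"])
        atoms["O"] = place_atom(n, ca, c, bb["C_O"], bb["CA_C_O"], bb["PSI"] + 180.0)
        atoms.update(_side_chain(comp, n, ca, c))
        rec = ResidueRecord(chain_id, first_seq_num + i, comp,
                            [AtomRecord(name, _ELEMENT1[name[0]], pos, 1.0, PROTEIN_B)
                             for name, pos in atoms.items()])
        residues.append(rec)
        ca_next = place_atom(ca, c, n_next, bb["N_CA"], bb["C_N_CA"], bb["OMEGA"])
        c_next = place_atom(c, n_next, ca_next, bb["CA_C"], bb["N_CA_C"], bb["PHI"])
        n, ca, c = n_next, ca_next, c_next
    return residues


def _clearance_place(parent: ResidueRecord, node, existing: list[np.ndarray]):
    """Place a template residue by maximal clearance from existing atoms."""
    from .builder import _attachment_frame
    ox_a, cx_a, ref_a = _attachment_frame(parent, node.position)
    best = (-np.inf, None)
    env = np.array(existing) if existing else None
    for phi in PHI_CANDIDATES[node.anomer]:
        for psi in PSI_CANDIDATES:
            coords = _place_template(node.comp, ox_a.pos, cx_a.pos, ref_a.pos, phi, psi)
            pts = np.array(list(coords.values()))
            if env is None:
                clearance = np.inf
            else:
                d = np.sqrt(((pts[:, None, :] - env[None, :, :]) ** 2).sum(axis=2))
                clearance = float(d.min())
            if clearance > best[0]:
                best = (clearance, coords)
    return best[1]


@dataclasses.dataclass
class GlycositeSpec:
    tree_type: str = "high-mannose"
    n_residues: int = 5
    resolution: float = 2.0
    noise_sd: float = 0.1
    crop: tuple[int, ...] | str = ()   # ordinals (1-based, build order) or "all"
    perturb: float = 0.0
    seed: int = 0
    strip_link: bool = False           # drop the Asn-NAG link record in the working model
    add_leaving_atom: bool = False     # put the O1 leaving atom back on the root NAG

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


def make_glycosite(spec: GlycositeSpec) -> tuple[StructureModel, DensityMap, StructureModel]:
    """(truth model, observed map, working model) for one glycosylation site."""
    rng = np.random.default_rng(spec.seed)
    peptide = build_peptide(["ALA", "GLY", "ASN", "GLY", "THR", "ALA", "GLY"])
    asn = next(r for r in peptide if r.comp_id == "ASN")

    typedefs = load_tree_types()
    if spec.tree_type not in typedefs:
        raise ValueError(f"unknown tree type {spec.tree_type!r}")
    typedef = typedefs[spec.tree_type]
    slots = sorted(typedef.nodes.values(), key=lambda n: _slot_order_key(typedef, n))
    if spec.n_residues > len(slots):
        raise ValueError(f"tree type {spec.tree_type} has only {len(slots)} residues")
    slots = slots[:spec.n_residues]

    residues = [r.copy() for r in peptide]
    links: list[LinkRecord] = []
    placed: dict[str, ResidueRecord] = {}
    seq = 401
    carb_order: list[ResidueRecord] = []
    for node in slots:
        parent = asn if node.parent is None else placed[node.parent]
        parent = next(r for r in residues if r.key == parent.key)
        existing = [a.pos for r in residues if r.key != parent.key for a in r.atoms]
        coords = _clearance_place(parent, node, existing)
        if coords is None:
            raise ValueError(f"could not place slot {node.id}")
        rec = ResidueRecord("A", seq, node.comp,
                            [AtomRecord(nm, nm[0], p, 1.0, CARB_B) for nm, p in coords.items()])
        residues.append(rec)
        placed[node.id] = rec
        carb_order.append(rec)
        existing.extend(p for p in coords.values())
        parent_atom = "ND2" if node.position == "N" else \
            ("O6" if node.position == 6 else f"O{node.position}")
        links.append(LinkRecord(
            (parent.chain_id, parent.seq_num, parent.ins_code, parent_atom),
            ("A", seq, "", "C1"), declared_distance=GLYCOSIDIC_BOND))
        seq += 1

    # shift into a P1 box with a solvent margin on every side
    pts = np.array([a.pos for r in residues for a in r.atoms])
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    shift = BOX_MARGIN - lo
    for r in residues:
        for a in r.atoms:
            a.pos = a.pos + shift
    cell_lengths = span + 2 * BOX_MARGIN
    cell = (float(cell_lengths[0]), float(cell_lengths[1]), float(cell_lengths[2]),
            90.0, 90.0, 90.0)

    truth = StructureModel(residues=residues, links=links, cell=cell,
                           resolution=spec.resolution)

    spacing = min(spec.resolution / 4.0, 0.6)
    map_obs = calc_model_map(truth, d_min=spec.resolution, spacing=spacing)
    map_obs = map_obs.sigma_normalized()
    if spec.noise_sd > 0:
        map_obs.grid += rng.normal(0.0, spec.noise_sd, map_obs.grid.shape)
    map_obs = map_obs.sigma_normalized()

    working = truth.copy()
    working.resolution = spec.resolution
    crop = spec.crop
    if crop == "all":
        crop = tuple(range(1, len(carb_order) + 1))
    if crop:
        bad = [i for i in crop if not 1 <= i <= len(carb_order)]
        if bad:
            raise ValueError(f"crop ordinals out of range: {bad}")
        working.remove_residues([carb_order[i - 1].key for i in crop])
    if spec.strip_link:
        root_key = carb_order[0].key if carb_order else None
        if root_key is not None:
            working.links = [ln for ln in working.links
                             if not (ln.involves(root_key) and
                                     (ln.atom_a[3] == "ND2" or ln.atom_b[3] == "ND2"))]
    if spec.add_leaving_atom and carb_order:
        root = working.residue(carb_order[0].key)
        if root is not None and root.atom("O1") is None:
            from .templates import get_template
            # approximate leaving-atom position: extend the Asn->C1 direction
            c1 = root.atom("C1")
            nd2 = working.residue(asn.key).atom("ND2")
            o1 = c1.pos + (c1.pos - nd2.pos) / np.linalg.norm(c1.pos - nd2.pos) * 1.4
            root.atoms.append(AtomRecord("O1", "O", o1, 1.0, CARB_B))
    if spec.perturb > 0:
        for r in working.residues:
            for a in r.atoms:
                a.pos = a.pos + rng.normal(0.0, spec.perturb, 3)
    return truth, map_obs, working


# -- link-detection case battery ------------------------------------------

@dataclasses.dataclass
class LinkCase:
    name: str
    model: StructureModel
    carb_key: tuple
    expected_outcome: str
    expected_flipped: bool = False


def _sequon_scaffold(third: str = "THR", x_res: str = "GLY") -> list[ResidueRecord]:
    return build_peptide(["ALA", "GLY", "ASN", x_res, third, "ALA", "GLY"])


def _carb_at(nd2: np.ndarray, direction: np.ndarray, d_c1: float,
             extra: list[tuple[str, np.ndarray]] | None = None,
             comp: str = "NAG", seq: int = 401) -> ResidueRecord:
    """Minimal carbohydrate with C1 at a controlled distance from ND2."""
    u = direction / np.linalg.norm(direction)
    c1 = nd2 + d_c1 * u
    atoms = [AtomRecord("C1", "C", c1, 1.0, CARB_B)]
    side = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    # a couple of far-side atoms so the residue is more than a lone carbon
    atoms.append(AtomRecord("C2", "C", c1 + 1.52 * u, 1.0, CARB_B))
    atoms.append(AtomRecord("O5", "O", c1 + 1.43 * (0.5 * u + 0.87 * side), 1.0, CARB_B))
    for name, pos in (extra or []):
        atoms.append(AtomRecord(name, name[0], pos, 1.0, CARB_B))
    return ResidueRecord("A", seq, comp, atoms)


def _box_model(residues: list[ResidueRecord]) -> StructureModel:
    return StructureModel(residues=[r.copy() for r in residues],
                          cell=(80.0, 80.0, 80.0, 90.0, 90.0, 90.0), resolution=2.0)


def make_link_cases(seed: int = 0) -> list[LinkCase]:
    """A constructed battery probing every link-detection rule."""
    cases: list[LinkCase] = []
    pep = _sequon_scaffold()
    asn = next(r for r in pep if r.comp_id == "ASN")
    nd2 = asn.atom("ND2").pos
    od1 = asn.atom("OD1").pos
    cg = asn.atom("CG").pos
    away = (nd2 - cg) / np.linalg.norm(nd2 - cg)

    def add(name, residues, carb_seq, outcome, flipped=False):
        carb_key = ("A", carb_seq, "")
        cases.append(LinkCase(name, _box_model(residues), carb_key, outcome, flipped))

    # 1. direct bond, leaving atom present
    carb = _carb_at(nd2, away, 3.2, extra=[("O1", nd2 + 3.2 * away + np.array([0, 1.4, 0]))])
    add("direct-bond-with-O1", pep + [carb], 401, "linked")
    # 2. long bond rescued by a secondary atom
    sec = nd2 + 3.3 * np.array([0.0, 0.0, 1.0])
    carb = _carb_at(nd2, away, 4.5, extra=[("C3", sec)])
    add("secondary-atom-rescue", pep + [carb], 401, "linked")
    # 3. long bond, no secondary atom near
    carb = _carb_at(nd2, away, 5.0)
    add("too-far-no-secondary", pep + [carb], 401, "rejected_distance")
    # 4. amide flip: C1 closer to OD1, valid bond after flipping
    away_o = (od1 - cg) / np.linalg.norm(od1 - cg)
    carb = _carb_at(od1, away_o, 3.0)
    add("flip-case", pep + [carb], 401, "linked", flipped=True)
    # 5. motif violated after Asn (Lys instead of Ser/Thr)
    pep_bad = _sequon_scaffold(third="LYS")
    asn_b = next(r for r in pep_bad if r.comp_id == "ASN")
    nd2_b = asn_b.atom("ND2").pos
    cg_b = asn_b.atom("CG").pos
    away_b = (nd2_b - cg_b) / np.linalg.norm(nd2_b - cg_b)
    add("no-sequon-third", pep_bad + [_carb_at(nd2_b, away_b, 3.2)], 401, "rejected_no_sequon")
    # 6. proline at X
    pep_pro = _sequon_scaffold(x_res="PRO")
    asn_p = next(r for r in pep_pro if r.comp_id == "ASN")
    nd2_p = asn_p.atom("ND2").pos
    cg_p = asn_p.atom("CG").pos
    away_p = (nd2_p - cg_p) / np.linalg.norm(nd2_p - cg_p)
    add("proline-at-X", pep_pro + [_carb_at(nd2_p, away_p, 3.2)], 401, "rejected_no_sequon")
    # 7. two asparagines both satisfied: ambiguous
    pep2 = [r.copy() for r in pep]
    twin = [r.copy() for r in _sequon_scaffold()]
    for r in twin:
        r.chain_id = "B"
        for a in r.atoms:
            a.pos = a.pos + (nd2 + 7.0 * away + np.array([0.0, 0.0, 4.0])) - nd2
    twin_asn = next(r for r in twin if r.comp_id == "ASN")
    mid = 0.5 * (nd2 + twin_asn.atom("ND2").pos)
    carb = ResidueRecord("A", 401, "NAG", [
        AtomRecord("C1", "C", mid, 1.0, CARB_B),
        AtomRecord("C2", "C", nd2 + 2.9 * away, 1.0, CARB_B),
        AtomRecord("C3", "C", twin_asn.atom("ND2").pos - 2.9 * away, 1.0, CARB_B)])
    add("two-asn-ambiguous", pep2 + twin + [carb], 401, "rejected_ambiguous")
    # 8. C1 already linked: detector must skip it entirely (no decision)
    carb = _carb_at(nd2, away, 3.2)
    m = _box_model(pep + [carb])
    m.links.append(LinkRecord((asn.chain_id, asn.seq_num, "", "ND2"), ("A", 401, "", "C1")))
    cases.append(LinkCase("already-linked", m, ("A", 401, ""), "skipped"))
    # 9. NDG with its O1L leaving atom
    c1pos = nd2 + 3.2 * away
    carb = _carb_at(nd2, away, 3.2, comp="NDG",
                    extra=[("O1L", c1pos + np.array([0.0, 1.4, 0.0]))])
    add("ndg-leaving-atom", pep + [carb], 401, "linked")
    # 10. carbohydrate without a C1 atom
    carb = ResidueRecord("A", 401, "NAG", [AtomRecord("C2", "C", nd2 + 3.0 * away, 1.0, CARB_B)])
    add("missing-C1", pep + [carb], 401, "no_candidate")
    # 11. no asparagine within the search radius
    carb = _carb_at(nd2, away, 7.0)
    add("out-of-range", pep + [carb], 401, "no_candidate")
    # 12. secondary atom just outside the 3.5 A rule
    sec = nd2 + 3.7 * np.array([0.0, 0.0, 1.0])
    carb = _carb_at(nd2, away, 4.5, extra=[("C3", sec)])
    add("secondary-just-outside", pep + [carb], 401, "rejected_distance")
    # 13. OD1 slightly farther than ND2: no flip
    carb = _carb_at(nd2, away, 3.4)
    add("no-flip-needed", pep + [carb], 401, "linked", flipped=False)
    return cases


def random_link_model(rng: np.random.Generator) -> StructureModel:
    """A randomized single-sugar geometry for oracle-equivalence testing."""
    third = rng.choice(["THR", "SER", "LYS"])
    x_res = rng.choice(["GLY", "ALA", "PRO"])
    pep = build_peptide(["ALA", "GLY", "ASN", str(x_res), str(third), "ALA", "GLY"])
    asn = next(r for r in pep if r.comp_id == "ASN")
    nd2 = asn.atom("ND2").pos
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    d = float(rng.uniform(2.5, 7.5))
    c1 = nd2 + d * u
    atoms = [AtomRecord("C1", "C", c1, 1.0, CARB_B)]
    for i in range(int(rng.integers(2, 5))):
        off = rng.normal(size=3)
        off *= rng.uniform(1.4, 3.0) / np.linalg.norm(off)
        name = ["C2", "C3", "O5", "O3"][i]
        atoms.append(AtomRecord(name, name[0], c1 + off, 1.0, CARB_B))
    comp = str(rng.choice(["NAG", "NDG"]))
    carb = ResidueRecord("A", 401, comp, atoms)
    return _box_model(pep + [carb])
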