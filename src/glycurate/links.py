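"""Detection of missing Asn-carbohydrate covalent links.

For every NAG/NDG whose anomeric carbon C1 is not yet covalently linked, the
detector searches for asparagine ND2 atoms within a 6 A radius and applies
three filters before declaring an N-glycosidic bond:

1. the asparagine must head a valid Asn-X-Ser/Thr sequon (X != Pro);
2. if the ND2-C1 distance exceeds 4 A, some other atom of the carbohydrate
   must lie within 3.5 A of ND2 (the sugar may be rotated so that C1 does
   not face the asparagine);
3. if more than one asparagine survives the previous filters the situation
   is ambiguous and no link is generated.

If OD1 is closer to C1 than ND2, the side-chain amide is flipped (OD1/ND2
swapped) before evaluation; the flip is kept when a link is accepted, since
the bond chemically requires the nitrogen at that position, and reverted
otherwise. On success the leaving atom (O1 for NAG, O1L for NDG) is removed.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .model import LinkRecord, ResidueKey, ResidueRecord, StructureModel
from .topology import find_sequons

log = logging.getLogger(__name__)


@dataclasses.dataclass
class LinkConfig:
    search_radius: float = 6.0
    direct_bond_max: float = 4.0
    secondary_atom_max: float = 3.5

    def __post_init__(self) -> None:
        if not 0 < self.direct_bond_max <= self.search_radius:
            raise ValueError("direct_bond_max must be in (0, search_radius]")
        if not self.secondary_atom_max < self.search_radius:
            raise ValueError("secondary_atom_max must be below search_radius")


@dataclasses.dataclass
class LinkDecision:
    carb: ResidueKey
    asn: ResidueKey | None
    outcome: str  # linked | rejected_no_sequon | rejected_distance | rejected_ambiguous | no_candidate
    flipped: bool = False
    removed_atoms: list[str] = dataclasses.field(default_factory=list)


LEAVING_ATOMS = {"NAG": "O1", "NDG": "O1L"}


def _c1_is_linked(model: StructureModel, key: ResidueKey) -> bool:
    for ln in model.links:
        if (ln.atom_a[:3] == key and ln.atom_a[3] == "C1") or \
           (ln.atom_b[:3] == key and ln.atom_b[3] == "C1"):
            return True
    return False


def _flip_amide(asn: ResidueRecord) -> None:
    od1, nd2 = asn.atom("OD1"), asn.atom("ND2")
    od1.pos, nd2.pos = nd2.pos.copy(), od1.pos.copy()


def detect_asn_links(
    model: StructureModel, cfg: LinkConfig | None = None
) -> tuple[list[LinkRecord], list[LinkDecision], StructureModel]:
    """Generate missing Asn ND2 - carbohydrate C1 link records.

    Returns the new link records, a per-carbohydrate decision log, and the
    modified model (links appended, accepted flips persisted, leaving atoms
    removed). The input model is not mutated.
    """
    cfg = cfg or LinkConfig()
    model = model.copy()
    sequon_asns = {site.asn for site in find_sequons(model)}

    new_links: list[LinkRecord] = []
    decisions: list[LinkDecision] = []

    carbs = [r for r in model.residues if r.comp_id in ("NAG", "NDG")]
    for carb in carbs:
        if _c1_is_linked(model, carb.key):
            continue
        c1 = carb.atom("C1")
        if c1 is None:
            log.warning("%r has no C1 atom; skipping", carb)
            decisions.append(LinkDecision(carb.key, None, "no_candidate"))
            continue

        # candidate asparagines: ND2 within the search radius; both side-chain
        # amide atoms must be present to allow the flip test
        candidates: list[tuple[ResidueRecord, bool]] = []
        for res in model.residues:
            if res.comp_id != "ASN":
                continue
            nd2, od1 = res.atom("ND2"), res.atom("OD1")
            if nd2 is None or od1 is None:
                continue
            d_nd2 = float(np.linalg.norm(nd2.pos - c1.pos))
            d_od1 = float(np.linalg.norm(od1.pos - c1.pos))
            if d_nd2 <= cfg.search_radius:
                candidates.append((res, d_od1 < d_nd2))
        if not candidates:
            decisions.append(LinkDecision(carb.key, None, "no_candidate"))
            continue

        # filter 1: sequon
        sequon_ok = [(res, flip) for res, flip in candidates if res.key in sequon_asns]
        if not sequon_ok:
            decisions.append(LinkDecision(carb.key, candidates[0][0].key, "rejected_no_sequon"))
            continue

        # filter 2: direct bond distance, else a secondary carbohydrate atom
        surviving: list[tuple[ResidueRecord, bool]] = []
        for res, flip in sequon_ok:
            nd2_pos = res.atom("OD1").pos if flip else res.atom("ND2").pos
            d = float(np.linalg.norm(nd2_pos - c1.pos))
            if d > cfg.direct_bond_max:
                others = [a for a in carb.heavy_atoms() if a.name != "C1"]
                if not others or min(float(np.linalg.norm(a.pos - nd2_pos))
                                     for a in others) > cfg.secondary_atom_max:
                    continue
            surviving.append((res, flip))
        if not surviving:
            decisions.append(LinkDecision(carb.key, sequon_ok[0][0].key, "rejected_distance"))
            continue

        # filter 3: ambiguity
        if len(surviving) > 1:
            decisions.append(LinkDecision(carb.key, None, "rejected_ambiguous"))
            continue

        asn, flip = surviving[0]
        if flip:
            _flip_amide(asn)
        nd2 = asn.atom("ND2")
        dist = float(np.linalg.norm(nd2.pos - c1.pos))
        link = LinkRecord((asn.chain_id, asn.seq_num, asn.ins_code, "ND2"),
                          (carb.chain_id, carb.seq_num, carb.ins_code, "C1"),
                          declared_distance=round(dist, 3))
        model.links.append(link)
        new_links.append(link)

        removed: list[str] = []
        leaving = LEAVING_ATOMS.get(carb.comp_id)
        if leaving is not None and carb.atom(leaving) is not None:
            carb.atoms = [a for a in carb.atoms if a.name != leaving]
            removed.append(leaving)
        decisions.append(LinkDecision(carb.key, asn.key, "linked",
                                      flipped=flip, removed_atoms=removed))
    return new_links, decisions, model


def rename_linked_ndg(model: StructureModel) -> StructureModel:
    """Rename every NDG whose C1 is linked to an Asn ND2 into NAG.

    The alpha-anomer code on an N-linked sugar is almost always a naming
    error: the N-glycosidic bond is beta. Leaving-atom removal has already
    happened during link generation; any stray O1L is renamed with the
    residue. The input model is not mutated.
    """
    model = model.copy()
    for res in model.residues:
        if res.comp_id != "NDG":
            continue
        for ln in model.links_of(res.key):
            this_atom = ln.atom_a[3] if ln.atom_a[:3] == res.key else ln.atom_b[3]
            other_ref = ln.atom_b if ln.atom_a[:3] == res.key else ln.atom_a
            other = model.residue(other_ref[:3])
            if this_atom == "C1" and other is not None and \
                    other.comp_id == "ASN" and other_ref[3] == "ND2":
                res.comp_id = "NAG"
                for a in res.atoms:
                    if a.name == "O1L":
                        a.name = "O1"
                break
    return model
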