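"""Independent brute-force oracles used by the tests.

These deliberately re-derive the expected behaviour from first principles
(regular expressions, exhaustive enumeration, literal rule application) and
never call the implementation paths they check.
"""
from __future__ import annotations

import math
import re

import numpy as np

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "SEC": "U", "PYL": "O",
}


def sequon_asn_keys(model) -> set:
    """Sequon-heading Asn keys via a regex over fully modeled stretches."""
    out = set()
    for chain_id in {r.chain_id for r in model.residues}:
        chain = [r for r in model.residues
                 if r.chain_id == chain_id and r.comp_id in AA3TO1]
        chain.sort(key=lambda r: (r.seq_num, r.ins_code))
        # break the chain into contiguous stretches (numbering + geometry)
        stretches = []
        cur = []
        prev = None
        for r in chain:
            broken = False
            if prev is not None:
                if r.seq_num - prev.seq_num != 1:
                    broken = True
                else:
                    c, n = prev.atom("C"), r.atom("N")
                    if c is not None and n is not None and \
                            np.linalg.norm(c.pos - n.pos) > 2.5:
                        broken = True
            if broken and cur:
                stretches.append(cur)
                cur = []
            cur.append(r)
            prev = r
        if cur:
            stretches.append(cur)
        for stretch in stretches:
            seq = "".join(AA3TO1[r.comp_id] for r in stretch)
            for m in re.finditer(r"(?=N[^P][ST])", seq):
                out.add(stretch[m.start()].key)
    return out


def link_oracle(model, search_radius=6.0, direct_bond_max=4.0, secondary_atom_max=3.5):
    """Literal application of the link-generation filters.

    Returns {carb_key: (outcome, flipped)} for every NAG/NDG whose C1 is not
    already linked; carbohydrates with a linked C1 are absent from the dict.
    """
    sequons = sequon_asn_keys(model)
    linked_c1 = set()
    for ln in model.links:
        for ref in (ln.atom_a, ln.atom_b):
            if ref[3] == "C1":
                linked_c1.add(ref[:3])
    results = {}
    for carb in model.residues:
        if carb.comp_id not in ("NAG", "NDG") or carb.key in linked_c1:
            continue
        c1 = carb.atom("C1")
        if c1 is None:
            results[carb.key] = ("no_candidate", False)
            continue
        candidates = []
        for asn in model.residues:
            if asn.comp_id != "ASN":
                continue
            nd2, od1 = asn.atom("ND2"), asn.atom("OD1")
            if nd2 is None or od1 is None:
                continue
            if math.dist(nd2.pos, c1.pos) <= search_radius:
                flip = math.dist(od1.pos, c1.pos) < math.dist(nd2.pos, c1.pos)
                candidates.append((asn, flip))
        if not candidates:
            results[carb.key] = ("no_candidate", False)
            continue
        with_sequon = [(a, f) for a, f in candidates if a.key in sequons]
        if not with_sequon:
            results[carb.key] = ("rejected_no_sequon", False)
            continue
        survivors = []
        for asn, flip in with_sequon:
            n_pos = asn.atom("OD1").pos if flip else asn.atom("ND2").pos
            d = math.dist(n_pos, c1.pos)
            if d > direct_bond_max:
                other = [a for a in carb.atoms if a.name != "C1"
                         and a.element not in ("H", "D")]
                if not other or min(math.dist(a.pos, n_pos) for a in other) > secondary_atom_max:
                    continue
            survivors.append((asn, flip))
        if not survivors:
            results[carb.key] = ("rejected_distance", False)
        elif len(survivors) > 1:
            results[carb.key] = ("rejected_ambiguous", False)
        else:
            results[carb.key] = ("linked", survivors[0][1])
    return results


def brute_force_symmetry_min(model, probe, target, exclude_identity=False):
    """All-pairs enumeration over operators and 27 lattice translations."""
    orth = model.orth_matrix()
    frac = model.frac_matrix()
    best = math.inf
    for rot, tran in model.sym_ops:
        is_ident = np.allclose(rot, np.eye(3)) and np.allclose(tran, 0.0)
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    zero_shift = (i == 0 and j == 0 and k == 0)
                    if exclude_identity and is_ident and zero_shift:
                        continue
                    for ta in target:
                        f = rot @ (frac @ ta.pos) + tran + np.array([i, j, k])
                        cart = orth @ f
                        for pa in probe:
                            if is_ident and zero_shift and \
                                    np.allclose(pa.pos, ta.pos):
                                continue
                            best = min(best, float(np.linalg.norm(pa.pos - cart)))
    return best


def accept_rule(rscc, ediam, ratio, resolution,
                rscc_accept=0.70, sum_accept=1.20,
                borderline_low=0.60, ratio_accept=0.25, res_cutoff=3.0) -> bool:
    """The density acceptance rule, written out literally."""
    if rscc >= rscc_accept:
        return True
    if rscc + ediam > sum_accept:
        return True
    if resolution < res_cutoff and borderline_low <= rscc < rscc_accept \
            and ratio >= ratio_accept:
        return True
    return False
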