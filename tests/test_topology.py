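import numpy as np
import pytest

from glycurate.model import AtomRecord, LinkRecord, ResidueRecord, StructureModel
from glycurate.synth import build_peptide
from glycurate.topology import (CORE_IDS, classify_residues, extract_trees,
                                find_sequons, load_tree_types, select_tree_type)
from oracles import sequon_asn_keys


def peptide_model(sequence, chain_id="A"):
    residues = build_peptide(sequence, chain_id=chain_id)
    return StructureModel(residues=residues, cell=(80, 80, 80, 90, 90, 90))


def carb(chain, seq, comp, pos=(0.0, 0.0, 0.0)):
    pos = np.asarray(pos, dtype=float)
    return ResidueRecord(chain, seq, comp, [
        AtomRecord("C1", "C", pos), AtomRecord("O4", "O", pos + [1.4, 0, 0]),
        AtomRecord("O3", "O", pos + [0, 1.4, 0]), AtomRecord("O6", "O", pos + [0, 0, 1.4]),
        AtomRecord("O2", "O", pos + [-1.4, 0, 0])])


def link(pk, pa, ck):
    return LinkRecord((pk[0], pk[1], "", pa), (ck[0], ck[1], "", "C1"))


class TestFindSequons:
    def test_canonical_sequon_found(self):
        m = peptide_model(["ALA", "ASN", "GLY", "THR", "ALA"])
        sites = find_sequons(m)
        assert len(sites) == 1
        assert sites[0].asn == ("A", 22, "")

    def test_proline_at_x_blocks(self):
        m = peptide_model(["ALA", "ASN", "PRO", "SER", "ALA"])
        assert find_sequons(m) == []

    def test_wrong_third_residue_blocks(self):
        m = peptide_model(["ALA", "ASN", "THR", "LYS", "ALA"])
        assert find_sequons(m) == []

    def test_numbering_gap_blocks(self):
        m = peptide_model(["ALA", "ASN", "GLY", "THR", "ALA"])
        for r in m.residues:
            if r.seq_num >= 24:  # push Thr and later residues away
                r.seq_num += 1
        assert find_sequons(m) == []

    def test_broken_backbone_blocks(self):
        m = peptide_model(["ALA", "ASN", "GLY", "THR", "ALA"])
        thr = next(r for r in m.residues if r.comp_id == "THR")
        for a in thr.atoms:
            a.pos = a.pos + np.array([25.0, 0.0, 0.0])
        assert find_sequons(m) == []

    def test_agrees_with_regex_oracle_on_random_chains(self):
        rng = np.random.default_rng(23)
        pool = ["ALA", "GLY", "ASN", "PRO", "SER", "THR", "LYS", "VAL"]
        for _ in range(100):
            n = int(rng.integers(4, 10))
            seq = [str(rng.choice(pool)) for _ in range(n)]
            m = peptide_model(seq)
            got = {s.asn for s in find_sequons(m)}
            assert got == sequon_asn_keys(m)


class TestExtractTrees:
    def asn_model(self, *extra, links=()):
        m = peptide_model(["ALA", "ASN", "GLY", "THR", "ALA"])
        for r in extra:
            m.residues.append(r)
        m.links.extend(links)
        return m

    def test_linear_chain_is_one_tree(self):
        m = self.asn_model(
            carb("A", 401, "NAG", (0, 0, 0)), carb("A", 402, "NAG", (5, 0, 0)),
            carb("A", 403, "BMA", (10, 0, 0)),
            links=[link(("A", 22), "ND2", ("A", 401)),
                   link(("A", 401), "O4", ("A", 402)),
                   link(("A", 402), "O4", ("A", 403))])
        trees, unattached = extract_trees(m)
        assert len(trees) == 1 and unattached == []
        assert len(trees[0].nodes) == 3 and len(trees[0].edges) == 3
        assert trees[0].root_carb == ("A", 401, "")

    def test_two_roots_two_trees(self):
        m = peptide_model(["ALA", "ASN", "GLY", "THR", "ASN", "GLY", "SER", "ALA"])
        m.residues += [carb("A", 401, "NAG"), carb("A", 402, "NAG", (6, 0, 0))]
        m.links += [link(("A", 22), "ND2", ("A", 401)), link(("A", 25), "ND2", ("A", 402))]
        trees, _ = extract_trees(m)
        assert len(trees) == 2
        assert all(len(t.nodes) == 1 for t in trees)

    def test_unattached_pair_reported_separately(self):
        m = self.asn_model(
            carb("A", 401, "NAG"), carb("A", 402, "NAG", (5, 0, 0)),
            links=[link(("A", 401), "O4", ("A", 402))])
        trees, unattached = extract_trees(m)
        assert trees == []
        assert unattached == [[("A", 401, ""), ("A", 402, "")]]

    def test_cycle_forming_link_dropped(self):
        m = self.asn_model(
            carb("A", 401, "NAG"), carb("A", 402, "NAG", (5, 0, 0)),
            links=[link(("A", 22), "ND2", ("A", 401)),
                   link(("A", 401), "O4", ("A", 402)),
                   link(("A", 402), "O4", ("A", 401))])  # back edge: cycle
        trees, _ = extract_trees(m)
        assert len(trees) == 1
        t = trees[0]
        assert len(t.nodes) == len(t.edges) == 2  # acyclic, back edge dropped

    def test_nodes_partition_and_count_edges_plus_one(self):
        m = self.asn_model(
            carb("A", 401, "NAG"), carb("A", 402, "NAG", (5, 0, 0)),
            carb("A", 403, "BMA", (10, 0, 0)), carb("A", 404, "MAN", (15, 0, 0)),
            links=[link(("A", 22), "ND2", ("A", 401)),
                   link(("A", 401), "O4", ("A", 402)),
                   link(("A", 402), "O4", ("A", 403)),
                   link(("A", 403), "O3", ("A", 404))])
        trees, _ = extract_trees(m)
        seen = [n for t in trees for n in t.nodes]
        assert len(seen) == len(set(seen))
        for t in trees:
            assert len(t.nodes) == len(t.edges)  # root edge from Asn included


class TestTreeTypes:
    def test_all_five_types_share_core(self):
        defs = load_tree_types()
        assert set(defs) == {"high-mannose", "hybrid-mammal", "complex-mammal",
                             "hybrid-plant", "complex-plant"}
        for d in defs.values():
            for cid in CORE_IDS:
                assert cid in d.nodes
        core_prods = {("ASN", "N", "NAG", "beta"), ("NAG", 4, "NAG", "beta"),
                      ("NAG", 4, "BMA", "beta"), ("BMA", 3, "MAN", "alpha"),
                      ("BMA", 6, "MAN", "alpha")}
        for d in defs.values():
            assert core_prods <= d.productions()

    def test_no_trees_defaults_to_high_mannose_with_fucoses(self):
        defs = load_tree_types()
        m = peptide_model(["ALA", "ASN", "GLY", "THR", "ALA"])
        chosen = select_tree_type([], defs, m)
        assert chosen.name == "high-mannose"
        assert set(chosen.fucose_ids) == {"fuc3", "fuc6"}

    def _core_model(self, extra_comps=()):
        """Asn + full core + optional beyond-core children of man3."""
        m = peptide_model(["ALA", "ASN", "GLY", "THR", "ALA"])
        comps = [("NAG", 401), ("NAG", 402), ("BMA", 403), ("MAN", 404), ("MAN", 405)]
        for i, (c, s) in enumerate(comps):
            m.residues.append(carb("A", s, c, (i * 4.0, 0, 0)))
        m.links += [link(("A", 22), "ND2", ("A", 401)),
                    link(("A", 401), "O4", ("A", 402)),
                    link(("A", 402), "O4", ("A", 403)),
                    link(("A", 403), "O3", ("A", 404)),
                    link(("A", 403), "O6", ("A", 405))]
        seq = 406
        for comp, parent, pos in extra_comps:
            m.residues.append(carb("A", seq, comp, (seq - 400) * 4.0))
            m.links.append(link(("A", parent), f"O{pos}", ("A", seq)))
            seq += 1
        return m

    def test_core_only_selects_default_type(self):
        defs = load_tree_types()
        m = self._core_model()
        trees, _ = extract_trees(m)
        assert select_tree_type(trees, defs, m).name == "high-mannose"

    def test_beyond_core_nag_selects_mammal_type(self):
        defs = load_tree_types()
        # NAG b1-2 on man3 + bisecting NAG b1-4 on bma: hybrid-mammal pattern
        m = self._core_model([("NAG", 404, 2), ("NAG", 403, 4)])
        trees, _ = extract_trees(m)
        assert select_tree_type(trees, defs, m).name == "hybrid-mammal"

    def test_beyond_core_xylose_selects_plant_type(self):
        defs = load_tree_types()
        m = self._core_model([("XYP", 403, 2)])
        trees, _ = extract_trees(m)
        assert select_tree_type(trees, defs, m).name.endswith("plant")

    def test_classify_core_all_conforming(self):
        defs = load_tree_types()
        m = self._core_model()
        trees, _ = extract_trees(m)
        cls = classify_residues(trees[0], defs, m)
        assert set(cls.values()) == {"conforming"}

    def test_unknown_component_and_descendants_nonstandard(self):
        defs = load_tree_types()
        m = self._core_model()
        # replace BMA with an inverted-chirality analogue: children follow
        m.residue(("A", 403, "")).comp_id = "LXZ"
        trees, _ = extract_trees(m)
        cls = classify_residues(trees[0], defs, m)
        assert cls[("A", 403, "")] == "nonstandard"
        assert cls[("A", 404, "")] == "nonstandard"
        assert cls[("A", 405, "")] == "nonstandard"
        assert cls[("A", 401, "")] == "conforming"

    def test_core_fucose_is_conforming(self):
        defs = load_tree_types()
        m = self._core_model()
        m.residues.append(carb("A", 406, "FUC", (30, 0, 0)))
        m.links.append(link(("A", 401), "O6", ("A", 406)))
        trees, _ = extract_trees(m)
        cls = classify_residues(trees[0], defs, m)
        assert cls[("A", 406, "")] == "conforming"

    def test_conforming_set_closed_under_ancestors(self):
        defs = load_tree_types()
        m = self._core_model([("NAG", 404, 2)])
        trees, _ = extract_trees(m)
        tree = trees[0]
        cls = classify_residues(tree, defs, m)
        for key, label in cls.items():
            if label != "conforming":
                continue
            edge = tree.parent_edge(key)
            while edge is not None and edge.position != "N":
                assert cls[edge.parent] == "conforming"
                edge = tree.parent_edge(edge.parent)
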