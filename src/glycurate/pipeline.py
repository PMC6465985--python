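"""End-to-end curation of N-glycosylation trees in a structure model.

The pipeline runs, in order: link generation for unlinked sugars, NDG
renaming, tree extraction and tree-type selection, cropping of poor-quality
or nonstandard carbohydrate residues, temporary clearing of blocking
molecules (all waters, unlinked single carbohydrates of the common types,
detached carbohydrate chains near sites of interest), extension of existing
trees followed by whole-tree addition at free sequon sites, density-based
filtering of everything newly built, old-vs-new tree comparison with
optional grafting of surviving old branches, and finally restoration of
cleared molecules that do not clash with the new build.

All decision rules are exposed via :class:`ScoreConfig` / :class:`LinkConfig`
defaults: new residues are accepted when RSCC >= 0.70, or RSCC + EDIAm >
1.20, or — at resolutions better than 3.0 A — when 0.60 <= RSCC < 0.70 and
the carbohydrate/main-chain density ratio is at least 0.25. Symmetry clashes
below 2.1 A kill a new residue; restoration uses 2.5 A (and 2.0 A against
rebuilt residues when grafting). Tree comparison counts 'yes' statuses first,
then 'check', then size, with the newly built tree winning exact ties.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import chem
from .builder import extend_tree, next_free_seq
from .density import DensityMap, ResidueScores, ScoreConfig, calc_model_map, score_residue
from .links import LinkConfig, LinkDecision, detect_asn_links, rename_linked_ndg
from .model import (LinkRecord, ResidueKey, ResidueRecord, StructureModel,
                    UndefinedDistanceError, min_symmetry_distance)
from .rings import RingStatus, validate_residue
from .topology import (GlycanTree, classify_residues, extract_trees, find_sequons,
                       load_tree_types, select_tree_type, _match_tree_to_type)

log = logging.getLogger(__name__)

CLEAR_NEAR_ASN = 2.5    # detached chains closer than this to a site are parked
GRAFT_LINK_MAX = 2.5    # old child's C1 must be this close to the rebuilt oxygen
GRAFT_CLASH = 2.0       # restored old branch must not clash with new residues
RESTORE_CLASH = 2.5     # parked molecules must not clash with new residues


@dataclasses.dataclass
class PipelineConfig:
    link: LinkConfig = dataclasses.field(default_factory=LinkConfig)
    score: ScoreConfig = dataclasses.field(default_factory=ScoreConfig)
    fit_threshold: float = 0.6
    b_new: float = 30.0


@dataclasses.dataclass
class ParkedSet:
    waters: list[ResidueRecord] = dataclasses.field(default_factory=list)
    single_carbs: list[ResidueRecord] = dataclasses.field(default_factory=list)
    detached_chains: list[list[ResidueRecord]] = dataclasses.field(default_factory=list)
    chain_links: list[LinkRecord] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class TreeVerdict:
    counts_old: tuple[int, int, int]
    counts_new: tuple[int, int, int]
    chosen: str  # 'old' | 'new' | 'grafted'


@dataclasses.dataclass
class BuildReport:
    built: list[ResidueKey] = dataclasses.field(default_factory=list)
    deleted: list[ResidueKey] = dataclasses.field(default_factory=list)
    restored: list[ResidueKey] = dataclasses.field(default_factory=list)
    links_added: list[LinkRecord] = dataclasses.field(default_factory=list)
    scores: dict[ResidueKey, ResidueScores] = dataclasses.field(default_factory=dict)
    filter_outcomes: dict[ResidueKey, str] = dataclasses.field(default_factory=dict)
    verdicts: dict[ResidueKey, TreeVerdict] = dataclasses.field(default_factory=dict)
    link_decisions: list[LinkDecision] = dataclasses.field(default_factory=list)
    tree_type: str | None = None


# -- individual stages ------------------------------------------------------

def tree_statuses(model: StructureModel, tree: GlycanTree) -> dict[ResidueKey, RingStatus]:
    """Ring-validation status for every node, using the parent-side
    attachment atom to judge the anomeric configuration."""
    statuses: dict[ResidueKey, RingStatus] = {}
    for key in tree.nodes:
        res = model.residue(key)
        if res is None:
            continue
        edge = tree.parent_edge(key)
        sub_pos = None
        if edge is not None:
            parent = model.residue(edge.parent)
            if parent is not None:
                at = parent.atom(edge.parent_atom)
                if at is not None:
                    sub_pos = at.pos
        expected = chem.declared_anomer(res.comp_id)
        if edge is not None and edge.position == "N":
            expected = "beta"  # the N-glycosidic root bond is beta
        _, status = validate_residue(res, expected, sub_pos)
        statuses[key] = status
    return statuses


def crop_poor_residues(
    model: StructureModel,
    trees: list[GlycanTree],
    statuses: dict[ResidueKey, RingStatus],
    classification: dict[ResidueKey, str],
) -> tuple[dict[ResidueKey, list[ResidueRecord]], list[ResidueKey], list[GlycanTree]]:
    """Delete check/no-status and nonstandard residues plus their descendants.

    Mutates ``model``. Returns (cropped residues per root Asn, sites whose
    whole tree vanished, surviving pruned trees).
    """
    cropped: dict[ResidueKey, list[ResidueRecord]] = {}
    whole_tree_sites: list[ResidueKey] = []
    survivors: list[GlycanTree] = []
    for tree in trees:
        to_delete: set[ResidueKey] = set()
        for key in tree.nodes:
            status = statuses.get(key)
            bad = status is None or status.status in ("check", "no")
            if classification.get(key) == "nonstandard":
                bad = True
            if bad:
                to_delete.add(key)
                to_delete.update(tree.descendants(key))
        removed = model.remove_residues(to_delete)
        if removed:
            cropped[tree.root_asn] = removed
        if tree.root_carb in to_delete:
            whole_tree_sites.append(tree.root_asn)
        else:
            pruned = GlycanTree(
                root_asn=tree.root_asn,
                edges=[e for e in tree.edges if e.child not in to_delete],
                nodes=[n for n in tree.nodes if n not in to_delete])
            survivors.append(pruned)
    return cropped, whole_tree_sites, survivors


def clear_blocking_molecules(
    model: StructureModel, asns_of_interest: list[ResidueKey]
) -> ParkedSet:
    """Temporarily remove molecules that could block carbohydrate building.

    All waters; unlinked single carbohydrates of the common N-glycan types;
    and detached (linked but protein-unattached) carbohydrate chains with any
    atom closer than 2.5 A to an asparagine of interest. Mutates ``model``.
    """
    parked = ParkedSet()
    water_keys = [r.key for r in model.residues if chem.is_water(r.comp_id)]
    parked.waters = model.remove_residues(water_keys)

    _, unattached = extract_trees(model)
    asn_pts = []
    for key in asns_of_interest:
        res = model.residue(key)
        if res is not None:
            asn_pts.extend(a.pos for a in res.heavy_atoms())
    asn_pts = np.array(asn_pts) if asn_pts else None
    for chain_keys in unattached:
        if asn_pts is None:
            break
        pts = [a.pos for k in chain_keys
               for a in (model.residue(k).heavy_atoms() if model.residue(k) else [])]
        if not pts:
            continue
        d = np.sqrt(((np.array(pts)[:, None, :] - asn_pts[None, :, :]) ** 2).sum(axis=2))
        if float(d.min()) < CLEAR_NEAR_ASN:
            parked.chain_links.extend(
                ln.copy() for ln in model.links
                if ln.atom_a[:3] in chain_keys or ln.atom_b[:3] in chain_keys)
            parked.detached_chains.append(model.remove_residues(chain_keys))

    singles = [r.key for r in model.residues
               if r.comp_id in chem.PARKABLE_COMPS and not model.links_of(r.key)]
    parked.single_carbs = model.remove_residues(singles)
    return parked


def filter_new_residues(
    new_trees: list[GlycanTree],
    new_keys: set[ResidueKey],
    scores: dict[ResidueKey, ResidueScores],
    statuses: dict[ResidueKey, RingStatus],
    cfg: ScoreConfig,
    model: StructureModel,
    preexisting: list[ResidueRecord],
    resolution: float | None,
) -> dict[ResidueKey, str]:
    """Accept/discard each newly built residue per the density rules.

    keep iff ring status is 'yes' AND no strong symmetry clash (< 2.1 A with
    symmetry copies of pre-existing atoms) AND the density rule passes:
    RSCC >= 0.70, or RSCC + EDIAm > 1.20, or the borderline density-ratio
    rule at better than 3.0 A resolution. Discarding a residue discards its
    descendants.
    """
    outcomes: dict[ResidueKey, str] = {}
    pre_atoms = [a for r in preexisting for a in r.heavy_atoms()]

    def density_ok(s: ResidueScores) -> bool:
        if s.rscc >= cfg.rscc_accept:
            return True
        if s.rscc + s.ediam > cfg.sum_accept:
            return True
        if (resolution is not None and resolution < cfg.ratio_resolution_cutoff
                and cfg.rscc_borderline_low <= s.rscc < cfg.rscc_accept
                and s.density_ratio >= cfg.ratio_accept):
            return True
        return False

    for tree in new_trees:
        for key in tree.nodes:
            if key not in new_keys:
                continue
            res = model.residue(key)
            if res is None:
                outcomes[key] = "discard:gone"
                continue
            st = statuses.get(key)
            if st is None or st.status != "yes":
                outcomes[key] = "discard:geometry"
                continue
            if pre_atoms:
                try:
                    d, _ = min_symmetry_distance(model, res.heavy_atoms(), pre_atoms,
                                                 exclude_identity=True)
                    if d < cfg.sym_clash:
                        outcomes[key] = "discard:sym-clash"
                        continue
                except UndefinedDistanceError:
                    pass
            s = scores.get(key)
            if s is None or not density_ok(s):
                outcomes[key] = "discard:density"
                continue
            outcomes[key] = "keep"
        # cascade discards down the tree
        for key in tree.nodes:
            if key not in new_keys or outcomes.get(key, "").startswith("discard"):
                continue
            edge = tree.parent_edge(key)
            while edge is not None:
                parent_out = outcomes.get(edge.parent)
                if parent_out is not None and parent_out.startswith("discard"):
                    outcomes[key] = "discard:parent"
                    break
                edge = tree.parent_edge(edge.parent)
    return outcomes


def choose_best_tree(counts_old: tuple[int, int, int],
                     counts_new: tuple[int, int, int]) -> TreeVerdict:
    """Old-vs-new comparison: most 'yes', then most 'check', then largest;
    exact ties keep the newly built tree."""
    yes_o, check_o, total_o = counts_old
    yes_n, check_n, total_n = counts_new
    if yes_n != yes_o:
        chosen = "new" if yes_n > yes_o else "old"
    elif check_n != check_o:
        chosen = "new" if check_n > check_o else "old"
    elif total_n != total_o:
        chosen = "new" if total_n > total_o else "old"
    else:
        chosen = "new"
    return TreeVerdict(counts_old, counts_new, chosen)


def status_counts(statuses: dict[ResidueKey, RingStatus],
                  keys: list[ResidueKey]) -> tuple[int, int, int]:
    yes = sum(1 for k in keys if k in statuses and statuses[k].status == "yes")
    check = sum(1 for k in keys if k in statuses and statuses[k].status == "check")
    return (yes, check, len(keys))


def graft_tree(
    model: StructureModel,
    new_tree: GlycanTree,
    old_tree: GlycanTree,
    old_residues: dict[ResidueKey, ResidueRecord],
    old_links: list[LinkRecord],
) -> tuple[list[ResidueRecord], list[LinkRecord]]:
    """Re-attach surviving old sub-branches onto rebuilt residues.

    For every old edge whose parent slot was rebuilt but whose child was not,
    the old child (with its whole sub-branch) is restored when its anomeric
    carbon lies within 2.5 A of the rebuilt parent's attachment oxygen and no
    atom of the branch comes within 2.0 A of a newly built residue. Mutates
    ``model``; returns (restored residues, links added).
    """
    typedefs = load_tree_types()
    # slot mapping for both trees against every type; use the type that maps
    # the most old residues (the old tree defines what there is to graft)
    best = None
    for typedef in typedefs.values():
        m_old = _match_tree_to_type(old_tree, typedef, _ResidueView(old_residues, model))
        m_new = _match_tree_to_type(new_tree, typedef, model)
        if best is None or len(m_old) > len(best[0]):
            best = (m_old, m_new)
    m_old, m_new = best
    slot_to_new = {slot: key for key, slot in m_new.items()}

    new_atom_list = []
    for key in new_tree.nodes:
        res = model.residue(key)
        if res is not None:
            new_atom_list.extend((key, a) for a in res.heavy_atoms())

    restored: list[ResidueRecord] = []
    links_added: list[LinkRecord] = []
    for edge in old_tree.edges:
        if edge.position == "N":
            continue
        parent_slot = m_old.get(edge.parent)
        child_slot = m_old.get(edge.child)
        if parent_slot is None or parent_slot not in slot_to_new:
            continue
        if child_slot is not None and child_slot in slot_to_new:
            continue  # child was itself rebuilt
        new_parent = model.residue(slot_to_new[parent_slot])
        ox = new_parent.atom(edge.parent_atom) if new_parent else None
        child = old_residues.get(edge.child)
        if ox is None or child is None:
            continue
        c1 = child.atom("C1")
        if c1 is None or float(np.linalg.norm(c1.pos - ox.pos)) >= GRAFT_LINK_MAX:
            continue
        branch_keys = [edge.child] + _old_descendants(old_tree, edge.child)
        branch = [old_residues[k] for k in branch_keys if k in old_residues]
        # clash check excludes the attachment oxygen: the new C1-Ox contact
        # is the covalent bond being formed, not a clash
        clash_env = [a.pos for k, a in new_atom_list
                     if not (k == new_parent.key and a.name == edge.parent_atom)]
        if clash_env and branch:
            pts = np.array([a.pos for r in branch for a in r.heavy_atoms()])
            env = np.array(clash_env)
            d = np.sqrt(((pts[:, None, :] - env[None, :, :]) ** 2).sum(axis=2))
            if float(d.min()) < GRAFT_CLASH:
                continue
        for r in branch:
            model.add_residue(r)
            restored.append(r)
        link = LinkRecord(
            (new_parent.chain_id, new_parent.seq_num, new_parent.ins_code, edge.parent_atom),
            (child.chain_id, child.seq_num, child.ins_code, "C1"),
            declared_distance=round(float(np.linalg.norm(c1.pos - ox.pos)), 3))
        model.links.append(link)
        links_added.append(link)
        branch_set = set(branch_keys)
        for ln in old_links:
            if ln.atom_a[:3] in branch_set and ln.atom_b[:3] in branch_set:
                model.links.append(ln.copy())
                links_added.append(ln)
    return restored, links_added


def _old_descendants(tree: GlycanTree, key: ResidueKey) -> list[ResidueKey]:
    return tree.descendants(key)


class _ResidueView:
    """Residue lookup over parked/cropped records, falling back to a model."""

    def __init__(self, store: dict[ResidueKey, ResidueRecord], model: StructureModel):
        self._store = store
        self._model = model

    def residue(self, key: ResidueKey) -> ResidueRecord | None:
        return self._store.get(key) or self._model.residue(key)


def restore_parked(
    model: StructureModel,
    parked: ParkedSet,
    new_residues: list[ResidueRecord],
) -> list[ResidueRecord]:
    """Put back parked waters/carbohydrates that do not clash with the build.

    A parked water or single carbohydrate returns unless any of its atoms is
    within 2.5 A (symmetry-aware) of a newly built residue; a detached chain
    returns only when none of its units clash. New residues are renumbered
    when restoration would duplicate a residue id; on flat-B models the new
    carbohydrates inherit the flat B value. Mutates ``model``.
    """
    new_atoms = [a for r in new_residues for a in r.heavy_atoms()]

    def clashes(res_list: list[ResidueRecord]) -> bool:
        if not new_atoms:
            return False
        atoms = [a for r in res_list for a in r.heavy_atoms()]
        if not atoms:
            return False
        try:
            d, _ = min_symmetry_distance(model, atoms, new_atoms)
        except UndefinedDistanceError:
            return False
        return d < RESTORE_CLASH

    restorable: list[ResidueRecord] = [w for w in parked.waters if not clashes([w])]
    restorable += [c for c in parked.single_carbs if not clashes([c])]
    chain_members: list[ResidueRecord] = []
    for chain in parked.detached_chains:
        if not clashes(chain):
            chain_members.extend(chain)
    incoming = {r.key for r in restorable} | {r.key for r in chain_members}

    # renumber colliding new residues first, while their links are still
    # unambiguous (the restored residues are not yet in the model)
    for r in new_residues:
        if r.key in incoming:
            old_key = r.key
            used = model.used_seq_nums(r.chain_id) | {
                k[1] for k in incoming if k[0] == r.chain_id}
            n = 401
            while n in used:
                n += 1
            r.seq_num = n
            _update_link_keys(model, old_key, r.key)

    restored: list[ResidueRecord] = []
    for r in restorable + chain_members:
        model.add_residue(r)
        restored.append(r)
    chain_keys = {r.key for r in chain_members}
    for ln in parked.chain_links:
        if ln.atom_a[:3] in chain_keys or ln.atom_b[:3] in chain_keys:
            model.links.append(ln.copy())

    if model.flat_b is not None:
        for r in new_residues:
            if chem.is_carbohydrate(r.comp_id):
                for a in r.atoms:
                    a.b = model.flat_b
    return restored


def _update_link_keys(model: StructureModel, old: ResidueKey, new: ResidueKey) -> None:
    for ln in model.links:
        if ln.atom_a[:3] == old:
            ln.atom_a = (new[0], new[1], new[2], ln.atom_a[3])
        if ln.atom_b[:3] == old:
            ln.atom_b = (new[0], new[1], new[2], ln.atom_b[3])


# -- the full pipeline ------------------------------------------------------

def run_pipeline(
    model: StructureModel,
    map_obs: DensityMap,
    cfg: PipelineConfig | None = None,
) -> tuple[StructureModel, BuildReport]:
    """Crop, clear, build, validate, compare, graft and restore.

    The input model is never mutated; the returned model is the curated
    version and the report accounts for every residue that was built,
    permanently deleted or restored.
    """
    cfg = cfg or PipelineConfig()
    report = BuildReport()
    obs = map_obs.sigma_normalized()

    # 1-2: link generation + NDG renaming
    new_links, decisions, work = detect_asn_links(model, cfg.link)
    report.link_decisions = decisions
    report.links_added.extend(new_links)
    work = rename_linked_ndg(work)

    # 3-4: tree extraction and type selection
    trees, _unattached = extract_trees(work)
    typedefs = load_tree_types()
    typedef = select_tree_type(trees, typedefs, work)
    report.tree_type = typedef.name

    # 5: crop poor/nonstandard residues
    statuses: dict[ResidueKey, RingStatus] = {}
    classification: dict[ResidueKey, str] = {}
    old_tree_by_asn: dict[ResidueKey, GlycanTree] = {t.root_asn: t for t in trees}
    old_statuses: dict[ResidueKey, RingStatus] = {}
    for tree in trees:
        st = tree_statuses(work, tree)
        statuses.update(st)
        old_statuses.update(st)
        classification.update(classify_residues(tree, typedefs, work))
    old_links_all = [ln.copy() for ln in work.links]
    cropped, whole_tree_sites, surviving_trees = crop_poor_residues(
        work, trees, statuses, classification)
    cropped_store: dict[ResidueKey, ResidueRecord] = {
        r.key: r for residues in cropped.values() for r in residues}

    # 6: asparagines of interest = free sequon sites (incl. fully cropped
    # roots), skipping chitobiose-blocked asparagines
    rooted = {t.root_asn for t in surviving_trees}
    cbs_blocked = set()
    for ln in work.links:
        for this, other in ((ln.atom_a, ln.atom_b), (ln.atom_b, ln.atom_a)):
            res = work.residue(other[:3])
            if res is not None and res.comp_id == "CBS" and this[3] == "ND2":
                cbs_blocked.add(this[:3])
    sites = [s.asn for s in find_sequons(work)
             if s.asn not in rooted and s.asn not in cbs_blocked]

    # 7: temporary clearing
    parked = clear_blocking_molecules(work, sites)

    # 8: extend existing trees first, then whole-tree addition
    preexisting = [r.copy() for r in work.residues]
    preexisting_keys = {r.key for r in preexisting}
    built_trees: list[GlycanTree] = []
    new_residues: list[ResidueRecord] = []
    for tree in surviving_trees:
        tree, grown = extend_tree(tree, typedef, obs, work,
                                  fit_threshold=cfg.fit_threshold, b_new=cfg.b_new)
        new_residues.extend(grown)
        built_trees.append(tree)
    for asn_key in sites:
        tree = GlycanTree(root_asn=asn_key)
        tree, grown = extend_tree(tree, typedef, obs, work,
                                  fit_threshold=cfg.fit_threshold, b_new=cfg.b_new)
        new_residues.extend(grown)
        if tree.nodes:
            built_trees.append(tree)

    new_keys = {r.key for r in new_residues}

    # 9: score and filter the new residues
    if new_residues:
        d_min = work.resolution or (model.resolution if model.resolution else None)
        map_calc = calc_model_map(
            work, d_min=d_min, shape=obs.grid.shape,
            b_override_comps=frozenset(chem.CARB_COMPS), b_override=cfg.score.b_override)
        new_statuses: dict[ResidueKey, RingStatus] = {}
        for tree in built_trees:
            new_statuses.update(tree_statuses(work, tree))
        statuses.update(new_statuses)
        scores = {}
        for r in new_residues:
            scores[r.key] = score_residue(r, work, obs, cfg.score, d_min, map_calc=map_calc)
        report.scores = scores
        outcomes = filter_new_residues(built_trees, new_keys, scores, new_statuses,
                                       cfg.score, work, preexisting, d_min)
        report.filter_outcomes = outcomes
        discard = [k for k, v in outcomes.items() if v.startswith("discard")]
        work.remove_residues(discard)
        new_residues = [r for r in new_residues if r.key not in set(discard)]
        new_keys = {r.key for r in new_residues}
        for tree in built_trees:
            tree.edges = [e for e in tree.edges if e.child not in set(discard)]
            tree.nodes = [n for n in tree.nodes if n not in set(discard)]

    # 10: old-vs-new comparison per rebuilt site + grafting
    final_statuses: dict[ResidueKey, RingStatus] = {}
    for tree in built_trees:
        final_statuses.update(tree_statuses(work, tree))
    for tree in built_trees:
        asn_key = tree.root_asn
        old_tree = old_tree_by_asn.get(asn_key)
        if old_tree is None or asn_key not in cropped:
            continue  # nothing was rebuilt here
        counts_old = status_counts(old_statuses, old_tree.nodes)
        counts_new = status_counts(final_statuses, tree.nodes)
        verdict = choose_best_tree(counts_old, counts_new)
        if verdict.chosen == "old":
            # revert: drop this site's new residues, restore all old ones
            site_new = [k for k in tree.nodes if k in new_keys]
            work.remove_residues(site_new)
            new_residues = [r for r in new_residues if r.key not in set(site_new)]
            new_keys -= set(site_new)
            for r in cropped[asn_key]:
                work.add_residue(r)
                report.restored.append(r.key)
                cropped_store.pop(r.key, None)
            for ln in old_links_all:
                if any(ln.involves(r.key) for r in cropped[asn_key]) and \
                        ln not in work.links:
                    work.links.append(ln.copy())
        else:
            grafted, graft_links = graft_tree(
                work, tree, old_tree, cropped_store, old_links_all)
            if grafted:
                verdict.chosen = "grafted"
                for r in grafted:
                    report.restored.append(r.key)
                    cropped_store.pop(r.key, None)
                report.links_added.extend(graft_links)
        report.verdicts[asn_key] = verdict

    # 11: restoration of parked molecules, renumbering, flat-B adaptation
    restored = restore_parked(work, parked, new_residues)
    report.restored.extend(r.key for r in restored)

    # 12: bookkeeping
    input_keys = {r.key for r in model.residues}
    final_keys = {r.key for r in work.residues}
    report.built = [r.key for r in new_residues]
    report.deleted = sorted(k for k in input_keys if k not in final_keys)
    return work, report
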