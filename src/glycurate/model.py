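"""Structure data model and I/O for crystallographic protein models.

A :class:`StructureModel` holds residues (with atoms), covalent-link records,
the unit cell, symmetry operators and optional resolution. File parsing and
writing are delegated to gemmi for both PDB and mmCIF dialects; everything
downstream of I/O operates on the plain containers defined here.

Conventions
-----------
* Residues are identified by the author triple ``(chain_id, seq_num, ins_code)``,
  matching LINK-record semantics.
* Only the highest-occupancy alternate conformer of each atom is retained.
* Hydrogens are kept on read but excluded from all geometry and density
  computations (see :meth:`ResidueRecord.heavy_atoms`).
"""
from __future__ import annotations

import dataclasses
import math
import os
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from . import chem

ResidueKey = tuple[str, int, str]


class DuplicateResidueError(ValueError):
    """Raised when writing a model with duplicated residue identifiers."""


class UndefinedDistanceError(ValueError):
    """Raised when a distance query is made against an empty atom set."""


@dataclasses.dataclass
class AtomRecord:
    name: str
    element: str
    pos: np.ndarray
    occ: float = 1.0
    b: float = 20.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.b < 0:
            raise ValueError(f"negative B factor for atom {self.name}")
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError(f"occupancy outside [0,1] for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.pos.copy(), self.occ, self.b, self.altloc)


@dataclasses.dataclass
class ResidueRecord:
    chain_id: str
    seq_num: int
    comp_id: str
    atoms: list[AtomRecord] = dataclasses.field(default_factory=list)
    ins_code: str = ""

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.ins_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def positions(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.pos for a in atoms])

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(self.chain_id, self.seq_num, self.comp_id,
                             [a.copy() for a in self.atoms], self.ins_code)

    def __repr__(self) -> str:  # compact, used in reports
        icode = self.ins_code or ""
        return f"{self.comp_id} {self.chain_id}{self.seq_num}{icode}"


AtomRef = tuple[str, int, str, str]  # chain, seq_num, ins_code, atom name


@dataclasses.dataclass
class LinkRecord:
    atom_a: AtomRef
    atom_b: AtomRef
    declared_distance: float | None = None

    def __post_init__(self) -> None:
        if self.atom_a == self.atom_b:
            raise ValueError("link endpoints must differ")

    def involves(self, key: ResidueKey) -> bool:
        return self.atom_a[:3] == key or self.atom_b[:3] == key

    def copy(self) -> "LinkRecord":
        return LinkRecord(self.atom_a, self.atom_b, self.declared_distance)


IDENTITY_OP = (np.eye(3), np.zeros(3))


@dataclasses.dataclass
class StructureModel:
    residues: list[ResidueRecord] = dataclasses.field(default_factory=list)
    links: list[LinkRecord] = dataclasses.field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
    sym_ops: list[tuple[np.ndarray, np.ndarray]] = dataclasses.field(
        default_factory=lambda: [IDENTITY_OP])
    resolution: float | None = None
    flat_b: float | None = None

    def __post_init__(self) -> None:
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0 or not all(0 < x < 180 for x in (al, be, ga)):
            raise ValueError(f"invalid cell {self.cell}")
        if not any(np.allclose(r, np.eye(3)) and np.allclose(t % 1.0, 0.0)
                   for r, t in self.sym_ops):
            self.sym_ops = [IDENTITY_OP] + list(self.sym_ops)

    # -- basic queries ----------------------------------------------------

    def unit_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    def orth_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix."""
        return np.array(self.unit_cell().orth.mat.tolist())

    def frac_matrix(self) -> np.ndarray:
        return np.array(self.unit_cell().frac.mat.tolist())

    def residue(self, key: ResidueKey) -> ResidueRecord | None:
        for r in self.residues:
            if r.key == key:
                return r
        return None

    def resolve_atom(self, ref: AtomRef) -> AtomRecord | None:
        res = self.residue(ref[:3])
        return res.atom(ref[3]) if res is not None else None

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def all_atoms(self, heavy_only: bool = True) -> Iterator[tuple[ResidueRecord, AtomRecord]]:
        for r in self.residues:
            for a in (r.heavy_atoms() if heavy_only else r.atoms):
                yield r, a

    def links_of(self, key: ResidueKey) -> list[LinkRecord]:
        return [ln for ln in self.links if ln.involves(key)]

    def duplicate_keys(self) -> list[ResidueKey]:
        seen: set[ResidueKey] = set()
        dups: list[ResidueKey] = []
        for r in self.residues:
            if r.key in seen and r.key not in dups:
                dups.append(r.key)
            seen.add(r.key)
        return dups

    def remove_residues(self, keys: Iterable[ResidueKey]) -> list[ResidueRecord]:
        """Remove residues (and any links touching them); returns the removed records."""
        keyset = set(keys)
        removed = [r for r in self.residues if r.key in keyset]
        self.residues = [r for r in self.residues if r.key not in keyset]
        self.links = [ln for ln in self.links
                      if not (ln.atom_a[:3] in keyset or ln.atom_b[:3] in keyset)]
        return removed

    def add_residue(self, residue: ResidueRecord, after: ResidueKey | None = None) -> None:
        if after is not None:
            for i, r in enumerate(self.residues):
                if r.key == after:
                    self.residues.insert(i + 1, residue)
                    return
        self.residues.append(residue)

    def used_seq_nums(self, chain_id: str) -> set[int]:
        return {r.seq_num for r in self.residues if r.chain_id == chain_id}

    def copy(self) -> "StructureModel":
        return StructureModel(
            residues=[r.copy() for r in self.residues],
            links=[ln.copy() for ln in self.links],
            cell=self.cell,
            sym_ops=[(r.copy(), t.copy()) for r, t in self.sym_ops],
            resolution=self.resolution,
            flat_b=self.flat_b,
        )


# -- I/O -------------------------------------------------------------------

_FORMATS = ("pdb", "mmcif")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    return "mmcif" if ext in (".cif", ".mmcif") else "pdb"


def _dedup_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    best: dict[str, gemmi.Atom] = {}
    for at in res:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ:
            best[at.name] = at
    # keep original file order of the surviving conformers
    chosen = set(id(a) for a in best.values())
    return [a for a in res if id(a) in chosen]


def read_structure(path: str, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Covalent `LINK` / `_struct_conn` entries become :class:`LinkRecord`;
    CRYST1 / `_cell` populates the cell; space-group symmetry operators are
    resolved through gemmi when a space group is recorded, otherwise only the
    identity operator is present.
    """
    fmt = _infer_format(path, fmt)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")

    model = st[0]
    residues: list[ResidueRecord] = []
    for ch in model:
        for res in ch:
            atoms = []
            for at in _dedup_altlocs(res):
                occ = min(max(float(at.occ), 0.0), 1.0)
                atoms.append(AtomRecord(
                    name=at.name, element=at.element.name,
                    pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occ=occ, b=max(float(at.b_iso), 0.0),
                    altloc=at.altloc if at.altloc != "\x00" else ""))
            residues.append(ResidueRecord(
                chain_id=ch.name, seq_num=res.seqid.num,
                comp_id=res.name.strip(), atoms=atoms,
                ins_code=res.seqid.icode.strip()))

    links: list[LinkRecord] = []
    for con in st.connections:
        if con.type not in (gemmi.ConnectionType.Covale, gemmi.ConnectionType.Unknown):
            continue
        p1, p2 = con.partner1, con.partner2
        ref_a = (p1.chain_name, p1.res_id.seqid.num, p1.res_id.seqid.icode.strip(), p1.atom_name)
        ref_b = (p2.chain_name, p2.res_id.seqid.num, p2.res_id.seqid.icode.strip(), p2.atom_name)
        if ref_a == ref_b:
            continue
        dist = float(con.reported_distance) if con.reported_distance > 0 else None
        links.append(LinkRecord(ref_a, ref_b, dist))

    cell = st.cell
    cell_params = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    if min(cell_params[:3]) <= 0:
        cell_params = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)

    sym_ops = [IDENTITY_OP]
    sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm) if st.spacegroup_hm else None
    if sg is not None:
        sym_ops = []
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            sym_ops.append((rot, tran))

    resolution = float(st.resolution) if st.resolution > 0 else None
    out = StructureModel(residues=residues, links=links, cell=cell_params,
                         sym_ops=sym_ops, resolution=resolution)
    out.flat_b = detect_flat_b(out)
    return out


def detect_flat_b(model: StructureModel, tol: float = 1e-3) -> float | None:
    """Return the shared B value if the model was refined with one overall B."""
    bs = [a.b for _, a in model.all_atoms(heavy_only=False)]
    if len(bs) > 10 and max(bs) - min(bs) < tol:
        return float(bs[0])
    return None


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = model.unit_cell()
    st.spacegroup_hm = "P 1"
    if model.resolution:
        st.resolution = model.resolution
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in model.residues:
        ch = chains.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id)
            chains[res.chain_id] = ch
            gm.add_chain(ch)
            ch = gm[-1]
            chains[res.chain_id] = ch
        gr = gemmi.Residue()
        gr.name = res.comp_id
        gr.seqid = gemmi.SeqId(res.seq_num, res.ins_code or " ")
        gr.het_flag = "A" if chem.is_amino_acid(res.comp_id) else "H"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occ
            ga.b_iso = a.b
            ga.altloc = a.altloc or "\x00"
            gr.add_atom(ga)
        ch.add_residue(gr)
    st.add_model(gm)
    for ln in model.links:
        con = gemmi.Connection()
        con.type = gemmi.ConnectionType.Covale
        con.asu = gemmi.Asu.Same
        p1 = gemmi.AtomAddress(ln.atom_a[0], gemmi.SeqId(ln.atom_a[1], ln.atom_a[2] or " "),
                               "", ln.atom_a[3])
        p2 = gemmi.AtomAddress(ln.atom_b[0], gemmi.SeqId(ln.atom_b[1], ln.atom_b[2] or " "),
                               "", ln.atom_b[3])
        # residue names are needed for the LINK record text
        res_a = model.residue(ln.atom_a[:3])
        res_b = model.residue(ln.atom_b[:3])
        p1.res_id.name = res_a.comp_id if res_a else ""
        p2.res_id.name = res_b.comp_id if res_b else ""
        con.partner1 = p1
        con.partner2 = p2
        if ln.declared_distance is not None:
            con.reported_distance = ln.declared_distance
        st.connections.append(con)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str, fmt: str | None = None) -> None:
    """Write a model to PDB or mmCIF; refuses models with duplicate residue ids."""
    dups = model.duplicate_keys()
    if dups:
        raise DuplicateResidueError(f"duplicate residue identifiers: {dups}")
    fmt = _infer_format(path, fmt)
    st = _to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))


# -- symmetry-aware distances ---------------------------------------------

_SHIFTS = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
                   dtype=float)


def min_symmetry_distance(
    model: StructureModel,
    probe_atoms: Sequence[AtomRecord],
    target_atoms: Sequence[AtomRecord],
    exclude_identity: bool = False,
) -> tuple[float, tuple[AtomRecord, AtomRecord]]:
    """Minimum distance between probe atoms and all symmetry/lattice images of
    target atoms.

    The minimum runs over every symmetry operator and lattice translations in
    {-1,0,1}^3. Under the identity operator with zero translation, pairs of
    literally identical atoms (same coordinates) are excluded so that an atom
    never reports distance zero to itself. With ``exclude_identity`` the
    identity image is skipped entirely, leaving only genuine symmetry copies.
    Returns ``(distance, (probe_atom, target_atom))``.
    """
    probe_atoms = list(probe_atoms)
    target_atoms = list(target_atoms)
    if not probe_atoms or not target_atoms:
        raise UndefinedDistanceError("empty atom set in symmetry distance query")
    probe = np.array([a.pos for a in probe_atoms])
    target = np.array([a.pos for a in target_atoms])
    orth = model.orth_matrix()
    frac = model.frac_matrix()
    target_f = target @ frac.T

    best = math.inf
    witness: tuple[AtomRecord, AtomRecord] | None = None
    for rot, tran in model.sym_ops:
        base = target_f @ rot.T + tran
        is_ident = np.allclose(rot, np.eye(3)) and np.allclose(tran, 0.0)
        for shift in _SHIFTS:
            if exclude_identity and is_ident and np.allclose(shift, 0.0):
                continue
            img = (base + shift) @ orth.T
            d2 = np.sum((probe[:, None, :] - img[None, :, :]) ** 2, axis=2)
            if is_ident and np.allclose(shift, 0.0):
                same = np.sum((probe[:, None, :] - target[None, :, :]) ** 2, axis=2) < 1e-18
                d2 = np.where(same, math.inf, d2)
            i, j = np.unravel_index(int(np.argmin(d2)), d2.shape)
            if d2[i, j] < best:
                best = float(d2[i, j])
                witness = (probe_atoms[i], target_atoms[j])
    if witness is None or not math.isfinite(best):
        raise UndefinedDistanceError("no valid atom pair in symmetry distance query")
    return math.sqrt(best), witness
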