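"""Real-space density maps, model-map synthesis and per-residue density
metrics (RSCC, EDIA/EDIAm, density ratio).

Model maps are sums of per-atom Gaussians derived from the four-Gaussian
International Tables X-ray form factors (taken from gemmi's IT92 table),
B-factor smeared and occupancy weighted, accumulated on a periodic grid over
the unit cell. An optional band limit truncates spatial frequencies beyond
1/d_min via FFT, approximating the resolution cutoff of a measured map.

Scoring follows the acceptance machinery used for automatically built
carbohydrates: all carbohydrate B factors are overridden with a constant
(default 30 A^2) before the model map is synthesized, so that good scores
require observed density at healthy contour levels rather than being
attainable by inflating B.
"""
from __future__ import annotations

import dataclasses
import math

import gemmi
import numpy as np

from . import chem
from .model import AtomRecord, ResidueRecord, StructureModel

FOUR_PI_SQ = 4.0 * math.pi ** 2


class UndefinedScoreError(ValueError):
    """A score could not be computed (empty mask, missing main chain, ...)."""


@dataclasses.dataclass
class DensityMap:
    grid: np.ndarray           # shape (nx, ny, nz), value at fractional (i/nx, j/ny, k/nz)
    cell: tuple[float, float, float, float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # fractional offset

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 points per axis")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    # -- geometry ---------------------------------------------------------

    def unit_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    def orth_matrix(self) -> np.ndarray:
        return np.array(self.unit_cell().orth.mat.tolist())

    def frac_matrix(self) -> np.ndarray:
        return np.array(self.unit_cell().frac.mat.tolist())

    @property
    def spacing(self) -> tuple[float, float, float]:
        a, b, c = self.cell[:3]
        nx, ny, nz = self.grid.shape
        return (a / nx, b / ny, c / nz)

    # -- values -----------------------------------------------------------

    def interpolate(self, positions: np.ndarray) -> np.ndarray:
        """Tri-linear periodic interpolation at Cartesian positions (N, 3)."""
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        frac = positions @ self.frac_matrix().T - np.asarray(self.origin)
        shape = np.array(self.grid.shape)
        idx = frac * shape  # fractional grid index
        i0 = np.floor(idx).astype(int)
        t = idx - i0
        out = np.zeros(len(positions))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                         * np.where(dy, t[:, 1], 1 - t[:, 1])
                         * np.where(dz, t[:, 2], 1 - t[:, 2]))
                    out += w * self.grid[(i0[:, 0] + dx) % shape[0],
                                         (i0[:, 1] + dy) % shape[1],
                                         (i0[:, 2] + dz) % shape[2]]
        return out

    def sigma_normalized(self) -> "DensityMap":
        """Map rescaled to mean 0, sd 1 over the full cell (sigma units)."""
        sd = float(self.grid.std())
        if sd < 1e-12:
            raise ValueError("cannot sigma-normalize a constant map")
        return DensityMap((self.grid - self.grid.mean()) / sd, self.cell, self.origin)

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.cell, self.origin)


@dataclasses.dataclass
class ResidueScores:
    rscc: float
    ediam: float
    density_ratio: float
    b_override: float


@dataclasses.dataclass
class ScoreConfig:
    b_override: float = 30.0
    rscc_accept: float = 0.70
    sum_accept: float = 1.20
    rscc_borderline_low: float = 0.60
    ratio_accept: float = 0.25
    ratio_resolution_cutoff: float = 3.0
    sym_clash: float = 2.1
    mask_radius: float = 2.0
    spacing: float = 0.5

    def __post_init__(self) -> None:
        if not self.rscc_borderline_low < self.rscc_accept:
            raise ValueError("rscc_borderline_low must be below rscc_accept")


# -- model-map synthesis ---------------------------------------------------

_FALLBACK_ELEMENT = "N"


def _gaussian_terms(element: str, b: float) -> list[tuple[float, float]]:
    """(amplitude, b_eff) pairs of the real-space density Gaussians.

    Each reciprocal-space term a*exp(-b s^2) transforms to
    a * (4pi/b_eff)^1.5 * exp(-4pi^2 r^2 / b_eff) with b_eff = b + B.
    The constant term c of the IT92 fit is carried as a sharp Gaussian
    smeared only by B (clamped to avoid a delta spike at tiny B).
    """
    el = gemmi.Element(element)
    if el.it92 is None:
        el = gemmi.Element(_FALLBACK_ELEMENT)
    coef = el.it92
    terms = [(a, bi + b) for a, bi in zip(coef.a, coef.b)]
    terms.append((coef.c, max(b, 2.0)))
    return [(a, be) for a, be in terms if a > 0]


def _grid_shape(cell, spacing: float) -> tuple[int, int, int]:
    return tuple(max(4, int(math.ceil(L / spacing))) for L in cell[:3])


def calc_model_map(model: StructureModel, d_min: float | None = None,
                   spacing: float = 0.5,
                   shape: tuple[int, int, int] | None = None,
                   b_override_comps: frozenset[str] | None = None,
                   b_override: float | None = None) -> DensityMap:
    """Synthesize the electron density of a model on a periodic grid.

    Non-hydrogen atoms only; occupancy-weighted; optionally band-limited to
    d_min by zeroing spatial frequencies beyond 1/d_min. ``b_override``
    replaces the B factor of atoms in residues whose comp_id is in
    ``b_override_comps`` (used for the constant-B carbohydrate convention).
    """
    cell = model.cell
    if shape is None:
        shape = _grid_shape(cell, spacing)
    grid = np.zeros(shape)
    dmap = DensityMap(grid, cell)
    orth = dmap.orth_matrix()
    frac = dmap.frac_matrix()
    # per-axis margin from reciprocal row norms (correct for triclinic cells)
    recip_norms = np.linalg.norm(frac, axis=1)
    nxyz = np.array(shape)

    for res in model.residues:
        override = (b_override is not None and b_override_comps is not None
                    and res.comp_id in b_override_comps)
        for atom in res.heavy_atoms():
            if atom.occ <= 0:
                continue
            b = b_override if override else atom.b
            terms = _gaussian_terms(atom.element, b)
            b_max = max(be for _, be in terms)
            # cut where the widest Gaussian falls to ~1e-5 of its peak
            r_cut = math.sqrt(b_max * math.log(1e5)) / (2 * math.pi)
            fpos = frac @ atom.pos
            lo = np.floor((fpos - r_cut * recip_norms) * nxyz).astype(int)
            hi = np.ceil((fpos + r_cut * recip_norms) * nxyz).astype(int)
            ix = np.arange(lo[0], hi[0] + 1)
            iy = np.arange(lo[1], hi[1] + 1)
            iz = np.arange(lo[2], hi[2] + 1)
            fx = ix / nxyz[0] - fpos[0]
            fy = iy / nxyz[1] - fpos[1]
            fz = iz / nxyz[2] - fpos[2]
            dx = np.stack(np.meshgrid(fx, fy, fz, indexing="ij"), axis=-1)
            cart = dx @ orth.T
            r2 = np.sum(cart * cart, axis=-1)
            dens = np.zeros_like(r2)
            for a, be in terms:
                dens += a * (4 * math.pi / be) ** 1.5 * np.exp(-FOUR_PI_SQ * r2 / be)
            dens *= atom.occ
            np.add.at(grid, (ix[:, None, None] % nxyz[0],
                             iy[None, :, None] % nxyz[1],
                             iz[None, None, :] % nxyz[2]), dens)
    if d_min is not None:
        dmap = band_limit(dmap, d_min)
    return dmap


def band_limit(dmap: DensityMap, d_min: float) -> DensityMap:
    """Zero all spatial frequencies with |s| > 1/d_min (s in 1/A)."""
    nx, ny, nz = dmap.grid.shape
    h = np.fft.fftfreq(nx) * nx
    k = np.fft.fftfreq(ny) * ny
    l = np.fft.fftfreq(nz) * nz
    hh, kk, ll = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([hh, kk, ll], axis=-1)
    svec = hkl @ dmap.frac_matrix()          # rows of frac are a*, b*, c*
    s2 = np.sum(svec * svec, axis=-1)
    f = np.fft.fftn(dmap.grid)
    f[s2 > 1.0 / d_min ** 2] = 0.0
    return DensityMap(np.real(np.fft.ifftn(f)), dmap.cell, dmap.origin)


# -- masks and RSCC --------------------------------------------------------

def grid_mask(dmap: DensityMap, atoms: list[AtomRecord], radius: float) -> np.ndarray:
    """Boolean grid mask: points within ``radius`` of any atom (periodic)."""
    mask = np.zeros(dmap.grid.shape, dtype=bool)
    frac = dmap.frac_matrix()
    orth = dmap.orth_matrix()
    recip_norms = np.linalg.norm(frac, axis=1)
    nxyz = np.array(dmap.grid.shape)
    r2max = radius * radius
    for atom in atoms:
        fpos = frac @ atom.pos
        lo = np.floor((fpos - radius * recip_norms) * nxyz).astype(int)
        hi = np.ceil((fpos + radius * recip_norms) * nxyz).astype(int)
        ix = np.arange(lo[0], hi[0] + 1)
        iy = np.arange(lo[1], hi[1] + 1)
        iz = np.arange(lo[2], hi[2] + 1)
        fx = ix / nxyz[0] - fpos[0]
        fy = iy / nxyz[1] - fpos[1]
        fz = iz / nxyz[2] - fpos[2]
        dxyz = np.stack(np.meshgrid(fx, fy, fz, indexing="ij"), axis=-1) @ orth.T
        inside = np.sum(dxyz * dxyz, axis=-1) <= r2max
        mask[np.ix_(ix % nxyz[0], iy % nxyz[1], iz % nxyz[2])] |= inside
    return mask


def rscc(residue: ResidueRecord, map_obs: DensityMap, map_calc: DensityMap,
         mask_radius: float = 2.0) -> float:
    """Real-space correlation coefficient over a mask around the residue."""
    if map_obs.grid.shape != map_calc.grid.shape:
        raise ValueError("observed and calculated maps must share a grid")
    atoms = residue.heavy_atoms()
    if not atoms:
        raise UndefinedScoreError(f"{residue}: no atoms to mask")
    mask = grid_mask(map_obs, atoms, mask_radius)
    n = int(mask.sum())
    if n < 2:
        raise UndefinedScoreError(f"{residue}: empty density mask")
    a = map_obs.grid[mask]
    b = map_calc.grid[mask]
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        raise UndefinedScoreError(f"{residue}: constant density in mask")
    return float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))


# -- EDIA -------------------------------------------------------------------

def edia_radius(resolution: float, b: float) -> float:
    """Electron-density radius of an atom, from resolution and B factor.

    Computed on the fly (rather than tabulated) as a linear profile in the
    resolution plus a soft B-dependence; clamped to a sane range. The
    constants below are this package's adopted profile.
    """
    r = 0.7 + 0.25 * resolution + 0.008 * b
    return float(min(max(r, 0.9), 3.0))


_PENALTY_OUTER = 1.25   # penalty shell extends to this multiple of the radius
_PENALTY_WEIGHT = 0.2
_CAP_SIGMA = 1.2        # density support saturates at this sigma level


def _edia_contrib(d: np.ndarray, z: np.ndarray, r: float) -> tuple[np.ndarray, np.ndarray]:
    """(contribution, positive-weight) arrays for the EDIA sum.

    Inside the density radius the (quadratically distance-weighted) capped
    density counts in full — positive support raises the score, negative
    density lowers it. In the shell just outside the radius only *negative*
    density is penalized: an atom's own density tail extending slightly past
    its radius is not evidence against it, but negative difference-density
    there is.
    """
    w_support = np.where(d <= r, 1.0 - (d / r) ** 2, 0.0)
    shell = (d > r) & (d <= _PENALTY_OUTER * r)
    contrib = w_support * z + np.where(shell, _PENALTY_WEIGHT * np.minimum(z, 0.0), 0.0)
    return contrib, w_support


def edia_atom(atom: AtomRecord, map_obs: DensityMap, resolution: float | None,
              b_override: float | None = None,
              competing_atoms: list[AtomRecord] | None = None) -> float:
    """Electron-density support for an individual atom, in [0, 1].

    ``map_obs`` must be sigma-normalized. Grid points around the atom are
    weighted by distance (quadratic falloff inside the density radius, a
    negative shell just outside), density values saturate at +1.2 sigma, and
    points owned by a closer competing atom do not contribute. The result is
    floored at zero: an atom in flat or negative density scores 0.
    """
    if resolution is None:
        raise UndefinedScoreError("EDIA needs the map resolution (d_min)")
    b = atom.b if b_override is None else b_override
    r = edia_radius(resolution, b)
    outer = _PENALTY_OUTER * r

    frac = map_obs.frac_matrix()
    orth = map_obs.orth_matrix()
    recip_norms = np.linalg.norm(frac, axis=1)
    nxyz = np.array(map_obs.grid.shape)
    fpos = frac @ atom.pos
    lo = np.floor((fpos - outer * recip_norms) * nxyz).astype(int)
    hi = np.ceil((fpos + outer * recip_norms) * nxyz).astype(int)
    ix = np.arange(lo[0], hi[0] + 1)
    iy = np.arange(lo[1], hi[1] + 1)
    iz = np.arange(lo[2], hi[2] + 1)
    fx = ix / nxyz[0] - fpos[0]
    fy = iy / nxyz[1] - fpos[1]
    fz = iz / nxyz[2] - fpos[2]
    cart = np.stack(np.meshgrid(fx, fy, fz, indexing="ij"), axis=-1) @ orth.T
    d = np.sqrt(np.sum(cart * cart, axis=-1))
    rho = map_obs.grid[np.ix_(ix % nxyz[0], iy % nxyz[1], iz % nxyz[2])]
    z = np.clip(rho / _CAP_SIGMA, -1.0, 1.0)
    contrib, w_support = _edia_contrib(d, z, r)
    if competing_atoms:
        pts = cart.reshape(-1, 3) + atom.pos
        dist_self = d.reshape(-1)
        owned = np.ones(len(pts), dtype=bool)
        for other in competing_atoms:
            if other is atom or np.allclose(other.pos, atom.pos):
                continue
            d_other = np.linalg.norm(pts - other.pos, axis=1)
            owned &= ~(d_other < dist_self)
        contrib = (contrib.reshape(-1) * owned).reshape(contrib.shape)
        w_support = (w_support.reshape(-1) * owned).reshape(w_support.shape)
    pos_sum = float(w_support.sum())
    if pos_sum < 1e-9:
        raise UndefinedScoreError("EDIA support region contains no grid points")
    score = float(contrib.sum() / pos_sum)
    return max(0.0, min(score, 1.2))


_EDIAM_FLOOR = 1e-2


def ediam(edias: list[float]) -> float:
    """Power mean with exponent -2 of per-atom EDIA values.

    The negative exponent makes a single unsupported atom dominate: one bad
    atom drags the residue score down regardless of how well the rest fit.
    Values are floored at a small epsilon for the mean and the result is
    capped at the maximum individual EDIA so the aggregate never exceeds the
    best atom.
    """
    if not edias:
        raise UndefinedScoreError("EDIAm of an empty atom set")
    arr = np.maximum(np.asarray(edias, dtype=float), _EDIAM_FLOOR)
    m = float(np.mean(arr ** -2.0) ** -0.5)
    return min(m, max(edias))


# -- residue-level scoring -------------------------------------------------

def density_ratio(residue: ResidueRecord, model: StructureModel,
                  map_obs: DensityMap) -> float:
    """Mean observed density at residue atoms over the protein main chain."""
    main_chain = [a for r in model.residues if chem.is_amino_acid(r.comp_id)
                  for a in r.heavy_atoms() if a.name in chem.MAIN_CHAIN_ATOMS]
    if not main_chain:
        raise UndefinedScoreError("no protein main chain for the density ratio")
    atoms = residue.heavy_atoms()
    if not atoms:
        raise UndefinedScoreError(f"{residue}: no atoms")
    num = float(np.mean(map_obs.interpolate(np.array([a.pos for a in atoms]))))
    den = float(np.mean(map_obs.interpolate(np.array([a.pos for a in main_chain]))))
    return max(num, 0.0) / max(den, 1e-6)


def score_residue(residue: ResidueRecord, model: StructureModel,
                  map_obs: DensityMap, cfg: ScoreConfig | None = None,
                  d_min: float | None = None,
                  map_calc: DensityMap | None = None) -> ResidueScores:
    """RSCC, EDIAm and density ratio for one residue.

    The model map is recomputed with every carbohydrate B factor set to
    ``cfg.b_override``, making the scores independent of the incoming B
    values. A precomputed ``map_calc`` (on the observed grid, with the same
    override) can be supplied to amortize the synthesis over many residues.
    """
    cfg = cfg or ScoreConfig()
    d_min = d_min or model.resolution
    if d_min is None:
        raise UndefinedScoreError("resolution (d_min) is required for scoring")
    obs = map_obs.sigma_normalized()
    if map_calc is None:
        map_calc = calc_model_map(
            model, d_min=d_min, shape=map_obs.grid.shape,
            b_override_comps=frozenset(chem.CARB_COMPS), b_override=cfg.b_override)
    cc = rscc(residue, obs, map_calc, cfg.mask_radius)
    atoms = residue.heavy_atoms()
    b_over = cfg.b_override if chem.is_carbohydrate(residue.comp_id) else None
    edias = [edia_atom(a, obs, d_min, b_override=b_over, competing_atoms=atoms)
             for a in atoms]
    em = ediam(edias)
    ratio = density_ratio(residue, model, obs)
    return ResidueScores(rscc=cc, ediam=em, density_ratio=ratio,
                         b_override=cfg.b_override)
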