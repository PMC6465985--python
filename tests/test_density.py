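import numpy as np
import pytest

from glycurate import chem
from glycurate.density import (DensityMap, ScoreConfig, UndefinedScoreError,
                               band_limit, calc_model_map, density_ratio,
                               edia_atom, ediam, rscc, score_residue)
from glycurate.geom import rotation_about_axis
from glycurate.model import AtomRecord, ResidueRecord, StructureModel


def single_atom_model(b=30.0, pos=(10.0, 10.0, 10.0), cell=(20, 20, 20, 90, 90, 90)):
    res = ResidueRecord("A", 1, "NAG", [AtomRecord("C1", "C", np.array(pos), b=b)])
    return StructureModel(residues=[res], cell=cell, resolution=2.0)


class TestModelMap:
    def test_single_atom_peak_at_site(self):
        m = single_atom_model()
        dmap = calc_model_map(m, spacing=0.5)
        peak_idx = np.unravel_index(dmap.grid.argmax(), dmap.grid.shape)
        assert peak_idx == (20, 20, 20)  # fractional (0.5, 0.5, 0.5)
        # spherical symmetry: equal values one step away on each axis
        c = peak_idx
        vals = [dmap.grid[c[0] + 1, c[1], c[2]], dmap.grid[c[0], c[1] + 1, c[2]],
                dmap.grid[c[0], c[1], c[2] + 1]]
        assert np.ptp(vals) < 1e-9

    def test_doubling_b_lowers_and_widens_peak(self):
        lo = calc_model_map(single_atom_model(b=30.0), spacing=0.5)
        hi = calc_model_map(single_atom_model(b=60.0), spacing=0.5)
        assert hi.grid.max() < lo.grid.max()

        def half_max_radius(dmap):
            half = dmap.grid.max() / 2
            row = dmap.grid[20, 20, 20:]
            return np.argmax(row < half) * dmap.spacing[2]

        assert half_max_radius(hi) > half_max_radius(lo)

    def test_superposition_linearity(self):
        a = single_atom_model(pos=(6.0, 10.0, 10.0))
        b = single_atom_model(pos=(14.0, 10.0, 10.0))
        both = a.copy()
        rb = b.residues[0].copy()
        rb.seq_num = 2
        both.residues.append(rb)
        ga = calc_model_map(a, spacing=0.5).grid
        gb = calc_model_map(b, spacing=0.5).grid
        gab = calc_model_map(both, spacing=0.5).grid
        np.testing.assert_allclose(gab, ga + gb, atol=1e-10)

    def test_rigid_motion_equivariance_by_probing(self):
        m = single_atom_model(pos=(8.0, 9.0, 11.0))
        rot = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 90.0)
        center = np.array([10.0, 10.0, 10.0])
        m2 = m.copy()
        m2.residues[0].atoms[0].pos = rot @ (m.residues[0].atoms[0].pos - center) + center
        d1 = calc_model_map(m, spacing=0.4)
        d2 = calc_model_map(m2, spacing=0.4)
        probes = np.array([[8.5, 9.5, 10.5], [7.5, 8.8, 11.2], [9.0, 9.0, 11.0]])
        moved = (probes - center) @ rot.T + center
        np.testing.assert_allclose(d2.interpolate(moved), d1.interpolate(probes), atol=1e-3)

    def test_unknown_element_falls_back(self):
        m = single_atom_model()
        m.residues[0].atoms[0].element = "Xx"
        dmap = calc_model_map(m, spacing=0.5)
        assert dmap.grid.max() > 0

    def test_band_limit_removes_high_frequencies(self):
        m = single_atom_model(b=10.0)
        raw = calc_model_map(m, spacing=0.4)
        smooth = band_limit(raw, 3.0)
        assert smooth.grid.max() < raw.grid.max()
        assert smooth.grid.sum() == pytest.approx(raw.grid.sum(), rel=1e-6)


class TestInterpolation:
    def test_trilinear_matches_grid_values_at_nodes(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(10, 12, 14))
        dmap = DensityMap(grid, (10, 12, 14, 90, 90, 90))
        # grid node (3, 4, 5) lies at Cartesian (3, 4, 5) in this cell
        val = dmap.interpolate(np.array([[3.0, 4.0, 5.0]]))[0]
        assert val == pytest.approx(grid[3, 4, 5])

    def test_periodic_wrap(self):
        grid = np.zeros((4, 4, 4))
        grid[0, 0, 0] = 1.0
        dmap = DensityMap(grid, (4, 4, 4, 90, 90, 90))
        assert dmap.interpolate(np.array([[4.0, 0.0, 0.0]]))[0] == pytest.approx(1.0)


class TestRscc:
    def test_self_correlation_near_one(self, glycosite_bundle):
        truth, dmap, _ = glycosite_bundle
        calc = calc_model_map(truth, d_min=2.0, shape=dmap.grid.shape)
        for res in truth.residues:
            if chem.is_carbohydrate(res.comp_id):
                assert rscc(res, calc, calc) >= 0.999

    def test_affine_invariance(self, glycosite_bundle):
        truth, dmap, _ = glycosite_bundle
        calc = calc_model_map(truth, d_min=2.0, shape=dmap.grid.shape)
        scaled = DensityMap(3.0 + 2.5 * calc.grid, calc.cell)
        res = next(r for r in truth.residues if r.comp_id == "NAG")
        assert rscc(res, scaled, calc) >= 0.999

    def test_uncorrelated_noise_scores_low(self, glycosite_bundle):
        truth, dmap, _ = glycosite_bundle
        calc = calc_model_map(truth, d_min=2.0, shape=dmap.grid.shape)
        rng = np.random.default_rng(1)
        noise = DensityMap(rng.normal(size=calc.grid.shape), calc.cell)
        res = next(r for r in truth.residues if r.comp_id == "NAG")
        assert abs(rscc(res, noise, calc)) < 0.2

    def test_empty_mask_is_undefined(self):
        m = single_atom_model()
        dmap = calc_model_map(m, spacing=0.5)
        ghost = ResidueRecord("A", 9, "HOH", [])
        with pytest.raises(UndefinedScoreError):
            rscc(ghost, dmap, dmap)


class TestEdia:
    def make_sigma_map(self, b=30.0):
        m = single_atom_model(b=b)
        dmap = calc_model_map(m, d_min=2.0, spacing=0.5)
        return m, dmap.sigma_normalized()

    def test_atom_on_own_peak_scores_high(self):
        m, obs = self.make_sigma_map()
        assert edia_atom(m.residues[0].atoms[0], obs, 2.0) > 0.8

    def test_atom_in_flat_map_scores_zero(self):
        m, obs = self.make_sigma_map()
        flat = DensityMap(np.zeros_like(obs.grid), obs.cell)
        assert edia_atom(m.residues[0].atoms[0], flat, 2.0) == 0.0

    def test_atom_in_negative_map_floored_at_zero(self):
        m, obs = self.make_sigma_map()
        neg = DensityMap(np.full_like(obs.grid, -2.0), obs.cell)
        assert edia_atom(m.residues[0].atoms[0], neg, 2.0) == 0.0

    def test_missing_resolution_is_an_error(self):
        m, obs = self.make_sigma_map()
        with pytest.raises(UndefinedScoreError, match="resolution"):
            edia_atom(m.residues[0].atoms[0], obs, None)

    def test_ediam_no_higher_than_best_atom(self):
        vals = [0.9, 0.8, 0.1]
        assert ediam(vals) <= max(vals)

    def test_ediam_dominated_by_worst_atom(self):
        assert ediam([0.9, 0.9, 0.05]) < 0.1

    def test_removing_worst_atom_never_decreases_ediam(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            vals = list(rng.uniform(0, 1.0, rng.integers(2, 8)))
            reduced = sorted(vals)[1:]
            assert ediam(reduced) >= ediam(vals) - 1e-12


class TestScoreResidue:
    def test_truth_residues_recover_high_scores(self, glycosite_bundle):
        truth, dmap, _ = glycosite_bundle
        cfg = ScoreConfig()
        for res in truth.residues:
            if chem.is_carbohydrate(res.comp_id):
                s = score_residue(res, truth, dmap, cfg, 2.0)
                assert s.rscc >= 0.95

    def test_displaced_residue_scores_poorly(self, glycosite_bundle):
        truth, dmap, _ = glycosite_bundle
        model = truth.copy()
        res = next(r for r in model.residues if r.comp_id == "BMA")
        for a in res.atoms:
            a.pos = a.pos + np.array([5.0, 0.0, 0.0])  # into bulk solvent
        s = score_residue(res, model, dmap, ScoreConfig(), 2.0)
        assert s.rscc < 0.3

    def test_scores_independent_of_incoming_b_factors(self, glycosite_bundle):
        truth, dmap, _ = glycosite_bundle
        res_key = next(r.key for r in truth.residues if r.comp_id == "BMA")
        base = score_residue(truth.residue(res_key), truth, dmap, ScoreConfig(), 2.0)
        perturbed = truth.copy()
        for r in perturbed.residues:
            if chem.is_carbohydrate(r.comp_id):
                for a in r.atoms:
                    a.b = 77.0
        redo = score_residue(perturbed.residue(res_key), perturbed, dmap,
                             ScoreConfig(), 2.0)
        assert redo.rscc == pytest.approx(base.rscc, abs=1e-9)
        assert redo.ediam == pytest.approx(base.ediam, abs=1e-9)
        assert redo.density_ratio == pytest.approx(base.density_ratio, abs=1e-9)

    def test_density_ratio_of_main_chain_against_itself(self, glycosite_bundle):
        truth, dmap, _ = glycosite_bundle
        obs = dmap.sigma_normalized()
        mc_atoms = [a.copy() for r in truth.residues if chem.is_amino_acid(r.comp_id)
                    for a in r.heavy_atoms() if a.name in chem.MAIN_CHAIN_ATOMS]
        fake = ResidueRecord("Z", 1, "ALA", mc_atoms)
        assert density_ratio(fake, truth, obs) == pytest.approx(1.0)

    def test_no_main_chain_is_undefined(self):
        m = single_atom_model()
        obs = calc_model_map(m, spacing=0.5).sigma_normalized()
        with pytest.raises(UndefinedScoreError):
            density_ratio(m.residues[0], m, obs)
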