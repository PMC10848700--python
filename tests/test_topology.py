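import numpy as np
import pytest

from densiwit.chem_io import GridSpec
from densiwit.density import eval_point
from densiwit.fixtures import (ToyGaussianSystem, toy_gaussian_system,
                               two_lump_bifurcation_separation,
                               two_lump_system)
from densiwit.topology import (assign_basins, basin_charges, classify_cp,
                               find_cps, poincare_hopf)


def toy(spec):
    return toy_gaussian_system(spec)


class TestTwoLumpBifurcation:
    """Midpoint character switches at a = 1/√(2β), β = 2α (closed form)."""

    def test_cp_census_across_the_bifurcation(self):
        alpha = 1.0
        a_star = two_lump_bifurcation_separation(alpha)
        wide = toy(two_lump_system(2 * (1.8 * a_star), alpha))
        cps_wide = find_cps(wide, seed=1)
        assert sorted(c.cp_type for c in cps_wide) == \
            ["bond", "nuclear_max", "nuclear_max"]
        mid = [c for c in cps_wide if c.cp_type == "bond"][0]
        assert np.allclose(mid.position, 0.0, atol=1e-8)

        narrow = toy(two_lump_system(2 * (0.6 * a_star), alpha))
        cps_narrow = find_cps(narrow, seed=1)
        maxima = [c for c in cps_narrow
                  if c.cp_type in ("nna", "nuclear_max")]
        assert len(maxima) == 1
        assert len(cps_narrow) == 1
        assert np.allclose(maxima[0].position, 0.0, atol=1e-8)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_bifurcation_point_matches_closed_form(self, alpha):
        a_star = two_lump_bifurcation_separation(alpha)
        just_above = toy(two_lump_system(2 * a_star * 1.05, alpha))
        just_below = toy(two_lump_system(2 * a_star * 0.95, alpha))
        pe_above = eval_point(just_above, [0, 0, 0])
        pe_below = eval_point(just_below, [0, 0, 0])
        # axial curvature changes sign across a*
        assert pe_above.hessian[0, 0] > 0
        assert pe_below.hessian[0, 0] < 0


class TestClassification:
    def test_nuclear_maximum_at_lih_lithium(self, models, cps_cache):
        li_pos = models["LiH"].atoms[0].position
        near_li = min(cps_cache["LiH"],
                      key=lambda c: np.linalg.norm(c.position - li_pos))
        # the Gaussian-basis maximum sits a fraction of a millibohr off Li
        assert np.linalg.norm(near_li.position - li_pos) < 0.01
        cp = classify_cp(near_li.position, models["LiH"])
        assert cp.cp_type == "nuclear_max"
        assert cp.signature == -3
        assert cp.rank == 3

    def test_li2_midbond_maximum_is_an_nna(self, models, cps_cache):
        nnas = [c for c in cps_cache["Li2"] if c.cp_type == "nna"]
        assert len(nnas) == 1
        assert np.allclose(nnas[0].position[:2], 0.0, atol=1e-6)
        assert nnas[0].nearest_atoms[0][1] > 2.0  # far from both Li

    def test_h2_midpoint_is_a_covalent_bond_cp(self, models):
        cp = classify_cp(np.zeros(3), models["H2"])
        assert cp.cp_type == "bond"
        assert cp.signature == -1
        assert cp.laplacian < 0  # covalent: local charge concentration

    def test_non_critical_point_raises(self, models):
        with pytest.raises(ValueError, match="not a critical point"):
            classify_cp([0.0, 0.0, 0.3], models["H2"])


class TestCriticalPointSearch:
    @pytest.mark.parametrize("name,n_max,n_bond", [
        ("H2", 2, 1), ("LiH", 2, 1), ("Li2", 3, 2), ("HCN", 3, 2),
    ])
    def test_expected_cp_census(self, cps_cache, name, n_max, n_bond):
        cps = cps_cache[name]
        maxima = [c for c in cps if c.cp_type in ("nuclear_max", "nna")]
        bonds = [c for c in cps if c.cp_type == "bond"]
        assert len(maxima) == n_max
        assert len(bonds) == n_bond

    @pytest.mark.parametrize("name", ["H2", "LiH", "Li2", "HCN",
                                      "H2_witness"])
    def test_poincare_hopf_holds(self, cps_cache, name):
        assert poincare_hopf(cps_cache[name]) == 1

    def test_poincare_hopf_with_a_ring_cp(self):
        # three lumps at a wide equilateral triangle: 3 maxima, 3 bond CPs,
        # 1 ring CP
        r = 2.2
        centers = tuple(
            (r * np.cos(t), r * np.sin(t), 0.0)
            for t in (0, 2 * np.pi / 3, 4 * np.pi / 3))
        model = toy(ToyGaussianSystem(centers=centers,
                                      exponents=(1.0,) * 3,
                                      weights=(1.0,) * 3))
        cps = find_cps(model, seed=2)
        census = sorted(c.cp_type for c in cps)
        assert census == ["bond"] * 3 + ["nuclear_max"] * 3 + ["ring"]
        assert poincare_hopf(cps) == 1

    @pytest.mark.parametrize("name", ["H2", "LiH", "Li2", "HCN"])
    def test_reported_cps_have_vanishing_gradient(self, models, cps_cache,
                                                  name):
        for cp in cps_cache[name]:
            pe = eval_point(models[name], cp.position)
            # tolerance scales with the Hessian magnitude (floating-point
            # floor at steep nuclear maxima)
            floor = 100 * np.finfo(float).eps * np.abs(pe.hessian).max() \
                * (1 + np.linalg.norm(cp.position))
            assert np.linalg.norm(pe.gradient) <= max(1e-10, floor)

    def test_duplicate_seeds_do_not_duplicate_cps(self, models):
        seeds = np.zeros((12, 3)) + [[0.0, 0.0, 0.01]]
        cps = find_cps(models["H2"], seeds=seeds)
        assert len(cps) == 1


class TestBasins:
    def test_single_gaussian_gives_one_basin(self):
        model = toy(ToyGaussianSystem(centers=((0, 0, 0),),
                                      exponents=(1.0,), weights=(1.0,)))
        grid = GridSpec.bounding(model.atoms, spacing=0.25, margin=5.0)
        bmap = assign_basins(model, grid)
        labels = bmap.labels.ravel()
        assert len(bmap.attractors) == 1
        assert set(labels[labels >= 0]) == {0}

    @pytest.mark.parametrize("method", ["weight", "ascent"])
    def test_h2_basins_are_mirror_symmetric(self, models, cps_cache, method):
        grid = GridSpec.bounding(models["H2"].atoms, spacing=0.15, margin=5.0)
        att = [c for c in cps_cache["H2"]
               if c.cp_type in ("nuclear_max", "nna")]
        bmap = assign_basins(models["H2"], grid, attractors=att,
                             method=method)
        counts = np.bincount(bmap.labels.ravel()[bmap.labels.ravel() >= 0])
        assert len(counts) == 2
        assert abs(counts[0] - counts[1]) <= 0.001 * counts.sum()

    def test_li2_has_three_basins_including_the_nna(self, models, cps_cache):
        grid = GridSpec.bounding(models["Li2"].atoms, spacing=0.2, margin=6.0)
        att = [c for c in cps_cache["Li2"]
               if c.cp_type in ("nuclear_max", "nna")]
        bmap = assign_basins(models["Li2"], grid, attractors=att)
        used = set(bmap.labels.ravel()) - {-1}
        assert used == {0, 1, 2}
        assert sum(1 for c in bmap.attractors if c.cp_type == "nna") == 1


class TestCharges:
    @pytest.mark.parametrize("name", ["H2", "LiH", "Li2"])
    def test_charge_sum_matches_grid_integral(self, models, cps_cache, name):
        from densiwit.density import eval_grid, integrate_density
        model = models[name]
        grid = GridSpec.bounding(model.atoms, spacing=0.15, margin=6.0)
        fld = eval_grid(model, grid)
        att = [c for c in cps_cache[name]
               if c.cp_type in ("nuclear_max", "nna")]
        bmap = assign_basins(model, grid, attractors=att,
                             field_values=fld.values)
        table = basin_charges(bmap, model, field_values=fld.values,
                              cusp_refine=False)
        total_z = sum(a.atomic_number for a in model.atoms)
        assert table.total_charge() == pytest.approx(
            total_z - integrate_density(fld), abs=0.03)

    def test_symmetry_equivalent_atoms_get_equal_charges(self, models,
                                                         cps_cache):
        for name in ("H2", "Li2"):
            model = models[name]
            grid = GridSpec.bounding(model.atoms, spacing=0.15, margin=6.0)
            att = [c for c in cps_cache[name]
                   if c.cp_type in ("nuclear_max", "nna")]
            bmap = assign_basins(model, grid, attractors=att)
            table = basin_charges(bmap, model)
            qs = [r["charge"] for r in table.rows if r["kind"] == "atom"]
            assert abs(qs[0] - qs[1]) < 0.02

    @pytest.mark.parametrize("name,spacings", [("H2", (0.2, 0.1)),
                                               ("LiH", (0.12, 0.06))])
    def test_charges_converge_under_grid_refinement(self, models, cps_cache,
                                                    name, spacings):
        """Halving the spacing moves no charge by more than 0.01 e.

        The ionic Li–H interface cuts through steeply varying density, so
        LiH starts from a finer base spacing than homonuclear H2."""
        model = models[name]
        att = [c for c in cps_cache[name]
               if c.cp_type in ("nuclear_max", "nna")]
        qs = {}
        for sp in spacings:
            grid = GridSpec.bounding(model.atoms, spacing=sp, margin=6.0)
            bmap = assign_basins(model, grid, attractors=att)
            table = basin_charges(bmap, model)
            qs[sp] = sorted(r["charge"] for r in table.rows)
        assert np.abs(np.array(qs[spacings[0]]) -
                      np.array(qs[spacings[1]])).max() < 0.01

    def test_populations_are_nonnegative(self, models, cps_cache):
        model = models["LiH"]
        grid = GridSpec.bounding(model.atoms, spacing=0.2, margin=5.0)
        att = [c for c in cps_cache["LiH"]
               if c.cp_type in ("nuclear_max", "nna")]
        table = basin_charges(assign_basins(model, grid, attractors=att),
                              model)
        assert all(r["population"] >= 0 for r in table.rows)
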