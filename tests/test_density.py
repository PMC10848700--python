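import numpy as np
import pytest

from densiwit.chem_io import GridSpec
from densiwit.density import (DensityModel, density_difference, eval_grid,
                              eval_point, integrate_density)
from densiwit.fixtures import (ToyGaussianSystem, toy_density,
                               toy_gaussian_system)
from densiwit.rdm import NoiseSpec, apply_noise, embed_active


def single_gaussian(alpha=1.0):
    return toy_gaussian_system(ToyGaussianSystem(
        centers=((0.0, 0.0, 0.0),), exponents=(alpha,), weights=(1.0,)))


class TestClosedFormOracles:
    def test_density_at_origin_matches_closed_form(self):
        """ρ(0) of a normalized s-Gaussian is (2α/π)^{3/2}."""
        for alpha in (0.5, 1.0, 2.3):
            pe = eval_point(single_gaussian(alpha), [0, 0, 0])
            assert pe.rho == pytest.approx((2 * alpha / np.pi) ** 1.5,
                                           abs=1e-10)
        assert eval_point(single_gaussian(1.0), [0, 0, 0]).rho == \
            pytest.approx(0.5079490874739278, abs=1e-10)

    def test_laplacian_at_origin_matches_closed_form(self):
        """∇²ρ(0) = −12α·ρ(0) for ρ ∝ exp(−2αr²)."""
        for alpha in (0.7, 1.0, 1.9):
            pe = eval_point(single_gaussian(alpha), [0, 0, 0])
            assert pe.laplacian == pytest.approx(-12 * alpha * pe.rho,
                                                 abs=1e-10)

    def test_off_center_density_matches_toy_oracle(self, rng):
        spec = ToyGaussianSystem(centers=((0, 0, 0), (1.5, 0.2, -0.3)),
                                 exponents=(1.0, 0.8), weights=(1.0, 1.2))
        model = toy_gaussian_system(spec)
        pts = rng.normal(scale=1.5, size=(40, 3))
        rho, _, _ = model.rho_batch(pts)
        assert np.allclose(rho, toy_density(spec, pts), atol=1e-12)


class TestDerivatives:
    @pytest.mark.parametrize("name", ["H2", "LiH", "HCN", "H2_witness"])
    def test_gradient_and_hessian_match_finite_differences(self, models,
                                                           name, rng):
        model = models[name]
        span = max(np.linalg.norm(a.position) for a in model.atoms) + 1.5
        pts = rng.uniform(-span, span, size=(100, 3))
        h = 1e-4
        for p in pts:
            pe = eval_point(model, p)
            if pe.rho < 1e-8:
                continue  # relative comparison meaningless in the far tail
            for ax in range(3):
                ep, em = p.copy(), p.copy()
                ep[ax] += h
                em[ax] -= h
                gp = eval_point(model, ep)
                gm = eval_point(model, em)
                grad_fd = (gp.rho - gm.rho) / (2 * h)
                scale = max(abs(pe.gradient[ax]), abs(pe.rho), 1e-10)
                assert abs(pe.gradient[ax] - grad_fd) / scale < 1e-6
                hess_fd = (gp.gradient - gm.gradient) / (2 * h)
                hscale = max(np.abs(pe.hessian[ax]).max(), abs(pe.rho), 1e-10)
                assert np.abs(pe.hessian[ax] - hess_fd).max() / hscale < 1e-6

    def test_laplacian_is_trace_of_hessian(self, models):
        pe = eval_point(models["LiH"], [0.1, -0.2, 1.0])
        assert pe.laplacian == pytest.approx(np.trace(pe.hessian), rel=1e-14)


class TestLinearityAndPositivity:
    def test_density_is_linear_in_the_rdm(self, bundles, rng):
        wfn, rdm = bundles["H2"]
        full = embed_active(rdm)
        d1 = full.matrix
        d2 = np.diag([0.5, 1.5])
        a, b = 0.3, 1.1
        pts = rng.normal(size=(20, 3))
        m1 = DensityModel(wfn, full.with_matrix(d1))
        m2 = DensityModel(wfn, full.with_matrix(d2))
        m12 = DensityModel(wfn, full.with_matrix(a * d1 + b * d2))
        r1, _, _ = m1.rho_batch(pts)
        r2, _, _ = m2.rho_batch(pts)
        r12, _, _ = m12.rho_batch(pts)
        assert np.allclose(r12, a * r1 + b * r2, atol=1e-13)

    def test_density_nonnegative_for_psd_rdm(self, models):
        for name in ("H2", "LiH", "H2_witness"):
            grid = GridSpec.bounding(models[name].atoms, spacing=0.4,
                                     margin=5.0)
            fld = eval_grid(models[name], grid)
            assert fld.values.min() >= -1e-14


class TestGrids:
    def test_toy_field_has_the_system_point_symmetry(self):
        model = single_gaussian(1.0)
        grid = GridSpec(origin=[-2, -2, -2], axes=np.eye(3) * 0.5,
                        shape=(9, 9, 9))
        v = eval_grid(model, grid).values
        assert np.abs(v - v[::-1, :, :]).max() < 1e-10
        assert np.abs(v - np.transpose(v, (2, 1, 0))).max() < 1e-10

    def test_h2_density_peaks_near_nuclei_not_box_edge(self, models):
        grid = GridSpec.bounding(models["H2"].atoms, spacing=0.2, margin=4.0)
        fld = eval_grid(models["H2"], grid)
        peak = np.unravel_index(np.argmax(fld.values), fld.values.shape)
        peak_pos = grid.origin + np.array(peak) @ grid.axes
        dmin = min(np.linalg.norm(peak_pos - a.position)
                   for a in models["H2"].atoms)
        assert dmin < 0.3

    def test_memory_budget_is_enforced(self, models):
        grid = GridSpec.bounding(models["H2"].atoms, spacing=0.05, margin=7.0)
        with pytest.raises(MemoryError):
            eval_grid(models["H2"], grid, memory_budget=10_000)

    def test_laplacian_field_integrates_to_nearly_zero(self, models):
        # ∫∇²ρ = 0 over all space (surface term vanishes)
        grid = GridSpec.bounding(models["H2"].atoms, spacing=0.12, margin=6.0)
        fld = eval_grid(models["H2"], grid, quantity="laplacian")
        assert abs(fld.values.sum() * grid.voxel_volume) < 5e-3


class TestIntegration:
    def test_constant_unit_field(self):
        grid = GridSpec([0, 0, 0], np.eye(3) * 0.5, (3, 3, 3))
        fld = eval_grid(single_gaussian(), grid)
        fld.values[:] = 1.0
        assert integrate_density(fld) == pytest.approx(27 * 0.125)

    def test_single_electron_toy_integrates_to_one(self):
        model = single_gaussian(1.0)
        grid = GridSpec.bounding(model.atoms, spacing=0.1, margin=8.0)
        assert integrate_density(eval_grid(model, grid)) == \
            pytest.approx(1.0, abs=1e-4)

    def test_h2_integrates_to_two_electrons(self, models):
        grid = GridSpec.bounding(models["H2"].atoms, spacing=0.1, margin=7.0)
        assert integrate_density(eval_grid(models["H2"], grid)) == \
            pytest.approx(2.0, rel=5e-3)


class TestDifferences:
    def test_identical_models_give_zero_field(self, models):
        grid = GridSpec.bounding(models["H2"].atoms, spacing=0.3, margin=4.0)
        diff = density_difference(models["H2"], models["H2"], grid)
        assert np.abs(diff.values).max() == 0.0

    def test_difference_integral_equals_count_discrepancy(self, bundles):
        wfn, rdm = bundles["LiH"]
        noisy = apply_noise(rdm, NoiseSpec("depolarizing", 0.1))
        m_ref = DensityModel(wfn, embed_active(rdm))
        m_noisy = DensityModel(wfn, embed_active(noisy))
        grid = GridSpec.bounding(wfn.atoms, spacing=0.12, margin=7.0)
        diff = density_difference(m_noisy, m_ref, grid)
        expected = embed_active(noisy).trace - embed_active(rdm).trace
        assert integrate_density(diff) == pytest.approx(expected, abs=5e-3)


class TestNodalPlaneProtection:
    def test_hcn_axial_density_blind_to_active_space_changes(self, bundles,
                                                             rng):
        """The (4,4) space holds only π/π* orbitals, whose nodal planes
        contain the molecular axis; any active-space perturbation leaves
        the on-axis density bit-for-bit unchanged."""
        wfn, rdm = bundles["HCN"]
        m_ref = DensityModel(wfn, embed_active(rdm))
        perturbed = rdm.with_matrix(rdm.matrix +
                                    rng.normal(scale=0.2, size=(4, 4)))
        m_pert = DensityModel(wfn, embed_active(perturbed))
        zs = np.linspace(-1.0, 5.5, 60)
        axis = np.stack([np.zeros_like(zs), np.zeros_like(zs), zs], axis=1)
        r_ref, _, _ = m_ref.rho_batch(axis)
        r_pert, _, _ = m_pert.rho_batch(axis)
        assert np.abs(r_ref - r_pert).max() < 1e-12
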