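import numpy as np
import pytest

from densiwit.rdm import (NoiseSpec, OneRDM, apply_noise, embed_active,
                          error_stats, mitigate, rescale_trace, symmetrize)


def active_rdm(matrix, frozen=(), active=None, n_act=2, n_mo=None):
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    active = tuple(range(len(frozen), len(frozen) + n)) if active is None \
        else tuple(active)
    n_mo = len(frozen) + n if n_mo is None else n_mo
    return OneRDM(matrix, "active", tuple(frozen), active, n_act, n_mo)


class TestSymmetrize:
    def test_averages_off_diagonal_pairs(self):
        out = symmetrize(active_rdm([[1.0, 0.2], [0.4, 1.0]]))
        assert np.allclose(out.matrix, [[1.0, 0.3], [0.3, 1.0]])

    def test_symmetric_input_is_fixed_point(self, rng):
        m = rng.normal(size=(4, 4))
        m = m + m.T
        out = symmetrize(active_rdm(m))
        assert np.array_equal(out.matrix, 0.5 * (m + m.T))
        assert np.allclose(out.matrix, m)

    def test_antisymmetric_off_diagonals_cancel(self):
        out = symmetrize(active_rdm([[0.5, -0.1], [0.1, 0.5]]))
        assert out.matrix[0, 1] == 0.0 == out.matrix[1, 0]

    def test_preserves_trace_exactly(self, rng):
        m = rng.normal(size=(5, 5))
        assert np.trace(symmetrize(active_rdm(m)).matrix) == np.trace(m)


class TestRescaleTrace:
    def test_lih_like_rescale(self):
        # trace 1.88 with 2 active electrons: every entry scaled by 2/1.88
        m = np.array([[0.94, 0.1, 0.0], [0.1, 0.64, 0.0], [0.0, 0.0, 0.3]])
        out = rescale_trace(active_rdm(m, frozen=(0,), active=(1, 2, 3)))
        assert np.allclose(out.matrix, m * (2.0 / 1.88))
        assert out.active_trace == pytest.approx(2.0, abs=1e-14)

    def test_correct_trace_unchanged(self):
        m = np.diag([1.6, 0.4])
        out = rescale_trace(active_rdm(m))
        assert np.allclose(out.matrix, m)

    def test_zero_trace_raises(self):
        with pytest.raises(ValueError, match="not positive"):
            rescale_trace(active_rdm(np.zeros((2, 2))))

    def test_preserves_eigenvectors(self, rng):
        m = rng.normal(size=(4, 4))
        m = m + m.T + 4 * np.eye(4)
        rdm = active_rdm(m, n_act=2)
        out = rescale_trace(rdm)
        w1, v1 = np.linalg.eigh(m)
        w2, v2 = np.linalg.eigh(out.matrix)
        factor = 2.0 / np.trace(m)
        assert np.allclose(w2, w1 * factor)
        assert np.allclose(np.abs(np.sum(v1 * v2, axis=0)), 1.0)


class TestMitigate:
    def test_composition_symmetric_and_trace_correct(self, rng):
        m = rng.normal(size=(3, 3)) + np.diag([1.0, 0.6, 0.2])
        out = mitigate(active_rdm(m))
        assert np.allclose(out.matrix, out.matrix.T)
        assert out.active_trace == pytest.approx(2.0, abs=1e-13)

    def test_clean_input_is_fixed_point(self):
        m = np.diag([1.7, 0.3])
        out = mitigate(active_rdm(m))
        assert np.allclose(out.matrix, m)

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(scale=0.3, size=(4, 4)) + np.diag([1.2, 0.5, 0.2, 0.1])
        once = mitigate(active_rdm(m))
        twice = mitigate(once)
        assert np.allclose(twice.matrix, once.matrix, atol=1e-14)


class TestEmbedActive:
    def test_h2_no_frozen(self):
        out = embed_active(active_rdm(np.diag([1.9, 0.1])))
        assert out.space == "full"
        assert out.trace == pytest.approx(2.0)

    def test_lih_one_frozen_core(self):
        out = embed_active(active_rdm(np.diag([1.9, 0.06, 0.04]),
                                      frozen=(0,), active=(1, 2, 3),
                                      n_mo=6))
        assert out.matrix.shape == (6, 6)
        assert out.matrix[0, 0] == 2.0
        assert out.trace == pytest.approx(4.0)

    def test_hcn_five_inactive_doubly_occupied(self):
        out = embed_active(active_rdm(np.diag([1.94, 1.94, 0.06, 0.06]),
                                      frozen=(0, 1, 2, 3, 4),
                                      active=(5, 6, 7, 8), n_act=4, n_mo=20))
        assert out.trace == pytest.approx(14.0)
        assert out.n_total_electrons == 14

    def test_index_out_of_range_raises(self):
        with pytest.raises(ValueError, match="outside MO space"):
            embed_active(active_rdm(np.eye(2), frozen=(0,), active=(1, 5),
                                    n_mo=3))


class TestErrorStats:
    def test_zero_error_for_identical(self):
        r = active_rdm(np.diag([1.8, 0.2]))
        rep = error_stats(r, r)
        assert np.allclose(rep.error_matrix, 0.0)
        assert rep.asymmetry_norm == 0.0
        assert rep.electron_count == pytest.approx(2.0)

    def test_asymmetric_part_carries_the_asymmetry(self):
        ref = active_rdm([[1.0, 0.3], [0.3, 1.0]])
        noisy = active_rdm([[1.0, 0.2], [0.4, 1.0]])
        rep = error_stats(noisy, ref)
        assert np.allclose(rep.asymmetric_part, [[0.0, -0.1], [0.1, 0.0]])
        assert np.allclose(rep.symmetric_part + rep.asymmetric_part,
                           rep.error_matrix)

    def test_decomposition_reassembles_exactly(self, rng):
        ref = active_rdm(np.diag([1.5, 0.5]))
        noisy = active_rdm(np.diag([1.5, 0.5]) + rng.normal(size=(2, 2)))
        rep = error_stats(noisy, ref)
        assert np.array_equal(rep.symmetric_part + rep.asymmetric_part,
                              rep.error_matrix)

    def test_shot_metadata_gives_count_sd(self):
        r = active_rdm(np.diag([1.8, 0.2]))
        noisy = apply_noise(r, NoiseSpec("shot", shots=10_000, seed=3))
        rep = error_stats(noisy, r)
        assert rep.electron_count_sd == pytest.approx(
            np.sqrt(2 / 10_000), rel=1e-12)


class TestApplyNoise:
    def test_depolarizing_zero_strength_is_identity(self):
        r = active_rdm(np.diag([1.9, 0.1]))
        out = apply_noise(r, NoiseSpec("depolarizing", 0.0))
        assert np.array_equal(out.matrix, r.matrix)

    def test_depolarizing_full_strength_overcounts_li2(self):
        # Li2 active space: 2 electrons in 4 orbitals; full depolarization
        # drives every orbital to occupation 1 -> 4 active electrons,
        # embedded total 4 + 4 > 6
        act = active_rdm(np.diag([1.9, 0.04, 0.03, 0.03]), frozen=(0, 1),
                         active=(2, 3, 4, 5), n_mo=10)
        noisy = apply_noise(act, NoiseSpec("depolarizing", 1.0))
        assert np.allclose(noisy.matrix, np.eye(4))
        assert embed_active(noisy).trace > 6.0

    def test_damping_undercounts(self):
        act = active_rdm(np.diag([1.9, 0.1]))
        noisy = apply_noise(act, NoiseSpec("damping", 0.06))
        assert embed_active(noisy).trace < 2.0

    def test_shot_noise_is_seeded_and_reproducible(self):
        r = active_rdm(np.diag([1.8, 0.2]))
        a = apply_noise(r, NoiseSpec("shot", shots=100, seed=7))
        b = apply_noise(r, NoiseSpec("shot", shots=100, seed=7))
        c = apply_noise(r, NoiseSpec("shot", shots=100, seed=8))
        assert np.array_equal(a.matrix, b.matrix)
        assert not np.array_equal(a.matrix, c.matrix)

    def test_depolarizing_mitigation_restores_count_for_any_strength(self):
        act = active_rdm(np.diag([1.9, 0.04, 0.03, 0.03]), frozen=(0, 1),
                         active=(2, 3, 4, 5), n_mo=10)
        for lam in (0.01, 0.3, 0.9):
            noisy = apply_noise(act, NoiseSpec("depolarizing", lam))
            fixed = mitigate(noisy)
            assert embed_active(fixed).trace == pytest.approx(6.0, abs=1e-12)

    def test_shot_asymmetry_scales_as_inverse_sqrt_shots(self):
        """Mean asymmetry norm over 120 seeds shrinks ∝ 1/√M."""
        ref = active_rdm(np.diag([1.8, 0.15, 0.05]), n_mo=3,
                         active=(0, 1, 2))
        means = []
        for shots in (10**2, 10**4, 10**6):
            norms = [error_stats(
                apply_noise(ref, NoiseSpec("shot", shots=shots, seed=s)),
                ref).asymmetry_norm for s in range(120)]
            means.append(np.mean(norms))
        r1 = means[0] / means[1]
        r2 = means[1] / means[2]
        assert r1 == pytest.approx(10.0, rel=0.15)
        assert r2 == pytest.approx(10.0, rel=0.15)
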