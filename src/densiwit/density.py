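"""Analytic evaluation of the electron density and its derivatives.

The density is built in the molecular-orbital basis,

    ρ(r) = Σ_pq D_pq φ_p(r) φ_q(r),

with D the spin-summed 1-RDM and φ_p contracted-Gaussian molecular orbitals.
Values, gradients and Hessians of the Cartesian Gaussian primitives are
computed analytically (product rule on x^a y^b z^c · exp(−αr²)); the
spherical-harmonic transformation is applied after differentiation, so the
Hessians used by the critical-point search carry no finite-difference error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import (GridSpec, ScalarField, Shell, Wavefunction,
                      cartesian_powers)
from .rdm import OneRDM

__all__ = ["DensityModel", "PointEvaluation", "eval_point", "eval_grid",
           "integrate_density", "density_difference"]

_DFACT = [1, 1, 3, 15, 105]  # (2n-1)!! for n = 0..4


def _dfact(n: int) -> int:
    return _DFACT[n] if n >= 0 else 1


# Cartesian -> real-spherical transformation, normalized-Cartesian convention,
# Molden spherical order m = 0,+1,-1,+2,-2(,+3,-3); Cartesian alphabetical.
_SQRT3_2 = np.sqrt(3.0) / 2.0
C2S = {
    0: np.eye(1),
    1: np.eye(3),
    2: np.array([
        # xx      xy   xz   yy       yz   zz
        [-0.5,    0.0, 0.0, -0.5,    0.0, 1.0],
        [0.0,     0.0, 1.0, 0.0,     0.0, 0.0],
        [0.0,     0.0, 0.0, 0.0,     1.0, 0.0],
        [_SQRT3_2, 0.0, 0.0, -_SQRT3_2, 0.0, 0.0],
        [0.0,     1.0, 0.0, 0.0,     0.0, 0.0],
    ]),
    3: np.array([
        # xxx        xxy        xxz        xyy        xyz  xzz        yyy        yyz        yzz        zzz
        [0.0, 0.0, -np.sqrt(9.0 / 20.0), 0.0, 0.0, 0.0, 0.0, -np.sqrt(9.0 / 20.0), 0.0, 1.0],
        [-np.sqrt(3.0 / 8.0), 0.0, 0.0, -np.sqrt(3.0 / 40.0), 0.0, np.sqrt(6.0 / 5.0), 0.0, 0.0, 0.0, 0.0],
        [0.0, -np.sqrt(3.0 / 40.0), 0.0, 0.0, 0.0, 0.0, -np.sqrt(3.0 / 8.0), 0.0, np.sqrt(6.0 / 5.0), 0.0],
        [0.0, 0.0, _SQRT3_2, 0.0, 0.0, 0.0, 0.0, -_SQRT3_2, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [np.sqrt(5.0 / 8.0), 0.0, 0.0, -np.sqrt(9.0 / 8.0), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, np.sqrt(9.0 / 8.0), 0.0, 0.0, 0.0, 0.0, -np.sqrt(5.0 / 8.0), 0.0, 0.0, 0.0],
    ]),
}


def primitive_norm(l: int, alpha: float) -> float:
    """Norm of the (l,0,0) Cartesian primitive x^l exp(-αr²)."""
    return ((2.0 * alpha / np.pi) ** 0.75 *
            (4.0 * alpha) ** (l / 2.0) / np.sqrt(_dfact(l)))


def contracted_norm(shell: Shell) -> float:
    """Renormalization of the contracted (l,0,0) component."""
    l = shell.angular_momentum
    a = np.asarray(shell.exponents)
    c = np.asarray(shell.contraction_coeffs)
    ai, aj = np.meshgrid(a, a, indexing="ij")
    ov = (2.0 * np.sqrt(ai * aj) / (ai + aj)) ** (l + 1.5)
    s = float(c @ ov @ c)
    return 1.0 / np.sqrt(s)


class _ShellData:
    """Precomputed per-shell evaluation data."""

    __slots__ = ("center", "l", "spherical", "exps", "coeffs", "powers",
                 "comp_scale")

    def __init__(self, shell: Shell, center: np.ndarray):
        self.center = np.asarray(center, dtype=float)
        self.l = shell.angular_momentum
        self.spherical = shell.spherical and self.l >= 2
        self.exps = np.asarray(shell.exponents, dtype=float)
        n = contracted_norm(shell)
        self.coeffs = n * np.array([
            c * primitive_norm(self.l, a)
            for a, c in zip(shell.exponents, shell.contraction_coeffs)])
        self.powers = cartesian_powers(self.l)
        # individual normalization of cross components relative to (l,0,0)
        self.comp_scale = np.array([
            np.sqrt(_dfact(self.l) / (_dfact(a) * _dfact(b) * _dfact(c)))
            for (a, b, c) in self.powers])


def _eval_shell(sd: _ShellData, pts: np.ndarray, deriv: int):
    """Evaluate one shell's AO block at pts.

    Returns (val, grad, hess): (P, nc), (P, nc, 3), (P, nc, 3, 3); the
    gradient/Hessian entries are None below the requested derivative level.
    """
    d = pts - sd.center  # (P, 3)
    r2 = np.einsum("pi,pi->p", d, d)
    ex = np.exp(-np.outer(r2, sd.exps))  # (P, K)
    R0 = ex @ sd.coeffs
    R1 = ex @ (sd.coeffs * sd.exps) if deriv >= 1 else None
    R2 = ex @ (sd.coeffs * sd.exps ** 2) if deriv >= 2 else None

    # monomial powers up to l per axis
    lmax = sd.l
    pw = np.ones((3, lmax + 1, len(pts)))
    for n in range(1, lmax + 1):
        pw[:, n] = pw[:, n - 1] * d.T

    nc = len(sd.powers)
    val = np.empty((len(pts), nc))
    grad = np.empty((len(pts), nc, 3)) if deriv >= 1 else None
    hess = np.empty((len(pts), nc, 3, 3)) if deriv >= 2 else None

    def mono(pows):
        out = np.ones(len(pts))
        for ax, n in enumerate(pows):
            if n > 0:
                out = out * pw[ax, n]
        return out

    for ci, pows in enumerate(sd.powers):
        f = sd.comp_scale[ci]
        P = mono(pows)
        val[:, ci] = f * P * R0
        if deriv < 1:
            continue
        dP = np.zeros((3, len(pts)))
        for ax in range(3):
            if pows[ax] > 0:
                low = list(pows)
                low[ax] -= 1
                dP[ax] = pows[ax] * mono(low)
            grad[:, ci, ax] = f * (dP[ax] * R0 - 2.0 * d[:, ax] * P * R1)
        if deriv < 2:
            continue
        for ax in range(3):
            for bx in range(ax, 3):
                if ax == bx:
                    if pows[ax] >= 2:
                        low = list(pows)
                        low[ax] -= 2
                        d2P = pows[ax] * (pows[ax] - 1) * mono(low)
                    else:
                        d2P = 0.0
                    h = (d2P * R0
                         - (4.0 * d[:, ax] * dP[ax] + 2.0 * P) * R1
                         + 4.0 * d[:, ax] ** 2 * P * R2)
                else:
                    if pows[ax] > 0 and pows[bx] > 0:
                        low = list(pows)
                        low[ax] -= 1
                        low[bx] -= 1
                        dxy = pows[ax] * pows[bx] * mono(low)
                    else:
                        dxy = 0.0
                    h = (dxy * R0
                         - 2.0 * (d[:, bx] * dP[ax] + d[:, ax] * dP[bx]) * R1
                         + 4.0 * d[:, ax] * d[:, bx] * P * R2)
                hess[:, ci, ax, bx] = f * h
                hess[:, ci, bx, ax] = f * h

    if sd.spherical:
        t = C2S[sd.l]
        val = val @ t.T
        if grad is not None:
            grad = np.einsum("sc,pci->psi", t, grad)
        if hess is not None:
            hess = np.einsum("sc,pcij->psij", t, hess)
    return val, grad, hess


@dataclass
class PointEvaluation:
    """Density and derivatives at one point (atomic units)."""
    position: np.ndarray
    rho: float
    gradient: np.ndarray       # (3,)
    hessian: np.ndarray        # (3, 3)

    @property
    def laplacian(self) -> float:
        return float(np.trace(self.hessian))


class DensityModel:
    """Electron density defined by a wavefunction and a full-space 1-RDM.

    The 1-RDM must span the whole MO set (use ``rdm.embed_active`` first for
    active-space matrices); it is symmetrized on construction, which leaves
    the density invariant because φ_p φ_q is symmetric in (p, q).
    """

    def __init__(self, wavefunction: Wavefunction, rdm: OneRDM):
        if rdm.space != "full":
            raise ValueError("DensityModel needs a full-space 1-RDM "
                             "(embed the active block first)")
        if rdm.matrix.shape[0] != wavefunction.mos.n_mo:
            raise ValueError(
                f"1-RDM dimension {rdm.matrix.shape[0]} does not match "
                f"{wavefunction.mos.n_mo} MOs")
        self.wavefunction = wavefunction
        self.rdm = rdm
        self.D = 0.5 * (rdm.matrix + rdm.matrix.T)
        self.C = wavefunction.mos.coefficients  # (n_mo, n_ao)
        self._shells = [
            _ShellData(sh, wavefunction.atoms[sh.center_index].position)
            for sh in wavefunction.shells]

    @property
    def atoms(self):
        return self.wavefunction.atoms

    def _ao_batch(self, pts: np.ndarray, deriv: int):
        n_ao = self.wavefunction.n_ao
        val = np.empty((len(pts), n_ao))
        grad = np.empty((len(pts), n_ao, 3)) if deriv >= 1 else None
        hess = np.empty((len(pts), n_ao, 3, 3)) if deriv >= 2 else None
        off = 0
        for sd in self._shells:
            v, g, h = _eval_shell(sd, pts, deriv)
            w = v.shape[1]
            val[:, off:off + w] = v
            if deriv >= 1:
                grad[:, off:off + w] = g
            if deriv >= 2:
                hess[:, off:off + w] = h
            off += w
        return val, grad, hess

    def rho_batch(self, pts: np.ndarray, deriv: int = 0):
        """Density (and derivatives) at a batch of points.

        Returns (rho, grad, hess) with None for unrequested levels.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        ao, ao_g, ao_h = self._ao_batch(pts, deriv)
        phi = ao @ self.C.T                      # (P, n_mo)
        t = phi @ self.D                         # (P, n_mo)
        rho = np.einsum("pm,pm->p", t, phi)
        grad = hess = None
        if deriv >= 1:
            phi_g = np.einsum("pai,ma->pmi", ao_g, self.C)
            grad = 2.0 * np.einsum("pm,pmi->pi", t, phi_g)
        if deriv >= 2:
            phi_h = np.einsum("paij,ma->pmij", ao_h, self.C)
            tg = np.einsum("pmi,mn->pni", phi_g, self.D)
            hess = 2.0 * (np.einsum("pmi,pmj->pij", tg, phi_g)
                          + np.einsum("pm,pmij->pij", t, phi_h))
        return rho, grad, hess


def eval_point(model: DensityModel, position) -> PointEvaluation:
    """Evaluate ρ, ∇ρ and the Hessian at a single point."""
    rho, grad, hess = model.rho_batch(np.asarray(position, dtype=float), deriv=2)
    return PointEvaluation(position=np.asarray(position, dtype=float),
                           rho=float(rho[0]), gradient=grad[0], hessian=hess[0])


_DEFAULT_MEMORY_BUDGET = 2 * 1024 ** 3  # bytes of AO scratch per grid


def eval_grid(model: DensityModel, grid: GridSpec, quantity: str = "density",
              batch_size: int = 20000,
              memory_budget: int = _DEFAULT_MEMORY_BUDGET) -> ScalarField:
    """Sample ρ or ∇²ρ on a regular grid."""
    if quantity not in ("density", "laplacian"):
        raise ValueError(f"unknown quantity {quantity!r}")
    if grid.n_points * 8 > memory_budget:
        raise MemoryError(
            f"grid of {grid.n_points} points exceeds the memory budget")
    pts = grid.points()
    out = np.empty(grid.n_points)
    deriv = 2 if quantity == "laplacian" else 0
    for start in range(0, grid.n_points, batch_size):
        chunk = pts[start:start + batch_size]
        rho, _, hess = model.rho_batch(chunk, deriv=deriv)
        if quantity == "laplacian":
            out[start:start + batch_size] = np.trace(hess, axis1=1, axis2=2)
        else:
            out[start:start + batch_size] = rho
    return ScalarField(grid, out.reshape(grid.shape), quantity)


def integrate_density(field: ScalarField) -> float:
    """Riemann-sum integral of a gridded density (electrons)."""
    if field.quantity not in ("density", "difference"):
        raise ValueError("integrate_density expects a density-like field")
    return float(field.values.sum() * field.grid.voxel_volume)


def density_difference(a: DensityModel, b: DensityModel,
                       grid: GridSpec) -> ScalarField:
    """Pointwise ρ_a − ρ_b on a shared grid."""
    fa = eval_grid(a, grid)
    fb = eval_grid(b, grid)
    return ScalarField(grid, fa.values - fb.values, "difference")
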