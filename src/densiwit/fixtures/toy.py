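"""Analytic toy systems: sums of normalized s-Gaussian lumps.

These have closed-form densities ρ(r) = Σ_i w_i N_i² exp(−2α_i |r−c_i|²),
so every quantity the pipeline computes (ρ, ∇ρ, Hessian, critical points,
the two-lump bifurcation) has an independent pencil-and-paper oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..chem_io import AtomSite, MOSet, Shell, Wavefunction
from ..density import DensityModel
from ..rdm import OneRDM

__all__ = ["ToyGaussianSystem", "toy_gaussian_system", "two_lump_system",
           "two_lump_bifurcation_separation"]


@dataclass(frozen=True)
class ToyGaussianSystem:
    """One normalized s-orbital per center, diagonal 1-RDM of weights."""
    centers: tuple
    exponents: tuple
    weights: tuple

    def __post_init__(self):
        if not (len(self.centers) == len(self.exponents) == len(self.weights)):
            raise ValueError("centers/exponents/weights length mismatch")
        if any(a <= 0 for a in self.exponents):
            raise ValueError("exponents must be positive")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")


def toy_gaussian_system(spec: ToyGaussianSystem) -> DensityModel:
    """Build a DensityModel whose density is exactly the closed form above.

    Each center gets a hydrogen placeholder nucleus (the toy density has no
    nuclear cusps, but the topology code wants atoms for seeding and charge
    bookkeeping).
    """
    n = len(spec.centers)
    atoms = [AtomSite("H", 1, np.asarray(c, dtype=float))
             for c in spec.centers]
    shells = [Shell(center_index=i, angular_momentum=0, spherical=True,
                    exponents=[float(spec.exponents[i])],
                    contraction_coeffs=[1.0]) for i in range(n)]
    # one MO per orbital: identity coefficients (AOs are already normalized)
    mos = MOSet(np.eye(n), np.asarray(spec.weights, dtype=float))
    wfn = Wavefunction(atoms, shells, mos, label="toy-gaussians")
    rdm = OneRDM(np.diag(np.asarray(spec.weights, dtype=float)), "full",
                 (), tuple(range(n)), int(round(sum(spec.weights))), n,
                 "toy")
    return DensityModel(wfn, rdm)


def toy_density(spec: ToyGaussianSystem, pts: np.ndarray) -> np.ndarray:
    """Closed-form oracle density (independent of the evaluator)."""
    pts = np.atleast_2d(pts)
    rho = np.zeros(len(pts))
    for c, a, w in zip(spec.centers, spec.exponents, spec.weights):
        n2 = (2.0 * a / np.pi) ** 1.5
        d2 = np.sum((pts - np.asarray(c)) ** 2, axis=1)
        rho += w * n2 * np.exp(-2.0 * a * d2)
    return rho


def two_lump_system(separation: float, alpha: float = 1.0) -> ToyGaussianSystem:
    """Two equal lumps at ±separation/2 along x."""
    a = separation / 2.0
    return ToyGaussianSystem(centers=((-a, 0.0, 0.0), (a, 0.0, 0.0)),
                             exponents=(alpha, alpha), weights=(1.0, 1.0))


def two_lump_bifurcation_separation(alpha: float = 1.0) -> float:
    """Half-separation a* where the midpoint changes character.

    The density profile along the axis is e^{−β(x−a)²} + e^{−β(x+a)²} with
    β = 2α; its midpoint second derivative 2e^{−βa²}(4β²a² − 2β) changes sign
    at a = 1/√(2β). Below a* the midpoint is a single maximum; above it is a
    (3,−1) saddle flanked by two maxima.
    """
    beta = 2.0 * alpha
    return 1.0 / np.sqrt(2.0 * beta)
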