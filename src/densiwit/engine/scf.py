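"""Restricted closed-shell Hartree–Fock with DIIS."""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh


def rhf(ints, n_electrons: int, max_iter: int = 100, tol: float = 1e-10,
        verbose: bool = False):
    """Solve RHF equations for a closed-shell system.

    Parameters
    ----------
    ints : IntegralEngine
    n_electrons : total electron count (must be even)

    Returns
    -------
    dict with keys: energy (total, hartree), mo_coeffs (n_mo, n_ao; rows are
    MOs over AOs), mo_energies, occupations, and the AO integral matrices.
    """
    if n_electrons % 2:
        raise ValueError("restricted HF needs an even electron count")
    nocc = n_electrons // 2
    S = ints.overlap()
    H = ints.core_hamiltonian()
    g = ints.eri()
    e_nuc = ints.nuclear_repulsion()

    # core guess
    e, C = eigh(H, S)
    Cocc = C[:, :nocc]
    P = 2.0 * Cocc @ Cocc.T

    focks, errs = [], []
    energy = 0.0
    for it in range(max_iter):
        J = np.einsum("pqrs,rs->pq", g, P)
        K = np.einsum("prqs,rs->pq", g, P)
        F = H + J - 0.5 * K
        err = F @ P @ S - S @ P @ F
        focks.append(F)
        errs.append(err)
        if len(focks) > 8:
            focks.pop(0)
            errs.pop(0)
        if len(focks) > 1:
            F = _diis(focks, errs)
        e, C = eigh(F, S)
        Cocc = C[:, :nocc]
        P_new = 2.0 * Cocc @ Cocc.T
        e_el = 0.5 * np.einsum("pq,pq->", P_new, H + F)
        new_energy = e_el + e_nuc
        dP = np.abs(P_new - P).max()
        if verbose:
            print(f"  SCF iter {it:3d}  E={new_energy:.10f}  dP={dP:.2e}")
        P = P_new
        if dP < tol and abs(new_energy - energy) < tol:
            energy = new_energy
            break
        energy = new_energy
    else:
        raise RuntimeError("SCF failed to converge")

    occ = np.zeros(C.shape[1])
    occ[:nocc] = 2.0
    return {
        "energy": float(energy),
        "mo_coeffs": C.T.copy(),   # (n_mo, n_ao)
        "mo_energies": e.copy(),
        "occupations": occ,
        "overlap": S,
        "hcore": H,
        "eri": g,
        "e_nuc": e_nuc,
    }


def _diis(focks, errs):
    n = len(focks)
    B = -np.ones((n + 1, n + 1))
    B[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = np.sum(errs[i] * errs[j])
    rhs = np.zeros(n + 1)
    rhs[n] = -1.0
    try:
        c = np.linalg.solve(B, rhs)
    except np.linalg.LinAlgError:
        return focks[-1]
    F = np.zeros_like(focks[0])
    for i in range(n):
        F += c[i] * focks[i]
    return F
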