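"""Determinant full CI in a small active space, and the spin-summed 1-RDM.

The noise-free fixture 1-RDMs are defined as the exact ground state of the
active-space Hamiltonian (frozen doubly occupied orbitals folded into an
effective one-body operator) — the idealization of a perfectly converged,
noiseless variational quantum eigensolver run. For two-electron systems the
Sz=0 determinant basis |i_α j_β⟩ makes CI exact in the full orbital space,
which doubles as the near-exact witness (coupled cluster with singles and
doubles is exact for two electrons).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

__all__ = ["casci", "fci_rdm1", "active_hamiltonian"]


def mo_transform(eri_ao: np.ndarray, C: np.ndarray) -> np.ndarray:
    """AO→MO transform of the (pq|rs) tensor; C rows are MOs."""
    g = np.einsum("ap,pqrs->aqrs", C, eri_ao)
    g = np.einsum("bq,aqrs->abrs", C, g)
    g = np.einsum("cr,abrs->abcs", C, g)
    g = np.einsum("ds,abcs->abcd", C, g)
    return g


def active_hamiltonian(scf_result: dict, frozen: list[int], active: list[int]):
    """Effective active-space (h_eff, eri_act, e_core) from an RHF solution."""
    C = scf_result["mo_coeffs"]
    h_ao = scf_result["hcore"]
    h_mo = C @ h_ao @ C.T
    g_mo = mo_transform(scf_result["eri"], C)
    frozen = list(frozen)
    active = list(active)
    e_core = scf_result["e_nuc"]
    for f in frozen:
        e_core += 2.0 * h_mo[f, f]
        for f2 in frozen:
            e_core += 2.0 * g_mo[f, f, f2, f2] - g_mo[f, f2, f2, f]
    h_eff = h_mo[np.ix_(active, active)].copy()
    for f in frozen:
        h_eff += (2.0 * g_mo[np.ix_(active, active, [f], [f])][:, :, 0, 0]
                  - g_mo[np.ix_(active, [f], [f], active)][:, 0, 0, :])
    g_act = g_mo[np.ix_(active, active, active, active)]
    return h_eff, g_act, e_core


def _dets(n_orb: int, n_alpha: int, n_beta: int):
    alphas = list(combinations(range(n_orb), n_alpha))
    betas = list(combinations(range(n_orb), n_beta))
    return [(a, b) for a in alphas for b in betas]


def _excitation(occ1: tuple, occ2: tuple):
    """(degree, holes, particles, phase) taking occ1 -> occ2 (sorted tuples)."""
    s1, s2 = set(occ1), set(occ2)
    holes = sorted(s1 - s2)
    parts = sorted(s2 - s1)
    deg = len(holes)
    if deg == 0:
        return 0, (), (), 1
    # phase: product of (-1)^(number of occupied orbitals crossed)
    phase = 1
    occ = list(occ1)
    for h, p in zip(holes, parts):
        i = occ.index(h)
        occ.pop(i)
        j = np.searchsorted(occ, p)
        phase *= (-1) ** (i + j)
        occ.insert(j, p)
    return deg, tuple(holes), tuple(parts), phase


def _h_element(det1, det2, h, g):
    """Slater–Condon matrix element between Sz-conserving determinants."""
    (a1, b1), (a2, b2) = det1, det2
    da, ha, pa, pha = _excitation(a1, a2)
    db, hb, pb, phb = _excitation(b1, b2)
    if da + db > 2:
        return 0.0
    phase = pha * phb
    if da + db == 0:
        e = sum(h[p, p] for p in a1) + sum(h[p, p] for p in b1)
        for p in a1:
            for q in a1:
                e += 0.5 * (g[p, p, q, q] - g[p, q, q, p])
        for p in b1:
            for q in b1:
                e += 0.5 * (g[p, p, q, q] - g[p, q, q, p])
        for p in a1:
            for q in b1:
                e += g[p, p, q, q]
        return e
    if da + db == 1:
        if da == 1:
            p, q = ha[0], pa[0]
            same, other = a1, b1
        else:
            p, q = hb[0], pb[0]
            same, other = b1, a1
        e = h[p, q]
        for r in same:
            if r != p:
                e += g[p, q, r, r] - g[p, r, r, q]
        for r in other:
            e += g[p, q, r, r]
        return phase * e
    # double excitation
    if da == 2:
        (p, r), (q, s) = ha, pa
        return phase * (g[p, q, r, s] - g[p, s, r, q])
    if db == 2:
        (p, r), (q, s) = hb, pb
        return phase * (g[p, q, r, s] - g[p, s, r, q])
    p, q = ha[0], pa[0]
    r, s = hb[0], pb[0]
    return phase * g[p, q, r, s]


def casci(scf_result: dict, n_active_electrons: int, frozen: list[int],
          active: list[int]):
    """Exact diagonalization in the active space.

    Returns (energy_total, rdm1_active, ci_info) where rdm1_active is the
    spin-summed active-space 1-RDM over the active MOs.
    """
    h_eff, g_act, e_core = active_hamiltonian(scf_result, frozen, active)
    n_orb = len(active)
    if n_active_electrons % 2:
        raise ValueError("only Sz=0 singlet-compatible counts supported")
    na = nb = n_active_electrons // 2
    if na == 1 and nb == 1:
        e, c2 = _two_electron_ground_state(h_eff, g_act)
        rdm = c2 @ c2.T + c2.T @ c2
        return e + e_core, rdm, {"n_det": n_orb * n_orb}
    dets = _dets(n_orb, na, nb)
    n = len(dets)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            H[i, j] = H[j, i] = _h_element(dets[i], dets[j], h_eff, g_act)
    w, v = np.linalg.eigh(H)
    c0 = v[:, 0]
    rdm = fci_rdm1(c0, dets, n_orb)
    return float(w[0]) + e_core, rdm, {"n_det": n}


def _two_electron_ground_state(h: np.ndarray, g: np.ndarray):
    """Ground state of two electrons (one α, one β) over all orbitals.

    Basis |i_α j_β⟩; H[(ij),(kl)] = h_ik δ_jl + δ_ik h_jl + (ik|jl).
    Returns (electronic energy, coefficient matrix C_ij).
    """
    n = h.shape[0]
    eye = np.eye(n)
    H = (np.kron(h, eye) + np.kron(eye, h)
         + g.transpose(0, 2, 1, 3).reshape(n * n, n * n))
    if n * n > 400:
        from scipy.sparse.linalg import eigsh
        w, v = eigsh(H, k=1, which="SA")
        e0, c = float(w[0]), v[:, 0]
    else:
        w, v = np.linalg.eigh(H)
        e0, c = float(w[0]), v[:, 0]
    return e0, c.reshape(n, n)


def fci_rdm1(ci: np.ndarray, dets, n_orb: int) -> np.ndarray:
    """Spin-summed 1-RDM D_pq = Σ_σ ⟨a†_pσ a_qσ⟩ from a CI vector."""
    index = {d: i for i, d in enumerate(dets)}
    D = np.zeros((n_orb, n_orb))
    for (a, b), i in index.items():
        ci_i = ci[i]
        if ci_i == 0.0:
            continue
        # diagonal occupations
        for p in a:
            D[p, p] += ci_i * ci_i
        for p in b:
            D[p, p] += ci_i * ci_i
        # single excitations within each spin
        for occ, which in ((a, 0), (b, 1)):
            occ_set = set(occ)
            for q in occ:             # annihilate q
                for p in range(n_orb):  # create p
                    if p == q or p in occ_set:
                        continue
                    new = tuple(sorted(occ_set - {q} | {p}))
                    det2 = (new, b) if which == 0 else (a, new)
                    j = index.get(det2)
                    if j is None:
                        continue
                    _, _, _, phase = _excitation(occ, new)
                    D[p, q] += phase * ci[j] * ci_i
    return D
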