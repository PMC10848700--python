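"""McMurchie–Davidson one- and two-electron integrals over contracted
Cartesian Gaussians, with the same normalization and AO-ordering conventions
as the density evaluator (spherical transformation applied last).

Dense in-core only; adequate for the few-atom fixture systems."""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln

from ..chem_io import AtomSite, Shell, cartesian_powers
from ..density import C2S, contracted_norm, primitive_norm


def boys(m_max: int, T: np.ndarray) -> np.ndarray:
    """Boys functions F_0..F_m at T; returns array (m_max+1, *T.shape)."""
    T = np.atleast_1d(np.asarray(T, dtype=float))
    out = np.empty((m_max + 1,) + T.shape)
    small = T < 1e-13
    for m in range(m_max + 1):
        a = m + 0.5
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.exp(gammaln(a)) * gammainc(a, T) / (2.0 * T ** a)
        vals = np.where(small, 1.0 / (2 * m + 1) - T / (2 * m + 3), vals)
        out[m] = vals
    return out


def _e_coeffs(l1: int, l2: int, a: float, b: float,
              AB: float) -> np.ndarray:
    """Hermite expansion coefficients E[i, j, t] for one dimension."""
    p = a + b
    mu = a * b / p
    E = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 2))
    E[0, 0, 0] = np.exp(-mu * AB * AB)
    PA = -b / p * AB  # P - A with AB = A - B
    PB = a / p * AB   # P - B
    for i in range(1, l1 + 1):
        for t in range(i + 1):
            E[i, 0, t] = (E[i - 1, 0, t - 1] / (2 * p) if t > 0 else 0.0) \
                + PA * E[i - 1, 0, t] + (t + 1) * E[i - 1, 0, t + 1]
    for j in range(1, l2 + 1):
        for i in range(l1 + 1):
            for t in range(i + j + 1):
                E[i, j, t] = (E[i, j - 1, t - 1] / (2 * p) if t > 0 else 0.0) \
                    + PB * E[i, j - 1, t] + (t + 1) * E[i, j - 1, t + 1]
    return E


def _hermite_r(tmax: int, umax: int, vmax: int, p: float,
               PC: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R_{tuv} via downward recursion."""
    n_max = tmax + umax + vmax
    F = boys(n_max, np.array(p * (PC @ PC)))[:, 0]
    R = np.zeros((n_max + 1, tmax + 1, umax + 1, vmax + 1))
    for n in range(n_max + 1):
        R[n, 0, 0, 0] = (-2.0 * p) ** n * F[n]
    for n in range(n_max - 1, -1, -1):
        for t in range(tmax + 1):
            for u in range(umax + 1):
                for v in range(vmax + 1):
                    if t + u + v == 0 or t + u + v > n_max - n:
                        continue
                    if v > 0:
                        R[n, t, u, v] = PC[2] * R[n + 1, t, u, v - 1] + \
                            (v - 1) * R[n + 1, t, u, v - 2] if v > 1 else \
                            PC[2] * R[n + 1, t, u, v - 1]
                    elif u > 0:
                        R[n, t, u, v] = PC[1] * R[n + 1, t, u - 1, v] + \
                            (u - 1) * R[n + 1, t, u - 2, v] if u > 1 else \
                            PC[1] * R[n + 1, t, u - 1, v]
                    else:
                        R[n, t, u, v] = PC[0] * R[n + 1, t - 1, u, v] + \
                            (t - 1) * R[n + 1, t - 2, u, v] if t > 1 else \
                            PC[0] * R[n + 1, t - 1, u, v]
    return R[0]


class IntegralEngine:
    """Overlap, kinetic, nuclear-attraction and electron-repulsion integrals
    in the final (spherical-where-flagged) AO basis."""

    def __init__(self, atoms: list[AtomSite], shells: list[Shell]):
        self.atoms = atoms
        self.shells = shells
        self._prep()

    def _prep(self):
        self._sh = []
        for sh in self.shells:
            center = self.atoms[sh.center_index].position
            norm = contracted_norm(sh)
            coeffs = np.array([c * primitive_norm(sh.angular_momentum, a) * norm
                               for a, c in zip(sh.exponents,
                                               sh.contraction_coeffs)])
            comp_scale = np.array([
                np.sqrt(_df(sh.angular_momentum) /
                        (_df(a) * _df(b) * _df(c)))
                for (a, b, c) in cartesian_powers(sh.angular_momentum)])
            self._sh.append(dict(
                l=sh.angular_momentum, center=center,
                exps=np.asarray(sh.exponents, float), coeffs=coeffs,
                powers=cartesian_powers(sh.angular_momentum),
                comp_scale=comp_scale,
                spherical=sh.spherical and sh.angular_momentum >= 2))

    # -- one-electron -----------------------------------------------------

    def _pair_blocks(self, A, B, kind: str, nuclei=None):
        """Cartesian-component integral block between two shell dicts."""
        la, lb = A["l"], B["l"]
        pa, pb = A["powers"], B["powers"]
        out = np.zeros((len(pa), len(pb)))
        AB = A["center"] - B["center"]
        for ea, ca in zip(A["exps"], A["coeffs"]):
            for eb, cb in zip(B["exps"], B["coeffs"]):
                p = ea + eb
                P = (ea * A["center"] + eb * B["center"]) / p
                lmax = la + lb + 2
                E = [_e_coeffs(la + 2, lb + 2, ea, eb, AB[d]) for d in range(3)]
                pref = (np.pi / p) ** 0.5
                if kind == "overlap":
                    for i, (ax, ay, az) in enumerate(pa):
                        for j, (bx, by, bz) in enumerate(pb):
                            out[i, j] += ca * cb * pref ** 3 * \
                                E[0][ax, bx, 0] * E[1][ay, by, 0] * E[2][az, bz, 0]
                elif kind == "kinetic":
                    def s1(d, i, j):
                        return E[d][i, j, 0] * pref

                    def k1(d, i, j):
                        term = -2.0 * eb * eb * s1(d, i, j + 2) \
                            + eb * (2 * j + 1) * s1(d, i, j)
                        if j >= 2:
                            term -= 0.5 * j * (j - 1) * s1(d, i, j - 2)
                        return term
                    for i, (ax, ay, az) in enumerate(pa):
                        for j, (bx, by, bz) in enumerate(pb):
                            val = (k1(0, ax, bx) * s1(1, ay, by) * s1(2, az, bz)
                                   + s1(0, ax, bx) * k1(1, ay, by) * s1(2, az, bz)
                                   + s1(0, ax, bx) * s1(1, ay, by) * k1(2, az, bz))
                            out[i, j] += ca * cb * val
                elif kind == "nuclear":
                    del lmax
                    for atom in nuclei:
                        PC = P - atom.position
                        R = _hermite_r(la + lb, la + lb, la + lb, p, PC)
                        for i, (ax, ay, az) in enumerate(pa):
                            for j, (bx, by, bz) in enumerate(pb):
                                acc = 0.0
                                for t in range(ax + bx + 1):
                                    for u in range(ay + by + 1):
                                        for v in range(az + bz + 1):
                                            acc += (E[0][ax, bx, t]
                                                    * E[1][ay, by, u]
                                                    * E[2][az, bz, v]
                                                    * R[t, u, v])
                                out[i, j] += (-atom.atomic_number * ca * cb
                                              * 2.0 * np.pi / p * acc)
        out *= np.outer(A["comp_scale"], B["comp_scale"])
        return out

    def _assemble(self, kind: str, nuclei=None) -> np.ndarray:
        blocks = []
        for A in self._sh:
            row = []
            for B in self._sh:
                blk = self._pair_blocks(A, B, kind, nuclei)
                if A["spherical"]:
                    blk = C2S[A["l"]] @ blk
                if B["spherical"]:
                    blk = blk @ C2S[B["l"]].T
                row.append(blk)
            blocks.append(row)
        return np.block(blocks)

    def overlap(self) -> np.ndarray:
        return self._assemble("overlap")

    def kinetic(self) -> np.ndarray:
        return self._assemble("kinetic")

    def nuclear(self) -> np.ndarray:
        return self._assemble("nuclear", nuclei=self.atoms)

    def core_hamiltonian(self) -> np.ndarray:
        return self.kinetic() + self.nuclear()

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i, a in enumerate(self.atoms):
            for j in range(i + 1, len(self.atoms)):
                b = self.atoms[j]
                e += a.atomic_number * b.atomic_number / \
                    np.linalg.norm(a.position - b.position)
        return e

    # -- two-electron -----------------------------------------------------

    def eri(self) -> np.ndarray:
        """Full (pq|rs) tensor, chemist notation, final AO basis."""
        sh = self._sh
        nsh = len(sh)
        sizes = [len(s["powers"]) if not s["spherical"] else 2 * s["l"] + 1
                 for s in sh]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        n_ao = offs[-1]
        out = np.zeros((n_ao, n_ao, n_ao, n_ao))
        for a in range(nsh):
            for b in range(a + 1):
                for c in range(nsh):
                    for d in range(c + 1):
                        if (a, b) < (c, d):
                            continue
                        blk = self._eri_shell_quartet(sh[a], sh[b], sh[c], sh[d])
                        self._scatter(out, blk, offs, a, b, c, d)
        return out

    def _eri_shell_quartet(self, A, B, C, D) -> np.ndarray:
        la, lb, lc, ld = A["l"], B["l"], C["l"], D["l"]
        pa, pb, pc, pd = A["powers"], B["powers"], C["powers"], D["powers"]
        AB = A["center"] - B["center"]
        CD = C["center"] - D["center"]
        nbra = len(pa) * len(pb)
        nket = len(pc) * len(pd)
        out = np.zeros((nbra, nket))
        lab, lcd = la + lb, lc + ld
        for ea, ca in zip(A["exps"], A["coeffs"]):
            for eb, cb in zip(B["exps"], B["coeffs"]):
                p = ea + eb
                P = (ea * A["center"] + eb * B["center"]) / p
                Eab = [_e_coeffs(la, lb, ea, eb, AB[dim]) for dim in range(3)]
                bra = np.zeros((nbra, lab + 1, lab + 1, lab + 1))
                for i, (ax, ay, az) in enumerate(pa):
                    for j, (bx, by, bz) in enumerate(pb):
                        idx = i * len(pb) + j
                        ex = Eab[0][ax, bx, :ax + bx + 1]
                        ey = Eab[1][ay, by, :ay + by + 1]
                        ez = Eab[2][az, bz, :az + bz + 1]
                        bra[idx, :ax + bx + 1, :ay + by + 1, :az + bz + 1] = \
                            ex[:, None, None] * ey[None, :, None] * ez[None, None, :]
                for ec, cc in zip(C["exps"], C["coeffs"]):
                    for ed, cd_ in zip(D["exps"], D["coeffs"]):
                        q = ec + ed
                        Q = (ec * C["center"] + ed * D["center"]) / q
                        Ecd = [_e_coeffs(lc, ld, ec, ed, CD[dim])
                               for dim in range(3)]
                        ket = np.zeros((nket, lcd + 1, lcd + 1, lcd + 1))
                        sign = np.fromfunction(
                            lambda t, u, v: (-1.0) ** (t + u + v),
                            (lcd + 1, lcd + 1, lcd + 1))
                        for k, (cx, cy, cz) in enumerate(pc):
                            for m, (dx, dy, dz) in enumerate(pd):
                                idx = k * len(pd) + m
                                ex = Ecd[0][cx, dx, :cx + dx + 1]
                                ey = Ecd[1][cy, dy, :cy + dy + 1]
                                ez = Ecd[2][cz, dz, :cz + dz + 1]
                                ket[idx, :cx + dx + 1, :cy + dy + 1, :cz + dz + 1] = \
                                    ex[:, None, None] * ey[None, :, None] * ez[None, None, :]
                        ket = ket * sign
                        omega = p * q / (p + q)
                        R = _hermite_r(lab + lcd, lab + lcd, lab + lcd,
                                       omega, P - Q)
                        # contract: res[bra,ket] = Σ bra_tuv ket_τνφ R_{t+τ,...}
                        res = np.zeros((nbra, nket))
                        for t in range(lab + 1):
                            for u in range(lab + 1):
                                for v in range(lab + 1):
                                    bcol = bra[:, t, u, v]
                                    if not np.any(bcol):
                                        continue
                                    rblk = R[t:t + lcd + 1, u:u + lcd + 1,
                                             v:v + lcd + 1]
                                    res += np.outer(
                                        bcol, ket.reshape(nket, -1)
                                        @ rblk.ravel())
                        pref = (ca * cb * cc * cd_ * 2.0 * np.pi ** 2.5 /
                                (p * q * np.sqrt(p + q)))
                        out += pref * res
        out *= np.outer(np.repeat(A["comp_scale"], len(pb)) *
                        np.tile(B["comp_scale"], len(pa)),
                        np.repeat(C["comp_scale"], len(pd)) *
                        np.tile(D["comp_scale"], len(pc)))
        # spherical transforms
        out = out.reshape(len(pa), len(pb), len(pc), len(pd))
        if A["spherical"]:
            out = np.einsum("sa,abcd->sbcd", C2S[la], out)
        if B["spherical"]:
            out = np.einsum("sb,abcd->ascd", C2S[lb], out)
        if C["spherical"]:
            out = np.einsum("sc,abcd->absd", C2S[lc], out)
        if D["spherical"]:
            out = np.einsum("sd,abcd->abcs", C2S[ld], out)
        return out

    @staticmethod
    def _scatter(out, blk, offs, a, b, c, d):
        sa = slice(offs[a], offs[a] + blk.shape[0])
        sb = slice(offs[b], offs[b] + blk.shape[1])
        sc = slice(offs[c], offs[c] + blk.shape[2])
        sd = slice(offs[d], offs[d] + blk.shape[3])
        out[sa, sb, sc, sd] = blk
        out[sb, sa, sc, sd] = blk.transpose(1, 0, 2, 3)
        out[sa, sb, sd, sc] = blk.transpose(0, 1, 3, 2)
        out[sb, sa, sd, sc] = blk.transpose(1, 0, 3, 2)
        out[sc, sd, sa, sb] = blk.transpose(2, 3, 0, 1)
        out[sd, sc, sa, sb] = blk.transpose(3, 2, 0, 1)
        out[sc, sd, sb, sa] = blk.transpose(2, 3, 1, 0)
        out[sd, sc, sb, sa] = blk.transpose(3, 2, 1, 0)


def _df(n: int) -> int:
    r = 1
    k = 2 * n - 1
    while k > 1:
        r *= k
        k -= 2
    return r
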