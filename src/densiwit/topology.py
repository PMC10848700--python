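"""QTAIM topological analysis of the electron density.

Critical points (∇ρ = 0) are located by Newton iteration with the analytic
Hessian and classified by the rank ω and signature κ of the Hessian (κ = sum
of eigenvalue signs): (3,−3) maxima — nuclear or non-nuclear attractors
(NNAs), (3,−1) bond critical points, (3,+1) ring, (3,+3) cage. Atomic basins
are assigned on a regular grid by near-grid steepest ascent (each voxel
follows its best-ascending 26-neighbor until a local maximum), realizing the
zero-flux partition implicitly; basin populations and partial charges
q = Z − N come from Riemann sums over basin voxels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chem_io import AtomSite, GridSpec
from .density import DensityModel, eval_grid

logger = logging.getLogger(__name__)

__all__ = ["CriticalPoint", "BasinMap", "ChargeTable", "find_cps",
           "classify_cp", "assign_basins", "basin_charges"]

GRAD_TOL = 1e-10          # |∇ρ| convergence for a converged CP
CLASSIFY_GRAD_TOL = 1e-8  # |∇ρ| accepted by classify_cp
EIG_ZERO_TOL = 1e-8       # |λ| below this counts as rank-deficient
NUCLEAR_DIST = 0.2        # bohr; maxima closer to a nucleus are nuclear
MERGE_DIST = 1e-4         # bohr; duplicate-CP merge radius
RHO_FLOOR = 1e-10         # discard CPs / leave voxels unassigned below this
ATTRACTOR_MIN_RHO = 1e-7  # grid maxima weaker than this never found basins
MAX_STEP = 0.3            # bohr; Newton step cap


@dataclass
class CriticalPoint:
    """A stationary point of ρ with its Hessian classification."""
    position: np.ndarray
    rho: float
    laplacian: float
    eigenvalues: np.ndarray        # ascending
    rank: int
    signature: int
    cp_type: str                   # nuclear_max | nna | bond | ring | cage
    nearest_atoms: list[tuple[int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "position": self.position.tolist(),
            "rho": self.rho,
            "laplacian": self.laplacian,
            "eigenvalues": self.eigenvalues.tolist(),
            "rank": self.rank,
            "signature": self.signature,
            "cp_type": self.cp_type,
            "nearest_atoms": [[int(i), float(d)] for i, d in self.nearest_atoms],
        }


@dataclass
class BasinMap:
    """Voxel-to-attractor assignment on a regular grid (−1 = unassigned).

    ``weights`` (flux-weight method only) holds fractional basin membership
    per voxel, shape (n_voxels, n_attractors); ``labels`` is the integer
    majority assignment either way.
    """
    grid: GridSpec
    labels: np.ndarray             # int array, grid.shape
    attractors: list[CriticalPoint]
    weights: np.ndarray | None = None


@dataclass
class ChargeTable:
    """Integrated basin populations and partial charges."""
    rows: list[dict]               # attractor_id, atom_index, kind, Z,
    #                                population, charge

    def total_charge(self) -> float:
        return sum(r["charge"] for r in self.rows)

    def charge_of_atom(self, atom_index: int) -> float:
        for r in self.rows:
            if r["atom_index"] == atom_index:
                return r["charge"]
        raise KeyError(f"no basin attached to atom {atom_index}")

    def nna_rows(self) -> list[dict]:
        return [r for r in self.rows if r["kind"] == "nna"]


def classify_cp(point, model: DensityModel) -> CriticalPoint:
    """Classify a stationary point by its analytic Hessian signature."""
    from .density import eval_point

    pe = eval_point(model, point)
    gnorm = float(np.linalg.norm(pe.gradient))
    # the floating-point floor of |∇ρ| scales with the Hessian magnitude
    # (steep nuclear maxima of heavier atoms)
    scale = float(np.abs(pe.hessian).max())
    gtol = max(CLASSIFY_GRAD_TOL,
               100.0 * np.finfo(float).eps * scale
               * (1.0 + float(np.linalg.norm(point))))
    if gnorm > gtol:
        raise ValueError(f"|∇ρ| = {gnorm:.2e} at point; not a critical point")
    eigs = np.linalg.eigvalsh(pe.hessian)
    signs = np.where(np.abs(eigs) <= EIG_ZERO_TOL, 0, np.sign(eigs)).astype(int)
    rank = int(np.count_nonzero(signs))
    kappa = int(signs.sum())
    dists = [float(np.linalg.norm(np.asarray(point) - a.position))
             for a in model.atoms]
    order = np.argsort(dists)
    nearest = [(int(i), dists[i]) for i in order[:2]]
    if rank == 3 and kappa == -3:
        cp_type = "nuclear_max" if nearest[0][1] <= NUCLEAR_DIST else "nna"
    elif rank == 3 and kappa == -1:
        cp_type = "bond"
    elif rank == 3 and kappa == 1:
        cp_type = "ring"
    elif rank == 3 and kappa == 3:
        cp_type = "cage"
    else:
        cp_type = "degenerate"
    return CriticalPoint(position=np.asarray(point, dtype=float),
                         rho=pe.rho, laplacian=pe.laplacian,
                         eigenvalues=eigs, rank=rank, signature=kappa,
                         cp_type=cp_type, nearest_atoms=nearest)


def _newton_search(model: DensityModel, seed: np.ndarray,
                   max_iter: int = 80) -> np.ndarray | None:
    x = np.asarray(seed, dtype=float).copy()
    for _ in range(max_iter):
        rho, grad, hess = model.rho_batch(x, deriv=2)
        g = grad[0]
        gnorm = np.linalg.norm(g)
        if gnorm <= GRAD_TOL:
            return x
        try:
            step = -np.linalg.solve(hess[0], g)
        except np.linalg.LinAlgError:
            return None
        slen = np.linalg.norm(step)
        # at very steep nuclear maxima the absolute gradient tolerance sits
        # below the floating-point floor (|∇ρ| noise ≈ |λ|·eps·|x|); a
        # vanishing Newton step means x is converged to machine resolution
        if slen < 1e-14 * (1.0 + np.linalg.norm(x)):
            return x
        if slen > MAX_STEP:
            step *= MAX_STEP / slen
        x = x + step
        if not np.all(np.isfinite(x)):
            return None
    return None


def default_seeds(model: DensityModel, n_random: int = 32,
                  seed: int = 0) -> np.ndarray:
    """Nuclei, pair midpoints, triple centroids, plus random points near
    each nucleus."""
    pos = np.array([a.position for a in model.atoms])
    seeds = [pos]
    n = len(pos)
    # midpoints plus off-center fractions along each pair (bond CPs of
    # heteronuclear or multi-bond systems sit well off the midpoint)
    fracs = (0.25, 0.35, 0.5, 0.65, 0.75)
    mids = [(1 - f) * pos[i] + f * pos[j]
            for i in range(n) for j in range(i + 1, n) for f in fracs]
    if mids:
        seeds.append(np.array(mids))
    cents = [(pos[i] + pos[j] + pos[k]) / 3
             for i in range(n) for j in range(i + 1, n)
             for k in range(j + 1, n)]
    if cents:
        seeds.append(np.array(cents))
    rng = np.random.default_rng(seed)
    for p in pos:
        seeds.append(p + rng.uniform(-3.0, 3.0, size=(n_random, 3)))
    return np.vstack(seeds)


def find_cps(model: DensityModel, seeds=None, seed: int = 0) -> list[CriticalPoint]:
    """Locate and classify critical points of ρ by seeded Newton search.

    Non-convergent seeds are dropped (logged); converged duplicates within
    MERGE_DIST are merged keeping the lower-|∇ρ| candidate; CPs with
    ρ below RHO_FLOOR are discarded.
    """
    if seeds is None:
        seeds = default_seeds(model, seed=seed)
    found: list[np.ndarray] = []
    n_failed = 0
    for s in np.atleast_2d(seeds):
        x = _newton_search(model, s)
        if x is None:
            n_failed += 1
            continue
        found.append(x)
    if n_failed:
        logger.debug("find_cps: %d of %d seeds did not converge",
                     n_failed, len(seeds))
    # merge duplicates, keep lowest |∇ρ|
    unique: list[np.ndarray] = []
    for x in found:
        dup = None
        for i, u in enumerate(unique):
            if np.linalg.norm(x - u) <= MERGE_DIST:
                dup = i
                break
        if dup is None:
            unique.append(x)
        else:
            _, gx, _ = model.rho_batch(x, deriv=1)
            _, gu, _ = model.rho_batch(unique[dup], deriv=1)
            if np.linalg.norm(gx[0]) < np.linalg.norm(gu[0]):
                unique[dup] = x
    cps = []
    for x in unique:
        rho, _, _ = model.rho_batch(x)
        if rho[0] < RHO_FLOOR:
            continue
        try:
            cp = classify_cp(x, model)
        except ValueError:
            # Newton stalled short of a true stationary point; drop it
            continue
        if cp.rank == 0:
            # |∇ρ| below tolerance merely because the density has decayed to
            # nothing; not a structural feature
            continue
        cps.append(cp)
    order = {"nuclear_max": 0, "nna": 1, "bond": 2, "ring": 3, "cage": 4,
             "degenerate": 5}
    cps.sort(key=lambda c: (order.get(c.cp_type, 9), c.position.tolist()))
    return cps


def poincare_hopf(cps: list[CriticalPoint]) -> int:
    """n_max − n_bond + n_ring − n_cage (should be 1 for a molecule)."""
    n = {"max": 0, "bond": 0, "ring": 0, "cage": 0}
    for c in cps:
        if c.cp_type in ("nuclear_max", "nna"):
            n["max"] += 1
        elif c.cp_type == "bond":
            n["bond"] += 1
        elif c.cp_type == "ring":
            n["ring"] += 1
        elif c.cp_type == "cage":
            n["cage"] += 1
    return n["max"] - n["bond"] + n["ring"] - n["cage"]


# -- grid basins -----------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array([(i, j, k)
                              for i in (-1, 0, 1)
                              for j in (-1, 0, 1)
                              for k in (-1, 0, 1)
                              if (i, j, k) != (0, 0, 0)])


def _ascent_parents(rho: np.ndarray, shape, spacing):
    """Best-ascending 26-neighbor per voxel (−1 target = local maximum).

    Ties in the gain criterion break to the first offset in scan order
    (lowest linear index), deterministically.
    """
    pad = np.full((shape[0] + 2, shape[1] + 2, shape[2] + 2), -np.inf)
    pad[1:-1, 1:-1, 1:-1] = rho
    best_gain = np.full(shape, 0.0)
    best_off = np.full(shape, -1, dtype=np.int64)
    for oi, (di, dj, dk) in enumerate(_NEIGHBOR_OFFSETS):
        nb = pad[1 + di:shape[0] + 1 + di,
                 1 + dj:shape[1] + 1 + dj,
                 1 + dk:shape[2] + 1 + dk]
        dist = np.linalg.norm(np.array([di, dj, dk]) * spacing)
        gain = (nb - rho) / dist
        take = gain > best_gain
        best_gain = np.where(take, gain, best_gain)
        best_off = np.where(take, oi, best_off)
    n = rho.size
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    off_lin = _NEIGHBOR_OFFSETS @ strides
    parent = np.arange(n, dtype=np.int64)
    has_up = best_off.ravel() >= 0
    parent[has_up] = np.arange(n)[has_up] + off_lin[best_off.ravel()[has_up]]
    return parent, has_up


def _match_attractors(model, grid, maxima_idx, flat_rho, attractors,
                      match_tol):
    """Map grid-maximum voxels to attractor indices (appending if needed)."""
    attractors = list(attractors)
    att_pos = np.array([c.position for c in attractors]) \
        if attractors else np.zeros((0, 3))
    shape = grid.shape
    mapping: dict[int, int] = {}
    for r in maxima_idx:
        ijk = np.array(np.unravel_index(r, shape))
        point = grid.origin + ijk @ grid.axes
        if len(att_pos):
            d = np.linalg.norm(att_pos - point, axis=1)
            i = int(np.argmin(d))
            if d[i] <= match_tol:
                mapping[r] = i
                continue
        if flat_rho[r] < ATTRACTOR_MIN_RHO:
            # far-tail micro-maximum (diffuse-basis ripple); leave its few
            # voxels unassigned instead of inventing an attractor
            continue
        warnings.warn(
            f"grid maximum at {np.round(point, 3)} has no matching attractor; "
            "appending a new one", stacklevel=2)
        try:
            new_cp = classify_cp(_newton_search(model, point), model)
        except (ValueError, TypeError):
            new_cp = CriticalPoint(position=point,
                                   rho=float(flat_rho[r]), laplacian=np.nan,
                                   eigenvalues=np.full(3, np.nan), rank=3,
                                   signature=-3, cp_type="nna",
                                   nearest_atoms=[])
        mapping[r] = len(attractors)
        attractors.append(new_cp)
        att_pos = np.vstack([att_pos, new_cp.position]) if len(att_pos) \
            else new_cp.position[None]
    return mapping, attractors


def assign_basins(model: DensityModel, grid: GridSpec,
                  attractors: list[CriticalPoint] | None = None,
                  field_values: np.ndarray | None = None,
                  method: str = "weight") -> BasinMap:
    """Grid basin assignment.

    method="weight" (default): flux-weight partition — every voxel's density
    is split among its strictly higher face neighbors in proportion to
    (ρ_nbr − ρ_self)·A/L, and the resulting fractional basin memberships are
    obtained by one sparse triangular solve in descending-ρ order. This is
    the standard accurate grid realization of the zero-flux partition (and
    what reference QTAIM grid integrators use); it converges much faster in
    the grid spacing than pure ascent, which matters for flat non-nuclear
    basins.

    method="ascent": near-grid steepest ascent — each voxel follows its
    best-ascending 26-neighbor (density-difference/distance criterion) with
    path compression until a grid-local maximum.

    Either way, grid maxima are matched to attractor CPs within 1.5× the
    grid spacing; unmatched significant maxima append new attractors with a
    warning.
    """
    if method not in ("weight", "ascent"):
        raise ValueError(f"unknown basin method {method!r}")
    if field_values is None:
        field_values = eval_grid(model, grid).values
    rho = field_values
    shape = grid.shape
    n = int(np.prod(shape))
    spacing = np.linalg.norm(grid.axes, axis=1)
    flat_rho = rho.ravel()
    match_tol = 1.5 * spacing.max()

    parent, has_up = _ascent_parents(rho, shape, spacing)
    if attractors is None:
        attractors = [c for c in find_cps(model)
                      if c.cp_type in ("nuclear_max", "nna")]
    attractors = [c for c in attractors if c.cp_type in ("nuclear_max", "nna")]

    if method == "ascent":
        root = parent.copy()
        while True:
            nxt = root[root]
            if np.array_equal(nxt, root):
                break
            root = nxt
        roots = np.unique(root[flat_rho >= RHO_FLOOR])
        mapping, attractors = _match_attractors(
            model, grid, roots, flat_rho, attractors, match_tol)
        lut = np.full(n, -1, dtype=np.int64)
        for r, lab in mapping.items():
            lut[r] = lab
        labels = np.full(n, -1, dtype=np.int64)
        assigned = flat_rho >= RHO_FLOOR
        labels[assigned] = lut[root[assigned]]
        return BasinMap(grid=grid, labels=labels.reshape(shape),
                        attractors=attractors)

    # flux-weight method
    import scipy.sparse as sp
    from scipy.sparse.linalg import spsolve_triangular

    idx3 = np.indices(shape).reshape(3, -1)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    rows_l, cols_l, vals_l = [], [], []
    for o in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
              (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        ov = np.array(o)
        valid = np.all((idx3 + ov[:, None] >= 0) &
                       (idx3 + ov[:, None] < np.array(shape)[:, None]), axis=0)
        src = np.arange(n, dtype=np.int32)[valid]
        dst = (src + ov @ strides).astype(np.int32)
        gain = flat_rho[dst] - flat_rho[src]
        pos = gain > 0
        rows_l.append(src[pos])
        cols_l.append(dst[pos])
        # face area / distance prefactor is common for a uniform cubic grid
        vals_l.append(gain[pos])
    del idx3
    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    vals = np.concatenate(vals_l)
    del rows_l, cols_l, vals_l
    rowsum = np.bincount(rows, weights=vals, minlength=n)
    # voxels with no strictly-higher face neighbor that are not genuine
    # 26-neighbor maxima (diagonal ridges): link them to their ascent parent
    stuck = (rowsum == 0) & has_up
    if stuck.any():
        si = np.where(stuck)[0].astype(np.int32)
        rows = np.concatenate([rows, si])
        cols = np.concatenate([cols, parent[si].astype(np.int32)])
        vals = np.concatenate([vals, np.ones(len(si))])
        rowsum[si] = 1.0
    sources = rowsum == 0
    inv = np.ones(n)
    inv[~sources] = 1.0 / rowsum[~sources]

    maxima_idx = np.where(sources & (flat_rho >= RHO_FLOOR))[0]
    mapping, attractors = _match_attractors(
        model, grid, maxima_idx, flat_rho, attractors, match_tol)
    nb = len(attractors)

    # build I - T directly in descending-ρ permutation (strictly lower
    # triangular transition matrix -> one forward substitution)
    order = np.argsort(-flat_rho, kind="stable")
    rank = np.empty(n, dtype=np.int32)
    rank[order] = np.arange(n, dtype=np.int32)
    vals = -vals * inv[rows]
    rows = rank[rows]
    cols = rank[cols]
    A = sp.csr_matrix(
        (np.concatenate([np.ones(n), vals]),
         (np.concatenate([np.arange(n, dtype=np.int32), rows]),
          np.concatenate([np.arange(n, dtype=np.int32), cols]))),
        shape=(n, n))
    del rows, cols, vals
    S = np.zeros((n, nb))
    for r, lab in mapping.items():
        S[rank[r], lab] = 1.0
    W = spsolve_triangular(A, S, lower=True)
    del A, S
    W = W[rank]
    W[flat_rho < RHO_FLOOR] = 0.0

    labels = np.full(n, -1, dtype=np.int64)
    wsum = W.sum(axis=1)
    got = wsum > 0
    labels[got] = np.argmax(W[got], axis=1)
    return BasinMap(grid=grid, labels=labels.reshape(shape),
                    attractors=attractors, weights=W)


def _cusp_corrections(basin_map: BasinMap, model: DensityModel,
                      refine: int = 6) -> np.ndarray:
    """Population correction per attractor from re-integrating the voxels
    near each nuclear maximum on a ``refine``³-times finer subgrid.

    The midpoint rule undersamples the steep density peak at heavier nuclei
    (the Riemann sum misses a few hundredths of an electron per first-row
    atom at 0.1 bohr spacing); the affected region is deep inside the basin,
    so the correction can be attributed to the attractor wholesale.
    """
    grid = basin_map.grid
    spacing = np.linalg.norm(grid.axes, axis=1).max()
    dv = grid.voxel_volume
    corr = np.zeros(len(basin_map.attractors))
    att_pos = np.array([c.position for c in basin_map.attractors]) \
        if basin_map.attractors else np.zeros((0, 3))
    # fine offsets covering one voxel, midpoint rule
    t = (np.arange(refine) + 0.5) / refine - 0.5
    offs = np.stack(np.meshgrid(t, t, t, indexing="ij"), -1).reshape(-1, 3)
    offs = offs @ grid.axes
    dv_fine = dv / refine ** 3
    for i, cp in enumerate(basin_map.attractors):
        if cp.cp_type != "nuclear_max":
            continue
        radius = 0.45
        if len(att_pos) > 1:
            d = np.linalg.norm(att_pos - cp.position, axis=1)
            radius = min(radius, 0.45 * d[d > 1e-6].min())
        # coarse voxel centers inside the sphere
        inv = np.linalg.inv(grid.axes)
        ijk0 = np.floor((cp.position - radius - grid.origin) @ inv).astype(int)
        ijk1 = np.ceil((cp.position + radius - grid.origin) @ inv).astype(int)
        ijk0 = np.maximum(ijk0, 0)
        ijk1 = np.minimum(ijk1, np.array(grid.shape) - 1)
        ranges = [np.arange(ijk0[d], ijk1[d] + 1) for d in range(3)]
        ijk = np.stack(np.meshgrid(*ranges, indexing="ij"), -1).reshape(-1, 3)
        centers = grid.origin + ijk @ grid.axes
        inside = np.linalg.norm(centers - cp.position, axis=1) <= radius
        centers = centers[inside]
        if not len(centers):
            continue
        coarse_rho, _, _ = model.rho_batch(centers)
        fine_pts = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        fine_rho, _, _ = model.rho_batch(fine_pts)
        corr[i] = fine_rho.sum() * dv_fine - coarse_rho.sum() * dv
    return corr


def basin_charges(basin_map: BasinMap, model: DensityModel,
                  atoms: list[AtomSite] | None = None,
                  field_values: np.ndarray | None = None,
                  cusp_refine: bool = True) -> ChargeTable:
    """Integrate basin populations and derive partial charges q = Z − N.

    NNA basins carry Z = 0. With ``cusp_refine`` the near-nucleus voxels are
    re-integrated on a finer subgrid (midpoint-rule cusp error). Warns when
    more than 1% of the total gridded density remains unassigned.
    """
    if atoms is None:
        atoms = model.atoms
    if field_values is None:
        field_values = eval_grid(model, basin_map.grid).values
    rho = field_values.ravel()
    labels = basin_map.labels.ravel()
    dv = basin_map.grid.voxel_volume
    total = rho.sum() * dv
    unassigned = rho[labels < 0].sum() * dv
    if total > 0 and unassigned / total > 0.01:
        warnings.warn(f"{unassigned / total:.1%} of the gridded density is "
                      "unassigned to any basin", stacklevel=2)
    if basin_map.weights is not None:
        pops = (basin_map.weights * rho[:, None]).sum(axis=0) * dv
    else:
        pops = np.array([rho[labels == i].sum() * dv
                         for i in range(len(basin_map.attractors))])
    if cusp_refine:
        pops = pops + _cusp_corrections(basin_map, model)
    rows = []
    for i, cp in enumerate(basin_map.attractors):
        pop = float(pops[i])
        if cp.cp_type == "nuclear_max":
            dists = [np.linalg.norm(cp.position - a.position) for a in atoms]
            ai = int(np.argmin(dists))
            z = atoms[ai].atomic_number
            kind = "atom"
        else:
            ai = -1
            z = 0
            kind = "nna"
        rows.append({"attractor_id": i, "atom_index": ai, "kind": kind,
                     "Z": z, "population": pop, "charge": float(z - pop)})
    return ChargeTable(rows=rows)
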