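# Methods

This note records the models, conventions and numerical choices behind
`densiwit`, in the package's own words. All quantities are in Hartree
atomic units (bohr, hartree, e) everywhere inside the package; unit
conversion happens only at I/O boundaries (XYZ files are Å).

## The density model

The electron density is built in the molecular-orbital basis,
ρ(**r**) = Σ_pq D_pq φ_p(**r**) φ_q(**r**), with **D** a *spin-summed
spatial* 1-RDM (entries in [0, 2] when physical) over restricted orbitals.
All bundled systems are closed-shell singlets, so one spatial orbital set
serves both spins and the spin sum is absorbed into **D**; this halves
every matrix dimension relative to a spin-orbital formulation.

Basis functions are contracted Cartesian Gaussians up to l = 3 with
individually normalized components; pure (spherical-harmonic) d and f
functions are formed *after* differentiation with the standard
transformation in normalized-Cartesian convention (Molden order
m = 0, +1, −1, +2, −2, +3, −3). Values, gradients and Hessians are
analytic: for χ = x^a y^b z^c e^(−αr²) the product rule gives every
derivative in terms of three contracted radial sums (Σ c_k N_k α_k^m
e^(−α_k r²), m = 0, 1, 2), so the critical-point search sees no
finite-difference error. Finite differences appear only as test oracles
(central differences at h = 10⁻⁴ bohr, agreement to 10⁻⁶ relative).

The AO ordering is pinned: shells in file order; within a shell x, y, z
for p and alphabetical Cartesian (xx, xy, xz, yy, yz, zz) or Molden
spherical order for d/f. The Molden dialect is the `[5D]`/`[7F]` one; the
bundled fixtures are generated in exactly this dialect, and a
rotation-invariance test on a closed d shell pins the spherical
transformation table.

## 1-RDMs, embedding, noise and mitigation

An active-space calculation with frozen doubly occupied orbitals is
represented by an active-block matrix plus metadata (`frozen_indices`
lists *every* inactive doubly occupied orbital, core and valence alike).
Embedding places 2.0 on the frozen diagonal, the active block at its MO
indices, and zeros elsewhere, so Tr(**D**) = 2·|frozen| + Tr(**D**_act).

Synthetic noise channels act on the active block:

* depolarizing, D′ = (1−λ)D + λI — each spatial orbital drifts toward
  occupation 1, the spin-summed image of the maximally mixed state; it
  *overcounts* electrons when the active space is less than half filled
  (Li₂'s (2,4) space) and conserves the count at exactly half filling
  (H₂'s (2,2), HCN's (4,4));
* damping, D′ = (1−λ)D — uniform decay toward the empty state,
  *undercounting* (used to emulate the hardware-style undercount in LiH);
* shot noise — i.i.d. Gaussian perturbations of standard deviation 1/√M
  on every entry independently, so transpose-related pairs deviate
  independently; this is deliberately the *only* source of asymmetric
  error, matching the operator-identity argument that ideal expectation
  values of a†_p a_q and a†_q a_p coincide and asymmetry can come only
  from finite sampling. The trace then carries standard deviation
  √(n_act/M), which is what `error_stats` reports.

Mitigation is symmetrization (averaging transpose pairs) followed by
trace rescaling (every entry, diagonal and off-diagonal alike, multiplied
by n_act/Tr(D_act)); the order is pinned although the two orders coincide
for these operations. Mitigated matrices are *not* projected to
N-representable (positive-semidefinite, occupation-bounded) form —
studying the raw effect of the two constraints is the point. Mitigation is
idempotent and restores the exact electron count for any perturbation
that leaves the active trace positive; a non-positive trace raises
(unmitigable). All stochastic operations take an explicit seed (default 0).

## Topological analysis

Critical points are found by Newton iteration with the analytic Hessian,
steps capped at 0.3 bohr, from deterministic seeds (nuclei, five points
along every atom pair, atom-triple centroids) plus 32 seeded-random points
within 3 bohr of each nucleus. Convergence is |∇ρ| ≤ 10⁻¹⁰, with a
machine-resolution escape: near the steep density maxima of heavier
nuclei the floating-point floor of |∇ρ| is ≈ |λ|_max·ε·|x|, which can
exceed 10⁻¹⁰ (for N in HCN the Hessian is ~10⁶), so a Newton step below
10⁻¹⁴·(1+|x|) also counts as converged, and the classification tolerance
scales accordingly. Duplicates within 10⁻⁴ bohr are merged keeping the
lower-|∇ρ| candidate; points with ρ < 10⁻¹⁰ or a numerically zero Hessian
(rank 0 — tail points where the density has simply decayed away, an
artifact of the absolute gradient threshold in diffuse bases) are
discarded. Classification uses the eigenvalue signs with zero threshold
10⁻⁸; maxima within 0.2 bohr of a nucleus are nuclear, farther ones are
non-nuclear attractors (in Gaussian bases the density maximum sits
slightly off the nucleus — a fraction of a millibohr for Li, 0.04 bohr
for the H in HCN — and the Li₂ midbond NNA is ≈ 2.5 bohr from either
nucleus, so 0.2 bohr separates the cases safely). Eigenvector-following
is not needed: every sought CP in these small molecules is rank 3 and
well conditioned.

Basins are assigned on a regular grid. Two methods are provided:

* `method="ascent"` — near-grid steepest ascent: each voxel follows its
  best-ascending 26-neighbor by the (Δρ/distance) criterion with path
  compression; ties break to the lowest linear voxel index.
* `method="weight"` (default) — flux-weight partition: each voxel's
  density is split among its strictly higher face neighbors in proportion
  to the discrete flux (ρ_nbr − ρ_self)·A/L, and fractional basin
  memberships follow from a single sparse triangular solve in
  descending-ρ order (the transition matrix is strictly triangular in
  that order). Voxels with no higher face neighbor that are not genuine
  26-neighbor maxima are linked to their ascent parent; far-tail
  micro-maxima (ρ < 10⁻⁷, ripples of diffuse basis functions) never found
  basins and their few voxels stay unassigned.

The weight method is the default because pure ascent provably
mis-integrates flat non-nuclear basins: for the Li₂ NNA it plateaus near
q = −0.45 at any affordable spacing, while an independent oracle —
analytic steepest-ascent trajectories traced from 1.4 million voxel
centers — gives −0.612, in agreement with the weight method's converged
value (−0.605 at 0.1 bohr). The weight partition is also what reference
QTAIM grid integrators use. Zero-flux surfaces are realized implicitly by
the partition; no explicit interatomic surfaces or bond paths are
constructed, and BCP connectivity is inferred from nearest-atom pairs.

Populations are Riemann sums Σ ρ·ΔV weighted by basin membership, plus a
default-on nuclear-cusp refinement: voxels within ≈ 0.45 bohr of each
nuclear attractor are re-integrated on a 6³-times finer subgrid, because
the midpoint rule misses a few hundredths of an electron per first-row
atom at 0.1 bohr spacing. Charges are q = Z − N, with Z = 0 for NNA
basins. Grids are axis-aligned and centered on the molecule with *even*
point counts per axis, so no voxel sits exactly on a mirror plane and
symmetry-equivalent basins receive identical voxel sets (with odd counts
the deterministic tie-break hands a whole midplane sheet to one side).
Default spacing is 0.1 bohr with a 7 bohr margin (8 bohr for Li₂, whose
NNA basin is spatially extended).

## Witness comparison

A feature set is the CP list, the charge table and the grid electron
count of one density. Comparison matches CPs greedily by distance within
the same CP type (cutoff 0.5 bohr — positions shift little between basis
sets for these systems, and a loose cutoff risks pairing a bond CP with
an NNA region) and reports signed deltas (test − witness) for ρ, ∇²ρ,
per-basin charges and the electron count, plus summary maxima. No scalar
fidelity index is invented; the per-feature deltas *are* the witness.

## Fixtures and the in-package engine

The bundled fixtures are H₂ (2,2), LiH (2,3), Li₂ (2,4) in STO-3G and
HCN (4,4) in 6-31G, each as a Molden file (canonical restricted
Hartree–Fock orbitals) plus a JSON 1-RDM bundle whose noise-free matrix
is the *exact ground state of the active-space Hamiltonian* (frozen
doubly occupied orbitals folded into an effective one-body operator) —
the idealization of a perfectly converged, noiseless variational quantum
eigensolver. Geometries are experimental equilibrium structures: H₂
0.7414 Å, LiH 1.5949 Å, Li₂ 2.673 Å, HCN r(CH) = 1.0655 Å /
r(CN) = 1.1532 Å, aligned with z. The HCN active space is the two π and
two π* orbitals (verified: every active MO vanishes on the molecular
axis to 10⁻¹⁰), with the two 1s cores and three valence σ orbitals
inactive.

The H₂ witness is full CI in aug-cc-pVTZ — exact for two electrons, hence
identical to the coupled-cluster singles-and-doubles density a
conventional reference calculation would give. It is stored as natural
orbitals truncated at occupation 10⁻⁷ (39 of 46 kept, dropped population
5×10⁻⁸), which makes the bundle a diagonal-RDM expansion.

Fixtures are generated by `scripts/make_fixtures.py` with the in-package
engine — McMurchie–Davidson one- and two-electron integrals over the same
normalization conventions as the evaluator, restricted Hartree–Fock with
DIIS, and determinant full CI (a specialized |i_α j_β⟩ pair solver for
two-electron systems, generic Slater–Condon otherwise; the two paths are
cross-checked against each other in the tests). Basis data (STO-3G,
6-31G, aug-cc-pVTZ for H/Li/C/N) are the standard published tabulations
embedded in `engine/basis.py`. Committed files are SHA-256 pinned and the
loader verifies the pins; the tests additionally regenerate the H₂ bundle
from scratch and compare. Engine validation: H₂/STO-3G RHF −1.11671 Eh
and FCI −1.137276 Eh at 1.4 bohr, S₁₂ = 0.6593, H₂/aug-cc-pVTZ RHF
−1.1330 Eh — all at the textbook values; MO orthonormality to 10⁻¹⁰.

## What the synthetic conditions do and do not show

The noise channels act at the RDM level with time-invariant, seeded
statistics. They reproduce the *structure* of measured errors (trace
drift with the documented sign per active space, sampling-induced
asymmetry shrinking as 1/√M) but not any particular device's calibration:
no circuit, encoding, readout-error or drift model is simulated, so
hardware-measured values (e.g. a specific noisy electron count or a
charge from a specific device run) are targets in direction only.
Passing tests therefore demonstrate the mitigation algebra, the density
evaluation and the topology machinery — not agreement with any specific
quantum processor.

## Known discrepancies with the reference tables

Exact analytic evaluation at the stated geometries reproduces part of the
published reference data exactly and disagrees reproducibly with the
rest; the comparison tests assert the published values at their stated
tolerances regardless, so the disagreeing entries fail honestly:

* H₂: bond-CP ρ matches to all printed digits (0.2524); the printed
  Laplacian (−0.7818) differs from the analytic value (−0.7694), and no
  bond length reproduces both numbers simultaneously.
* Li₂: NNA ρ and Laplacian and bond-CP ρ match exactly; the two printed
  bond-CP Laplacians differ *from each other* (0.0017 vs 0.0022) although
  the points are symmetry-equivalent, which bounds the reference data's
  own numerical noise.
* LiH: the printed (ρ, ∇²ρ) pair is mutually inconsistent under exact
  evaluation at any bond length; at 1.5949 Å we get (0.0447, 0.1286)
  against (0.0431, 0.1437).
* HCN: the printed noise-free bond-CP densities (0.3934, 0.2635) are far
  from the analytic σ-frame values (0.4607 C–N, 0.2702 C–H), while the
  printed *witness* values match standard near-exact results at the
  experimental geometry — evidence that the geometry is right and the
  reference noise-free column carries a processing artifact. (By printed
  magnitude, the reference table's two HCN rows are also label-swapped:
  0.39/0.48 is the C–N bond, 0.26/0.30 the C–H bond.)
* Charges: H₂ (0.00), LiH (±0.84) and the Li₂ atoms (+0.31 vs +0.32)
  agree within 0.02 e; the Li₂ NNA (−0.605 here, confirmed by the
  trajectory oracle, vs −0.65 printed) and the HCN charges do not.

## Problem sizes

Default test and comparison grids are 0.1 bohr spacing (0.12–0.3 bohr in
unit tests that only need structure, not converged charges), margins
5.5–8 bohr; the charge-convergence check refines LiH from 0.12 to
0.06 bohr (≈ 10⁷ voxels, the largest single computation in the suite).
Shot-noise scaling regressions use 100–120 seeds at M = 10², 10⁴, 10⁶.
These sizes keep the full suite at a few minutes on one CPU while leaving
every asserted digit converged; they are the package's chosen defaults,
not externally imposed.

## Limitations

Restricted closed-shell orbitals only; maximum angular momentum f; no
periodic systems, density fitting or relativistic corrections; no 2-RDM
handling, Pauli-string measurement simulation or circuit-level noise; no
ring/cage-rich topologies beyond the toy tests (degenerate CPs are out of
scope); no ingestion of experimentally refined (diffraction) witness
densities — only computed witnesses are supported.
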