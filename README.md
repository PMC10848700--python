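# densiwit

Topological electron-density analysis as a *fidelity witness* for
quantum-computed wavefunctions.

A hybrid quantum–classical chemistry calculation stores its orbitals
φ_p(**r**) classically and measures the one-particle reduced density matrix
(1-RDM) **D** on the quantum device. The electron density

    ρ(r) = Σ_pq D_pq φ_p(r) φ_q(r)

is then fully determined, and its *topology* — critical points where
∇ρ = 0, classified by the signature κ (the sum of the signs of the three
Hessian eigenvalues), and atomic basins bounded by zero-flux surfaces with
partial charges q = Z − N — forms a compact, experimentally accessible
feature set against which the quality of the quantum computation can be
judged. Measurement noise perturbs **D** (asymmetric off-diagonal errors
from finite sampling; trace errors that change the apparent electron
count); enforcing two exact properties of the 1-RDM —

* hermiticity, by averaging transpose-related off-diagonal pairs,
  D'_pq = (D_pq + D_qp)/2, and
* particle conservation, by rescaling every entry so that
  Tr(**D**) = n_el —

gives a *noise-mitigated* 1-RDM whose density topology can be compared
against a trusted witness density from near-exact conventional theory (or,
prospectively, from diffraction experiments).

`densiwit` implements this pipeline end to end for users studying
RDM-level error mitigation in quantum computational chemistry:

* **chem_io** — XYZ, Molden (with `[5D]`/`[7F]` spherical dialect),
  Gaussian cube, and a JSON bundle format for 1-RDMs with active-space
  metadata; atomic units internally.
* **rdm** — spin-summed spatial 1-RDMs, frozen-core embedding, synthetic
  noise channels (depolarizing, damping, finite-shot), the
  symmetrize + rescale mitigation, and error decomposition.
* **density** — analytic ρ, ∇ρ, Hessian and Laplacian from contracted
  Gaussians up to *f*, evaluated in the MO basis on points and grids.
* **topology** — Newton critical-point search with analytic Hessians,
  (rank, κ) classification including non-nuclear attractors (NNAs),
  flux-weight basin integration on grids, and QTAIM partial charges.
* **witness** — topological feature sets and per-feature comparison
  reports (Δρ and Δ∇²ρ at matched critical points, Δq per basin, Δn_el).
* **fixtures** — analytic toy Gaussian systems with closed-form topology,
  plus bundled molecular fixtures (H₂, LiH, Li₂ / STO-3G and HCN / 6-31G
  with (2,2), (2,3), (2,4) and (4,4) active spaces, and a near-exact H₂
  witness in aug-cc-pVTZ) generated by the in-package electronic-structure
  engine and SHA-256 pinned.
* **engine** — a compact McMurchie–Davidson integrals + restricted
  Hartree–Fock + small-active-space full-CI engine used to build the
  fixtures and to cross-check the density evaluator.

## Worked example

Critical points of the H₂ (2,2)/STO-3G exact ground-state density:

```python
from densiwit.fixtures import load_fixture
from densiwit.rdm import embed_active
from densiwit.density import DensityModel
from densiwit.topology import find_cps

wfn, rdm = load_fixture("H2")
model = DensityModel(wfn, embed_active(rdm))
for cp in find_cps(model):
    print(f"{cp.cp_type:12s} (3,{cp.signature:+d})  rho = {cp.rho:.4f}"
          f"  lap = {cp.laplacian:.4f}")
```

prints

```
nuclear_max  (3,-3)  rho = 0.3648  lap = -6.3787
nuclear_max  (3,-3)  rho = 0.3648  lap = -6.3787
bond         (3,-1)  rho = 0.2524  lap = -0.7694
```

two symmetry-equivalent nuclear maxima and one bond critical point at the
midbond, whose negative Laplacian marks the covalent charge concentration.
The same density evaluated against the bundled aug-cc-pVTZ witness gives
Δρ = −0.016 e·bohr⁻³ at the bond CP — the minimal-basis error the witness
comparison is designed to expose.

The noise experiment driver reruns the noise-free / noisy / mitigated
comparison; a 6% damping channel on the LiH active space reproduces the
characteristic electron undercount and its repair:

```bash
$ densiwit experiment --molecule LiH --noise damping --strength 0.06 \
      --seed 0 --grid 0.15 --out results/
electron counts: {'noise_free': 4.0, 'noisy': 3.88, 'mitigated': 4.0}; \
wrote results/LiH_experiment.json
```

Other entry points: `densiwit qtaim` (full topological report as JSON),
`densiwit density` (cube files), `densiwit noise` / `densiwit mitigate`
(1-RDM bundle transforms), `densiwit witness` (feature-set comparison).
Every run writes a manifest with input hashes, seeds and configuration.

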