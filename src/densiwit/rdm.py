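"""One-particle reduced density matrices: representation, embedding,
synthetic noise channels, and the symmetrize/rescale error mitigation.

The 1-RDM here is the spin-summed spatial matrix D_pq = Σ_σ ⟨a†_pσ a_qσ⟩ over
restricted molecular orbitals, so a doubly occupied orbital carries diagonal
2.0 and Tr(D) equals the electron count. Measured (noisy) matrices may break
both hermiticity and the trace; mitigation restores them by averaging
transpose-related off-diagonal pairs and rescaling the whole matrix so the
active-space trace equals the known active electron count. Noisy matrices are
deliberately NOT projected to N-representable (PSD, occupation-bounded) form:
the point is to study the raw effect of the two constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["OneRDM", "NoiseSpec", "ErrorReport", "symmetrize", "rescale_trace",
           "mitigate", "embed_active", "error_stats", "apply_noise"]


@dataclass(frozen=True)
class OneRDM:
    """Spin-summed 1-RDM over spatial MOs with active-space metadata.

    ``space`` is "active" when ``matrix`` spans only the active orbitals and
    "full" when it spans the whole MO space (frozen/inactive doubly occupied
    orbitals embedded with diagonal 2.0). ``frozen_indices`` lists every
    inactive doubly occupied orbital (core and inactive valence alike).
    """
    matrix: np.ndarray
    space: str  # "active" | "full"
    frozen_indices: tuple[int, ...]
    active_indices: tuple[int, ...]
    n_active_electrons: int
    mo_space_size: int
    provenance: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "frozen_indices", tuple(self.frozen_indices))
        object.__setattr__(self, "active_indices", tuple(self.active_indices))
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("1-RDM must be a square matrix")
        if self.space not in ("active", "full"):
            raise ValueError(f"unknown space tag {self.space!r}")
        if set(self.frozen_indices) & set(self.active_indices):
            raise ValueError("frozen and active index sets overlap")
        if self.space == "active" and m.shape[0] != len(self.active_indices):
            raise ValueError("active-space matrix dimension mismatch")
        if self.space == "full" and m.shape[0] != self.mo_space_size:
            raise ValueError("full-space matrix dimension mismatch")

    @property
    def n_total_electrons(self) -> int:
        return self.n_active_electrons + 2 * len(self.frozen_indices)

    @property
    def active_block(self) -> np.ndarray:
        if self.space == "active":
            return self.matrix
        idx = np.asarray(self.active_indices, dtype=int)
        return self.matrix[np.ix_(idx, idx)]

    @property
    def trace(self) -> float:
        return float(np.trace(self.matrix))

    @property
    def active_trace(self) -> float:
        return float(np.trace(self.active_block))

    def with_matrix(self, matrix: np.ndarray, provenance: str | None = None) -> "OneRDM":
        return replace(self, matrix=np.asarray(matrix, dtype=float),
                       provenance=self.provenance if provenance is None else provenance)


@dataclass(frozen=True)
class NoiseSpec:
    """Synthetic RDM-level noise channel.

    kind="depolarizing": D' = (1-λ)·D + λ·I  — every spatial orbital drifts
        toward occupation 1 (the spin-summed image of the maximally mixed
        state); overcounts electrons when the active space is less than
        half filled.
    kind="damping":      D' = (1-λ)·D        — uniform decay toward the empty
        state; undercounts electrons.
    kind="shot":         adds i.i.d. zero-mean Gaussian noise of standard
        deviation 1/√M to every entry independently, so transpose-related
        off-diagonal pairs deviate independently — the sole source of
        asymmetric error.
    """
    kind: str
    strength: float = 0.0
    shots: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("depolarizing", "damping", "shot"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind in ("depolarizing", "damping") and not (0.0 <= self.strength <= 1.0):
            raise ValueError("noise strength must be in [0, 1]")
        if self.kind == "shot" and self.shots < 1:
            raise ValueError("shots must be >= 1")


@dataclass
class ErrorReport:
    """Decomposition of a noisy-minus-reference 1-RDM error matrix."""
    error_matrix: np.ndarray
    symmetric_part: np.ndarray
    asymmetric_part: np.ndarray
    asymmetry_norm: float
    electron_count: float
    electron_count_sd: float | None = None


def symmetrize(rdm: OneRDM) -> OneRDM:
    """Enforce hermiticity by averaging transpose-related off-diagonal pairs."""
    out = 0.5 * (rdm.matrix + rdm.matrix.T)
    return rdm.with_matrix(out, provenance=_tag(rdm.provenance, "symmetrized"))


def rescale_trace(rdm: OneRDM) -> OneRDM:
    """Rescale so the active-space trace equals the active electron count.

    Every entry (diagonal and off-diagonal alike) is multiplied by the same
    factor n_active / Tr(D_active); for a full-space matrix the frozen
    diagonal is left at 2.0 and only the active block is scaled.
    """
    tr = rdm.active_trace
    if tr <= 0.0:
        raise ValueError(f"active trace {tr:.6f} is not positive; unmitigable")
    factor = rdm.n_active_electrons / tr
    if rdm.space == "active":
        out = rdm.matrix * factor
    else:
        out = rdm.matrix.copy()
        idx = np.asarray(rdm.active_indices, dtype=int)
        out[np.ix_(idx, idx)] *= factor
    return rdm.with_matrix(out, provenance=_tag(rdm.provenance, "rescaled"))


def mitigate(rdm: OneRDM) -> OneRDM:
    """Noise mitigation: symmetrize, then rescale the trace (in that order)."""
    out = rescale_trace(symmetrize(rdm))
    return replace(out, provenance=_tag(rdm.provenance, "mitigated"))


def embed_active(rdm: OneRDM, n_mo_total: int | None = None) -> OneRDM:
    """Embed an active-space 1-RDM into the full MO space.

    Frozen/inactive doubly occupied orbitals get diagonal 2.0; the active
    block is inserted at the active indices; everything else (virtuals) is
    zero. Total trace = 2·|frozen| + Tr(D_active).
    """
    if rdm.space != "active":
        raise ValueError("embed_active expects an active-space 1-RDM")
    n = rdm.mo_space_size if n_mo_total is None else int(n_mo_total)
    idx = np.asarray(rdm.active_indices, dtype=int)
    frozen = np.asarray(rdm.frozen_indices, dtype=int)
    if len(idx) and idx.max() >= n:
        raise ValueError("active index outside MO space")
    if len(frozen) and frozen.max() >= n:
        raise ValueError("frozen index outside MO space")
    full = np.zeros((n, n))
    full[frozen, frozen] = 2.0
    full[np.ix_(idx, idx)] = rdm.matrix
    return replace(rdm, matrix=full, space="full", mo_space_size=n,
                   provenance=_tag(rdm.provenance, "embedded"))


def error_stats(noisy: OneRDM, reference: OneRDM) -> ErrorReport:
    """Decompose the elementwise error ε = D_noisy − D_ref into its
    transpose-symmetric and antisymmetric parts."""
    if noisy.matrix.shape != reference.matrix.shape:
        raise ValueError("shape mismatch between noisy and reference 1-RDM")
    if noisy.space != reference.space:
        raise ValueError("space mismatch between noisy and reference 1-RDM")
    eps = noisy.matrix - reference.matrix
    sym = 0.5 * (eps + eps.T)
    asym = 0.5 * (eps - eps.T)
    if noisy.space == "active":
        count = embed_active(noisy).trace
    else:
        count = noisy.trace
    sd = None
    prov = noisy.provenance
    m = _shots_from_provenance(prov)
    if m is not None:
        # each diagonal entry carries independent N(0, 1/M) noise; the trace
        # over n_active entries then has sd sqrt(n_active/M)
        sd = float(np.sqrt(noisy.active_block.shape[0] / m))
    return ErrorReport(error_matrix=eps, symmetric_part=sym,
                       asymmetric_part=asym,
                       asymmetry_norm=float(np.linalg.norm(asym)),
                       electron_count=float(count), electron_count_sd=sd)


def apply_noise(rdm: OneRDM, spec: NoiseSpec) -> OneRDM:
    """Apply a synthetic noise channel to an active-space 1-RDM."""
    if rdm.space != "active":
        raise ValueError("noise channels act on the active-space 1-RDM")
    d = rdm.matrix
    if spec.kind == "depolarizing":
        out = (1.0 - spec.strength) * d + spec.strength * np.eye(d.shape[0])
        tag = f"depolarizing(lam={spec.strength})"
    elif spec.kind == "damping":
        out = (1.0 - spec.strength) * d
        tag = f"damping(lam={spec.strength})"
    else:  # shot
        rng = np.random.default_rng(spec.seed)
        sigma = 1.0 / np.sqrt(spec.shots)
        out = d + rng.normal(0.0, sigma, size=d.shape)
        tag = f"shot(M={spec.shots},seed={spec.seed})"
    return rdm.with_matrix(out, provenance=_tag(rdm.provenance, tag))


def _tag(prov: str, op: str) -> str:
    return f"{prov}|{op}" if prov else op


def _shots_from_provenance(prov: str) -> int | None:
    import re
    m = re.search(r"shot\(M=(\d+)", prov)
    return int(m.group(1)) if m else None
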