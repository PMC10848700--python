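"""Bundled quantum-chemistry fixtures: four closed-shell molecules with
active-space exact-diagonalization 1-RDMs, plus a near-exact H₂ witness.

The committed files (Molden wavefunction + JSON 1-RDM bundle per system)
are generated once by ``scripts/make_fixtures.py`` using the in-package
electronic-structure engine and are SHA-256 pinned; loading verifies the
hashes. Geometries are experimental equilibrium structures; the noise-free
active-space 1-RDM is the exact ground state of the active-space
Hamiltonian — the idealization of a converged, noiseless variational
quantum eigensolver.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ..chem_io import (AtomSite, MOSet, Wavefunction, read_molden,
                       read_rdm_bundle, ANGSTROM_TO_BOHR)
from ..rdm import OneRDM

__all__ = ["FIXTURES", "fixture_geometry", "build_fixture",
           "load_fixture", "list_fixtures", "fixture_wavefunctions"]


@dataclass(frozen=True)
class FixtureDef:
    molecule: str
    basis: str
    atoms: tuple            # (symbol, Z, (x, y, z) bohr)
    n_electrons: int
    frozen: tuple           # inactive doubly occupied MO indices
    active: tuple           # active MO indices
    n_active_electrons: int
    margin: float = 7.0     # bohr; grid margin (diffuse systems need more)
    witness: bool = False


def _along_z(*entries):
    return tuple((sym, z, (0.0, 0.0, pos * ANGSTROM_TO_BOHR))
                 for sym, z, pos in entries)


FIXTURES: dict[str, FixtureDef] = {
    # H2, experimental r_e = 0.7414 Å, (2e, 2o), no frozen core
    "H2": FixtureDef("H2", "sto-3g",
                     _along_z(("H", 1, -0.3707), ("H", 1, 0.3707)),
                     2, (), (0, 1), 2),
    # LiH, r_e = 1.5949 Å, (2e, 3o), frozen Li 1s
    "LiH": FixtureDef("LiH", "sto-3g",
                      _along_z(("Li", 3, 0.0), ("H", 1, 1.5949)),
                      4, (0,), (1, 2, 3), 2),
    # Li2, r_e = 2.673 Å, (2e, 4o), frozen both 1s; diffuse NNA basin
    "Li2": FixtureDef("Li2", "sto-3g",
                      _along_z(("Li", 3, -1.3365), ("Li", 3, 1.3365)),
                      6, (0, 1), (2, 3, 4, 5), 2, margin=8.0),
    # HCN, r_CH = 1.0655 Å, r_CN = 1.1532 Å, (4e, 4o) π/π* space,
    # frozen C1s+N1s plus three inactive valence σ
    "HCN": FixtureDef("HCN", "6-31g",
                      _along_z(("H", 1, 0.0), ("C", 6, 1.0655),
                               ("N", 7, 2.2187)),
                      14, (0, 1, 2, 3, 4), (5, 6, 7, 8), 4),
    # near-exact H2 witness: full CI (≡ CCSD for two electrons) in
    # aug-cc-pVTZ, stored as truncated natural orbitals
    "H2_witness": FixtureDef("H2", "aug-cc-pvtz",
                             _along_z(("H", 1, -0.3707), ("H", 1, 0.3707)),
                             2, (), (0, 1), 2, witness=True),
}

_NO_TRUNCATION = 1e-7  # natural-occupation cutoff for the stored witness


def fixture_geometry(name: str) -> list[AtomSite]:
    fd = FIXTURES[name]
    return [AtomSite(sym, z, np.array(pos)) for sym, z, pos in fd.atoms]


def list_fixtures() -> list[str]:
    return list(FIXTURES)


def build_fixture(name: str) -> tuple[Wavefunction, OneRDM, dict]:
    """Generate a fixture bundle from scratch with the in-package engine.

    Returns (wavefunction, active-space 1-RDM, info). For the witness, the
    wavefunction holds truncated natural orbitals and the 1-RDM is their
    diagonal occupation matrix over the full (kept) space.
    """
    from ..engine import IntegralEngine, build_shells, casci, rhf

    fd = FIXTURES[name]
    atoms = fixture_geometry(name)
    shells = build_shells(atoms, fd.basis)
    ints = IntegralEngine(atoms, shells)
    scf = rhf(ints, fd.n_electrons)
    n_mo = scf["mo_coeffs"].shape[0]
    if fd.witness:
        e, rdm_full, info = casci(scf, fd.n_electrons, [], list(range(n_mo)))
        occ, U = np.linalg.eigh(rdm_full)        # natural orbitals
        order = np.argsort(occ)[::-1]
        occ, U = occ[order], U[:, order]
        keep = occ > _NO_TRUNCATION
        occ, U = occ[keep], U[:, keep]
        no_coeffs = U.T @ scf["mo_coeffs"]       # NOs over AOs
        mos = MOSet(no_coeffs, occ)
        wfn = Wavefunction(atoms, shells, mos,
                           label=f"{fd.molecule}/{fd.basis} full-CI witness "
                                 f"(natural orbitals, cutoff {_NO_TRUNCATION:g})")
        n_kept = int(keep.sum())
        rdm = OneRDM(np.diag(occ), "full", (), tuple(range(n_kept)),
                     fd.n_electrons, n_kept,
                     provenance=f"{fd.molecule}/{fd.basis} full-CI witness")
        return wfn, rdm, {"energy": e, "n_kept": n_kept,
                          "dropped_population": float(2.0 - occ.sum())}
    e, rdm_act, info = casci(scf, fd.n_active_electrons,
                             list(fd.frozen), list(fd.active))
    mos = MOSet(scf["mo_coeffs"], scf["occupations"], scf["mo_energies"])
    wfn = Wavefunction(atoms, shells, mos,
                       label=f"{fd.molecule}/{fd.basis} RHF orbitals")
    rdm = OneRDM(rdm_act, "active", fd.frozen, fd.active,
                 fd.n_active_electrons, n_mo,
                 provenance=f"{fd.molecule}/{fd.basis} "
                            f"({fd.n_active_electrons},{len(fd.active)}) "
                            "active-space exact diagonalization")
    return wfn, rdm, {"energy": e, "scf_energy": scf["energy"],
                      "n_det": info["n_det"]}


# -- committed-file loading ------------------------------------------------

def _data_root():
    return resources.files("densiwit.fixtures") / "data"


def _read_text(fname: str) -> str:
    path = _data_root() / fname
    text = path.read_text()
    hashes = json.loads((_data_root() / "hashes.json").read_text())
    expect = hashes.get(fname)
    digest = hashlib.sha256(text.encode()).hexdigest()
    if expect is None:
        raise FileNotFoundError(f"{fname} missing from hash manifest")
    if digest != expect:
        raise ValueError(f"fixture file {fname} is corrupt "
                         f"(sha256 {digest[:12]}… != pinned {expect[:12]}…)")
    return text


def load_fixture(name: str) -> tuple[Wavefunction, OneRDM]:
    """Load a committed, hash-verified fixture bundle."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {list(FIXTURES)}")
    wfn = read_molden(_read_text(f"{name}.molden"))
    rdm = read_rdm_bundle(_read_text(f"{name}.rdm.json"))
    return wfn, rdm


def fixture_wavefunctions() -> dict[str, tuple[Wavefunction, OneRDM]]:
    """Catalog of all bundled fixture systems (loaded and hash-verified)."""
    return {name: load_fixture(name) for name in FIXTURES}
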