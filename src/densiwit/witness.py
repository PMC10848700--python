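"""Topological feature extraction and witness comparison.

A FeatureSet packages the density's critical points, basin charges and
electron count; a ComparisonReport holds per-feature deltas (test − witness)
between two FeatureSets of the same molecule. No single scalar fidelity
number is derived — the per-feature deltas plus their summary maxima are the
witness, mirroring how tabulated CP properties and charges are compared
between levels of theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_io import AtomSite, GridSpec
from .density import DensityModel
from .topology import (BasinMap, ChargeTable, CriticalPoint, assign_basins,
                       basin_charges, find_cps)

__all__ = ["FeatureSet", "ComparisonReport", "extract_features",
           "compare_features"]

MATCH_CUTOFF = 0.5  # bohr; max CP pairing distance


@dataclass
class FeatureSet:
    """Topological features of one density."""
    label: str
    cps: list[CriticalPoint]
    charges: ChargeTable
    electron_count: float
    n_atoms: int

    def cps_of_type(self, cp_type: str) -> list[CriticalPoint]:
        return [c for c in self.cps if c.cp_type == cp_type]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "electron_count": self.electron_count,
            "n_atoms": self.n_atoms,
            "cps": [c.to_dict() for c in self.cps],
            "charges": self.charges.rows,
        }


@dataclass
class ComparisonReport:
    """Per-feature deltas of a test FeatureSet against a witness."""
    matched_pairs: list[dict]          # test/witness CP dicts + deltas
    unmatched_test: list[CriticalPoint]
    unmatched_witness: list[CriticalPoint]
    charge_deltas: list[dict]
    electron_count_delta: float

    @property
    def max_abs_delta_rho(self) -> float:
        return max((abs(p["delta_rho"]) for p in self.matched_pairs),
                   default=0.0)

    @property
    def max_abs_delta_charge(self) -> float:
        return max((abs(r["delta_charge"]) for r in self.charge_deltas),
                   default=0.0)

    def to_dict(self) -> dict:
        return {
            "matched_pairs": self.matched_pairs,
            "unmatched_test": [c.to_dict() for c in self.unmatched_test],
            "unmatched_witness": [c.to_dict() for c in self.unmatched_witness],
            "charge_deltas": self.charge_deltas,
            "electron_count_delta": self.electron_count_delta,
            "summary": {
                "max_abs_delta_rho": self.max_abs_delta_rho,
                "max_abs_delta_charge": self.max_abs_delta_charge,
                "abs_electron_count_delta": abs(self.electron_count_delta),
            },
        }


def extract_features(model: DensityModel, atoms: list[AtomSite] | None = None,
                     grid: GridSpec | None = None, spacing: float = 0.1,
                     margin: float = 7.0, label: str = "",
                     seed: int = 0) -> FeatureSet:
    """Run the full topological analysis on one density model."""
    if atoms is None:
        atoms = model.atoms
    if grid is None:
        grid = GridSpec.bounding(atoms, spacing=spacing, margin=margin)
    cps = find_cps(model, seed=seed)
    attractors = [c for c in cps if c.cp_type in ("nuclear_max", "nna")]
    from .density import eval_grid, integrate_density
    fld = eval_grid(model, grid)
    bmap = assign_basins(model, grid, attractors=attractors,
                         field_values=fld.values)
    charges = basin_charges(bmap, model, atoms, field_values=fld.values)
    return FeatureSet(label=label, cps=cps, charges=charges,
                      electron_count=float(integrate_density(fld)),
                      n_atoms=len(atoms))


def compare_features(test: FeatureSet, witness: FeatureSet) -> ComparisonReport:
    """Match CPs greedily by distance within type and report signed deltas.

    Deltas are test − witness. Charges are matched by attached atom index;
    NNA basins are matched to NNA basins by attractor position order.
    """
    if test.n_atoms != witness.n_atoms:
        raise ValueError("feature sets come from different molecules "
                         f"({test.n_atoms} vs {witness.n_atoms} atoms)")
    matched = []
    used_w: set[int] = set()
    unmatched_t = []
    # greedy nearest-distance matching within each cp type
    pairs_all = []
    for ti, tc in enumerate(test.cps):
        for wi, wc in enumerate(witness.cps):
            if tc.cp_type != wc.cp_type:
                continue
            d = float(np.linalg.norm(tc.position - wc.position))
            if d <= MATCH_CUTOFF:
                pairs_all.append((d, ti, wi))
    pairs_all.sort(key=lambda t: (t[0], t[1], t[2]))
    used_t: set[int] = set()
    for d, ti, wi in pairs_all:
        if ti in used_t or wi in used_w:
            continue
        used_t.add(ti)
        used_w.add(wi)
        tc, wc = test.cps[ti], witness.cps[wi]
        matched.append({
            "cp_type": tc.cp_type,
            "test_position": tc.position.tolist(),
            "witness_position": wc.position.tolist(),
            "distance": d,
            "delta_rho": tc.rho - wc.rho,
            "delta_laplacian": tc.laplacian - wc.laplacian,
        })
    unmatched_t = [c for i, c in enumerate(test.cps) if i not in used_t]
    unmatched_w = [c for i, c in enumerate(witness.cps) if i not in used_w]

    charge_deltas = []
    wit_by_atom = {r["atom_index"]: r for r in witness.charges.rows
                   if r["kind"] == "atom"}
    for r in test.charges.rows:
        if r["kind"] == "atom" and r["atom_index"] in wit_by_atom:
            w = wit_by_atom[r["atom_index"]]
            charge_deltas.append({
                "atom_index": r["atom_index"], "kind": "atom",
                "delta_charge": r["charge"] - w["charge"]})
    t_nna = test.charges.nna_rows()
    w_nna = witness.charges.nna_rows()
    for tr, wr in zip(t_nna, w_nna):
        charge_deltas.append({"atom_index": -1, "kind": "nna",
                              "delta_charge": tr["charge"] - wr["charge"]})
    return ComparisonReport(
        matched_pairs=matched, unmatched_test=unmatched_t,
        unmatched_witness=unmatched_w, charge_deltas=charge_deltas,
        electron_count_delta=test.electron_count - witness.electron_count)
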