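"""Readers and writers for the chemistry formats the pipeline touches.

Formats: XYZ (Å in, bohr internally), Molden (geometry + Gaussian shells +
molecular orbitals), Gaussian cube (volumetric scalar fields), and the
package's own JSON bundle for one-particle reduced density matrices.

Internal units are atomic units everywhere (bohr, hartree, e); conversion
happens only at the I/O boundary.

AO ordering convention (pinned): shells appear in file order; within a shell
the Cartesian components are ordered x,y,z for p and alphabetically
(xx,xy,xz,yy,yz,zz; xxx,xxy,xxz,xyy,xyz,xzz,yyy,yyz,yzz,zzz) for d and f;
spherical components follow the Molden order m = 0,+1,-1,+2,-2(,+3,-3).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

ANGSTROM_TO_BOHR = 1.8897261246

_ELEMENTS = [
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
]
SYMBOL_TO_Z = {s: i + 1 for i, s in enumerate(_ELEMENTS)}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

_L_LETTERS = {"s": 0, "p": 1, "d": 2, "f": 3}
_MAX_L = 3


def n_cartesian(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def n_spherical(l: int) -> int:
    return 2 * l + 1


def cartesian_powers(l: int) -> list[tuple[int, int, int]]:
    """Alphabetical Cartesian component order for angular momentum l."""
    return [(l - a, b, a - b) for a in range(l + 1) for b in range(a, -1, -1)]


# -- domain types ----------------------------------------------------------

@dataclass(frozen=True)
class AtomSite:
    """A nucleus: element symbol, charge Z and position in bohr."""
    element: str
    atomic_number: int
    position: np.ndarray  # (3,) bohr

    def __post_init__(self):
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))
        if self.atomic_number < 1:
            raise ValueError("atomic_number must be >= 1")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position must be finite")


@dataclass(frozen=True)
class Shell:
    """A contracted Gaussian shell on one center.

    ``contraction_coeffs`` refer to individually normalized primitives; the
    contracted function is renormalized downstream, so mildly unnormalized
    published contractions are harmless.
    """
    center_index: int
    angular_momentum: int
    spherical: bool
    exponents: list[float]
    contraction_coeffs: list[float]

    def __post_init__(self):
        if not (0 <= self.angular_momentum <= _MAX_L):
            raise ValueError(
                f"angular momentum {self.angular_momentum} unsupported (max f)")
        if len(self.exponents) != len(self.contraction_coeffs):
            raise ValueError("exponent/coefficient length mismatch")
        if any(e <= 0 for e in self.exponents):
            raise ValueError("exponents must be strictly positive")

    @property
    def n_functions(self) -> int:
        l = self.angular_momentum
        return n_spherical(l) if (self.spherical and l >= 2) else n_cartesian(l)


@dataclass
class MOSet:
    """Molecular orbitals: coefficients over AOs plus occupations."""
    coefficients: np.ndarray  # (n_mo, n_ao)
    occupations: np.ndarray   # (n_mo,) in [0, 2]
    energies: np.ndarray | None = None  # hartree, optional
    ao_order: str = "shell-order; p: x,y,z; cart d/f alphabetical; sph m=0,+1,-1,..."

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.occupations = np.asarray(self.occupations, dtype=float)
        if self.coefficients.ndim != 2:
            raise ValueError("coefficients must be a 2-D matrix")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if self.n_mo > self.n_ao:
            raise ValueError("more MOs than AOs")

    @property
    def n_mo(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_ao(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class Wavefunction:
    """Geometry + basis shells + molecular orbitals (restricted, closed shell)."""
    atoms: list[AtomSite]
    shells: list[Shell]
    mos: MOSet
    label: str = ""

    def __post_init__(self):
        for sh in self.shells:
            if not (0 <= sh.center_index < len(self.atoms)):
                raise ValueError("shell references a missing atom")
        if self.n_ao != self.mos.n_ao:
            raise ValueError(
                f"shells imply {self.n_ao} AOs but MO set has {self.mos.n_ao}")

    @property
    def n_ao(self) -> int:
        return sum(sh.n_functions for sh in self.shells)

    @property
    def n_electrons(self) -> float:
        return float(np.sum(self.mos.occupations))


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D grid: origin, three step vectors, point counts."""
    origin: np.ndarray  # (3,) bohr
    axes: np.ndarray    # (3,3) rows are step vectors, bohr
    shape: tuple[int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if any(n < 2 for n in self.shape):
            raise ValueError("grid shape components must be >= 2")
        if abs(np.linalg.det(self.axes)) < 1e-14:
            raise ValueError("grid axes must be linearly independent")

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    def points(self) -> np.ndarray:
        """All grid points, shape (nx*ny*nz, 3), z-fastest."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return self.origin + idx @ self.axes

    @staticmethod
    def bounding(atoms, spacing: float = 0.1, margin: float = 7.0) -> "GridSpec":
        """Uniform axis-aligned grid covering all atoms plus a margin (bohr)."""
        pos = np.array([a.position for a in atoms])
        lo = pos.min(axis=0) - margin
        hi = pos.max(axis=0) + margin
        center = 0.5 * (lo + hi)
        # centered box with even point counts: no voxel sits exactly on a
        # mirror plane through the center, so symmetry-equivalent basins get
        # identical voxel sets instead of tie-broken midplane sheets
        shape = tuple(2 * ((int(np.ceil((hi[d] - lo[d]) / spacing)) + 2) // 2)
                      for d in range(3))
        origin = center - 0.5 * spacing * (np.array(shape) - 1)
        return GridSpec(origin=origin, axes=np.eye(3) * spacing, shape=shape)


@dataclass
class ScalarField:
    """A density-like quantity sampled on a regular grid."""
    grid: GridSpec
    values: np.ndarray  # grid.shape
    quantity: str = "density"  # density | laplacian | difference

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")


# -- XYZ -------------------------------------------------------------------

def read_xyz(text: str) -> list[AtomSite]:
    """Parse XYZ content (coordinates in Å) into AtomSites in bohr."""
    lines = text.splitlines()
    if not lines:
        raise ValueError("empty XYZ content")
    try:
        natom = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed XYZ count line: {lines[0]!r}") from exc
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) < natom:
        raise ValueError(f"expected {natom} atom lines, found {len(body)}")
    atoms = []
    for ln in body[:natom]:
        parts = ln.split()
        sym = parts[0].capitalize()
        if sym not in SYMBOL_TO_Z:
            raise ValueError(f"unknown element symbol {parts[0]!r}")
        xyz = np.array([float(p) for p in parts[1:4]]) * ANGSTROM_TO_BOHR
        atoms.append(AtomSite(sym, SYMBOL_TO_Z[sym], xyz))
    return atoms


def write_xyz(atoms: list[AtomSite], comment: str = "") -> str:
    lines = [str(len(atoms)), comment]
    for a in atoms:
        x, y, z = a.position / ANGSTROM_TO_BOHR
        lines.append(f"{a.element:<2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(lines) + "\n"


# -- Molden ----------------------------------------------------------------

_SECTION_RE = re.compile(r"^\s*\[([^\]]+)\]\s*(.*)$")


def _split_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        m = _SECTION_RE.match(raw)
        if m:
            current = m.group(1).strip().lower()
            sections[current] = []
            trailing = m.group(2).strip()
            if trailing:
                sections[current].append(trailing)
        elif current is not None:
            sections[current].append(raw)
    return sections


def _fnum(tok: str) -> float:
    return float(tok.replace("D", "E").replace("d", "e"))


def read_molden(text: str) -> Wavefunction:
    """Parse a Molden file into a Wavefunction.

    Supports the [5D]/[7F] spherical flags (both must be absent for pure
    Cartesian files); shells above f raise. Occupations come from ``Occup=``.
    """
    sec = _split_sections(text)
    for required in ("atoms", "gto", "mo"):
        if required not in sec:
            raise ValueError(f"Molden content missing [{required}] section")

    spherical = any(k in sec for k in ("5d", "5d7f", "7f", "9g", "5d10f"))

    # [Atoms] — unit tag on the section line
    atoms_lines = sec["atoms"]
    unit = "angs"
    if atoms_lines and atoms_lines[0].strip().lower() in ("au", "angs", "(au)", "(angs)"):
        unit = atoms_lines[0].strip().lower().strip("()")
        atoms_lines = atoms_lines[1:]
    scale = 1.0 if unit == "au" else ANGSTROM_TO_BOHR
    atoms = []
    for ln in atoms_lines:
        if not ln.strip():
            continue
        parts = ln.split()
        sym = parts[0].capitalize()
        z = int(parts[2])
        pos = np.array([_fnum(p) for p in parts[3:6]]) * scale
        atoms.append(AtomSite(sym, z, pos))

    # [GTO]
    shells: list[Shell] = []
    lines = [ln for ln in sec["gto"] if ln.strip()]
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        atom_idx = int(parts[0]) - 1
        i += 1
        while i < len(lines):
            head = lines[i].split()
            letter = head[0].lower() if head else ""
            if len(head) >= 2 and letter in ("g", "h", "i"):
                raise ValueError(f"unsupported angular momentum {head[0]!r}")
            if len(head) >= 2 and (letter in _L_LETTERS or letter == "sp"):
                nprim = int(head[1])
                i += 1
                prims = []
                for _ in range(nprim):
                    toks = lines[i].split()
                    prims.append(tuple(_fnum(t) for t in toks[:3 if letter == "sp" else 2]))
                    i += 1
                if letter == "sp":
                    shells.append(Shell(atom_idx, 0, spherical,
                                        [p[0] for p in prims], [p[1] for p in prims]))
                    shells.append(Shell(atom_idx, 1, spherical,
                                        [p[0] for p in prims], [p[2] for p in prims]))
                else:
                    l = _L_LETTERS[letter]
                    shells.append(Shell(atom_idx, l, spherical,
                                        [p[0] for p in prims], [p[1] for p in prims]))
            else:
                break  # next atom block
        else:
            break
    n_ao = sum(sh.n_functions for sh in shells)

    # [MO]
    coeff_rows, occs, enes = [], [], []
    current: dict[int, float] | None = None

    def flush():
        if current is not None:
            row = np.zeros(n_ao)
            for idx, val in current.items():
                if not (1 <= idx <= n_ao):
                    raise ValueError(
                        f"MO coefficient index {idx} out of range (n_ao={n_ao})")
                row[idx - 1] = val
            coeff_rows.append(row)

    for ln in sec["mo"]:
        s = ln.strip()
        if not s:
            continue
        low = s.lower()
        if low.startswith(("sym=", "spin=")):
            continue
        if low.startswith("ene="):
            enes.append(_fnum(s.split("=", 1)[1]))
            continue
        if low.startswith("occup="):
            flush()
            current = {}
            occs.append(_fnum(s.split("=", 1)[1]))
            continue
        parts = s.split()
        if len(parts) >= 2 and current is not None:
            current[int(parts[0])] = _fnum(parts[1])
    flush()

    if not coeff_rows:
        raise ValueError("no molecular orbitals found in [MO] section")
    mos = MOSet(np.array(coeff_rows), np.array(occs),
                np.array(enes) if len(enes) == len(occs) else None)
    return Wavefunction(atoms, shells, mos)


def write_molden(wfn: Wavefunction, title: str = "densiwit") -> str:
    """Serialize a Wavefunction in the package's Molden dialect ([5D][7F])."""
    out = ["[Molden Format]", f"[Title]\n {title}", "[Atoms] AU"]
    for i, a in enumerate(wfn.atoms, start=1):
        x, y, z = a.position
        out.append(f"{a.element:<2s} {i:4d} {a.atomic_number:4d} "
                   f"{x:20.12f} {y:20.12f} {z:20.12f}")
    out.append("[GTO]")
    letters = {v: k for k, v in _L_LETTERS.items()}
    by_atom: dict[int, list[Shell]] = {}
    for sh in wfn.shells:
        by_atom.setdefault(sh.center_index, []).append(sh)
    for i in range(len(wfn.atoms)):
        out.append(f"{i + 1} 0")
        for sh in by_atom.get(i, []):
            out.append(f" {letters[sh.angular_momentum]} {len(sh.exponents)} 1.00")
            for e, c in zip(sh.exponents, sh.contraction_coeffs):
                out.append(f"  {e:20.10E} {c:20.10E}")
        out.append("")
    if any(sh.spherical for sh in wfn.shells):
        out.append("[5D]")
        out.append("[7F]")
    out.append("[MO]")
    enes = wfn.mos.energies
    for m in range(wfn.mos.n_mo):
        out.append(" Sym= A")
        out.append(f" Ene= {0.0 if enes is None else enes[m]:.10f}")
        out.append(" Spin= Alpha")
        out.append(f" Occup= {wfn.mos.occupations[m]:.10f}")
        for a in range(wfn.mos.n_ao):
            out.append(f" {a + 1:4d} {wfn.mos.coefficients[m, a]:20.12E}")
    return "\n".join(out) + "\n"


# -- Gaussian cube ---------------------------------------------------------

def write_cube(fld: ScalarField, atoms: list[AtomSite],
               comment: str = "densiwit scalar field") -> str:
    """Serialize a ScalarField as a Gaussian cube (bohr, Z-fastest)."""
    g = fld.grid
    lines = [comment, f"quantity: {fld.quantity}"]
    ox, oy, oz = g.origin
    lines.append(f"{len(atoms):5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}")
    for d in range(3):
        ax = g.axes[d]
        lines.append(f"{g.shape[d]:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}")
    for a in atoms:
        x, y, z = a.position
        lines.append(f"{a.atomic_number:5d} {float(a.atomic_number):12.6f} "
                     f"{x:12.6f} {y:12.6f} {z:12.6f}")
    flat = fld.values.reshape(g.shape[0] * g.shape[1], g.shape[2])
    for row in flat:
        for start in range(0, len(row), 6):
            chunk = row[start:start + 6]
            lines.append("".join(f" {v:12.5E}" for v in chunk))
    return "\n".join(lines) + "\n"


def read_cube(text: str) -> tuple[ScalarField, list[AtomSite]]:
    lines = text.splitlines()
    quantity = "density"
    if lines[1].startswith("quantity:"):
        quantity = lines[1].split(":", 1)[1].strip()
    hdr = lines[2].split()
    natom = int(hdr[0])
    origin = np.array([float(x) for x in hdr[1:4]])
    shape, axes = [], []
    for d in range(3):
        parts = lines[3 + d].split()
        shape.append(abs(int(parts[0])))
        axes.append([float(x) for x in parts[1:4]])
    atoms = []
    for i in range(natom):
        parts = lines[6 + i].split()
        z = int(parts[0])
        pos = np.array([float(x) for x in parts[2:5]])
        atoms.append(AtomSite(Z_TO_SYMBOL.get(z, "X"), max(z, 1), pos))
    vals = []
    for ln in lines[6 + natom:]:
        vals.extend(float(t) for t in ln.split())
    grid = GridSpec(origin, np.array(axes), tuple(shape))
    values = np.array(vals).reshape(grid.shape)
    return ScalarField(grid, values, quantity), atoms


# -- 1-RDM bundle ----------------------------------------------------------

_BUNDLE_KEYS = ("matrix", "mo_space_size", "frozen_indices", "active_indices",
                "n_active_electrons", "provenance")


def read_rdm_bundle(text: str):
    """Parse the JSON 1-RDM bundle into a OneRDM (see rdm module)."""
    from .rdm import OneRDM

    data = json.loads(text)
    missing = [k for k in _BUNDLE_KEYS if k not in data]
    if missing:
        raise ValueError(f"RDM bundle missing keys: {missing}")
    matrix = np.asarray(data["matrix"])
    if np.iscomplexobj(matrix):
        raise ValueError("RDM bundle matrix must be real")
    matrix = matrix.astype(float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("RDM bundle matrix must be square")
    frozen = list(data["frozen_indices"])
    active = list(data["active_indices"])
    if set(frozen) & set(active):
        raise ValueError("frozen and active index sets overlap")
    n_act = int(data["n_active_electrons"])
    space = "active" if matrix.shape[0] == len(active) and \
        len(active) < int(data["mo_space_size"]) else "full"
    if matrix.shape[0] == int(data["mo_space_size"]) == len(active) and not frozen:
        space = "full" if not frozen else space
    # an active-space matrix over the whole MO space with no frozen orbitals
    # is simultaneously "full"; prefer the explicit tag when given
    space = data.get("space", space)
    rdm = OneRDM(matrix=matrix, space=space,
                 frozen_indices=frozen, active_indices=active,
                 n_active_electrons=n_act,
                 mo_space_size=int(data["mo_space_size"]),
                 provenance=str(data["provenance"]))
    tr = float(np.trace(matrix))
    if tr > 2.0 * matrix.shape[0]:
        import warnings
        warnings.warn(f"RDM trace {tr:.3f} is unphysically large", stacklevel=2)
    return rdm


def write_rdm_bundle(rdm) -> str:
    return json.dumps({
        "matrix": rdm.matrix.tolist(),
        "mo_space_size": rdm.mo_space_size,
        "frozen_indices": list(rdm.frozen_indices),
        "active_indices": list(rdm.active_indices),
        "n_active_electrons": rdm.n_active_electrons,
        "provenance": rdm.provenance,
        "space": rdm.space,
    }, indent=1)
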