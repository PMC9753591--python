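"""Contracted Cartesian Gaussian basis sets.

Basis definitions are read from Gaussian94-format text (STO-3G and 6-31G for
H/O are bundled; larger sets are user-supplied).  All angular components are
Cartesian; the AO ordering is deterministic: atoms in input order, shells in
file order per atom, and within a shell the Cartesian components in
descending lexicographic order ((lx, ly, lz) with lx major), e.g. p -> x, y,
z and d -> xx, xy, xz, yy, yz, zz.  Every AO is normalized to unit
self-overlap.

Ghost atoms carry basis functions but no nuclear charge (the counterpoise
construction); they are flagged per atom and excluded from the nuclear
attraction and nuclear repulsion sums.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .cluster import Atom

_SHELL_L = {"S": 0, "P": 1, "D": 2, "F": 3, "G": 4}

_DFACT = {-1: 1.0, 0: 1.0, 1: 1.0}


def _double_factorial(n: int) -> float:
    if n not in _DFACT:
        _DFACT[n] = n * _double_factorial(n - 2)
    return _DFACT[n]


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian monomial powers of a shell, in canonical order."""
    return [(lx, ly, l - lx - ly)
            for lx in range(l, -1, -1)
            for ly in range(l - lx, -1, -1)]


def primitive_norm(alpha: float, l: int) -> float:
    """Normalization of an (l,0,0)-type Cartesian primitive Gaussian."""
    return ((2.0 * alpha / np.pi) ** 0.75
            * (4.0 * alpha) ** (l / 2.0)
            / np.sqrt(_double_factorial(2 * l - 1)))


@dataclass(frozen=True)
class GaussianShell:
    """One contracted shell: center (bohr), angular momentum and primitives.

    ``coefficients`` already include the primitive normalization factors."""

    center: np.ndarray
    l: int
    exponents: np.ndarray
    coefficients: np.ndarray
    atom_index: int

    def __post_init__(self):
        exps = np.asarray(self.exponents, dtype=float)
        coefs = np.asarray(self.coefficients, dtype=float)
        if exps.shape != coefs.shape or exps.ndim != 1:
            raise ValueError("exponent/coefficient arrays must match in length")
        if np.any(exps <= 0):
            raise ValueError("primitive exponents must be positive")
        object.__setattr__(self, "exponents", exps)
        object.__setattr__(self, "coefficients", coefs)
        object.__setattr__(self, "center",
                           np.asarray(self.center, dtype=float))

    @property
    def n_cart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def _self_overlap(shell: GaussianShell, comp: tuple[int, int, int]) -> float:
    """Raw self-overlap of one Cartesian component of a contracted shell."""
    a = shell.exponents[:, None]
    b = shell.exponents[None, :]
    c = shell.coefficients
    p = a + b
    pref = (np.pi / p) ** 1.5
    for n in comp:
        pref = pref * _double_factorial(2 * n - 1) / (2.0 * p) ** n
    return float(c @ pref @ c)


# ---------------------------------------------------------------------------
# Gaussian94 parsing
# ---------------------------------------------------------------------------

def parse_gaussian94(text: str) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Parse Gaussian94-format basis text into
    ``{element: [(l, exponents, coefficients), ...]}`` with raw (unnormalized)
    contraction coefficients.  SP blocks are split into an S and a P shell."""
    library: dict[str, list] = {}
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.lstrip().startswith("!")]
    i = 0
    while i < len(lines):
        if lines[i].strip() == "****":
            i += 1
            continue
        head = lines[i].split()
        element = head[0].capitalize()
        shells: list = []
        i += 1
        while i < len(lines) and lines[i].strip() != "****":
            parts = lines[i].split()
            ltag = parts[0].upper()
            nprim = int(parts[1])
            rows = []
            for k in range(nprim):
                i += 1
                rows.append([float(x.replace("D", "E").replace("d", "e"))
                             for x in lines[i].split()])
            rows = np.array(rows)
            if ltag == "SP":
                shells.append((0, rows[:, 0].copy(), rows[:, 1].copy()))
                shells.append((1, rows[:, 0].copy(), rows[:, 2].copy()))
            elif ltag in _SHELL_L:
                shells.append((_SHELL_L[ltag], rows[:, 0].copy(), rows[:, 1].copy()))
            else:
                raise ValueError(f"unsupported shell type {ltag!r}")
            i += 1
        library[element] = shells
        i += 1
    return library


def load_basis_library(name_or_path: str) -> dict:
    """Load a basis library by bundled name (e.g. ``"sto-3g"``) or file path."""
    candidate = Path(str(name_or_path))
    if candidate.exists():
        return parse_gaussian94(candidate.read_text())
    fname = re.sub(r"\s+", "", str(name_or_path)).lower() + ".gbs"
    ref = resources.files("efmag.data").joinpath(fname)
    if not ref.is_file():
        raise FileNotFoundError(
            f"basis {name_or_path!r}: no such file and no bundled set {fname!r}"
        )
    return parse_gaussian94(ref.read_text())


# ---------------------------------------------------------------------------
# BasisSet
# ---------------------------------------------------------------------------

@dataclass
class BasisSet:
    """A concrete AO basis over a list of atoms (some possibly ghosts)."""

    atoms: tuple[Atom, ...]
    shells: list[GaussianShell]
    ghost: np.ndarray  # bool per atom

    ao_shell: np.ndarray = field(init=False)       # shell index per AO
    ao_component: list = field(init=False)          # (lx,ly,lz) per AO
    ao_norms: np.ndarray = field(init=False)
    shell_offsets: np.ndarray = field(init=False)

    def __post_init__(self):
        self.ghost = np.asarray(self.ghost, dtype=bool)
        ao_shell, comps, norms, offsets = [], [], [], []
        nao = 0
        for s_idx, sh in enumerate(self.shells):
            offsets.append(nao)
            for comp in cartesian_components(sh.l):
                ao_shell.append(s_idx)
                comps.append(comp)
                norms.append(1.0 / np.sqrt(_self_overlap(sh, comp)))
                nao += 1
        self.ao_shell = np.array(ao_shell, dtype=int)
        self.ao_component = comps
        self.ao_norms = np.array(norms)
        self.shell_offsets = np.array(offsets + [nao], dtype=int)

    @property
    def n_ao(self) -> int:
        return len(self.ao_shell)

    @property
    def n_electrons(self) -> int:
        return int(sum(a.Z for a, g in zip(self.atoms, self.ghost) if not g))

    def nuclear_charges(self) -> list[tuple[float, np.ndarray]]:
        """(Z, position) for every non-ghost atom."""
        return [(float(a.Z), a.position)
                for a, g in zip(self.atoms, self.ghost) if not g]

    def nuclear_repulsion(self) -> float:
        nucs = self.nuclear_charges()
        e = 0.0
        for i in range(len(nucs)):
            for j in range(i + 1, len(nucs)):
                e += nucs[i][0] * nucs[j][0] / np.linalg.norm(
                    nucs[i][1] - nucs[j][1])
        return e

    def ao_centers(self) -> np.ndarray:
        """Shell center of each AO, shape (n_ao, 3)."""
        return np.array([self.shells[s].center for s in self.ao_shell])

    def eval_ao(self, points: np.ndarray) -> np.ndarray:
        """Values of all (normalized) AOs on ``points`` (npts, 3) -> (npts, n_ao)."""
        pts = np.asarray(points, dtype=float)
        out = np.empty((len(pts), self.n_ao))
        ao = 0
        for sh in self.shells:
            d = pts - sh.center
            r2 = np.einsum("pi,pi->p", d, d)
            radial = np.einsum(
                "k,pk->p", sh.coefficients,
                np.exp(-np.outer(r2, sh.exponents)))
            for comp in cartesian_components(sh.l):
                poly = d[:, 0] ** comp[0] * d[:, 1] ** comp[1] * d[:, 2] ** comp[2]
                out[:, ao] = poly * radial
                ao += 1
        return out * self.ao_norms[None, :]


def build_basis(atoms, library, ghost=None) -> BasisSet:
    """Construct a :class:`BasisSet` for ``atoms`` from a parsed library (or
    its name/path).  ``ghost`` is an optional boolean mask per atom."""
    if isinstance(library, str):
        library = load_basis_library(library)
    atoms = tuple(atoms)
    if ghost is None:
        ghost = np.zeros(len(atoms), dtype=bool)
    shells = []
    for idx, atom in enumerate(atoms):
        if atom.symbol not in library:
            raise KeyError(f"basis library has no entry for element {atom.symbol}")
        for l, exps, coefs in library[atom.symbol]:
            norm = np.array([primitive_norm(e, l) for e in exps])
            shells.append(GaussianShell(
                center=atom.position, l=l, exponents=exps,
                coefficients=coefs * norm, atom_index=idx))
    return BasisSet(atoms=atoms, shells=shells, ghost=np.asarray(ghost, dtype=bool))
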