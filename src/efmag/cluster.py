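"""Geometry and fragment data model: atoms, monomers, clusters, subsystems.

Clusters are ordered lists of monomers (noncovalently bound fragments); every
energy expression in the many-body expansion is indexed by tuples of monomer
indices (``Subsystem``).  File I/O uses XYZ (Angstrom on disk, bohr in
memory); fragments are either delimited by blank lines in the coordinate
block or auto-detected from a covalent-radius bond graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ANGSTROM_TO_BOHR,
    BOHR_TO_ANGSTROM,
    COVALENT_RADIUS,
    ELEMENT_Z,
    WATER_R_OH_ANGSTROM,
    WATER_THETA_HOH_DEG,
)


class XYZParseError(ValueError):
    """Malformed XYZ input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FragmentationError(ValueError):
    """Invalid fragment partition (overlapping or incomplete)."""


class ChargedMonomerError(ValueError):
    """The dipole embedding model requires neutral monomers."""


class PlacementError(RuntimeError):
    """Synthetic cluster generation could not satisfy its constraints."""


@dataclass(frozen=True)
class Atom:
    """A nucleus: element symbol, charge Z and position (bohr)."""

    symbol: str
    position: np.ndarray  # (3,) bohr

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for {self.symbol}: {self.position}")
        object.__setattr__(self, "position", pos)
        if self.symbol not in ELEMENT_Z:
            raise ValueError(f"unknown element symbol {self.symbol!r}")

    @property
    def Z(self) -> int:
        return ELEMENT_Z[self.symbol]


@dataclass(frozen=True)
class Monomer:
    """A covalently intact fragment.  Only neutral monomers are accepted:
    the dipole embedding drops the monopole term of the multipole expansion,
    which is only exact for vanishing net charge."""

    atoms: tuple[Atom, ...]
    charge: int = 0

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("monomer must contain at least one atom")
        if self.charge != 0:
            raise ChargedMonomerError(
                f"monomer with net charge {self.charge}: the dipole embedding "
                "field assumes neutral monomers (vanishing monopole term)"
            )

    @property
    def n_electrons(self) -> int:
        return sum(a.Z for a in self.atoms) - self.charge

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([float(a.Z) for a in self.atoms])


def nuclear_charge_center(monomer: Monomer) -> np.ndarray:
    """Charge-weighted nuclear centroid: the point about which the nuclear
    dipole moment of the monomer vanishes (the natural center for the
    two-point-charge dipole site)."""
    Z = monomer.charges
    return Z @ monomer.positions / Z.sum()


@dataclass
class Cluster:
    """An ordered, atom-disjoint collection of monomers plus the external
    uniform magnetic field ``B`` (units of B0) and gauge origin (bohr)."""

    monomers: list[Monomer]
    B: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gauge_origin: np.ndarray | None = None
    title: str = ""

    def __post_init__(self):
        if not self.monomers:
            raise ValueError("cluster must contain at least one monomer")
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (3,):
            raise ValueError("B must be a length-3 vector (units of B0)")
        seen: set[tuple] = set()
        for m in self.monomers:
            for a in m.atoms:
                key = (a.symbol, *np.round(a.position, 12))
                if key in seen:
                    raise FragmentationError(
                        f"atom {a.symbol} at {a.position} appears in two monomers"
                    )
                seen.add(key)
        if self.gauge_origin is None:
            # Default gauge origin: nuclear-charge centroid of the whole
            # cluster (only CGO energies depend on it; LAO results do not).
            Z = np.concatenate([m.charges for m in self.monomers])
            R = np.concatenate([m.positions for m in self.monomers])
            self.gauge_origin = Z @ R / Z.sum()
        else:
            self.gauge_origin = np.asarray(self.gauge_origin, dtype=float)

    def __len__(self) -> int:
        return len(self.monomers)

    @property
    def atoms(self) -> list[Atom]:
        return [a for m in self.monomers for a in m.atoms]

    @property
    def n_electrons(self) -> int:
        return sum(m.n_electrons for m in self.monomers)

    def subsystem(self, indices) -> "Subsystem":
        return Subsystem(tuple(sorted(indices)), len(self))

    def translated(self, shift) -> "Cluster":
        shift = np.asarray(shift, dtype=float)
        mons = [
            Monomer(tuple(Atom(a.symbol, a.position + shift) for a in m.atoms))
            for m in self.monomers
        ]
        return Cluster(
            mons, B=self.B.copy(), gauge_origin=self.gauge_origin + shift,
            title=self.title,
        )


@dataclass(frozen=True)
class Subsystem:
    """A sorted tuple of monomer indices: size 1 = monomer, 2 = dimer."""

    indices: tuple[int, ...]
    n_monomers: int

    def __post_init__(self):
        idx = self.indices
        if len(set(idx)) != len(idx) or tuple(sorted(idx)) != idx:
            raise ValueError(f"subsystem indices must be sorted and unique: {idx}")
        if not idx or min(idx) < 0 or max(idx) >= self.n_monomers:
            raise ValueError(
                f"subsystem indices {idx} invalid for {self.n_monomers} monomers"
            )

    def __iter__(self):
        return iter(self.indices)

    def __len__(self):
        return len(self.indices)


# ---------------------------------------------------------------------------
# Fragment detection
# ---------------------------------------------------------------------------

def detect_fragments(atoms: list[Atom], bond_scale: float = 1.2) -> list[list[int]]:
    """Partition atoms into connected components of the bond graph.

    Two atoms are bonded when their distance is at most ``bond_scale`` times
    the sum of their covalent radii.  Components are returned ordered by
    their lowest atom index.
    """
    if not atoms:
        raise ValueError("no atoms to fragment")
    n = len(atoms)
    pos = np.array([a.position for a in atoms])
    rad = np.array([COVALENT_RADIUS[a.symbol] for a in atoms])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cutoff = bond_scale * (rad[:, None] + rad[None, :])
    bonded = (d <= cutoff) & ~np.eye(n, dtype=bool)

    seen = [False] * n
    components: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(bonded[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        components.append(sorted(comp))
    components.sort(key=lambda c: c[0])
    return components


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

def _parse_field_tag(comment: str) -> np.ndarray | None:
    """Extract an optional ``B= bx by bz`` tag (B0 units) from an XYZ comment."""
    if "B=" not in comment:
        return None
    tail = comment.split("B=", 1)[1].split()
    try:
        return np.array([float(x) for x in tail[:3]])
    except (ValueError, IndexError):
        raise XYZParseError(f"malformed B= tag in comment {comment!r}")


def read_cluster_xyz(path, fragmentation: str = "auto",
                     bond_scale: float = 1.2) -> Cluster:
    """Read a (possibly extended) XYZ file into a :class:`Cluster`.

    Coordinates on disk are Angstrom and are converted to bohr.  With
    ``fragmentation="blank-line-delimited"`` blank lines inside the
    coordinate block separate monomers; with ``"auto"`` the partition is
    the connected components of the covalent-radius bond graph.
    """
    if fragmentation not in ("auto", "blank-line-delimited"):
        raise ValueError(f"unknown fragmentation mode {fragmentation!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZParseError("empty file", line=1)
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"expected atom count, got {lines[0]!r}", line=1)
    comment = lines[1] if len(lines) > 1 else ""
    B = _parse_field_tag(comment)

    atoms: list[Atom] = []
    blocks: list[list[int]] = [[]]
    for ln, raw in enumerate(lines[2:], start=3):
        text = raw.strip()
        if not text:
            if blocks[-1]:
                blocks.append([])
            continue
        parts = text.split()
        if len(parts) < 4:
            raise XYZParseError(f"expected 'El x y z', got {raw!r}", line=ln)
        sym = parts[0].capitalize()
        try:
            xyz = np.array([float(p) for p in parts[1:4]]) * ANGSTROM_TO_BOHR
        except ValueError:
            raise XYZParseError(f"non-numeric coordinate in {raw!r}", line=ln)
        try:
            atoms.append(Atom(sym, xyz))
        except ValueError as exc:
            raise XYZParseError(str(exc), line=ln)
        blocks[-1].append(len(atoms) - 1)
    if blocks and not blocks[-1]:
        blocks.pop()
    if len(atoms) != natoms:
        raise XYZParseError(
            f"header declares {natoms} atoms but {len(atoms)} were read", line=1
        )

    if fragmentation == "blank-line-delimited":
        partition = blocks
    else:
        partition = detect_fragments(atoms, bond_scale=bond_scale)
    covered = sorted(i for blk in partition for i in blk)
    if covered != list(range(len(atoms))):
        raise FragmentationError("fragment partition does not cover atoms exactly once")
    monomers = [Monomer(tuple(atoms[i] for i in blk)) for blk in partition]
    kwargs = {} if B is None else {"B": B}
    return Cluster(monomers, title=comment.split("B=")[0].strip(), **kwargs)


def write_cluster_xyz(cluster: Cluster, path) -> None:
    """Write an extended XYZ file (Angstrom, blank lines between monomers,
    ``B=`` tag in the comment when a field is set)."""
    lines = [str(sum(len(m.atoms) for m in cluster.monomers))]
    comment = cluster.title
    if np.any(cluster.B != 0.0):
        comment = (comment + " " if comment else "") + \
            "B= {:.10g} {:.10g} {:.10g}".format(*cluster.B)
    lines.append(comment)
    for k, m in enumerate(cluster.monomers):
        if k > 0:
            lines.append("")
        for a in m.atoms:
            x, y, z = a.position * BOHR_TO_ANGSTROM
            lines.append(f"{a.symbol:<3s} {x: .12f} {y: .12f} {z: .12f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic water structures
# ---------------------------------------------------------------------------

def make_cyclic_water_trimer(oo: float = 5.2724,
                             donor_tilt_deg: float = 25.0) -> Cluster:
    """Deterministic compact cyclic water trimer (synthetic stand-in for a
    hydrogen-bonded ring, not an optimized literature structure).

    Oxygens sit on an equilateral triangle of side ``oo`` (bohr, default
    2.79 Angstrom); each water donates one hydrogen toward the next
    oxygen, tilted ``donor_tilt_deg`` outward of the ring so the hydrogen
    bonds are bent as in real trimers (H...O about 1.93 Angstrom, no H-H
    contact under 2.1 Angstrom); free hydrogens alternate above/below the
    O3 plane."""
    r = WATER_R_OH_ANGSTROM * ANGSTROM_TO_BOHR
    theta = math.radians(WATER_THETA_HOH_DEG)
    tilt = math.radians(donor_tilt_deg)
    centers = [oo / math.sqrt(3.0) * np.array(
        [math.cos(2 * math.pi * k / 3), math.sin(2 * math.pi * k / 3), 0.0])
        for k in range(3)]
    monomers = []
    for k in range(3):
        O = centers[k]
        u = centers[(k + 1) % 3] - O
        u = u / np.linalg.norm(u)
        n_out = O / np.linalg.norm(O)
        w = np.array([0.0, 0.0, 1.0 if k % 2 == 0 else -1.0])
        d_dir = math.cos(tilt) * u + math.sin(tilt) * n_out
        d_dir = d_dir / np.linalg.norm(d_dir)
        f_dir = math.cos(theta) * d_dir + math.sin(theta) * w
        monomers.append(Monomer((Atom("O", O), Atom("H", O + r * d_dir),
                                 Atom("H", O + r * f_dir))))
    return Cluster(monomers, title="synthetic cyclic water trimer")



def _water_template() -> np.ndarray:
    """Rigid water coordinates (bohr), O at the origin, C2v axis along +z."""
    r = WATER_R_OH_ANGSTROM * ANGSTROM_TO_BOHR
    half = math.radians(WATER_THETA_HOH_DEG) / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [r * math.sin(half), 0.0, r * math.cos(half)],
        [-r * math.sin(half), 0.0, r * math.cos(half)],
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, sign-fixed)."""
    M = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 2] = -Q[:, 2]
    return Q


def generate_water_cluster(n: int, box: float, min_OO: float, seed: int,
                           B=(0.0, 0.0, 0.0), max_retries: int = 2000) -> Cluster:
    """Place ``n`` rigid water monomers at uniformly random positions and
    orientations in a cubic box of edge ``box`` (bohr), rejecting placements
    with any O-O distance below ``min_OO`` (bohr).

    This emulates the liquid-like snapshots used to exercise the fragment
    method (the reference data came from a TIP3P molecular-dynamics snapshot
    in a 30 Angstrom box; dynamics itself is out of scope here).  Output is
    bit-reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    template = _water_template()
    oxygens: list[np.ndarray] = []
    monomers: list[Monomer] = []
    for _ in range(n):
        for attempt in range(max_retries):
            origin = rng.uniform(0.0, box, size=3)
            if all(np.linalg.norm(origin - o) >= min_OO for o in oxygens):
                break
        else:
            raise PlacementError(
                f"could not place monomer {len(monomers) + 1} of {n} in a "
                f"box of {box:.1f} bohr with min O-O {min_OO:.2f} bohr "
                f"after {max_retries} retries"
            )
        rot = _random_rotation(rng)
        coords = template @ rot.T + origin
        oxygens.append(origin)
        monomers.append(Monomer((
            Atom("O", coords[0]), Atom("H", coords[1]), Atom("H", coords[2]),
        )))
    return Cluster(monomers, B=np.asarray(B, dtype=float),
                   title=f"synthetic water cluster n={n} seed={seed}")
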