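"""Many-body expansion assembly: energies, counterpoise, densities, MIE.

The production path is the second-order expansion ("embedded fragment
method"): cluster energy = sum of embedded monomer energies plus pairwise
corrections E_ij - E_i - E_j, every subsystem solved in the converged
dipole field of the monomers outside it.  The untruncated expansion
(inclusion-exclusion over all k-mers, no embedding) is exact at full order
and serves as the module's master oracle.  The counterpoise-corrected
total replaces each pair correction with ghost-basis monomer energies
evaluated in the dimer basis and in the embedding field excluding the
dimer.

Subsystem densities assemble the same way: cluster density = sum of
monomer density matrices plus pairwise density corrections, embedded in
cluster AO indexing; the inclusion-exclusion weights make the assembled
density conserve the electron count exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .backend import Backend
from .basis import BasisSet
from .cluster import Cluster, nuclear_charge_center
from .constants import HARTREE_TO_KCAL
from .embedding import EmbeddingField
from .scf import (
    SCFConvergenceError,
    build_subsystem_basis,
    dimer_superposition_guess,
    mp2_energy,
)


@dataclass
class SubsystemRecord:
    """Energy ledger entry for one subsystem job."""

    key: tuple
    e_scf: float
    e_corr: float
    n_iterations: int
    converged: bool
    density: np.ndarray | None = None   # spatial AO density
    n_ao: int = 0

    @property
    def energy(self) -> float:
        return self.e_scf + self.e_corr


@dataclass
class MBEResult:
    """Second-order expansion ledger and totals (hartree)."""

    n_monomers: int
    method: str
    B: np.ndarray
    monomer_energies: dict
    dimer_energies: dict
    isolated_energies: dict
    records: dict
    counterpoise: bool = False
    cp_monomer_energies: dict = dataclass_field(default_factory=dict)

    @property
    def pair_corrections(self) -> dict:
        return {(i, j): self.dimer_energies[(i, j)]
                - self.monomer_energies[i] - self.monomer_energies[j]
                for (i, j) in sorted(self.dimer_energies)}

    @property
    def total(self) -> float:
        """E^EFM = sum E_i + sum (E_ij - E_i - E_j), compensated summation
        in sorted key order so parallel execution is reproducible."""
        terms = [self.monomer_energies[i]
                 for i in sorted(self.monomer_energies)]
        terms += [self.pair_corrections[k]
                  for k in sorted(self.pair_corrections)]
        return math.fsum(terms)

    @property
    def cp_total(self) -> float | None:
        """Counterpoise-corrected total: pair corrections use monomer
        energies in the dimer (ghost-augmented) basis, embedded in the
        field excluding the dimer."""
        if not self.counterpoise:
            return None
        terms = [self.monomer_energies[i]
                 for i in sorted(self.monomer_energies)]
        for (i, j) in sorted(self.dimer_energies):
            terms.append(self.dimer_energies[(i, j)]
                         - self.cp_monomer_energies[(i, (i, j))]
                         - self.cp_monomer_energies[(j, (i, j))])
        return math.fsum(terms)

    @property
    def e_isolated_sum(self) -> float:
        return math.fsum(self.isolated_energies[i]
                         for i in sorted(self.isolated_energies))

    @property
    def interaction_energy(self) -> float:
        """E^EFM - sum_i E_i^iso (hartree)."""
        return self.total - self.e_isolated_sum


def mean_interaction_energy(result: MBEResult, relative_to:
                            "MBEResult | None" = None) -> float:
    """Mean interaction energy per monomer, kcal/mol:
    (E^EFM - sum E_iso) / n.  With ``relative_to`` given, returns
    MIE - MIE_ref (the two results must share method and monomer count)."""
    mie = result.interaction_energy / result.n_monomers * HARTREE_TO_KCAL
    if relative_to is None:
        return mie
    if (relative_to.method != result.method
            or relative_to.n_monomers != result.n_monomers):
        raise ValueError(
            "relative MIE requires matching method and monomer count")
    return mie - mean_interaction_energy(relative_to)


# ---------------------------------------------------------------------------
# Job execution
# ---------------------------------------------------------------------------

def _record(key, backend: Backend, result, keep_density=True) -> SubsystemRecord:
    e_corr = 0.0
    if result.converged and backend.method == "hf+mp2":
        e_corr = mp2_energy(result)
    return SubsystemRecord(
        key=key, e_scf=result.energy, e_corr=e_corr,
        n_iterations=result.n_iterations, converged=result.converged,
        density=result.spatial_density() if keep_density else None,
        n_ao=result.n_ao)


def _check_all_converged(records: dict):
    bad = [k for k, r in records.items() if not r.converged]
    if bad:
        raise SCFConvergenceError(
            f"unconverged subsystem jobs: {bad}; no partial total is reported")


def efm_energy(cluster: Cluster, backend: Backend,
               field: EmbeddingField | None,
               counterpoise: bool = False,
               dimer_cutoff: float = math.inf,
               map_fn=map) -> MBEResult:
    """Second-order embedded-fragment energy of a cluster.

    ``field`` is a converged :class:`EmbeddingField` (or ``None`` for the
    unembedded second-order expansion).  All subsystem jobs are independent
    and dispatched through ``map_fn``.  ``dimer_cutoff`` optionally skips
    pairs whose nuclear-charge centers are farther apart (their pair
    correction is taken as zero); the default keeps every pair.
    """
    n = len(cluster)
    if field is not None and not field.converged:
        raise ValueError("embedding field must be converged (or None)")

    def charges_excluding(exclude):
        return field.charges_for(exclude) if field is not None else []

    guess_bank = (field.monomer_results if field is not None
                  and field.monomer_results is not None else None)

    # stage 1: embedded monomers (and isolated references)
    def solve_monomer(i):
        res = backend.solve(
            cluster, (i,), charges=charges_excluding((i,)),
            guess_density=guess_bank[i].density if guess_bank else None)
        return _record((i,), backend, res)

    def solve_isolated(i):
        if field is not None and field.isolated_results is not None:
            return _record(("iso", i), backend, field.isolated_results[i])
        return _record(("iso", i), backend, backend.solve(cluster, (i,)))

    mono_records = {r.key[0]: r for r in map_fn(solve_monomer, range(n))}
    iso_records = {r.key[1]: r for r in map_fn(solve_isolated, range(n))}

    # stage 2: dimers (superposed-monomer guesses) and counterpoise terms
    centers = [nuclear_charge_center(m) for m in cluster.monomers]
    pairs = [(i, j) for i, j in itertools.combinations(range(n), 2)
             if np.linalg.norm(centers[i] - centers[j]) <= dimer_cutoff]

    def solve_dimer(pair):
        i, j = pair
        charges = charges_excluding(pair)
        guess = None
        ri, rj = mono_records[i], mono_records[j]
        if ri.density is not None and rj.density is not None:
            nd = ri.n_ao + rj.n_ao
            guess = dimer_superposition_guess(
                [_as_guess(ri), _as_guess(rj)],
                [slice(0, ri.n_ao), slice(ri.n_ao, nd)], nd)
        res = backend.solve(cluster, pair, charges=charges,
                            guess_density=guess)
        return _record(pair, backend, res)

    def solve_cp(term):
        active, pair = term
        res = backend.solve(cluster, pair, charges=charges_excluding(pair),
                            ghost_active=active)
        return _record((active, pair), backend, res, keep_density=False)

    dimer_records = {r.key: r for r in map_fn(solve_dimer, pairs)}
    cp_records = {}
    if counterpoise:
        terms = [(i, pair) for pair in pairs for i in pair]
        cp_records = {r.key: r for r in map_fn(solve_cp, terms)}

    all_records = {("mono", k): v for k, v in mono_records.items()}
    all_records.update({("iso", k): v for k, v in iso_records.items()})
    all_records.update({("dimer", *k): v for k, v in dimer_records.items()})
    all_records.update({("cp", *k): v for k, v in cp_records.items()})
    _check_all_converged(all_records)

    return MBEResult(
        n_monomers=n, method=backend.method, B=backend.B.copy(),
        monomer_energies={i: r.energy for i, r in mono_records.items()},
        dimer_energies={k: r.energy for k, r in dimer_records.items()},
        isolated_energies={i: r.energy for i, r in iso_records.items()},
        records=all_records, counterpoise=counterpoise,
        cp_monomer_energies={k: r.energy for k, r in cp_records.items()})


class _GuessShim:
    """Minimal view of a record for the superposition-guess helper."""

    def __init__(self, record: SubsystemRecord):
        self.density = record.density
        self.spin_model = "rhf"  # spatial densities are promoted as needed
        self.n_ao = record.n_ao


def _as_guess(record: SubsystemRecord) -> _GuessShim:
    return _GuessShim(record)


def mbe_full_order(cluster: Cluster, backend: Backend, order: int,
                   map_fn=map) -> float:
    """Untruncated (unembedded) many-body expansion through ``order``:
    inclusion-exclusion over all subsets of up to ``order`` monomers.  At
    ``order == len(cluster)`` this equals the conventional supersystem
    energy to SCF tolerance — the exactness oracle of the expansion."""
    n = len(cluster)
    if not 1 <= order <= n:
        raise ValueError(f"order must be in [1, {n}], got {order}")
    subsets = [tuple(c) for k in range(1, order + 1)
               for c in itertools.combinations(range(n), k)]

    def solve(sub):
        res = backend.solve(cluster, sub).require_converged()
        return sub, backend.total_energy(res)

    energies = dict(map_fn(solve, subsets))
    eps: dict[tuple, float] = {}
    for sub in sorted(subsets, key=len):
        inner = math.fsum(
            eps[t] for k in range(1, len(sub))
            for t in itertools.combinations(sub, k))
        eps[sub] = energies[sub] - inner
    return math.fsum(eps[s] for s in sorted(eps))


# ---------------------------------------------------------------------------
# Density assembly
# ---------------------------------------------------------------------------

@dataclass
class DensityAssembly:
    """Cluster AO density matrix assembled from subsystem densities."""

    basis: BasisSet
    D: np.ndarray
    n_electrons: int
    B: np.ndarray
    gauge_origin: np.ndarray

    def trace_overlap(self) -> float:
        from .integrals import one_electron_integrals
        S = one_electron_integrals(self.basis, [], np.zeros(3)).S
        return float(np.einsum("ij,ji->", self.D, S).real)


def _monomer_ao_slices(cluster: Cluster, backend: Backend) -> list[slice]:
    sizes = [build_subsystem_basis(cluster, (i,), backend.basis).n_ao
             for i in range(len(cluster))]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    return [slice(int(offs[i]), int(offs[i + 1])) for i in range(len(sizes))]


def assemble_density(cluster: Cluster, backend: Backend,
                     result: MBEResult,
                     use_dimers: bool = True,
                     isolated: bool = False) -> DensityAssembly:
    """Embed the subsystem density matrices into cluster AO indexing with
    inclusion-exclusion weights:

        D = sum_i D^i + sum_{i<j} (D^ij - D^i (+) D^j)

    Every pair term is traceless, so trace(D S) equals the electron count
    exactly.  With ``use_dimers=False`` the plain monomer superposition is
    returned (``isolated=True`` uses the isolated- rather than the
    embedded-monomer densities), which is the reference for difference
    densities."""
    basis = build_subsystem_basis(cluster, range(len(cluster)), backend.basis)
    slices = _monomer_ao_slices(cluster, backend)
    nao = basis.n_ao
    D = np.zeros((nao, nao), dtype=complex)
    mono_key = "iso" if isolated else "mono"
    mono = {i: result.records[(mono_key, i)] for i in range(len(cluster))}
    for i, rec in mono.items():
        if rec.density is None:
            raise ValueError("subsystem records carry no densities")
        D[slices[i], slices[i]] += rec.density
    if use_dimers:
        for key, rec in result.records.items():
            if key[0] != "dimer":
                continue
            i, j = key[1], key[2]
            idx = np.r_[slices[i], slices[j]]
            D[np.ix_(idx, idx)] += rec.density
            D[slices[i], slices[i]] -= mono[i].density
            D[slices[j], slices[j]] -= mono[j].density
    if not np.any(np.asarray(backend.B) != 0.0):
        D = D.real
    return DensityAssembly(basis=basis, D=D, n_electrons=cluster.n_electrons,
                           B=np.asarray(backend.B, dtype=float),
                           gauge_origin=np.asarray(backend.gauge_origin,
                                                   dtype=float))


@dataclass(frozen=True)
class RegularGrid:
    """Axis-aligned regular grid: origin (bohr), per-axis point counts and
    spacings."""

    origin: np.ndarray
    shape: tuple[int, int, int]
    spacing: np.ndarray  # (3,) bohr

    @classmethod
    def covering(cls, cluster: Cluster, spacing: float = 0.4,
                 margin: float = 4.0) -> "RegularGrid":
        pos = np.concatenate([m.positions for m in cluster.monomers])
        lo = pos.min(axis=0) - margin
        hi = pos.max(axis=0) + margin
        shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1
                      for d in range(3))
        return cls(origin=lo, shape=shape,
                   spacing=np.full(3, float(spacing)))

    def points(self) -> np.ndarray:
        axes = [self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
                for d in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def density_on_grid(assembly: DensityAssembly, grid: RegularGrid,
                    chunk: int = 20000) -> np.ndarray:
    """Real-space density rho(r) = Re sum_{mu nu} D_{mu nu} w_mu(r) w_nu*(r)
    on the grid (London phase factors included at finite field)."""
    pts = grid.points()
    out = np.empty(len(pts))
    B = assembly.B
    use_phase = bool(np.any(B != 0.0))
    centers = assembly.basis.ao_centers()
    Avec = 0.5 * np.cross(np.broadcast_to(B, centers.shape),
                          centers - assembly.gauge_origin)
    for start in range(0, len(pts), chunk):
        p = pts[start:start + chunk]
        ao = assembly.basis.eval_ao(p)
        if use_phase:
            phase = np.exp(-1j * ((p @ Avec.T)
                                  - np.sum(Avec * centers, axis=1)[None, :]))
            w = ao * phase
            out[start:start + chunk] = np.einsum(
                "pm,mn,pn->p", w, assembly.D, w.conj(), optimize=True).real
        else:
            out[start:start + chunk] = np.einsum(
                "pm,mn,pn->p", ao, assembly.D.real, ao, optimize=True)
    return out.reshape(grid.shape)


def write_cube(path, grid: RegularGrid, values: np.ndarray,
               cluster: Cluster, comment: str = "efmag density") -> None:
    """Gaussian cube file (bohr units, axis-aligned grid)."""
    atoms = cluster.atoms
    with open(path, "w") as fh:
        fh.write(f"{comment}\n generated by efmag\n")
        fh.write(f"{len(atoms):5d} {grid.origin[0]:12.6f} "
                 f"{grid.origin[1]:12.6f} {grid.origin[2]:12.6f}\n")
        for d in range(3):
            step = np.zeros(3)
            step[d] = grid.spacing[d]
            fh.write(f"{grid.shape[d]:5d} {step[0]:12.6f} {step[1]:12.6f} "
                     f"{step[2]:12.6f}\n")
        for a in atoms:
            fh.write(f"{a.Z:5d} {float(a.Z):12.6f} {a.position[0]:12.6f} "
                     f"{a.position[1]:12.6f} {a.position[2]:12.6f}\n")
        flat = values.reshape(grid.shape)
        for ix in range(grid.shape[0]):
            for iy in range(grid.shape[1]):
                row = flat[ix, iy]
                for start in range(0, len(row), 6):
                    fh.write("".join(f"{v:13.5E}"
                                     for v in row[start:start + 6]) + "\n")
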