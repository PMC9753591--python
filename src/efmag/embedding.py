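"""Self-consistent dipole embedding field.

Each monomer's charge distribution is reduced to its electrostatic dipole,
represented by a pair of point charges (+e_j, -e_j) a fixed small distance
``d`` apart, centered at the monomer's nuclear-charge center (where the
nuclear dipole vanishes) and aligned with the monomer dipole so that
``e_j d = |mu_j|``.  The dipoles are iterated to a fixed point: every
monomer is solved in the point-charge field of all the others, fresh
dipoles are extracted, and the site strengths are updated (with
under-relaxation) until the largest change in any ``e_j`` falls below
threshold.  Optionally the potential of every site charge is attenuated at
short range by erf(mu r), which tames the unphysical near-field of a bare
point dipole without affecting its long-range form.

The full-Coulomb (FMO-style) embedding operator is also provided, as a
validation reference that bounds the dipole approximation error; it is not
a production path.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .backend import Backend
from .basis import BasisSet
from .cluster import Cluster, Monomer, nuclear_charge_center
from .integrals import PointCharge, eri_blocks, one_electron_integrals
from .scf import SCFResult

#: Dipole length (bohr): small against intermonomer distances, so the pair
#: potential equals the point-dipole potential to O((d/r)^2).
DEFAULT_DIPOLE_LENGTH = 0.01
#: Convergence threshold on max_j |delta e_j| (a.u.).
DEFAULT_THRESHOLD = 1e-4


class EmbeddingConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class EmbeddingSettings:
    d: float = DEFAULT_DIPOLE_LENGTH
    threshold: float = DEFAULT_THRESHOLD
    mu: float | None = None        # erf attenuation; None = unattenuated
    damping: float = 0.5           # mixing weight of the fresh dipole
    max_iterations: int = 60

    def __post_init__(self):
        if not (0.0 < self.damping <= 1.0):
            raise ValueError("damping must be in (0, 1]")
        if self.d <= 0:
            raise ValueError("dipole length d must be positive")


@dataclass
class DipoleSite:
    """Point-charge-pair representation of one monomer's dipole."""

    monomer: int
    center: np.ndarray          # nuclear-charge center (bohr)
    dipole: np.ndarray          # current dipole vector (a.u.)
    d: float

    @property
    def e(self) -> float:
        """Charge magnitude satisfying e * d = |mu|."""
        return float(np.linalg.norm(self.dipole) / self.d)

    @property
    def direction(self) -> np.ndarray:
        m = np.linalg.norm(self.dipole)
        if m == 0.0:
            return np.zeros(3)
        return self.dipole / m


def site_point_charges(site: DipoleSite,
                       attenuation: float | None = None) -> list[PointCharge]:
    """The +/- charge pair of a site, each tagged with the attenuation.

    The positive charge sits on the side the dipole points toward, so the
    pair's dipole moment equals the site's dipole vector.  A zero dipole
    yields a legal zero-charge pair (a no-op)."""
    e = site.e
    u = site.direction
    half = 0.5 * site.d * u
    return [
        PointCharge(+e, site.center + half, mu=attenuation),
        PointCharge(-e, site.center - half, mu=attenuation),
    ]


@dataclass
class EmbeddingField:
    """Converged (or in-progress) set of dipole sites, one per monomer."""

    sites: list[DipoleSite]
    mu: float | None
    history: list[float] = dataclass_field(default_factory=list)
    converged: bool = False
    monomer_results: list[SCFResult] | None = None
    isolated_results: list[SCFResult] | None = None

    def charges_for(self, exclude) -> list[PointCharge]:
        excluded = set(exclude)
        out: list[PointCharge] = []
        for s in self.sites:
            if s.monomer not in excluded:
                out.extend(site_point_charges(s, self.mu))
        return out


def field_for_subsystem(field: EmbeddingField, subsystem) -> list[PointCharge]:
    """Point charges of every site whose monomer is outside ``subsystem``
    (for counterpoise terms the excluded set is the caller's subsystem b,
    which may differ from the subsystem being solved)."""
    return field.charges_for(tuple(subsystem))


def monomer_dipole(result: SCFResult, basis: BasisSet, monomer: Monomer,
                   origin) -> np.ndarray:
    """Electric dipole (a.u.) of a converged monomer SCF about ``origin``:
    nuclear dipole minus the electronic expectation value.  Real even for
    complex (finite-field) densities."""
    result.require_converged()
    origin = np.asarray(origin, dtype=float)
    D = result.spatial_density()
    # operators carry <r - o0> about the nuclear-charge center o0
    Z = monomer.charges
    R = monomer.positions
    o0 = Z @ R / Z.sum()
    elec = np.array([np.einsum("ij,ji->", D, result.operators.dipole[d]).real
                     for d in range(3)])
    nuc = Z @ (R - o0[None, :])
    mu = nuc - elec
    # translating the reference shifts the dipole by -(net charge) * shift
    net = Z.sum() - result.n_electrons
    return mu - net * (o0 - origin)


def converge_embedding(cluster: Cluster, backend: Backend,
                       settings: EmbeddingSettings = EmbeddingSettings(),
                       map_fn=map) -> EmbeddingField:
    """Iterate the dipole embedding field to self-consistency.

    Iteration 0 solves every monomer in isolation (at the backend's field
    strength); each subsequent outer iteration solves every monomer in the
    charge field of all other sites (Jacobi update, so the inner solves are
    independent) and mixes the fresh dipoles into the sites.  Convergence
    is measured on max_j |delta e_j|.
    """
    n = len(cluster)
    centers = [nuclear_charge_center(m) for m in cluster.monomers]

    iso_results = list(map_fn(
        lambda i: backend.solve(cluster, (i,)).require_converged(), range(n)))
    dipoles = [monomer_dipole(iso_results[i],
                              None, cluster.monomers[i], centers[i])
               for i in range(n)]
    field = EmbeddingField(
        sites=[DipoleSite(i, centers[i], dipoles[i], settings.d)
               for i in range(n)],
        mu=settings.mu, isolated_results=iso_results)
    results = list(iso_results)

    if n == 1:
        field.converged = True
        field.history.append(0.0)
        field.monomer_results = results
        return field

    for _ in range(settings.max_iterations):
        e_old = np.array([s.e for s in field.sites])

        def solve_one(i):
            charges = field.charges_for((i,))
            return backend.solve(cluster, (i,), charges=charges,
                                 guess_density=results[i].density
                                 ).require_converged()

        results = list(map_fn(solve_one, range(n)))
        fresh = [monomer_dipole(results[i], None, cluster.monomers[i],
                                centers[i]) for i in range(n)]
        lam = settings.damping
        for i, s in enumerate(field.sites):
            s.dipole = lam * fresh[i] + (1.0 - lam) * s.dipole
        delta = float(np.max(np.abs(
            np.array([s.e for s in field.sites]) - e_old)))
        field.history.append(delta)
        if delta < settings.threshold:
            field.converged = True
            field.monomer_results = results
            return field

    raise EmbeddingConvergenceError(
        f"dipole field not converged after {settings.max_iterations} outer "
        f"iterations (last max|delta e| = {field.history[-1]:.3e}); "
        "consider stronger damping or short-range attenuation (mu)")


def coulomb_embedding_reference(external: list[tuple[SCFResult, BasisSet]],
                                target_basis: BasisSet) -> np.ndarray:
    """Exact Coulomb embedding operator of the external monomers on the
    target subsystem's AO basis (FMO-style; Eq-level validation reference).

    For each external monomer the operator is the nuclear point-charge
    attraction plus the Coulomb contraction of its electron density with
    the cross two-electron integrals.  Returns the one-electron matrix to
    be added to the target core Hamiltonian (electron charge included).
    """
    n = target_basis.n_ao
    out = np.zeros((n, n))
    for result, ext_basis in external:
        charges = [PointCharge(z, r) for z, r in ext_basis.nuclear_charges()]
        if charges:
            ops = one_electron_integrals(target_basis, charges,
                                         np.zeros(3))
            ops0 = one_electron_integrals(target_basis, [], np.zeros(3))
            out += (ops.V - ops0.V).real  # -sum_J Z_J <mu|1/r_J|nu>
        D = result.spatial_density().real
        cross = eri_blocks(target_basis, ext_basis)
        out += np.einsum("mnls,sl->mn", cross, D, optimize=True)
    return out
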