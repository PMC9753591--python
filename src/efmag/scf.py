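"""Self-consistent field solutions and MP2 correlation.

Two SCF paths share one driver: a real restricted Hartree-Fock fast path at
zero field, and a complex general Hartree-Fock (GHF) path for finite
magnetic fields with either common-gauge-origin (CGO) or London-orbital
(LAO) integrals.  The spin Zeeman term B.S enters the GHF core Hamiltonian
as (1/2) sigma.B in the spin blocks; orbital field terms come from the
integral layer.  Embedding point charges polarize the subsystem (they act
on its electrons and nuclei) but never interact with each other.

Convergence is deliberately tight by default (1e-9 hartree, 1e-7 RMS
density): a many-body expansion sums and differences many subsystem
energies, so per-subsystem noise accumulates directly in the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .basis import BasisSet, build_basis
from .cluster import Cluster, Subsystem
from .integrals import (
    FieldOperatorSet,
    PointCharge,
    cgo_operator_set,
    eri_tensor,
    lao_eri_tensor,
    lao_operator_set,
    nuclear_point_charge_energy,
    one_electron_integrals,
)


class SCFConvergenceError(RuntimeError):
    pass


class LinearDependenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SCFSettings:
    max_iterations: int = 200
    energy_tol: float = 1e-9
    density_tol: float = 1e-7
    diis_size: int = 8
    level_shift: float = 0.0
    spin_model: str = "rhf"           # rhf | ghf
    field_treatment: str = "none"     # none | cgo | lao
    guess: str = "core"               # core | superposition
    s_min_eig: float = 1e-10

    def __post_init__(self):
        if self.energy_tol <= 0 or self.density_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.spin_model not in ("rhf", "ghf"):
            raise ValueError(f"unknown spin model {self.spin_model!r}")
        if self.field_treatment not in ("none", "cgo", "lao"):
            raise ValueError(f"unknown field treatment {self.field_treatment!r}")


@dataclass
class SCFResult:
    """Converged (or flagged) SCF state of one subsystem.

    ``density`` is the AO density matrix in the working representation:
    spatial (trace(D S) = N) for RHF, spinor (2n x 2n) for GHF.  The
    spatial density (summed over spin) is always available via
    :meth:`spatial_density`.
    """

    energy: float
    energy_electronic: float
    e_nuclear: float
    e_nuc_charges: float
    mo_coeff: np.ndarray
    mo_energy: np.ndarray
    density: np.ndarray
    n_electrons: int
    n_iterations: int
    converged: bool
    spin_model: str
    field_treatment: str
    B: np.ndarray
    s_z: float
    operators: FieldOperatorSet
    eri: np.ndarray | None = None
    history: list | None = None  # electronic energy per iteration

    @property
    def n_ao(self) -> int:
        return self.operators.S.shape[0]

    def spatial_density(self) -> np.ndarray:
        if self.spin_model == "rhf":
            return self.density
        n = self.n_ao
        return self.density[:n, :n] + self.density[n:, n:]

    def require_converged(self):
        if not self.converged:
            raise SCFConvergenceError(
                f"SCF did not converge in {self.n_iterations} iterations "
                f"({self.spin_model}/{self.field_treatment}, "
                f"{self.n_electrons} electrons)")
        return self


_PAULI = (
    np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex),
    np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex),
    np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex),
)


def _orthogonalizer(S: np.ndarray, s_min: float) -> np.ndarray:
    evals, evecs = np.linalg.eigh(S)
    if evals[0] < s_min:
        raise LinearDependenceError(
            f"overlap matrix is numerically singular (smallest eigenvalue "
            f"{evals[0]:.3e} < {s_min:.0e})")
    return evecs / np.sqrt(evals)[None, :]


class _DIIS:
    """Pulay DIIS on the (complex) Fock-density commutator, with a damped
    fallback when the extrapolation system degenerates."""

    def __init__(self, size: int):
        self.size = size
        self.focks: list[np.ndarray] = []
        self.errors: list[np.ndarray] = []

    def update(self, F, err):
        self.focks.append(F)
        self.errors.append(err)
        if len(self.focks) > self.size:
            self.focks.pop(0)
            self.errors.pop(0)
        m = len(self.focks)
        if m < 2:
            return F
        Bmat = np.empty((m + 1, m + 1), dtype=complex)
        Bmat[-1, :] = -1.0
        Bmat[:, -1] = -1.0
        Bmat[-1, -1] = 0.0
        for i in range(m):
            for j in range(m):
                Bmat[i, j] = np.vdot(self.errors[i], self.errors[j])
        rhs = np.zeros(m + 1, dtype=complex)
        rhs[-1] = -1.0
        try:
            coef = np.linalg.solve(Bmat, rhs)[:m]
        except np.linalg.LinAlgError:
            return 0.7 * F + 0.3 * self.focks[-2]
        out = sum(c * Fk for c, Fk in zip(coef, self.focks))
        return out.real if not np.iscomplexobj(F) else out


def _build_operators(basis: BasisSet, charges, B, gauge_origin,
                     settings: SCFSettings):
    """Integral sets appropriate for the requested field treatment."""
    B = np.asarray(B, dtype=float)
    nucs = basis.nuclear_charges()
    if nucs:
        Z = np.array([z for z, _ in nucs])
        R = np.array([r for _, r in nucs])
        dip_origin = Z @ R / Z.sum()
    else:
        dip_origin = np.zeros(3)
    treatment = settings.field_treatment
    if treatment == "none" or not np.any(B != 0.0):
        ops = one_electron_integrals(basis, charges, dip_origin)
        eri = eri_tensor(basis)
    elif treatment == "cgo":
        ops = cgo_operator_set(basis, charges, B, gauge_origin, dip_origin)
        eri = eri_tensor(basis).astype(complex)
    else:  # lao
        ops = lao_operator_set(basis, B, gauge_origin, charges, dip_origin)
        eri = lao_eri_tensor(basis, B, gauge_origin)
    return ops, eri


def _spinor_core(ops: FieldOperatorSet, B: np.ndarray) -> np.ndarray:
    """GHF core Hamiltonian: orbital part in both spin blocks plus the spin
    Zeeman term (1/2) sigma.B (x) S."""
    h = ops.hcore
    S = ops.S
    n = h.shape[0]
    h2 = np.zeros((2 * n, 2 * n), dtype=complex)
    h2[:n, :n] = h
    h2[n:, n:] = h
    for a in range(3):
        if B[a] != 0.0:
            sig = _PAULI[a]
            for si in range(2):
                for sj in range(2):
                    if sig[si, sj] != 0.0:
                        h2[si * n:(si + 1) * n, sj * n:(sj + 1) * n] += \
                            0.5 * B[a] * sig[si, sj] * S
    return h2


def _fock_rhf(h, eri, D):
    J = np.einsum("ijkl,lk->ij", eri, D, optimize=True)
    K = np.einsum("ijkl,jk->il", eri, D, optimize=True)
    return h + J - 0.5 * K


def _fock_ghf(h2, eri, D2):
    n = h2.shape[0] // 2
    Dt = D2[:n, :n] + D2[n:, n:]
    J = np.einsum("ijkl,lk->ij", eri, Dt, optimize=True)
    F = h2.copy()
    F[:n, :n] += J
    F[n:, n:] += J
    for si in range(2):
        for sj in range(2):
            Dblk = D2[si * n:(si + 1) * n, sj * n:(sj + 1) * n]
            K = np.einsum("ijkl,jk->il", eri, Dblk, optimize=True)
            F[si * n:(si + 1) * n, sj * n:(sj + 1) * n] -= K
    return F


def scf_solve(basis: BasisSet, n_electrons: int,
              charges: list[PointCharge] = (),
              B=(0.0, 0.0, 0.0), gauge_origin=(0.0, 0.0, 0.0),
              settings: SCFSettings = SCFSettings(),
              guess_density: np.ndarray | None = None,
              _precomputed=None) -> SCFResult:
    """Solve the (embedded) SCF problem for one subsystem.

    ``charges`` is the external embedding field; it excludes the
    subsystem's own monomers (caller contract) and its internal
    interactions are excluded from the energy by construction.
    """
    B = np.asarray(B, dtype=float)
    settings_in = settings
    if settings.spin_model == "rhf":
        if np.any(B != 0.0):
            raise ValueError("RHF path requires B = 0; use spin_model='ghf'")
        if n_electrons % 2:
            raise ValueError("RHF requires an even electron count")
    if settings.field_treatment == "none" and np.any(B != 0.0):
        raise ValueError("field_treatment='none' requires B = 0")

    if _precomputed is not None:
        ops, eri = _precomputed
    else:
        ops, eri = _build_operators(basis, charges, B, gauge_origin, settings)
    e_nuc = basis.nuclear_repulsion()
    e_ext = nuclear_point_charge_energy(basis, charges)

    ghf = settings.spin_model == "ghf"
    if ghf:
        h = _spinor_core(ops, B)
        n = basis.n_ao
        S = np.zeros((2 * n, 2 * n), dtype=complex)
        S[:n, :n] = ops.S
        S[n:, n:] = ops.S
        nocc = n_electrons
        occ_factor = 1.0
    else:
        h = ops.hcore
        S = ops.S
        nocc = n_electrons // 2
        occ_factor = 2.0

    X = _orthogonalizer(S, settings.s_min_eig)

    def density_from(C):
        Cocc = C[:, :nocc]
        return occ_factor * (Cocc @ Cocc.conj().T)

    def fock(D):
        return _fock_ghf(h, eri, D) if ghf else _fock_rhf(h, eri, D)

    def diag(F):
        Fo = X.conj().T @ F @ X
        Fo = 0.5 * (Fo + Fo.conj().T)
        eps, Co = np.linalg.eigh(Fo)
        return eps, X @ Co

    # initial guess
    if guess_density is not None:
        D = _promote_guess(guess_density, basis.n_ao, ghf)
    else:
        _, C = diag(h)
        D = density_from(C)

    diis = _DIIS(settings.diis_size)
    energy = None
    mo_e, C = None, None
    converged = False
    it = 0
    history: list[float] = []
    for it in range(1, settings.max_iterations + 1):
        F = fock(D)
        e_elec = 0.5 * np.einsum("ij,ji->", D, h + F).real
        history.append(float(e_elec))
        err = F @ D @ S - S @ D @ F
        err = X.conj().T @ err @ X
        F_use = diis.update(F, err)
        if settings.level_shift > 0.0:
            # raise the virtual manifold: S - S (D/f) S projects onto it
            F_use = F_use + settings.level_shift * (
                S - S @ (D / occ_factor) @ S)
        mo_e, C = diag(F_use)
        D_new = density_from(C)
        d_rms = np.sqrt(np.mean(np.abs(D_new - D) ** 2))
        dE = np.inf if energy is None else abs(e_elec - energy)
        energy = e_elec
        D = D_new
        if dE < settings.energy_tol and d_rms < settings.density_tol:
            converged = True
            break

    # final consistent energy with the converged density
    F = fock(D)
    e_elec = 0.5 * np.einsum("ij,ji->", D, h + F).real
    total = e_elec + e_nuc + e_ext

    if ghf:
        n = basis.n_ao
        sz = 0.5 * (np.einsum("ij,ji->", D[:n, :n], ops.S)
                    - np.einsum("ij,ji->", D[n:, n:], ops.S)).real
    else:
        sz = 0.0

    return SCFResult(
        energy=total, energy_electronic=e_elec, e_nuclear=e_nuc,
        e_nuc_charges=e_ext, mo_coeff=C, mo_energy=mo_e, density=D,
        n_electrons=n_electrons, n_iterations=it, converged=converged,
        spin_model=settings_in.spin_model,
        field_treatment=settings_in.field_treatment, B=B, s_z=sz,
        operators=ops, eri=eri, history=history)


def _promote_guess(D, n_ao, ghf: bool) -> np.ndarray:
    """Accept a spatial or spinor guess density in either representation."""
    D = np.asarray(D)
    if ghf:
        if D.shape[0] == 2 * n_ao:
            return D.astype(complex)
        D2 = np.zeros((2 * n_ao, 2 * n_ao), dtype=complex)
        D2[:n_ao, :n_ao] = D / 2.0
        D2[n_ao:, n_ao:] = D / 2.0
        return D2
    if D.shape[0] == 2 * n_ao:
        n = n_ao
        return (D[:n, :n] + D[n:, n:]).real
    return D.real if np.iscomplexobj(D) else D


# ---------------------------------------------------------------------------
# Guesses and ghost bases
# ---------------------------------------------------------------------------

def dimer_superposition_guess(monomer_results, ao_slices,
                              n_ao_dimer: int) -> np.ndarray:
    """Block-diagonal embedding of monomer densities into dimer AO indexing.

    ``ao_slices`` gives, per monomer result, the slice of dimer AO indices
    owned by that monomer's basis functions.  The result is in the same
    representation (spatial or spinor) as the inputs.
    """
    if len(monomer_results) != len(ao_slices):
        raise IndexError("one AO slice required per monomer result")
    ghf = monomer_results[0].spin_model == "ghf"
    for r in monomer_results:
        if (r.spin_model == "ghf") != ghf:
            raise IndexError("mixed spin models in superposition guess")
    if ghf:
        D = np.zeros((2 * n_ao_dimer, 2 * n_ao_dimer), dtype=complex)
        for res, sl in zip(monomer_results, ao_slices):
            n = res.n_ao
            for si in range(2):
                for sj in range(2):
                    rows = slice(sl.start + si * n_ao_dimer,
                                 sl.stop + si * n_ao_dimer)
                    cols = slice(sl.start + sj * n_ao_dimer,
                                 sl.stop + sj * n_ao_dimer)
                    D[rows, cols] = res.density[si * n:(si + 1) * n,
                                                sj * n:(sj + 1) * n]
        return D
    dtype = np.result_type(*(r.density.dtype for r in monomer_results))
    D = np.zeros((n_ao_dimer, n_ao_dimer), dtype=dtype)
    for res, sl in zip(monomer_results, ao_slices):
        D[sl, sl] = res.density
    return D


def extract_monomer_blocks(D, ao_slices):
    """Inverse of :func:`dimer_superposition_guess` for spatial densities."""
    return [D[sl, sl].copy() for sl in ao_slices]


def subsystem_atoms(cluster: Cluster, indices) -> list:
    return [a for i in indices for a in cluster.monomers[i].atoms]


def build_subsystem_basis(cluster: Cluster, subsystem, library) -> BasisSet:
    """Plain basis over the atoms of the given monomer indices."""
    return build_basis(subsystem_atoms(cluster, tuple(subsystem)), library)


def build_ghost_basis(cluster: Cluster, subsystem, monomer_index: int,
                      library) -> BasisSet:
    """Counterpoise basis: functions of every atom of ``subsystem``, with
    the nuclear charges of atoms outside ``monomer_index`` suppressed."""
    indices = tuple(subsystem)
    if monomer_index not in indices:
        raise ValueError(
            f"monomer {monomer_index} is not part of subsystem {indices}")
    atoms, ghost = [], []
    for i in indices:
        for a in cluster.monomers[i].atoms:
            atoms.append(a)
            ghost.append(i != monomer_index)
    return build_basis(atoms, library, ghost=np.array(ghost))


# ---------------------------------------------------------------------------
# MP2
# ---------------------------------------------------------------------------

def mp2_energy(result: SCFResult, eri: np.ndarray | None = None,
               gap_threshold: float = 1e-8) -> float:
    """Second-order Moller-Plesset correlation energy from a converged SCF
    reference (spin-orbital formulation for GHF, closed-shell spatial
    formulation for RHF).  Real-valued and non-positive for a bound ground
    state."""
    result.require_converged()
    if eri is None:
        eri = result.eri
    C = result.mo_coeff
    eps = result.mo_energy
    if result.spin_model == "rhf":
        nocc = result.n_electrons // 2
        Co, Cv = C[:, :nocc], C[:, nocc:]
        eo, ev = eps[:nocc], eps[nocc:]
        if nocc == 0 or Cv.shape[1] == 0:
            return 0.0
        _check_gap(eo, ev, gap_threshold)
        ovov = np.einsum("mnls,mi,na,lj,sb->iajb", eri, Co, Cv, Co, Cv,
                         optimize=True)
        denom = (eo[:, None, None, None] - ev[None, :, None, None]
                 + eo[None, None, :, None] - ev[None, None, None, :])
        return float(np.einsum(
            "iajb,iajb->", ovov * (2.0 * ovov - ovov.transpose(0, 3, 2, 1)),
            1.0 / denom))

    # GHF spinor path
    n = result.n_ao
    nocc = result.n_electrons
    Ca, Cb = C[:n], C[n:]
    Co_a, Cv_a = Ca[:, :nocc], Ca[:, nocc:]
    Co_b, Cv_b = Cb[:, :nocc], Cb[:, nocc:]
    eo, ev = eps[:nocc], eps[nocc:]
    if nocc == 0 or len(ev) == 0:
        return 0.0
    _check_gap(eo, ev, gap_threshold)
    # (ia|jb) with each vertex summed over its spin component
    half = (np.einsum("mnls,mi,na->ials", eri, Co_a.conj(), Cv_a,
                      optimize=True)
            + np.einsum("mnls,mi,na->ials", eri, Co_b.conj(), Cv_b,
                        optimize=True))
    ovov = (np.einsum("ials,lj,sb->iajb", half, Co_a.conj(), Cv_a,
                      optimize=True)
            + np.einsum("ials,lj,sb->iajb", half, Co_b.conj(), Cv_b,
                        optimize=True))
    anti = ovov - ovov.transpose(0, 3, 2, 1)  # <ij||ab> in (ia|jb) layout
    denom = (eo[:, None, None, None] - ev[None, :, None, None]
             + eo[None, None, :, None] - ev[None, None, None, :])
    e2 = 0.25 * np.sum(np.abs(anti) ** 2 / denom)
    return float(e2.real)


def _check_gap(eo, ev, threshold):
    gap = ev.min() - eo.max()
    if gap < threshold:
        import warnings
        warnings.warn(
            f"occupied-virtual gap {gap:.3e} below {threshold:.0e}; "
            "the MP2 denominator is near-singular", RuntimeWarning)
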