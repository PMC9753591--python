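"""Gaussian-basis molecular integrals.

McMurchie–Davidson recurrences over contracted Cartesian Gaussians provide
the standard real integrals (overlap, kinetic, point-charge attraction with
optional erf short-range attenuation, multipole moments, two-electron
repulsion), the magnetic one-electron terms for a common gauge origin
(orbital Zeeman and diamagnetic matrices), and the complex London-orbital
(LAO) variants of everything.

A London orbital here is ``omega_mu(r) = exp(-i A_mu.(r - R_mu)) phi_mu(r)``
with ``A_mu = (1/2) B x (R_mu - O)``; a product of two LAOs is a plane-wave
modulated Gaussian pair, which the same recurrences handle after shifting
the Gaussian product center into the complex plane.  The one-electron field
Hamiltonian ``(1/2) pi^2`` is reduced against the ket orbital's own center,

    <omega_mu| (1/2) pi^2 |omega_nu> =
        <phi_mu| e^{i k.r} [ T + (1/2) B.L_(R_nu) + (1/8)(B x (r - R_nu))^2 ] |phi_nu>,

which makes every matrix element independent of the gauge origin up to the
constant per-function phases — LAO gauge invariance is exact by
construction.  Coulomb kernels with complex arguments use a series /
asymptotic split of the Boys function.

Erf attenuation of a point-charge potential (kernel ``erf(mu r)/r``) is
exact through the long-range Boys identity: with ``s = mu^2/(p + mu^2)``
the Boys values ``F_n(T)`` are replaced by ``s^(n+1/2) F_n(s T)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .basis import BasisSet, GaussianShell, cartesian_components

#: Largest AO count for dense in-core tensors; fragment subsystems are small
#: by construction, so this guard mainly catches accidental whole-cluster use.
DEFAULT_MAX_AO = 400


class IntegralSizeError(MemoryError):
    pass


@dataclass(frozen=True)
class PointCharge:
    """External point charge: value (a.u.), position (bohr) and optional
    erf attenuation parameter ``mu`` (``None`` means unattenuated)."""

    q: float
    position: np.ndarray
    mu: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))
        if self.mu is not None and self.mu <= 0:
            raise ValueError("attenuation parameter mu must be positive")


# ---------------------------------------------------------------------------
# Boys function (real and complex arguments)
# ---------------------------------------------------------------------------

_SERIES_MAX_TERMS = 600
#: series/continued-fraction split: the downward series loses ~e^(|T|-Re T)
#: digits to cancellation, so it is used only for moderate |T|
_CF_SPLIT = 12.0


def boys_real(nmax: int, T: np.ndarray) -> np.ndarray:
    """F_n(T) for real T >= 0; returns shape (len(T), nmax+1)."""
    T = np.asarray(T, dtype=float)
    out = np.empty((T.size, nmax + 1))
    n = np.arange(nmax + 1)[None, :]
    small = T < 1e-13
    Ts = T[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        gam = special.gamma(n + 0.5)
        out = gam * special.gammainc(n + 0.5, Ts) / (2.0 * Ts ** (n + 0.5))
    if np.any(small):
        # second-order Taylor about T = 0
        out[small] = (1.0 / (2 * n + 1) - Ts[small] / (2 * n + 3)
                      + Ts[small] ** 2 / (2 * (2 * n + 5)))
    return out


def _upper_gamma_cf(a: float, z: np.ndarray, max_iter: int = 300):
    """Upper incomplete gamma Gamma(a, z) by the modified Lentz continued
    fraction; accurate for |z| not small and Re(z) >~ 0."""
    tiny = 1e-300
    b0 = z + 1.0 - a
    C = np.where(np.abs(b0) < tiny, tiny, b0).astype(complex)
    D = np.zeros_like(C)
    f = C.copy()
    for i in range(1, max_iter):
        an = -i * (i - a)
        bn = b0 + 2.0 * i
        D = bn + an * D
        D = np.where(np.abs(D) < tiny, tiny, D)
        C = bn + an / C
        C = np.where(np.abs(C) < tiny, tiny, C)
        D = 1.0 / D
        delta = C * D
        f = f * delta
        if np.all(np.abs(delta - 1.0) < 1e-15):
            break
    else:
        raise FloatingPointError(
            "continued fraction for the incomplete gamma did not converge "
            f"(|z| up to {np.max(np.abs(z)):.3g})")
    return np.exp(-z + a * np.log(z)) / f


def boys_complex(nmax: int, T: np.ndarray) -> np.ndarray:
    """F_n(T) for complex T; returns shape (len(T), nmax+1).

    Cancellation-free series with downward recursion for moderate |T|;
    continued fraction for the incomplete gamma,
    F_n(T) = [Gamma(n+1/2) - Gamma(n+1/2, T)] / (2 T^(n+1/2)),
    for large |T| (the series loses digits when |Im T| is large).
    """
    T = np.atleast_1d(np.asarray(T, dtype=complex))
    out = np.empty((T.size, nmax + 1), dtype=complex)
    big = np.abs(T) > _CF_SPLIT

    if np.any(~big):
        z = T[~big]
        # F_nmax via the (cancellation-free) confluent series,
        # F_n(z) = e^{-z} sum_k (2z)^k (2n-1)!! / (2n+2k+1)!!
        term = np.full(z.shape, 1.0 / (2 * nmax + 1), dtype=complex)
        acc = term.copy()
        twoz = 2.0 * z
        for k in range(1, _SERIES_MAX_TERMS):
            term = term * twoz / (2 * nmax + 2 * k + 1)
            acc += term
            if np.all(np.abs(term) <= 1e-17 * np.maximum(np.abs(acc), 1e-300)):
                break
        else:
            raise FloatingPointError(
                f"complex Boys series failed to converge for argument(s) "
                f"with |T| up to {np.max(np.abs(z)):.3g}"
            )
        ez = np.exp(-z)
        F = np.empty((z.size, nmax + 1), dtype=complex)
        F[:, nmax] = ez * acc
        for n in range(nmax, 0, -1):
            F[:, n - 1] = (twoz * F[:, n] + ez) / (2 * n - 1)
        out[~big] = F

    if np.any(big):
        z = T[big]
        a = nmax + 0.5
        gamma_upper = _upper_gamma_cf(a, z)
        Fn = (special.gamma(a) - gamma_upper) / (2.0 * z ** a)
        F = np.empty((z.size, nmax + 1), dtype=complex)
        F[:, nmax] = Fn
        ez = np.exp(-z)
        for n in range(nmax, 0, -1):
            F[:, n - 1] = (2.0 * z * F[:, n] + ez) / (2 * n - 1)
        out[big] = F
    return out


def boys(nmax: int, T: np.ndarray) -> np.ndarray:
    T = np.atleast_1d(T)
    if np.iscomplexobj(T):
        return boys_complex(nmax, T)
    return boys_real(nmax, T)


# ---------------------------------------------------------------------------
# Hermite expansion coefficients
# ---------------------------------------------------------------------------

def _e1d(la: int, lb: int, PA, PB, oo2p) -> np.ndarray:
    """1-D Hermite expansion coefficients E[npp, la+1, lb+1, la+lb+1].

    ``PA = Ptilde - A`` etc. may be complex (plane-wave shifted product
    centers); ``oo2p = 1/(2p)``.
    """
    npp = len(oo2p)
    dtype = np.result_type(PA, PB, float)
    E = np.zeros((npp, la + 1, lb + 1, la + lb + 2), dtype=dtype)
    E[:, 0, 0, 0] = 1.0
    for i in range(la):
        for t in range(i + 2):
            E[:, i + 1, 0, t] = (
                (oo2p * E[:, i, 0, t - 1] if t > 0 else 0.0)
                + PA * E[:, i, 0, t]
                + (t + 1) * E[:, i, 0, t + 1]
            )
    for j in range(lb):
        for i in range(la + 1):
            for t in range(i + j + 2):
                E[:, i, j + 1, t] = (
                    (oo2p * E[:, i, j, t - 1] if t > 0 else 0.0)
                    + PB * E[:, i, j, t]
                    + (t + 1) * E[:, i, j, t + 1]
                )
    return E[:, :, :, : la + lb + 1]


class _ShellPair:
    """Primitive-pair tables for a bra/ket shell pair, optionally modulated
    by a plane wave exp(i k.r) (the LAO pair phase) and with ``ket_extra``
    additional ket angular-momentum room for operator assembly."""

    def __init__(self, shA: GaussianShell, shB: GaussianShell,
                 k: np.ndarray | None = None, ket_extra: int = 0):
        self.shA, self.shB = shA, shB
        a = shA.exponents
        b = shB.exponents
        av = np.repeat(a, len(b))
        bv = np.tile(b, len(a))
        cc = np.outer(shA.coefficients, shB.coefficients).ravel()
        self.a, self.b = av, bv
        p = av + bv
        self.p = p
        self.oo2p = 0.5 / p
        A, B = shA.center, shB.center
        AB = A - B
        U0 = cc * np.exp(-(av * bv / p) * (AB @ AB))
        P = (av[:, None] * A[None, :] + bv[:, None] * B[None, :]) / p[:, None]
        if k is not None and np.any(k != 0.0):
            Pt = P + 1j * k[None, :] / (2.0 * p[:, None])
            U0 = U0 * np.exp(1j * (P @ k) - (k @ k) / (4.0 * p))
        else:
            Pt = P
        self.U0 = U0
        self.Ptilde = Pt
        self.E = [
            _e1d(shA.l, shB.l + ket_extra,
                 Pt[:, d] - A[d], Pt[:, d] - B[d], self.oo2p)
            for d in range(3)
        ]
        self.w_overlap = U0 * (np.pi / p) ** 1.5
        self.w_coulomb = U0 * (2.0 * np.pi / p)

    # 1-D primitives; all return arrays over the primitive-pair axis
    def S1(self, d: int, i: int, j: int):
        if i < 0 or j < 0 or j >= self.E[d].shape[2]:
            return 0.0
        return self.E[d][:, i, j, 0]

    def D1(self, d: int, i: int, j: int):
        """d/dx_d acting on the ket Gaussian."""
        out = -2.0 * self.b * self.S1(d, i, j + 1)
        if j > 0:
            out = out + j * self.S1(d, i, j - 1)
        return out

    def T1(self, d: int, i: int, j: int):
        """-(1/2) d^2/dx_d^2 acting on the ket Gaussian."""
        out = (self.b * (2 * j + 1) * self.S1(d, i, j)
               - 2.0 * self.b ** 2 * self.S1(d, i, j + 2))
        if j > 1:
            out = out - 0.5 * j * (j - 1) * self.S1(d, i, j - 2)
        return out

    def M1(self, d: int, i: int, j: int, shift: float):
        """(x_d - c) with c = ket center - shift along dimension d."""
        return self.S1(d, i, j + 1) + shift * self.S1(d, i, j)

    def M2(self, d: int, i: int, j: int, shift: float):
        return (self.S1(d, i, j + 2) + 2.0 * shift * self.S1(d, i, j + 1)
                + shift ** 2 * self.S1(d, i, j))

    def components(self):
        return (cartesian_components(self.shA.l),
                cartesian_components(self.shB.l))

    def hermite_product(self) -> np.ndarray:
        """W[ci, cj, t, u, v, npp]: products of 1-D E coefficients (cached)."""
        cached = getattr(self, "_W", None)
        if cached is not None:
            return cached
        ca, cb = self.components()
        la, lb = self.shA.l, self.shB.l
        nt = la + lb + 1
        npp = len(self.p)
        dtype = self.E[0].dtype
        W = np.zeros((len(ca), len(cb), nt, nt, nt, npp), dtype=dtype)
        for ia, (ix, iy, iz) in enumerate(ca):
            for jb, (jx, jy, jz) in enumerate(cb):
                Ex = self.E[0][:, ix, jx, : ix + jx + 1]
                Ey = self.E[1][:, iy, jy, : iy + jy + 1]
                Ez = self.E[2][:, iz, jz, : iz + jz + 1]
                W[ia, jb, : ix + jx + 1, : iy + jy + 1, : iz + jz + 1] = (
                    Ex.T[:, None, None, :] * Ey.T[None, :, None, :]
                    * Ez.T[None, None, :, :]
                )
        self._W = W
        return W


# ---------------------------------------------------------------------------
# Hermite Coulomb tensor
# ---------------------------------------------------------------------------

def _hermite_R(ntot: int, X, Y, Z, Fbase) -> np.ndarray:
    """R^0_{tuv} for t+u+v <= ntot; Fbase[:, n] must be (-2 p_eff)^n F_n.

    Returns array of shape (ntot+1, ntot+1, ntot+1, nq)."""
    nq = Fbase.shape[0]
    dtype = np.result_type(Fbase, X, Y, Z)
    R = np.zeros((ntot + 1, ntot + 1, ntot + 1, ntot + 1, nq), dtype=dtype)
    for n in range(ntot + 1):
        R[n, 0, 0, 0] = Fbase[:, n]
    for n in range(ntot - 1, -1, -1):
        for total in range(1, ntot - n + 1):
            for t in range(total, -1, -1):
                for u in range(total - t, -1, -1):
                    v = total - t - u
                    if t >= 1:
                        val = X * R[n + 1, t - 1, u, v]
                        if t >= 2:
                            val = val + (t - 1) * R[n + 1, t - 2, u, v]
                    elif u >= 1:
                        val = Y * R[n + 1, t, u - 1, v]
                        if u >= 2:
                            val = val + (u - 1) * R[n + 1, t, u - 2, v]
                    else:
                        val = Z * R[n + 1, t, u, v - 1]
                        if v >= 2:
                            val = val + (v - 1) * R[n + 1, t, u, v - 2]
                    R[n, t, u, v] = val
    return R[0]


# ---------------------------------------------------------------------------
# One-electron matrices
# ---------------------------------------------------------------------------

def _pair_phase(shA, shB, B, origin):
    """LAO pair data: plane-wave vector k = A_mu - A_nu and the constant
    phase from referencing each London phase to its own shell center."""
    Avec = 0.5 * np.cross(B, shA.center - origin)
    Bvec = 0.5 * np.cross(B, shB.center - origin)
    k = Avec - Bvec
    gamma = -(Avec @ shA.center - Bvec @ shB.center)
    return k, np.exp(1j * gamma)


def _assemble(basis: BasisSet, block_fn, dtype=float, nmats: int = 1):
    """Drive per-shell-pair block functions into full AO matrices."""
    n = basis.n_ao
    mats = np.zeros((nmats, n, n), dtype=dtype)
    off = basis.shell_offsets
    for iA, shA in enumerate(basis.shells):
        for iB, shB in enumerate(basis.shells):
            blocks = block_fn(shA, shB)
            sl = (slice(off[iA], off[iA + 1]), slice(off[iB], off[iB + 1]))
            for m in range(nmats):
                mats[m][sl] = blocks[m]
    norm = basis.ao_norms
    mats *= norm[None, :, None] * norm[None, None, :]
    return mats


def _block_overlap(sp: _ShellPair):
    ca, cb = sp.components()
    out = np.empty((len(ca), len(cb)), dtype=sp.E[0].dtype)
    for ia, ci in enumerate(ca):
        for jb, cj in enumerate(cb):
            val = sp.S1(0, ci[0], cj[0]) * sp.S1(1, ci[1], cj[1]) \
                * sp.S1(2, ci[2], cj[2])
            out[ia, jb] = np.sum(sp.w_overlap * val)
    return out


def _block_kinetic(sp: _ShellPair):
    ca, cb = sp.components()
    out = np.empty((len(ca), len(cb)), dtype=sp.E[0].dtype)
    for ia, ci in enumerate(ca):
        for jb, cj in enumerate(cb):
            val = 0.0
            for d in range(3):
                term = sp.T1(d, ci[d], cj[d])
                for o in range(3):
                    if o != d:
                        term = term * sp.S1(o, ci[o], cj[o])
                val = val + term
            out[ia, jb] = np.sum(sp.w_overlap * val)
    return out


def _block_moment(sp: _ShellPair, center: np.ndarray):
    """First-moment blocks (3, na, nb) about ``center``."""
    ca, cb = sp.components()
    shift = sp.shB.center - center
    out = np.empty((3, len(ca), len(cb)), dtype=sp.E[0].dtype)
    for ia, ci in enumerate(ca):
        for jb, cj in enumerate(cb):
            s = [sp.S1(d, ci[d], cj[d]) for d in range(3)]
            for d in range(3):
                m = sp.M1(d, ci[d], cj[d], shift[d])
                others = [s[o] for o in range(3) if o != d]
                out[d, ia, jb] = np.sum(sp.w_overlap * m * others[0] * others[1])
    return out


_EPS_LC = [(0, 1, 2, 1.0), (0, 2, 1, -1.0), (1, 2, 0, 1.0),
           (1, 0, 2, -1.0), (2, 0, 1, 1.0), (2, 1, 0, -1.0)]


def _block_angmom(sp: _ShellPair, center: np.ndarray):
    """L = (r - center) x (-i grad) blocks, (3, na, nb), complex."""
    ca, cb = sp.components()
    shift = sp.shB.center - center
    out = np.zeros((3, len(ca), len(cb)), dtype=complex)
    for ia, ci in enumerate(ca):
        for jb, cj in enumerate(cb):
            s = [sp.S1(d, ci[d], cj[d]) for d in range(3)]
            for a, bdim, cdim, sign in _EPS_LC:
                m = sp.M1(bdim, ci[bdim], cj[bdim], shift[bdim])
                dv = sp.D1(cdim, ci[cdim], cj[cdim])
                rem = [d for d in range(3) if d not in (bdim, cdim)][0]
                out[a, ia, jb] += sign * (-1j) * np.sum(
                    sp.w_overlap * m * dv * s[rem])
    return out


def _block_diamagnetic(sp: _ShellPair, B: np.ndarray, center: np.ndarray):
    """(1/8) (B x (r - center))^2 block."""
    ca, cb = sp.components()
    shift = sp.shB.center - center
    M = (B @ B) * np.eye(3) - np.outer(B, B)
    out = np.zeros((len(ca), len(cb)), dtype=sp.E[0].dtype)
    for ia, ci in enumerate(ca):
        for jb, cj in enumerate(cb):
            s = [sp.S1(d, ci[d], cj[d]) for d in range(3)]
            val = 0.0
            for da in range(3):
                for db in range(3):
                    if M[da, db] == 0.0:
                        continue
                    if da == db:
                        term = sp.M2(da, ci[da], cj[da], shift[da])
                        for o in range(3):
                            if o != da:
                                term = term * s[o]
                    else:
                        term = (sp.M1(da, ci[da], cj[da], shift[da])
                                * sp.M1(db, ci[db], cj[db], shift[db]))
                        rem = [d for d in range(3) if d not in (da, db)][0]
                        term = term * s[rem]
                    val = val + M[da, db] * term
            out[ia, jb] = 0.125 * np.sum(sp.w_overlap * val)
    return out


def _block_attraction(sp: _ShellPair, charges: list[PointCharge]):
    """sum_c q_c <a| erf(mu_c r_c)/r_c |b> block (positive kernel)."""
    ca, cb = sp.components()
    la, lb = sp.shA.l, sp.shB.l
    ntot = la + lb
    W = sp.hermite_product()  # (na, nb, t, u, v, npp)
    out = np.zeros((len(ca), len(cb)), dtype=sp.E[0].dtype)
    p = sp.p
    for ch in charges:
        if ch.q == 0.0:
            continue
        PC = sp.Ptilde - ch.position[None, :]
        r2 = np.sum(PC * PC, axis=1)
        ns = np.arange(ntot + 1)[None, :]
        if ch.mu is None:
            F = boys(ntot, p * r2)
            Fbase = F * (-2.0 * p)[:, None] ** ns
        else:
            # erf(mu r)/r kernel: scaled-argument Boys identity
            s = ch.mu ** 2 / (p + ch.mu ** 2)
            F = boys(ntot, s * p * r2)
            Fbase = F * (-2.0 * p * s)[:, None] ** ns * np.sqrt(s)[:, None]
        R = _hermite_R(ntot, PC[:, 0], PC[:, 1], PC[:, 2], Fbase)
        out = out + ch.q * np.einsum(
            "abtuvP,tuvP,P->ab", W, R, sp.w_coulomb,
            optimize=True)
    return out


@dataclass
class FieldOperatorSet:
    """One-electron operator matrices over one AO basis.

    ``V`` is the electron attraction energy operator (electron charge
    included): ``V = -sum_c q_c <mu| erf(mu_c r_c)/r_c |nu>``.  ``zeeman``
    holds (1/2) B.L (about the gauge origin for CGO, about ket shell
    centers with London modulation for LAO) and ``diamagnetic`` the
    (1/8)(B x r)^2 term; both are zero matrices at B = 0.  The core
    Hamiltonian is their sum with T and V; the spin Zeeman term lives at
    the SCF level.
    """

    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    dipole: np.ndarray
    zeeman: np.ndarray
    diamagnetic: np.ndarray
    is_complex: bool

    @property
    def hcore(self) -> np.ndarray:
        return self.T + self.V + self.zeeman + self.diamagnetic


def one_electron_integrals(basis: BasisSet, charges: list[PointCharge],
                           dipole_origin) -> FieldOperatorSet:
    """Standard real one-electron integrals: S, T, V (true nuclei of
    non-ghost atoms plus the supplied embedding charges) and dipole
    matrices about ``dipole_origin``."""
    dipole_origin = np.asarray(dipole_origin, dtype=float)
    all_charges = [PointCharge(z, pos) for z, pos in basis.nuclear_charges()]
    all_charges += list(charges)

    S = _assemble(basis, lambda a, b: [_block_overlap(_ShellPair(a, b))])[0]
    T = _assemble(basis, lambda a, b: [_block_kinetic(
        _ShellPair(a, b, ket_extra=2))])[0]
    V = -_assemble(basis, lambda a, b: [_block_attraction(
        _ShellPair(a, b), all_charges)])[0]
    dip = _assemble(basis, lambda a, b: list(_block_moment(
        _ShellPair(a, b, ket_extra=2), dipole_origin)), nmats=3)
    n = basis.n_ao
    zero = np.zeros((n, n))
    return FieldOperatorSet(S=S, T=T, V=V, dipole=dip, zeeman=zero,
                            diamagnetic=zero, is_complex=False)


def field_one_electron(basis: BasisSet, B, gauge_origin):
    """Common-gauge-origin field matrices: angular momentum L_O (3
    components, imaginary antisymmetric) and the diamagnetic matrix
    (1/8)(B x r_O)^2 (real symmetric PSD)."""
    B = np.asarray(B, dtype=float)
    O = np.asarray(gauge_origin, dtype=float)
    L = _assemble(basis, lambda a, b: list(_block_angmom(
        _ShellPair(a, b, ket_extra=2), O)), dtype=complex, nmats=3)
    dia = _assemble(basis, lambda a, b: [_block_diamagnetic(
        _ShellPair(a, b, ket_extra=2), B, O)])[0]
    return L, dia


def cgo_operator_set(basis: BasisSet, charges: list[PointCharge], B,
                     gauge_origin, dipole_origin) -> FieldOperatorSet:
    """Field operators in the common-gauge-origin treatment (unmodified
    Gaussians; gauge-origin dependent in a finite basis)."""
    B = np.asarray(B, dtype=float)
    base = one_electron_integrals(basis, charges, dipole_origin)
    L, dia = field_one_electron(basis, B, gauge_origin)
    zeeman = 0.5 * np.einsum("a,aij->ij", B, L)
    return FieldOperatorSet(
        S=base.S.astype(complex), T=base.T.astype(complex),
        V=base.V.astype(complex), dipole=base.dipole.astype(complex),
        zeeman=zeeman, diamagnetic=dia.astype(complex), is_complex=True)


def lao_operator_set(basis: BasisSet, B, gauge_origin,
                     charges: list[PointCharge],
                     dipole_origin) -> FieldOperatorSet:
    """London-orbital one-electron operators (complex).

    At B = 0 every matrix reduces to the real set.  ``T`` is the plain
    kinetic matrix in the LAO pair phase; ``zeeman`` and ``diamagnetic``
    are the ket-center-reduced field terms, so ``hcore`` is the full
    <omega_mu| (1/2) pi^2 + V |omega_nu> matrix.  Note that only the sum
    (and the multiplicative operators S, V, dipole) is Hermitian: the
    ket-side reduction distributes the field terms asymmetrically between
    T, zeeman and diamagnetic, and the asymmetries cancel in hcore.
    """
    B = np.asarray(B, dtype=float)
    O = np.asarray(gauge_origin, dtype=float)
    dipole_origin = np.asarray(dipole_origin, dtype=float)
    all_charges = [PointCharge(z, pos) for z, pos in basis.nuclear_charges()]
    all_charges += list(charges)

    def blocks(shA, shB):
        k, phase = _pair_phase(shA, shB, B, O)
        sp = _ShellPair(shA, shB, k=k, ket_extra=2)
        S = _block_overlap(sp)
        T = _block_kinetic(sp)
        V = -_block_attraction(sp, all_charges)
        dip = _block_moment(sp, dipole_origin)
        Lket = _block_angmom(sp, shB.center)
        zee = 0.5 * np.einsum("a,aij->ij", B, Lket)
        dia = _block_diamagnetic(sp, B, shB.center)
        return [phase * S, phase * T, phase * V,
                phase * dip[0], phase * dip[1], phase * dip[2],
                phase * zee, phase * dia]

    mats = _assemble(basis, blocks, dtype=complex, nmats=8)
    return FieldOperatorSet(
        S=mats[0], T=mats[1], V=mats[2], dipole=mats[3:6],
        zeeman=mats[6], diamagnetic=mats[7], is_complex=True)


# ---------------------------------------------------------------------------
# Two-electron integrals
# ---------------------------------------------------------------------------

def _eri_quartet(sp1: _ShellPair, sp2: _ShellPair) -> np.ndarray:
    """Contracted ERI block (na, nb, nc, nd) in chemists' notation
    (ab|cd) for one bra pair and one ket pair."""
    la, lb = sp1.shA.l, sp1.shB.l
    lc, ld = sp2.shA.l, sp2.shB.l
    n1, n2 = la + lb, lc + ld
    ntot = n1 + n2
    p = sp1.p
    q = sp2.p
    pq = p[:, None] * q[None, :]
    psum = p[:, None] + q[None, :]
    alpha = (pq / psum).ravel()
    PQ = (sp1.Ptilde[:, None, :] - sp2.Ptilde[None, :, :]).reshape(-1, 3)
    T = alpha * np.sum(PQ * PQ, axis=1)
    F = boys(ntot, T)
    ns = np.arange(ntot + 1)[None, :]
    Fbase = F * (-2.0 * alpha[:, None]) ** ns
    R = _hermite_R(ntot, PQ[:, 0], PQ[:, 1], PQ[:, 2], Fbase)

    W1 = sp1.hermite_product()  # (na, nb, t, u, v, npp1)
    W2 = sp2.hermite_product()  # (nc, nd, tau, nu, phi, npp2)
    na, nb = W1.shape[:2]
    nc, nd = W2.shape[:2]
    nq = len(alpha)
    dtype = np.result_type(W1, W2, R)
    # J[cd, t, u, v, nq] = sum_{tau nu phi} (-1)^(tau+nu+phi) W2 * R(t+tau,...)
    J = np.zeros((nc * nd, n1 + 1, n1 + 1, n1 + 1, nq), dtype=dtype)
    W2f = W2.reshape(nc * nd, n2 + 1, n2 + 1, n2 + 1, len(q))
    Rq = R.reshape(ntot + 1, ntot + 1, ntot + 1, len(p), len(q))
    for tau in range(n2 + 1):
        for nu in range(n2 + 1 - tau):
            for phi in range(n2 + 1 - tau - nu):
                w = W2f[:, tau, nu, phi, :]  # (ncd, npp2)
                if not np.any(w):
                    continue
                sign = -1.0 if (tau + nu + phi) % 2 else 1.0
                Rsub = Rq[tau: tau + n1 + 1, nu: nu + n1 + 1,
                          phi: phi + n1 + 1]  # (t,u,v,npp1,npp2)
                J += sign * (w[:, None, None, None, None, :]
                             * Rsub[None]).reshape(
                    nc * nd, n1 + 1, n1 + 1, n1 + 1, nq)
    pref = (2.0 * np.pi ** 2.5 / (pq * np.sqrt(psum))).ravel()
    weights = (pref * np.outer(sp1.U0, sp2.U0).ravel())
    W1f = W1.reshape(na * nb, n1 + 1, n1 + 1, n1 + 1, len(p))
    W1q = np.repeat(W1f, len(q), axis=-1)  # expand to quartet axis
    out = np.einsum("atuvP,btuvP,P->ab", W1q, J, weights, optimize=True)
    return out.reshape(na, nb, nc, nd)


def _shell_pairs_for(basis: BasisSet, B=None, gauge_origin=None):
    """Unique unordered shell pairs; for LAO both (a,b) and (b,a) phase
    variants are needed, so pairs are built on demand."""
    return [(i, j) for i in range(len(basis.shells)) for j in range(i + 1)]


def eri_tensor(basis: BasisSet, max_ao: int = DEFAULT_MAX_AO) -> np.ndarray:
    """Full real two-electron tensor (chemists' (mu nu|lam sig)), 8-fold
    permutational symmetry, dense in-core storage."""
    n = basis.n_ao
    if n > max_ao:
        raise IntegralSizeError(
            f"{n} AOs exceeds the dense-ERI guard of {max_ao}; fragment "
            "subsystems should be far smaller")
    eri = np.zeros((n, n, n, n))
    off = basis.shell_offsets
    pairs = _shell_pairs_for(basis)
    sps = {}
    for (i, j) in pairs:
        sps[(i, j)] = _ShellPair(basis.shells[i], basis.shells[j])
    for a_idx, (i, j) in enumerate(pairs):
        for (k, l) in pairs[: a_idx + 1]:
            block = _eri_quartet(sps[(i, j)], sps[(k, l)])
            _scatter_real(eri, block, off, i, j, k, l)
    norm = basis.ao_norms
    eri *= (norm[:, None, None, None] * norm[None, :, None, None]
            * norm[None, None, :, None] * norm[None, None, None, :])
    return eri


def _scatter_real(eri, block, off, i, j, k, l):
    si = slice(off[i], off[i + 1])
    sj = slice(off[j], off[j + 1])
    sk = slice(off[k], off[k + 1])
    sl = slice(off[l], off[l + 1])
    eri[si, sj, sk, sl] = block
    eri[sj, si, sk, sl] = block.transpose(1, 0, 2, 3)
    eri[si, sj, sl, sk] = block.transpose(0, 1, 3, 2)
    eri[sj, si, sl, sk] = block.transpose(1, 0, 3, 2)
    eri[sk, sl, si, sj] = block.transpose(2, 3, 0, 1)
    eri[sl, sk, si, sj] = block.transpose(3, 2, 0, 1)
    eri[sk, sl, sj, si] = block.transpose(2, 3, 1, 0)
    eri[sl, sk, sj, si] = block.transpose(3, 2, 1, 0)


def lao_eri_tensor(basis: BasisSet, B, gauge_origin,
                   max_ao: int = DEFAULT_MAX_AO) -> np.ndarray:
    """Complex LAO two-electron tensor.  Symmetry is reduced to the 4-fold
    complex group: (ab|cd) = (cd|ab) = (ba|dc)* = (dc|ba)*."""
    B = np.asarray(B, dtype=float)
    O = np.asarray(gauge_origin, dtype=float)
    if not np.any(B != 0.0):
        return eri_tensor(basis, max_ao=max_ao).astype(complex)
    n = basis.n_ao
    if n > max_ao:
        raise IntegralSizeError(
            f"{n} AOs exceeds the dense-ERI guard of {max_ao}")
    eri = np.zeros((n, n, n, n), dtype=complex)
    off = basis.shell_offsets
    shells = basis.shells
    pairs = _shell_pairs_for(basis)

    def make_sp(i, j):
        k, phase = _pair_phase(shells[i], shells[j], B, O)
        sp = _ShellPair(shells[i], shells[j], k=k)
        return sp, phase

    sps = {(i, j): make_sp(i, j) for (i, j) in pairs}
    for a_idx, (i, j) in enumerate(pairs):
        sp1, ph1 = sps[(i, j)]
        for (k, l) in pairs[: a_idx + 1]:
            sp2, ph2 = sps[(k, l)]
            # two independent blocks per unordered quartet (4-fold symmetry)
            blk1 = ph1 * ph2 * _eri_quartet(sp1, sp2)          # (ij|kl)
            _scatter_complex(eri, blk1, off, i, j, k, l)
            if k != l:
                sp2b, ph2b = sps.get((l, k)) or make_sp(l, k)
                if (l, k) not in sps:
                    sps[(l, k)] = (sp2b, ph2b)
                blk2 = ph1 * ph2b * _eri_quartet(sp1, sp2b)    # (ij|lk)
                _scatter_complex(eri, blk2, off, i, j, l, k)
            elif i != j:
                spb, phb = sps.get((j, i)) or make_sp(j, i)
                if (j, i) not in sps:
                    sps[(j, i)] = (spb, phb)
                blk2 = phb * ph2 * _eri_quartet(spb, sp2)      # (ji|kl)
                _scatter_complex(eri, blk2, off, j, i, k, l)
    norm = basis.ao_norms
    eri *= (norm[:, None, None, None] * norm[None, :, None, None]
            * norm[None, None, :, None] * norm[None, None, None, :])
    return eri


def _scatter_complex(eri, block, off, i, j, k, l):
    si = slice(off[i], off[i + 1])
    sj = slice(off[j], off[j + 1])
    sk = slice(off[k], off[k + 1])
    sl = slice(off[l], off[l + 1])
    eri[si, sj, sk, sl] = block                                  # (ab|cd)
    eri[sk, sl, si, sj] = block.transpose(2, 3, 0, 1)            # (cd|ab)
    eri[sj, si, sl, sk] = block.conj().transpose(1, 0, 3, 2)     # (ba|dc)*
    eri[sl, sk, sj, si] = block.conj().transpose(3, 2, 1, 0)     # (dc|ba)*


def eri_blocks(basis_bra: BasisSet, basis_ket: BasisSet) -> np.ndarray:
    """Cross two-electron integrals (mu nu | lam sig) with the bra pair in
    ``basis_bra`` and the ket pair in ``basis_ket`` (real Gaussians only;
    used by the full-Coulomb embedding reference)."""
    n1, n2 = basis_bra.n_ao, basis_ket.n_ao
    if n1 * n2 > DEFAULT_MAX_AO ** 2:
        raise IntegralSizeError("cross-ERI block too large for dense storage")
    out = np.zeros((n1, n1, n2, n2))
    off1, off2 = basis_bra.shell_offsets, basis_ket.shell_offsets
    sps1 = {}
    for i, shA in enumerate(basis_bra.shells):
        for j, shB in enumerate(basis_bra.shells):
            if j > i:
                continue
            sps1[(i, j)] = _ShellPair(shA, shB)
    for k, shC in enumerate(basis_ket.shells):
        for l, shD in enumerate(basis_ket.shells):
            if l > k:
                continue
            sp2 = _ShellPair(shC, shD)
            for (i, j), sp1 in sps1.items():
                block = _eri_quartet(sp1, sp2)
                out[off1[i]:off1[i + 1], off1[j]:off1[j + 1],
                    off2[k]:off2[k + 1], off2[l]:off2[l + 1]] = block
                out[off1[j]:off1[j + 1], off1[i]:off1[i + 1],
                    off2[k]:off2[k + 1], off2[l]:off2[l + 1]] = \
                    block.transpose(1, 0, 2, 3)
                out[off1[i]:off1[i + 1], off1[j]:off1[j + 1],
                    off2[l]:off2[l + 1], off2[k]:off2[k + 1]] = \
                    block.transpose(0, 1, 3, 2)
                out[off1[j]:off1[j + 1], off1[i]:off1[i + 1],
                    off2[l]:off2[l + 1], off2[k]:off2[k + 1]] = \
                    block.transpose(1, 0, 3, 2)
    nb1, nb2 = basis_bra.ao_norms, basis_ket.ao_norms
    out *= (nb1[:, None, None, None] * nb1[None, :, None, None]
            * nb2[None, None, :, None] * nb2[None, None, None, :])
    return out


def nuclear_point_charge_energy(basis: BasisSet,
                                charges: list[PointCharge]) -> float:
    """Interaction of the subsystem's (non-ghost) nuclei with the external
    embedding charges, honoring each charge's attenuation.  The mutual
    interaction of the embedding charges themselves is excluded everywhere
    by convention."""
    e = 0.0
    for Z, R in basis.nuclear_charges():
        for ch in charges:
            r = np.linalg.norm(R - ch.position)
            if ch.mu is None:
                e += Z * ch.q / r
            else:
                e += Z * ch.q * math.erf(ch.mu * r) / r
    return e
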