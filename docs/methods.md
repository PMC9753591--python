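# Methods

## Model

The cluster energy is expanded over fragments ("monomers") and truncated
at second order:

    E^EFM = Σᵢ Eᵢ + Σᵢ<ⱼ (Eᵢⱼ − Eᵢ − Eⱼ).

The expansion is exact at full order (the package carries the untruncated
inclusion–exclusion assembly as its master oracle and asserts agreement
with conventional supersystem SCF for 2–3 waters); truncation at pairs
misses three-body and higher terms, which for polar monomers are dominated
by many-body polarization. To recover most of that polarization, every
subsystem is solved in an external point-charge field representing the
other monomers:

- monomer j is reduced to its electric dipole **μ**ⱼ (monopole vanishes:
  only neutral monomers are accepted, and charged ones are rejected with
  an explicit error);
- the dipole is realized as charges ±eⱼ at **R**ⱼ ± (d/2)·**û**ⱼ, where
  **R**ⱼ is the nuclear-charge center (the point where the nuclear dipole
  vanishes, making the site origin-independent), d = 0.01 bohr is fixed,
  and eⱼ·d = |**μ**ⱼ|;
- the sites are iterated to a fixed point: all monomers are solved in the
  field of the others (Jacobi update — all monomers see the previous
  iteration's sites, which keeps the inner solves independent and
  parallel), fresh dipoles are mixed in with under-relaxation, and
  convergence is declared when max|Δeⱼ| < 10⁻⁴ a.u. Iteration 0 uses
  isolated-monomer dipoles.

Quadrupole and higher multipoles, and any magnetic-induction contribution
to the embedding, are intentionally absent. The pair potential of a site
equals the ideal point-dipole potential to O((d/r)²); at d = 0.01 bohr and
intermonomer distances of several bohr this error is ~10⁻⁶ relative.

Embedding charges polarize the subsystem (they interact with its electrons
and nuclei) but their mutual interaction energy is excluded everywhere;
since it would appear identically in every term of a pair correction only
if included consistently, exclusion is the simpler convention and is
stated here once.

An exact-Coulomb (FMO-style) embedding operator — nuclear point charges
plus the Coulomb contraction of each external monomer density with cross
two-electron integrals — is implemented as a validation reference only;
tests use it to bound the dipole approximation error and verify its r⁻³
decay.

### Short-range attenuation

Optionally every site charge's potential is damped as q·erf(μr)/r. This is
exact in the integrals (the erf kernel maps onto scaled-argument Boys
functions), bounded pointwise by the bare potential, finite at the charge
position (limit 2qμ/√π), and leaves the long-range dipole form untouched.
Attenuation is applied per charge rather than to the summed pair
potential: the per-charge form has an exact integral route, and the two
differ only at O((d/r)²) like the pair/point-dipole difference itself.
The default is unattenuated for HF/MP2; μ = 0.45 is the recommended
pragmatic choice if a density-functional backend (out of scope here) were
plugged in, where diffuse densities make the bare short-range dipole field
a convergence hazard.

### Counterpoise correction

The counterpoise-corrected total is

    E^CP = Σᵢ Eᵢ^{(i),(i)} + Σᵢ<ⱼ [ Eᵢⱼ^{(ij),(ij)} − Eᵢ^{(ij),(ij)} − Eⱼ^{(ij),(ij)} ],

where superscripts denote (basis, embedding-exclusion): Eᵢ^{(ij),(ij)} is
monomer i in the full dimer basis (partner atoms as ghosts: functions
present, nuclear charge and nuclear repulsion suppressed) and in the
embedding field of all monomers *outside the dimer*. All three bracket
terms share one external field, so the bracket is a pure basis-consistent
interaction energy. Two limits pin the construction down and are asserted:
the correction vanishes at 500 bohr separation, and ghost-basis monomer
energies lie variationally below own-basis ones. Note a sign subtlety the
tests document: relative to the *plain* EFM total (whose monomer terms are
embedded excluding only themselves), the embedded CP correction is not
necessarily positive — the bracket's monomer terms lose the partner's
polarization as well as gaining ghost functions. In the unembedded limit
the correction is strictly positive (pure BSSE removal).

## Magnetic fields

The electronic Hamiltonian in a uniform field **B** with gauge origin
**O** is H = H₀ + ½**B**·**L**_O + **B**·**S** + ⅛(**B**×**r**_O)². The
SCF is complex general Hartree–Fock (GHF): one spinor Fock matrix, spin
Zeeman entering as ½**σ**·**B** ⊗ S. GHF rather than UHF keeps one code
path valid for arbitrary field directions; at B = 0 a real RHF fast path
is used and the complex paths are verified to reproduce it to 10⁻⁹
hartree. Ground states follow aufbau occupation of the spinor spectrum; at
the modest fields exercised here closed-shell waters remain S_z ≈ 0.

Two field treatments:

- **CGO**: unmodified Gaussians with angular-momentum and diamagnetic
  matrices about a common origin. Finite-basis energies are gauge-origin
  dependent; the package refuses gauge-sensitive production runs with CGO
  unless explicitly overridden, and a test documents the variance rather
  than hiding it.
- **LAO**: London orbitals ω_μ = exp(−i A_μ·(r − R_μ)) φ_μ with
  A_μ = ½B×(R_μ−O). A pair of LAOs is a plane-wave-modulated Gaussian
  pair; the modulation is absorbed by shifting the Gaussian product center
  into the complex plane, after which the standard McMurchie–Davidson
  recurrences apply unchanged. The one-electron operator ½π² is reduced
  against the ket shell center:
  ⟨ω_μ|½π²|ω_ν⟩ = ⟨φ_μ|e^{ik·r}[T + ½B·L_{R_ν} + ⅛(B×(r−R_ν))²]|φ_ν⟩ with
  k = A_μ − A_ν. Every ingredient (k, the ket-centered operators, the
  attraction and repulsion kernels) is then independent of **O**, so LAO
  gauge invariance is exact by construction and verified to 10⁻¹⁴
  hartree. Referencing each phase to its own shell center also makes all
  LAO integrals invariant under rigid translation, which the tests assert
  elementwise. One consequence of the ket-side reduction worth knowing:
  the T/zeeman/diamagnetic matrices are Hermitian only in sum (hcore);
  the multiplicative operators (S, V, dipole) are Hermitian individually.

Complex Coulomb kernels use the Boys function of complex argument: a
cancellation-free confluent series with downward recursion for |T| ≤ 12,
and a modified-Lentz continued fraction for the upper incomplete gamma
beyond (the series loses ~e^(|T|−Re T) digits, which matters exactly when
|Im T| is large); both branches are validated against an arbitrary-
precision oracle to 10⁻¹⁰ over the arc of physically occurring arguments.

MP2 uses the spin-orbital formulation with antisymmetrized integrals over
complex GHF spinors (closed-shell spatial fast path for RHF); it is
checked against the closed-form two-level result for minimal-basis H₂ and
is real and non-positive for bound references.

## Integrals and numerics

- Cartesian Gaussians throughout; AO order is atoms-in-input-order, shells
  in file order, Cartesian components in descending lexicographic power
  order (x, y, z; xx, xy, xz, yy, yz, zz). Every AO is normalized to unit
  self-overlap (componentwise — xx and xy need different factors).
- Basis input is Gaussian94 text; STO-3G and 6-31G for H/O are bundled.
  Ghost atoms carry functions but no charge.
- Dense in-core ERI storage with a 400-AO guard: embedded-fragment
  subsystems are monomers and dimers, so large supersystems only arise if
  the tool is misused, and the guard fails loudly.
- Real ERIs exploit the full 8-fold permutational symmetry; complex LAO
  ERIs the 4-fold group (ab|cd) = (cd|ab) = (ba|dc)* = (dc|ba)*, computing
  two blocks per unordered quartet.
- SCF: canonical orthogonalization (smallest overlap eigenvalue below
  10⁻¹⁰ raises a linear-dependence error naming the eigenvalue), DIIS on
  the Fock–density commutator in the orthonormal basis (subspace 8,
  damped fallback on a singular extrapolation system), optional level
  shift. Defaults are deliberately tight — 10⁻⁹ hartree, 10⁻⁷ RMS
  density — because the expansion sums and differences many subsystem
  energies and per-job noise accumulates linearly in the total.
- Dimer jobs start from the superposition of the embedded monomer
  densities (block-diagonal embedding into dimer AO indexing), which
  measurably beats the core guess at bonding distances and is exact in
  the noninteracting limit.
- Totals are assembled by compensated summation over sorted subsystem
  keys, so results are bitwise reproducible across worker counts and
  restarts. Non-convergence of any subsystem aborts the run with the
  offending keys; no partial total is ever reported.
- Reproducibility across *different* SCF guesses is bounded by the SCF
  tolerance itself: variational HF energies agree to ~10⁻¹², MP2 (linear
  in the orbital error) to ~10⁻⁹.

## Densities

Cluster densities assemble with the same inclusion–exclusion weights:
D = Σᵢ Dⁱ + Σᵢ<ⱼ(Dⁱʲ − Dⁱ ⊕ Dʲ) in cluster AO indexing. Every pair term
is traceless, so trace(D·S) equals the electron count exactly (asserted to
10⁻⁶ for 1–3 waters). Real-space evaluation includes the London phase
factors at finite field; difference densities subtract either the
isolated-monomer superposition or a second field's assembly, and are
written as Gaussian cube files. Uniform grids resolve hydrogen densities
at ~0.3 bohr spacing but undersample the sharp oxygen core (exponent
~130); grid-integral checks therefore use hydrogen-only systems, while
trace-based conservation checks cover oxygen.

## Synthetic data

The generator places rigid TIP3P-geometry waters (r_OH = 0.9572 Å,
θ_HOH = 104.52°) at uniformly random positions and orientations in a cubic
box, rejecting placements with O–O below a floor; it is bit-reproducible
per seed and errors out (naming n, box and floor) if the box cannot host
the requested count. It emulates a liquid-like snapshot: the field-trend
study uses n = 4 in a 19.2-bohr box — the density of a 103-molecule,
30 Å cell — with a 5.2-bohr O–O floor (the liquid's nearest-neighbor
distance). What it does **not** emulate: hydrogen-bond network topology,
thermal orientation correlations, or monomer flexibility. Passing tests on
these clusters demonstrate the correctness and field response of the
machinery, not the statistical mechanics of water; quantitative
liquid-state numbers would need real simulation snapshots (dynamics is
out of scope).

A deterministic compact ring trimer (O–O 2.79 Å, donors tilted 25° out of
the ring so hydrogen bonds are bent and no intermonomer H–H contact falls
below 2.1 Å; free hydrogens alternate across the plane) serves as the
hydrogen-bonded benchmark fixture. Its geometry was chosen on those
geometric criteria alone; it is not an optimized literature structure, so
energies on it carry a geometry caveat when compared with published
trimer tables.

## Observables and study design

The mean interaction energy MIE = (E^EFM − ΣEᵢ^iso)/n is reported in
kcal/mol (hartree→kcal/mol = 627.509474); isolated references are
recomputed at every field strength with the same method and treatment, and
a relative mode returns MIE(B) − MIE(0). On the liquid-density synthetic
cluster the relative MIE decreases monotonically over B ∈ {0, 0.01, 0.02}
B₀ — the field strengthens intermolecular binding. On the compact ring
trimer in the minimal basis the same scan moves slightly the other way;
the minimal basis has no flexibility to describe the diamagnetic response
of a strained ring, so field trends reported here should be read from the
liquid-density setup.

At second order with dipole embedding, the trimer truncation error against
the conventional supersystem is 1.35 kcal/mol (HF/STO-3G, this geometry),
down from 1.99 kcal/mol unembedded: the embedding recovers the
polarization part of the three-body energy, while the remaining error is
three-body exchange/charge transfer, which no electrostatic embedding can
capture and which is unusually large for a compact minimal-basis ring.

## Orchestration

All subsystem jobs after the embedding fixed point are independent and run
through an ordered process pool (joblib); results are keyed, so any worker
count yields bitwise-identical ledgers. Runs write a JSON archive (config
snapshot, per-subsystem energy/convergence records, embedding history and
sites, totals) from which every reported number can be regenerated without
recomputation; a rerun over a matching archive is a pure read. Densities
are not archived, so density assembly needs a fresh run. A TOML config
file plus CLI overrides drives the `efmag` command (`run`, `scan-field`,
`density-diff`, `make-cluster`).

## Known limitations

- Second-order truncation only; three-body embedded terms are not a
  production path (the full-order assembly exists as an oracle).
- Dipole-only embedding: no quadrupoles, no magnetic induction in the
  embedding potential.
- HF and MP2 backends; no DFT/CDFT, MP3 or CCSD.
- Dense integrals; no screening, density fitting or Cholesky, hence the
  AO-count guard.
- Neutral monomers only (the monopole embedding term is dropped).
- No geometry optimization or gradients; field trends are fixed-geometry
  statements.
- CGO results are gauge-origin dependent by construction; use LAO for
  anything quantitative.
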