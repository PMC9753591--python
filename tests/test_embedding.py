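"""Dipole embedding field: moments, sites, self-consistency, attenuation
and the full-Coulomb reference."""

import math

import numpy as np
import pytest

from efmag.backend import Backend
from efmag.basis import build_basis
from efmag.cluster import Atom, Cluster, nuclear_charge_center
from efmag.embedding import (
    DipoleSite,
    EmbeddingConvergenceError,
    EmbeddingSettings,
    converge_embedding,
    coulomb_embedding_reference,
    field_for_subsystem,
    monomer_dipole,
    site_point_charges,
)
from efmag.integrals import PointCharge
from efmag.scf import SCFSettings, build_subsystem_basis, scf_solve

from conftest import far_water_pair, water_at


def classical_potential(charges, points):
    """Independent evaluation of the (possibly attenuated) point-charge
    potential on grid points."""
    out = np.zeros(len(points))
    for ch in charges:
        r = np.linalg.norm(points - ch.position[None, :], axis=1)
        if ch.mu is None:
            out += ch.q / r
        else:
            out += ch.q * np.array([math.erf(ch.mu * ri) / ri if ri > 1e-12
                                    else 2 * ch.mu / math.sqrt(math.pi)
                                    for ri in r])
    return out


class TestMonomerDipole:
    def test_homonuclear_h2_zero(self):
        b = build_basis([Atom("H", np.zeros(3)),
                         Atom("H", np.array([0.0, 0.0, 1.4]))], "sto-3g")
        res = scf_solve(b, 2)
        from efmag.cluster import Monomer
        m = Monomer((Atom("H", np.zeros(3)),
                     Atom("H", np.array([0.0, 0.0, 1.4]))))
        mu = monomer_dipole(res, b, m, np.zeros(3))
        assert np.max(np.abs(mu)) < 1e-8

    def test_origin_independent_for_neutral(self):
        m = water_at(np.zeros(3))
        b = build_basis(m.atoms, "sto-3g")
        res = scf_solve(b, 10)
        mu1 = monomer_dipole(res, b, m, np.zeros(3))
        mu2 = monomer_dipole(res, b, m, np.array([3.0, -1.0, 2.0]))
        assert np.max(np.abs(mu1 - mu2)) < 1e-10

    def test_water_dipole_vs_finite_field_oracle(self):
        """Independent oracle: by Hellmann-Feynman the dipole equals
        dE/d(eps) in a weak uniform potential V = eps*z, realized here by
        two distant point charges; no dipole integrals are involved."""
        m = water_at(np.zeros(3))
        b = build_basis(m.atoms, "sto-3g")
        res = scf_solve(b, 10)
        o = nuclear_charge_center(m)
        mu = monomer_dipole(res, b, m, o)
        R, eps = 2000.0, 1e-4
        Q = eps * R ** 2 / 2.0

        def energy(sign):
            ch = [PointCharge(sign * Q, o + [0, 0, R]),
                  PointCharge(-sign * Q, o - [0, 0, R])]
            return scf_solve(b, 10, charges=ch).energy
        mz = (energy(+1) - energy(-1)) / (2.0 * eps)
        assert abs(mz - mu[2]) < 1e-5
        # the symmetry axis of this water is z: transverse components null
        assert np.max(np.abs(mu[:2])) < 1e-8


class TestDipoleSites:
    def site(self, e=1.0, d=0.01, direction=(0, 0, 1.0)):
        direction = np.asarray(direction, float)
        return DipoleSite(monomer=0, center=np.zeros(3),
                          dipole=e * d * direction, d=d)

    def test_charge_strength_relation(self):
        s = self.site(e=2.5)
        assert abs(s.e * s.d - np.linalg.norm(s.dipole)) < 1e-15

    def test_point_dipole_potential_on_axis(self):
        s = self.site(e=1.0, d=0.01)
        charges = site_point_charges(s)
        v = classical_potential(charges, np.array([[0.0, 0.0, 10.0]]))[0]
        mu = np.linalg.norm(s.dipole)
        assert abs(v - mu / 100.0) / (mu / 100.0) < 1e-6

    def test_positive_charge_on_dipole_side(self):
        charges = site_point_charges(self.site())
        assert charges[0].q > 0 and charges[0].position[2] > 0

    def test_large_mu_equals_unattenuated(self):
        s = self.site(e=1.3)
        pts = np.array([[0.2, 0.1, 5.0], [1.0, 1.0, 1.0]])
        v_att = classical_potential(site_point_charges(s, 1e8), pts)
        v = classical_potential(site_point_charges(s), pts)
        assert np.max(np.abs(v - v_att)) < 1e-8

    def test_attenuated_potential_finite_at_charge(self):
        s = self.site(e=1.0)
        mu = 0.45
        charges = site_point_charges(s, mu)
        at_plus = classical_potential(charges, charges[0].position[None, :])
        # the erf(mu r)/r singular part tends to 2 q mu / sqrt(pi)
        self_part = 2 * charges[0].q * mu / math.sqrt(math.pi)
        assert np.isfinite(at_plus[0])
        other = charges[1].q * math.erf(mu * s.d) / s.d
        assert abs(at_plus[0] - (self_part + other)) < 1e-10

    def test_attenuated_bounded_by_bare_on_grid(self):
        # Eq-level monotone bound: |erf(mu r)/r| <= 1/r pointwise
        s = self.site(e=0.8, direction=(0.3, -0.5, 0.9))
        rng = np.random.default_rng(2)
        pts = rng.uniform(-4, 4, size=(200, 3))
        bare = np.abs(classical_potential(site_point_charges(s), pts))
        for mu in (0.3, 0.45, 1.0, 3.0):
            att = np.abs(classical_potential(site_point_charges(s, mu), pts))
            assert np.all(att <= bare + 1e-12)

    def test_zero_dipole_is_noop(self):
        s = DipoleSite(monomer=0, center=np.zeros(3),
                       dipole=np.zeros(3), d=0.01)
        charges = site_point_charges(s)
        assert all(c.q == 0.0 for c in charges)


class TestSelfConsistency:
    def test_single_monomer_one_outer_cycle(self):
        c = Cluster([water_at(np.zeros(3))])
        be = Backend.for_cluster(c, basis="sto-3g")
        fld = converge_embedding(c, be)
        assert fld.converged and len(fld.history) == 1
        iso_mu = np.linalg.norm(monomer_dipole(
            fld.isolated_results[0], None, c.monomers[0],
            nuclear_charge_center(c.monomers[0])))
        assert abs(fld.sites[0].e * fld.sites[0].d - iso_mu) < 1e-12

    def test_distant_monomers_keep_isolated_dipoles(self):
        c = far_water_pair(500.0)
        be = Backend.for_cluster(c, basis="sto-3g")
        fld = converge_embedding(c, be)
        assert fld.converged
        for i, s in enumerate(fld.sites):
            iso = np.linalg.norm(monomer_dipole(
                fld.isolated_results[i], None, c.monomers[i],
                nuclear_charge_center(c.monomers[i])))
            assert abs(s.e * s.d - iso) < 1e-4

    def test_hydrogen_bonded_dimer_mutual_polarization(self, smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        fld = converge_embedding(smith_dimer, be)
        assert fld.converged
        for i, s in enumerate(fld.sites):
            iso = np.linalg.norm(monomer_dipole(
                fld.isolated_results[i], None, smith_dimer.monomers[i],
                nuclear_charge_center(smith_dimer.monomers[i])))
            assert np.linalg.norm(s.dipole) > iso

    def test_fixed_point_idempotent(self, smith_dimer):
        settings = EmbeddingSettings()
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        fld = converge_embedding(smith_dimer, be, settings)
        # one more outer cycle changes no e_j beyond the threshold
        e_before = [s.e for s in fld.sites]
        results = [be.solve(smith_dimer, (i,), charges=fld.charges_for((i,)))
                   for i in range(2)]
        for i in range(2):
            fresh = monomer_dipole(results[i], None, smith_dimer.monomers[i],
                                   nuclear_charge_center(
                                       smith_dimer.monomers[i]))
            e_new = np.linalg.norm(fresh) / settings.d
            assert abs(e_new - e_before[i]) < 2 * settings.threshold

    def test_translation_equivariance(self, smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        fld = converge_embedding(smith_dimer, be)
        shift = np.array([7.0, -3.0, 2.0])
        moved = smith_dimer.translated(shift)
        be2 = Backend.for_cluster(moved, basis="sto-3g")
        fld2 = converge_embedding(moved, be2)
        for s, s2 in zip(fld.sites, fld2.sites):
            assert np.max(np.abs(s2.center - (s.center + shift))) < 1e-8
        e1 = [r.energy for r in fld.monomer_results]
        e2 = [r.energy for r in fld2.monomer_results]
        assert np.max(np.abs(np.array(e1) - np.array(e2))) < 1e-8

    def test_nonconvergence_raises_with_guidance(self, smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        with pytest.raises(EmbeddingConvergenceError, match="damping"):
            converge_embedding(smith_dimer, be,
                               EmbeddingSettings(max_iterations=1))


class TestFieldForSubsystem:
    def make_field(self, n):
        cluster = Cluster([water_at(np.array([0.0, 0.0, 8.0 * i]))
                           for i in range(n)])
        be = Backend.for_cluster(cluster, basis="sto-3g")
        return converge_embedding(cluster, be), cluster

    def test_whole_cluster_excluded_gives_empty(self):
        fld, c = self.make_field(2)
        assert field_for_subsystem(fld, c.subsystem((0, 1))) == []

    def test_charge_counting(self):
        fld, c = self.make_field(3)
        assert len(field_for_subsystem(fld, c.subsystem((0,)))) == 4
        # counterpoise-style exclusion of a larger set than the solved one
        assert len(fld.charges_for((0, 1))) == 2

    def test_attenuation_tag_propagates(self, smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        fld = converge_embedding(smith_dimer, be,
                                 EmbeddingSettings(mu=0.45))
        for ch in field_for_subsystem(fld, smith_dimer.subsystem((0,))):
            assert ch.mu == 0.45

    def test_large_attenuation_reproduces_unattenuated_energy(self,
                                                              smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        fld = converge_embedding(smith_dimer, be)
        fld_att = converge_embedding(smith_dimer, be,
                                     EmbeddingSettings(mu=1e3))
        e = [r.energy for r in fld.monomer_results]
        ea = [r.energy for r in fld_att.monomer_results]
        assert np.max(np.abs(np.array(e) - np.array(ea))) < 1e-8


class TestCoulombReference:
    def test_zero_external_gives_zero_matrix(self):
        b = build_basis(water_at(np.zeros(3)).atoms, "sto-3g")
        assert np.max(np.abs(coulomb_embedding_reference([], b))) == 0.0

    def test_dipole_embedding_approaches_full_coulomb(self):
        """At 15 bohr separation the dipole-site operator should agree with
        the exact Coulomb embedding operator of the partner water to the
        size of the neglected quadrupole term, and far better than at
        short range (the error decays with distance)."""
        from efmag.integrals import one_electron_integrals
        errs = []
        for sep in (15.0, 30.0):
            c = far_water_pair(sep)
            target = build_subsystem_basis(c, (0,), "sto-3g")
            ext = build_subsystem_basis(c, (1,), "sto-3g")
            res = scf_solve(ext, 10)
            ref = coulomb_embedding_reference([(res, ext)], target)
            mu = monomer_dipole(res, ext, c.monomers[1],
                                nuclear_charge_center(c.monomers[1]))
            site = DipoleSite(1, nuclear_charge_center(c.monomers[1]),
                              mu, 0.01)
            ch = site_point_charges(site)
            ops = one_electron_integrals(target, ch, np.zeros(3))
            ops0 = one_electron_integrals(target, [], np.zeros(3))
            approx = ops.V - ops0.V
            errs.append(np.max(np.abs(approx - ref)))
        # quadrupole term ~ r^-3 vs dipole r^-2: error ratio ~ 2^-3
        assert errs[1] < errs[0] / 4.0
        assert errs[0] < 1e-3
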