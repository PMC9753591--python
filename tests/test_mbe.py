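"""Many-body expansion: telescoping, exactness oracle, counterpoise
limits, density assembly and mean interaction energies."""

import numpy as np
import pytest

from efmag.backend import Backend
from efmag.cluster import Atom, Cluster, Monomer
from efmag.embedding import converge_embedding
from efmag.mbe import (
    RegularGrid,
    assemble_density,
    density_on_grid,
    efm_energy,
    mbe_full_order,
    mean_interaction_energy,
    write_cube,
)

from conftest import far_water_pair, water_at


def h2_monomer(origin, axis=(0.0, 0.0, 1.0)) -> Monomer:
    origin = np.asarray(origin, float)
    axis = np.asarray(axis, float)
    axis = 0.7 * axis / np.linalg.norm(axis)
    return Monomer((Atom("H", origin - axis), Atom("H", origin + axis)))


@pytest.fixture(scope="module")
def embedded_dimer(smith_dimer):
    be = Backend.for_cluster(smith_dimer, basis="sto-3g")
    fld = converge_embedding(smith_dimer, be)
    return smith_dimer, be, fld


class TestEnergies:
    def test_n2_telescoping_equals_conventional(self, embedded_dimer):
        cluster, be, fld = embedded_dimer
        res = efm_energy(cluster, be, fld)
        conv = be.solve(cluster, (0, 1)).energy
        assert abs(res.total - conv) < 1e-12

    def test_bookkeeping_identity(self, embedded_dimer):
        cluster, be, fld = embedded_dimer
        res = efm_energy(cluster, be, fld)
        rebuilt = (sum(res.monomer_energies.values())
                   + sum(res.pair_corrections.values()))
        assert abs(res.total - rebuilt) < 1e-12

    def test_noninteracting_limit(self):
        c = Cluster([water_at([0.0, 0.0, 0.0]),
                     water_at([500.0, 0.0, 0.0]),
                     water_at([0.0, 500.0, 0.0])])
        be = Backend.for_cluster(c, basis="sto-3g")
        fld = converge_embedding(c, be)
        res = efm_energy(c, be, fld)
        assert all(abs(v) < 1e-6 for v in res.pair_corrections.values())
        assert abs(res.total - res.e_isolated_sum) < 1e-6
        assert abs(mean_interaction_energy(res)) < 1e-3

    def test_permutation_invariance(self, smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        swapped = Cluster(list(reversed(smith_dimer.monomers)))
        fld1 = converge_embedding(smith_dimer, be)
        fld2 = converge_embedding(swapped, Backend.for_cluster(
            swapped, basis="sto-3g"))
        r1 = efm_energy(smith_dimer, be, fld1)
        r2 = efm_energy(swapped, Backend.for_cluster(swapped,
                                                     basis="sto-3g"), fld2)
        assert abs(r1.total - r2.total) < 1e-10

    def test_extensivity_under_duplication(self, smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        fld = converge_embedding(smith_dimer, be)
        single = efm_energy(smith_dimer, be, fld)
        shift = np.array([1000.0, 0.0, 0.0])
        doubled = Cluster(
            list(smith_dimer.monomers)
            + [Monomer(tuple(Atom(a.symbol, a.position + shift)
                             for a in m.atoms))
               for m in smith_dimer.monomers])
        be2 = Backend.for_cluster(doubled, basis="sto-3g")
        fld2 = converge_embedding(doubled, be2)
        res2 = efm_energy(doubled, be2, fld2)
        assert abs(res2.total - 2.0 * single.total) < 1e-6

    def test_unembedded_mode_matches_field_free_jobs(self, smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        res = efm_energy(smith_dimer, be, None)
        conv = be.solve(smith_dimer, (0, 1)).energy
        assert abs(res.total - conv) < 1e-12

    def test_mp2_correlation_included_per_subsystem(self, smith_dimer):
        be_hf = Backend.for_cluster(smith_dimer, basis="sto-3g")
        be = Backend.for_cluster(smith_dimer, basis="sto-3g",
                                 method="hf+mp2")
        res = efm_energy(smith_dimer, be, None)
        res_hf = efm_energy(smith_dimer, be_hf, None)
        assert res.total < res_hf.total  # correlation binds
        from efmag.scf import mp2_energy
        conv = be.solve(smith_dimer, (0, 1))
        # agreement across different SCF guesses is limited by the SCF
        # convergence threshold (MP2 is linear in the orbital error)
        assert abs(res.total - (conv.energy + mp2_energy(conv))) < 1e-8


class TestFullOrder:
    def test_k1_is_isolated_sum(self, smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        e1 = mbe_full_order(smith_dimer, be, 1)
        iso = sum(be.solve(smith_dimer, (i,)).energy for i in range(2))
        assert abs(e1 - iso) < 1e-12

    def test_third_order_term_by_direct_evaluation(self, trimer):
        be = Backend.for_cluster(trimer, basis="sto-3g")
        e2 = mbe_full_order(trimer, be, 2)
        e3 = mbe_full_order(trimer, be, 3)
        # brute-force inclusion-exclusion of the single 3-body term
        E = {s: be.solve(trimer, s).energy
             for s in [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]}
        third = (E[(0, 1, 2)]
                 - (E[(0, 1)] + E[(0, 2)] + E[(1, 2)])
                 + (E[(0,)] + E[(1,)] + E[(2,)]))
        assert abs((e3 - e2) - third) < 1e-9

    def test_invalid_order_rejected(self, smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        with pytest.raises(ValueError):
            mbe_full_order(smith_dimer, be, 3)


class TestCounterpoise:
    def test_correction_vanishes_at_large_separation(self):
        c = far_water_pair(500.0)
        be = Backend.for_cluster(c, basis="sto-3g")
        fld = converge_embedding(c, be)
        res = efm_energy(c, be, fld, counterpoise=True)
        assert abs(res.cp_total - res.total) < 1e-7

    def test_cp_raises_unembedded_dimer_energy(self, smith_dimer):
        # with no embedding the only difference in the CP bracket is the
        # ghost-augmented basis; BSSE is strongly attractive in a minimal
        # basis, so removing it must raise the total
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        res = efm_energy(smith_dimer, be, None, counterpoise=True)
        assert res.cp_total > res.total

    def test_embedded_cp_bracket_uses_consistent_exclusion(self,
                                                           embedded_dimer):
        # the ghost-basis monomer terms exclude the whole dimer from the
        # embedding (for N = 2: no external charges at all), so they match
        # an independent unembedded ghost-basis solve exactly
        cluster, be, fld = embedded_dimer
        res = efm_energy(cluster, be, fld, counterpoise=True)
        direct = be.solve(cluster, (0, 1), ghost_active=0).energy
        assert abs(res.cp_monomer_energies[(0, (0, 1))] - direct) < 1e-9

    def test_plain_result_has_no_cp_total(self, embedded_dimer):
        cluster, be, fld = embedded_dimer
        assert efm_energy(cluster, be, fld).cp_total is None


class TestDensityAssembly:
    def test_single_monomer_density_unchanged(self):
        c = Cluster([water_at(np.zeros(3))])
        be = Backend.for_cluster(c, basis="sto-3g")
        res = efm_energy(c, be, None)
        da = assemble_density(c, be, res)
        assert np.max(np.abs(da.D
                             - res.records[("mono", 0)].density)) < 1e-14

    def test_trace_conservation(self, trimer):
        be = Backend.for_cluster(trimer, basis="sto-3g")
        fld = converge_embedding(trimer, be)
        res = efm_energy(trimer, be, fld)
        da = assemble_density(trimer, be, res)
        assert abs(da.trace_overlap() - 30.0) < 1e-6

    def test_n2_assembly_equals_conventional_dimer_density(self,
                                                           smith_dimer):
        be = Backend.for_cluster(smith_dimer, basis="sto-3g")
        res = efm_energy(smith_dimer, be, None)
        da = assemble_density(smith_dimer, be, res)
        conv = be.solve(smith_dimer, (0, 1)).spatial_density()
        assert np.max(np.abs(da.D - conv)) < 1e-7

    def test_grid_integral_and_difference_density(self, tmp_path):
        # hydrogen-only monomers: modest exponents, so a uniform grid
        # resolves the density (an O core would need a far finer mesh)
        c = Cluster([h2_monomer([0.0, 0.0, 0.0]),
                     h2_monomer([0.0, 0.0, 6.0], axis=(1.0, 0.0, 0.0))])
        be = Backend.for_cluster(c, basis="sto-3g")
        res = efm_energy(c, be, None)
        da = assemble_density(c, be, res)
        grid = RegularGrid.covering(c, spacing=0.3, margin=5.0)
        rho = density_on_grid(da, grid)
        ne = rho.sum() * grid.voxel_volume
        assert abs(ne - 4.0) / 4.0 < 0.005
        # difference against the isolated superposition: integrates to ~0
        ref = assemble_density(c, be, res, use_dimers=False, isolated=True)
        diff = rho - density_on_grid(ref, grid)
        assert abs(diff.sum() * grid.voxel_volume) < 1e-3
        cube = tmp_path / "d.cube"
        write_cube(cube, grid, diff, c)
        assert cube.read_text().startswith("efmag density")

    def test_difference_density_of_noninteracting_monomers_vanishes(self):
        c = Cluster([h2_monomer([0.0, 0.0, 0.0]),
                     h2_monomer([60.0, 0.0, 0.0])])
        be = Backend.for_cluster(c, basis="sto-3g")
        res = efm_energy(c, be, None)
        da = assemble_density(c, be, res)
        ref = assemble_density(c, be, res, use_dimers=False, isolated=True)
        grid = RegularGrid.covering(c, spacing=0.5, margin=3.0)
        diff = density_on_grid(da, grid) - density_on_grid(ref, grid)
        assert np.max(np.abs(diff)) < 1e-8

    def test_field_difference_density_integrates_to_zero(self):
        # equal electron counts at the two field strengths
        c0 = Cluster([h2_monomer([0.0, 0.0, 0.0]),
                      h2_monomer([0.0, 0.0, 6.0], axis=(1.0, 0.0, 0.0))])
        cB = Cluster([m for m in c0.monomers], B=(0.0, 0.0, 0.1),
                     gauge_origin=c0.gauge_origin)
        grid = RegularGrid.covering(c0, spacing=0.3, margin=5.0)
        rhos = {}
        for c in (c0, cB):
            be = Backend.for_cluster(c, basis="sto-3g")
            res = efm_energy(c, be, None)
            da = assemble_density(c, be, res)
            rhos[tuple(c.B)] = density_on_grid(da, grid)
        diff = rhos[(0.0, 0.0, 0.1)] - rhos[(0.0, 0.0, 0.0)]
        assert abs(diff.sum() * grid.voxel_volume) < 1e-3


class TestMIE:
    def test_relative_mie_contract(self, embedded_dimer):
        cluster, be, fld = embedded_dimer
        res = efm_energy(cluster, be, fld)
        assert mean_interaction_energy(res, relative_to=res) == 0.0
        other = efm_energy(cluster, Backend.for_cluster(
            cluster, basis="sto-3g", method="hf+mp2"), fld)
        with pytest.raises(ValueError):
            mean_interaction_energy(res, relative_to=other)

    def test_hydrogen_bonded_dimer_binds(self, embedded_dimer):
        cluster, be, fld = embedded_dimer
        res = efm_energy(cluster, be, fld)
        # known scale for the water dimer at HF/minimal basis: several
        # kcal/mol of binding (BSSE-inflated), shared between 2 monomers
        assert -6.0 < mean_interaction_energy(res) < -1.0
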