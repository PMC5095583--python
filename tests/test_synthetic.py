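"""Generators: analytic double wells, toy polymers, steric fixtures,
and overdamped biased sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import proofscape as ps
from proofscape.forcefield import assign_charges, detect_contacts, energy
from proofscape.synthetic import destabilize_segment, potential_from_profile


class TestDoubleWell:
    def test_symmetric_when_offset_zero(self):
        pot = ps.make_double_well(0.0, 10.0, 8.0, basin_offset=0.0)
        assert pot(0.0) == pytest.approx(pot(10.0), abs=1e-12)

    def test_barrier_height_exact(self):
        pot = ps.make_double_well(0.0, 10.0, 10.0, 2.0)
        xs = np.linspace(0.0, 10.0, 20001)
        assert np.max(pot(xs)) == pytest.approx(10.0, abs=1e-6)
        assert pot(0.0) == pytest.approx(0.0, abs=1e-12)
        assert pot(10.0) == pytest.approx(-2.0, abs=1e-12)

    def test_offset_difference_is_pointwise_at_basin2(self):
        a = ps.make_double_well(0.0, 10.0, 10.0, 0.0)
        b = ps.make_double_well(0.0, 10.0, 10.0, 8.0)
        assert a(10.0) - b(10.0) == pytest.approx(8.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [
        dict(basin1_pos=np.nan, basin2_pos=1, barrier_height_fwd=5),
        dict(basin1_pos=5, basin2_pos=1, barrier_height_fwd=5),
        dict(basin1_pos=0, basin2_pos=1, barrier_height_fwd=-2),
        dict(basin1_pos=0, basin2_pos=1, barrier_height_fwd=np.inf),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ps.make_double_well(**bad)

    @given(barrier=st.floats(1.0, 20.0), offset=st.floats(-0.5, 10.0),
           span=st.floats(2.0, 30.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_declared_extrema_are_stationary(self, barrier, offset, span):
        if barrier <= -offset + 0.5:
            offset = -barrier + 0.5
        pot = ps.make_double_well(0.0, span, barrier, offset)
        for x0 in (*pot.basins, pot.barrier):
            assert abs(pot.grad(x0)) < 1e-8
        xs = np.linspace(*pot.bounds, 512)
        assert np.all(np.isfinite(pot(xs)))

    def test_destabilize_segment_raises_start_only(self):
        pot = ps.make_double_well(0.0, 20.0, 12.0, 0.0)
        c = np.linspace(-5, 25, 600)
        F2 = destabilize_segment(c, pot(c), 8.0, split=5.0)
        assert F2[c < 1.0][0] - pot(c[c < 1.0][0]) == pytest.approx(8.0, abs=1e-3)
        far = c > 15.0
        np.testing.assert_allclose(F2[far], pot(c[far]), atol=1e-6)


class TestToyHairpin:
    def test_deterministic_for_fixed_seed(self):
        a = ps.make_toy_hairpin(8, seed=7)
        b = ps.make_toy_hairpin(8, seed=7)
        assert np.array_equal(a.coords, b.coords)
        c = ps.make_toy_hairpin(8, seed=8)
        assert not np.array_equal(a.coords, c.coords)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            ps.make_toy_hairpin(3)

    def test_one_phosphate_charge_per_residue(self, hairpin):
        q = assign_charges(hairpin)
        assert np.count_nonzero(q == -1.0) == 10
        assert q.sum() == -10.0

    def test_contact_count_matches_brute_force_scan(self, hairpin):
        from proofscape.topology import build_topology

        contacts = detect_contacts(hairpin, cutoff=4.0)
        bonded = build_topology(hairpin).bonded_pairs()
        n = hairpin.n_atoms
        count = 0
        for i in range(n):
            for j in range(i + 1, n):
                if (hairpin.chain[i], hairpin.resid[i]) == (hairpin.chain[j], hairpin.resid[j]):
                    continue
                if (i, j) in bonded:
                    continue
                if np.linalg.norm(hairpin.coords[i] - hairpin.coords[j]) <= 4.0:
                    count += 1
        assert len(contacts) == count > 0

    def test_nonadjacent_residues_in_contact(self, hairpin):
        contacts = detect_contacts(hairpin)
        sep = np.abs(hairpin.resid[contacts.i] - hairpin.resid[contacts.j])
        assert np.any(sep > 1)


class TestGatedSystem:
    def test_coordinate_spec_is_valid(self):
        fx = ps.make_gated_system(0)
        # construction raises if the coordinate references missing atoms
        assert fx.coordinate.value(fx.structure.coords) == pytest.approx(
            fx.bound_basin, abs=0.3)

    def test_gate_deletion_energies_coincide_away_from_gate(self):
        g = ps.make_gated_system(4)
        ng = ps.make_gated_system(4, gate=False)
        fg, fng = g.build_forcefield(), ng.build_forcefield()
        x = g.structure.coords
        assert energy(x, fg).total == pytest.approx(energy(x, fng).total, abs=1e-10)

    def test_gate_contributes_only_at_the_ring(self):
        g = ps.make_gated_system(4)
        ng = ps.make_gated_system(4, gate=False)
        fg, fng = g.build_forcefield(), ng.build_forcefield()
        x = g.structure.coords.copy()
        x[4:7] += np.array([7.7, 0.0, 0.0])    # ligand into the ring plane
        assert energy(x, fg).total > energy(x, fng).total + 1.0

    def test_steric_bodies_have_no_contacts(self):
        fx = ps.make_gated_system(0)
        ff = fx.build_forcefield()
        steric = set(np.flatnonzero(
            np.isin(fx.structure.resname, ("GAT", "CAP", "WAL"))).tolist())
        for i, j in zip(ff.contacts.i, ff.contacts.j):
            assert i not in steric and j not in steric


class TestConfinementWall:
    def test_wall_overlapping_bound_basin_rejected(self):
        fx = ps.make_gated_system(0)
        with pytest.raises(ValueError):
            ps.add_confinement_wall(fx, 6.0)

    def test_energy_unchanged_far_from_wall(self):
        fx = ps.make_gated_system(0)
        walled = ps.add_confinement_wall(fx, 18.0)
        x0 = fx.structure.coords
        e_without = energy(x0, fx.build_forcefield()).total
        e_with = energy(walled.structure.coords, walled.build_forcefield()).total
        assert e_with == pytest.approx(e_without, abs=1e-10)

    def test_wall_atoms_carry_no_contacts(self):
        walled = ps.add_confinement_wall(ps.make_gated_system(0), 18.0)
        ff = walled.build_forcefield()
        wall = set(walled.wall_atoms.tolist())
        for i, j in zip(ff.contacts.i, ff.contacts.j):
            assert i not in wall and j not in wall

    def test_wall_repels_ligand_near_it(self):
        fx = ps.make_gated_system(0)
        walled = ps.add_confinement_wall(fx, 18.0)
        x = walled.structure.coords.copy()
        lig = walled.structure.select(resname="LIG")
        x[lig] += np.array([11.0, 0.0, 0.0])    # ligand tip ~1.2 Å from wall
        e_near = energy(x, walled.build_forcefield()).repulsion
        e_far = energy(walled.structure.coords, walled.build_forcefield()).repulsion
        assert e_near > e_far + 1.0


class TestBiasedSampling1D:
    def test_equipartition_in_harmonic_well(self):
        k_h = 2.0
        xs = np.linspace(-4, 4, 801)
        pot = potential_from_profile(xs, 0.5 * k_h * xs ** 2)
        s = ps.sample_biased_1d(pot, 0.0, 0.0, 40000, seed=2)
        se = np.sqrt(2.0 / len(s)) * (1.0 / k_h)   # var SE for correlated-ish data
        assert s.var() == pytest.approx(1.0 / k_h, abs=10 * se)

    def test_strong_bias_centers_samples(self):
        pot = ps.make_double_well(0.0, 10.0, 6.0)
        s = ps.sample_biased_1d(pot, 7.0, 400.0, 5000, seed=3)
        assert s.mean() == pytest.approx(7.0, abs=0.1)

    def test_invalid_inputs_rejected(self):
        pot = ps.make_double_well(0.0, 10.0, 6.0)
        with pytest.raises(ValueError):
            ps.sample_biased_1d(pot, 0.0, 1.0, 100, temperature=-1.0)
        with pytest.raises(ValueError):
            ps.sample_biased_1d(pot, 0.0, 1.0, 0)

    def test_basin_occupancy_matches_boltzmann_integral(self):
        pot = ps.make_double_well(0.0, 8.0, 5.0, 1.5)
        s = ps.sample_biased_1d(pot, 0.0, 0.0, 120000, seed=11)
        frac2 = np.mean(s > 4.0)
        xs = np.linspace(*pot.bounds, 4001)
        w = np.exp(-pot(xs))
        expected = np.trapezoid(w[xs > 4.0], xs[xs > 4.0]) / np.trapezoid(w, xs)
        assert frac2 / (1 - frac2) == pytest.approx(
            expected / (1 - expected), rel=0.25)

    def test_biased_histogram_is_boltzmann(self):
        """KS test of long-run samples against the biased Boltzmann CDF."""
        pot = ps.make_double_well(0.0, 6.0, 4.0, 1.0)
        c, k = 3.0, 1.0
        s = ps.sample_biased_1d(pot, c, k, 200000, seed=5)
        xs = np.linspace(*pot.bounds, 8001)
        w = np.exp(-(pot(xs) + 0.5 * k * (xs - c) ** 2))
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        # KS on decorrelated subsample (plain KS assumes independence)
        sub = s[:: 10]
        stat = stats.kstest(sub, lambda v: np.interp(v, xs, cdf)).pvalue
        assert stat > 0.01

    def test_deterministic_under_seed(self):
        pot = ps.make_double_well(0.0, 10.0, 6.0)
        a = ps.sample_biased_1d(pot, 5.0, 2.0, 1000, seed=9)
        b = ps.sample_biased_1d(pot, 5.0, 2.0, 1000, seed=9)
        assert np.array_equal(a, b)
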