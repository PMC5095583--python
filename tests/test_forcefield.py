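"""Structure-based potential: contact rules, charges, normalisation,
energies and analytic forces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import proofscape as ps
from proofscape.forcefield import (ContactList, ElectrostaticParams,
                                   EnergyParams, assign_charges,
                                   bjerrum_length, build_forcefield,
                                   classify_and_scale_contacts,
                                   detect_contacts, energy, energy_and_forces,
                                   forces)
from proofscape.structure import MolecularStructure


def _pair_structure(distance, resname="U", names=("N1", "N1")):
    """Two single-atom residues a given distance apart."""
    return MolecularStructure(
        serial=np.array([1, 2]),
        name=np.array(list(names), dtype=object),
        resname=np.array([resname] * 2, dtype=object),
        resid=np.array([1, 5]),
        chain=np.array(["A", "A"], dtype=object),
        coords=np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
    )


class TestDetectContacts:
    @pytest.mark.parametrize("d,expected", [(3.9, 1), (4.1, 0)])
    def test_cutoff_threshold(self, d, expected):
        assert len(detect_contacts(_pair_structure(d))) == expected

    def test_bonded_pairs_never_contacts(self, hairpin):
        from proofscape.topology import build_topology

        topo = build_topology(hairpin)
        contacts = detect_contacts(hairpin, topology=topo)
        pairs = contacts.pairs()
        for i, j in topo.bonds:
            assert (min(i, j), max(i, j)) not in pairs

    def test_sigma_is_native_distance(self):
        c = detect_contacts(_pair_structure(3.5))
        assert c.sigma[0] == pytest.approx(3.5)

    def test_empty_structure_rejected(self, hairpin):
        empty = hairpin.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            detect_contacts(empty)


class TestContactScaling:
    def test_stacked_rna_bases_scaled_one_third(self, hairpin):
        params = EnergyParams()
        c = classify_and_scale_contacts(detect_contacts(hairpin), hairpin, params)
        stacked = c.weight_class == "stacked"
        assert np.any(stacked)
        np.testing.assert_allclose(c.eps[stacked], 1.0 / 3.0)
        # stacked = base-base pairs of sequence-adjacent residues only
        for n in np.flatnonzero(stacked):
            assert abs(hairpin.resid[c.i[n]] - hairpin.resid[c.j[n]]) == 1

    def test_interface_pairs_scaled_half(self, hairpin):
        params = EnergyParams()
        raw = detect_contacts(hairpin)
        # declare one residue pair that is actually in contact as interface
        normal = classify_and_scale_contacts(raw, hairpin, params)
        n = np.flatnonzero(normal.weight_class == "normal")[0]
        pair = ((hairpin.chain[normal.i[n]], int(hairpin.resid[normal.i[n]])),
                (hairpin.chain[normal.j[n]], int(hairpin.resid[normal.j[n]])))
        scaled = classify_and_scale_contacts(raw, hairpin, params,
                                             interface_pairs=[pair])
        m = scaled.weight_class == "interface_scaled"
        assert np.any(m)
        np.testing.assert_allclose(scaled.eps[m], 0.5)

    def test_exclusion_list_removes_contacts(self, hairpin):
        params = EnergyParams()
        raw = detect_contacts(hairpin)
        pair = ((hairpin.chain[raw.i[0]], int(hairpin.resid[raw.i[0]])),
                (hairpin.chain[raw.j[0]], int(hairpin.resid[raw.j[0]])))
        out = classify_and_scale_contacts(raw, hairpin, params,
                                          exclude_pairs=[pair])
        assert len(out) < len(raw)

    def test_unknown_residue_in_lists_rejected(self, hairpin):
        with pytest.raises(ValueError):
            classify_and_scale_contacts(
                detect_contacts(hairpin), hairpin, EnergyParams(),
                interface_pairs=[(("A", 1), ("Z", 99))])

    def test_empty_lists_identity_for_non_rna(self, peptide):
        raw = detect_contacts(peptide)
        out = classify_and_scale_contacts(raw, peptide, EnergyParams())
        np.testing.assert_array_equal(out.eps, raw.eps)


class TestCharges:
    def test_his_uncharged_and_acid_base_residues_signed(self, peptide):
        q = assign_charges(peptide)
        for chain, resid, idx in peptide.residues():
            resname = peptide.resname[idx[0]]
            total = q[idx].sum()
            expected = {"ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1}.get(resname, 0)
            assert total == expected, resname
            assert np.count_nonzero(q[idx]) <= 1   # single designated atom

    def test_magnesium_plus_two(self):
        s = MolecularStructure(
            serial=np.array([1]), name=np.array(["MG"], dtype=object),
            resname=np.array(["MG"], dtype=object), resid=np.array([1]),
            chain=np.array(["A"], dtype=object), coords=np.zeros((1, 3)))
        assert assign_charges(s)[0] == 2.0


class TestBuildNormalisation:
    def test_contact_to_dihedral_ratio_is_two(self, hairpin_ff):
        ratio = hairpin_ff.total_contact_energy / hairpin_ff.total_dihedral_energy
        assert ratio == pytest.approx(2.0, abs=1e-9)

    def test_total_stabilising_energy_is_n_atoms(self, hairpin, hairpin_ff):
        total = hairpin_ff.total_contact_energy + hairpin_ff.total_dihedral_energy
        assert total == pytest.approx(hairpin.n_atoms, abs=1e-9)

    def test_backbone_sidechain_ratio_protein_two_rna_one(self, hairpin, peptide):
        for s, expected in ((peptide, 2.0), (hairpin, 1.0)):
            ff = build_forcefield(s)
            bb = ff.dihedral_class == "BB"
            assert np.any(bb) and np.any(~bb)
            ratio = ff.dihedral_k[bb].mean() / ff.dihedral_k[~bb].mean()
            assert ratio == pytest.approx(expected, abs=1e-9)

    def test_scale_invariance_of_prenormalised_eps(self, hairpin):
        c1 = classify_and_scale_contacts(detect_contacts(hairpin), hairpin,
                                         EnergyParams())
        c2 = ContactList(c1.i, c1.j, c1.sigma, 2.0 * c1.eps, c1.weight_class)
        ff1 = build_forcefield(hairpin, contacts=c1)
        ff2 = build_forcefield(hairpin, contacts=c2)
        np.testing.assert_allclose(ff1.contacts.eps, ff2.contacts.eps)
        np.testing.assert_allclose(ff1.dihedral_k, ff2.dihedral_k)

    def test_zero_contacts_rejected(self):
        s = _pair_structure(9.0)
        with pytest.raises(ValueError, match="zero native contacts"):
            build_forcefield(s)

    @given(n=st.integers(5, 12), seed=st.integers(0, 100))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_normalisation_holds_for_random_toys(self, n, seed):
        s = ps.make_toy_hairpin(n, seed=seed)
        ff = build_forcefield(s)
        assert (ff.total_contact_energy / ff.total_dihedral_energy
                == pytest.approx(2.0, abs=1e-9))
        assert (ff.total_contact_energy + ff.total_dihedral_energy
                == pytest.approx(s.n_atoms, abs=1e-9))


class TestEnergy:
    def test_native_minimum_identity(self, hairpin, hairpin_ff):
        br = energy(hairpin.coords, hairpin_ff)
        assert br.bonds == br.angles == br.impropers == br.planars == br.dihedrals == 0.0
        assert br.contacts == pytest.approx(-hairpin_ff.contacts.eps.sum(), abs=1e-10)
        assert br.repulsion == pytest.approx(0.0, abs=1e-12)
        assert br.total == pytest.approx(-hairpin_ff.contacts.eps.sum(), abs=1e-9)

    def test_breakdown_total_is_sum_of_components(self, hairpin, hairpin_ff):
        rng = np.random.default_rng(1)
        br = energy(hairpin.coords + rng.normal(0, 0.2, hairpin.coords.shape),
                    hairpin_ff)
        parts = sum(br.as_dict()[k] for k in
                    ("bonds", "angles", "impropers", "planars", "dihedrals",
                     "contacts", "repulsion", "electrostatics", "restraints"))
        assert br.total == pytest.approx(parts, rel=1e-10)

    def test_contact_functional_form(self):
        s = _pair_structure(3.5)
        ff = build_forcefield(s)
        eps = ff.contacts.eps[0]
        assert energy(s.coords, ff).contacts == pytest.approx(-eps, abs=1e-12)
        far = s.coords.copy()
        far[1, 0] = 500.0
        assert energy(far, ff).contacts == pytest.approx(0.0, abs=1e-9)

    def test_debye_huckel_matches_closed_form(self):
        s = _pair_structure(3.0, names=("P", "P"))
        es = ElectrostaticParams(screening_length_nm=1.4)
        ff = build_forcefield(s, electrostatics=es,
                              contacts=detect_contacts(_pair_structure(3.0)))
        kappa = 1.0 / 14.0
        lb = bjerrum_length(es.temperature_K, 80.0)
        for r in (3.0, 14.0, 28.0):
            x = s.coords.copy()
            x[1, 0] = r
            got = energy(x, ff).electrostatics
            shift = np.exp(-kappa * 56.0) / 56.0
            expected = lb * (+1) * np.exp(-kappa * r) / r - lb * shift
            assert got == pytest.approx(expected, rel=1e-12)

    def test_electrostatics_off_ignores_charge_map(self, hairpin):
        ff_off = build_forcefield(hairpin, electrostatics=None)
        ff_zero = build_forcefield(hairpin, electrostatics=None)
        ff_zero.charges[:] = 0.0
        rng = np.random.default_rng(2)
        x = hairpin.coords + rng.normal(0, 0.3, hairpin.coords.shape)
        assert energy(x, ff_off).total == energy(x, ff_zero).total

    def test_non_finite_coordinates_rejected(self, hairpin_ff):
        bad = np.full((hairpin_ff.n_atoms, 3), np.nan)
        with pytest.raises(ValueError):
            energy(bad, hairpin_ff)


class TestForces:
    def test_native_structure_is_force_free(self, hairpin, hairpin_ff):
        F = forces(hairpin.coords, hairpin_ff)
        assert np.abs(F).max() < 1e-6

    def test_finite_difference_consistency(self, hairpin):
        ff = build_forcefield(hairpin, electrostatics=ElectrostaticParams())
        rng = np.random.default_rng(0)
        x = hairpin.coords + rng.normal(0, 0.15, hairpin.coords.shape)
        _, F = energy_and_forces(x, ff)
        h = 1e-6
        num = np.zeros_like(F)
        for a in range(ff.n_atoms):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[a, d] += h
                xm[a, d] -= h
                num[a, d] = -(energy(xp, ff).total - energy(xm, ff).total) / (2 * h)
        assert np.abs(F - num).max() / np.abs(F).max() < 1e-5

    def test_zero_net_force_and_torque(self, hairpin):
        ff = build_forcefield(hairpin, electrostatics=ElectrostaticParams())
        rng = np.random.default_rng(5)
        x = hairpin.coords + rng.normal(0, 0.2, hairpin.coords.shape)
        F = forces(x, ff)
        assert np.abs(F.sum(axis=0)).max() < 1e-10
        assert np.abs(np.cross(x, F).sum(axis=0)).max() < 1e-9
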