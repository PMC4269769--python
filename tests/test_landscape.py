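"""Bending angle, Rg, free-energy landscape, contacts, secondary
structure."""

import numpy as np
import pytest

from repave import landscape as lsc
from repave import synthetic as syn
from repave._geometry import rotation_matrix
from repave.ensemble_io import ConformationEnsemble, Structure, Topology


def _ca_chain(points, masses=None):
    n = len(points)
    topo = Topology(["A"] * n, np.arange(1, n + 1), ["ALA"] * n,
                    ["CA"] * n, ["C"] * n, masses=masses)
    return Structure(topo, np.asarray(points, dtype=float))


_POINT_REGIONS = lsc.RegionSpec(((1, 1),), ((2, 2),), ((3, 3),))


class TestBendingAngle:
    def test_collinear_centroids_give_180(self):
        s = _ca_chain([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        assert lsc.bending_angle(s, _POINT_REGIONS) == pytest.approx(180.0)

    def test_right_angle_at_the_hinge_vertex(self):
        s = _ca_chain([[5, 0, 0], [0, 0, 0], [0, 5, 0]])
        assert lsc.bending_angle(s, _POINT_REGIONS) == pytest.approx(90.0)

    def test_hand_placed_coordinates_match_arccos_oracle(self):
        a, b, c = np.array([3.0, 1.0, -2.0]), np.array([0.5, -1.0, 4.0]), \
            np.array([-2.0, 2.0, 1.0])
        s = _ca_chain([a, b, c])
        v1, v2 = a - b, c - b
        oracle = np.degrees(np.arccos(
            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert lsc.bending_angle(s, _POINT_REGIONS) == pytest.approx(
            oracle, abs=1e-10)

    def test_missing_region_residue_is_named_in_error(self):
        s = _ca_chain([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        regions = lsc.RegionSpec(((1, 1),), ((2, 2),), ((7, 8),))
        with pytest.raises(ValueError, match=r"\[7, 8\]"):
            lsc.bending_angle(s, regions)

    def test_rigid_body_invariance(self, template, hinge_regions):
        rot = rotation_matrix([1.0, 1.0, 0.0], 0.8)
        moved = template.transformed(rotation=rot, translation=[3, -9, 12])
        assert lsc.bending_angle(moved, hinge_regions) == pytest.approx(
            lsc.bending_angle(template, hinge_regions), rel=1e-10)

    def test_region_spec_validation(self):
        with pytest.raises(ValueError):
            lsc.RegionSpec(((1, 3),), ((2, 4),), ((7, 8),))  # overlap
        # defaults encode the published region definitions
        spec = lsc.RegionSpec()
        assert spec.residues("II") == [32, 33, 34, 35]
        assert 111 in spec.residues("I") and 165 in spec.residues("I")
        assert 45 in spec.residues("III") and 61 in spec.residues("III")


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert lsc.radius_of_gyration(_ca_chain([[1, 2, 3]])) == pytest.approx(0.0, abs=1e-12)

    def test_two_unit_masses_two_angstrom_apart(self):
        s = _ca_chain([[0, 0, 0], [2, 0, 0]], masses=[1.0, 1.0])
        assert lsc.radius_of_gyration(s) == pytest.approx(1.0)

    def test_heavy_selection_drops_hydrogens(self, template):
        rg_all = lsc.radius_of_gyration(template, "all")
        rg_heavy = lsc.radius_of_gyration(template, "heavy")
        assert rg_heavy != rg_all  # pseudo-H present in the toy model

    def test_rigid_body_invariance(self, template):
        rot = rotation_matrix([0.0, 1.0, 1.0], 1.9)
        moved = template.transformed(rotation=rot, translation=[5, 5, -2])
        assert lsc.radius_of_gyration(moved) == pytest.approx(
            lsc.radius_of_gyration(template), rel=1e-10)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            lsc.radius_of_gyration(_ca_chain([[0, 0, 0]]), "unknown")


class TestLandscape:
    def test_uniform_occupancy_is_flat(self, hinge_model, hinge_regions):
        members = [hinge_model.at_angle(a) for a in (90.0, 100.0, 110.0,
                                                     120.0)]
        ens = ConformationEnsemble(members)
        grid = lsc.free_energy_landscape(
            ens, hinge_regions,
            angle_bins=np.array([85, 95, 105, 115, 125.0]),
            rg_bins=np.array([0.0, 100.0]))
        occupied = grid.free_energy[~grid.empty_mask]
        assert np.allclose(occupied, 0.0)

    def test_two_bin_free_energy_difference_is_ln4(self, hinge_model,
                                                   hinge_regions):
        members = [hinge_model.at_angle(100.0), hinge_model.at_angle(120.0)]
        ens = ConformationEnsemble(members, weights=[0.8, 0.2])
        grid = lsc.free_energy_landscape(
            ens, hinge_regions, angle_bins=np.array([95, 110, 125.0]),
            rg_bins=np.array([0.0, 100.0]))
        occupied = np.sort(grid.free_energy[~grid.empty_mask].ravel())
        assert occupied[0] == 0.0
        assert occupied[1] == pytest.approx(np.log(4.0), rel=1e-12)

    def test_probability_normalized_and_minimum_shifted(self, small_ensemble,
                                                        hinge_regions):
        grid = lsc.free_energy_landscape(small_ensemble, hinge_regions)
        assert grid.probability.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.nanmin(grid.free_energy) == 0.0
        assert np.all(grid.free_energy[~grid.empty_mask] >= 0.0)
        assert np.all(np.isnan(grid.free_energy[grid.empty_mask]))

    def test_landscape_recovers_generator_parameters(self, hinge_model,
                                                     hinge_regions):
        spec = syn.AngleDistributionSpec(110.0, 8.0)
        n = 2000
        ens = syn.sample_hinge_ensemble(hinge_model, spec, n, seed=21)
        grid = lsc.free_energy_landscape(ens, hinge_regions)
        assert grid.mode_angle == pytest.approx(110.0, abs=2.0)
        angles = np.array([lsc.bending_angle(s, hinge_regions) for s in ens])
        se_mean = spec.sd_angle / np.sqrt(n)
        se_sd = spec.sd_angle / np.sqrt(2 * n)
        assert abs(angles.mean() - 110.0) < 3 * se_mean
        assert abs(angles.std() - 8.0) < 3 * se_sd

    def test_single_occupied_bin_is_a_valid_landscape(self, hinge_model,
                                                      hinge_regions):
        ens = ConformationEnsemble([hinge_model.at_angle(110.0)] * 3)
        grid = lsc.free_energy_landscape(ens, hinge_regions)
        assert (~grid.empty_mask).sum() == 1
        assert grid.probability.sum() == pytest.approx(1.0)


class TestProjection:
    def test_projected_members_match_landscape_inputs(self, small_ensemble,
                                                      hinge_regions):
        table = lsc.project_structures({"self": small_ensemble},
                                       hinge_regions)
        s0 = small_ensemble[0]
        assert table.iloc[0]["angle"] == pytest.approx(
            lsc.bending_angle(s0, hinge_regions))
        assert table.iloc[0]["rg"] == pytest.approx(
            lsc.radius_of_gyration(s0, "ca", False))

    def test_single_structure_single_row(self, template, hinge_regions):
        table = lsc.project_structures({"ref": template}, hinge_regions)
        assert len(table) == 1

    def test_known_pose_recovered_to_numerical_precision(self, hinge_model,
                                                         hinge_regions):
        table = lsc.project_structures(
            {"pose": hinge_model.at_angle(97.25)}, hinge_regions)
        assert table.iloc[0]["angle"] == pytest.approx(97.25, abs=1e-6)

    def test_numbering_mismatch_yields_error_entry(self, template):
        regions = lsc.RegionSpec(((200, 205),), ((210, 212),), ((220, 223),))
        table = lsc.project_structures({"bad": template}, regions)
        assert np.isnan(table.iloc[0]["angle"])
        assert table.iloc[0]["error"] != ""


class TestContactMap:
    def test_rigid_ensemble_yields_binary_map(self, template):
        ens = ConformationEnsemble([template, template])
        _, freq = lsc.contact_map(ens)
        assert set(np.unique(freq)) <= {0.0, 1.0}

    def test_pair_at_exact_cutoff_is_not_a_contact(self):
        s = _ca_chain([[0, 0, 0], [0, 0, 4.0], [0, 0, 8.0]])
        _, freq = lsc.contact_map(ConformationEnsemble([s]), cutoff=8.0)
        assert freq[0, 2] == 0.0  # exactly 8.0 apart: strict inequality
        assert freq[0, 1] == 1.0

    def test_matches_brute_force_all_pairs_oracle(self, hinge_model):
        ens = syn.sample_hinge_ensemble(
            hinge_model, syn.AngleDistributionSpec(110, 12), 5, seed=13)
        resids, freq = lsc.contact_map(ens, cutoff=8.0)
        ca = ens.select(atom_names=["CA"])
        n = len(resids)
        brute = np.zeros((n, n))
        for coords in ca.coords:
            for i in range(n):
                for j in range(n):
                    d = np.linalg.norm(coords[i] - coords[j])
                    brute[i, j] += (d < 8.0) / len(ens)
        np.fill_diagonal(brute, 1.0)
        assert np.allclose(freq, brute, atol=1e-12)

    def test_symmetric_with_unit_diagonal_and_monotone_in_cutoff(
            self, small_ensemble):
        _, f8 = lsc.contact_map(small_ensemble, cutoff=8.0)
        _, f10 = lsc.contact_map(small_ensemble, cutoff=10.0)
        assert np.allclose(f8, f8.T)
        assert np.allclose(np.diag(f8), 1.0)
        assert np.all(f10 >= f8)


class TestSecondaryStructure:
    def test_ideal_alpha_helix_interior_is_fully_helical(self):
        helix = syn.ideal_alpha_helix(16)
        table = lsc.ss_occupancy(ConformationEnsemble([helix]))
        interior = table[(table.residue >= 5) & (table.residue <= 11)]
        assert np.allclose(interior.helix_fraction, 1.0)

    def test_extended_chain_has_no_secondary_structure(self):
        chain = syn.build_peptide_backbone(12, phi=-180.0, psi=180.0)
        table = lsc.ss_occupancy(ConformationEnsemble([chain]))
        assert np.allclose(table.helix_fraction, 0.0)
        assert np.allclose(table.sheet_fraction, 0.0)

    def test_fractions_are_a_partition_bound(self, small_ensemble):
        table = lsc.ss_occupancy(small_ensemble, mode="ca")
        assert np.all(table.helix_fraction + table.sheet_fraction <= 1.0)

    def test_backbone_mode_on_ca_only_input_directs_to_fallback(
            self, small_ensemble):
        with pytest.raises(ValueError, match="mode='ca'"):
            lsc.ss_occupancy(small_ensemble, mode="backbone")

    def test_ca_fallback_sees_toy_subdomain_helices(self, hinge_model):
        ens = ConformationEnsemble([hinge_model.template])
        table = lsc.ss_occupancy(ens, mode="ca")
        core = table[(table.residue >= 3) & (table.residue <= 17)]
        assert core.helix_fraction.mean() > 0.8
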