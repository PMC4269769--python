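"""NOE checking and Debye/χ² SAXS scoring."""

import numpy as np
import pytest

from repave import synthetic as syn
from repave import validation as val
from repave._geometry import fibonacci_sphere, rotation_matrix
from repave.ensemble_io import (ConformationEnsemble, NoeRestraint,
                                SaxsProfile, Structure, Topology)


def _beads(points):
    n = len(points)
    topo = Topology(["A"] * n, np.arange(1, n + 1), ["ALA"] * n,
                    ["CA"] * n, ["C"] * n)
    return Structure(topo, np.asarray(points, dtype=float))


class TestNoeCheck:
    def test_reference_fulfills_its_own_restraints(self, template):
        restraints = syn.synth_noe(template, 8.0, padding=0.5)
        report = val.noe_check(ConformationEnsemble([template]), restraints)
        assert report.fulfilled_percent == pytest.approx([100.0])
        assert report.violated_percent == pytest.approx([0.0])

    def test_unattainable_bounds_are_all_violated(self, template):
        restraints = [NoeRestraint(r.residue_i, "CA", r.residue_j, "CA", 0.1)
                      for r in syn.synth_noe(template, 8.0)]
        report = val.noe_check(ConformationEnsemble([template]), restraints,
                               tolerance=0.0)
        assert report.fulfilled_percent == pytest.approx([0.0])

    def test_fractions_match_brute_force_distance_check(self, small_ensemble,
                                                        hinge_model):
        restraints = syn.synth_noe(hinge_model.template, 10.0, padding=0.2)
        tol = 0.5
        report = val.noe_check(small_ensemble, restraints, tolerance=tol)
        for k in (0, 91):
            s = small_ensemble[k]
            ok = 0
            for r in restraints:
                d = np.linalg.norm(s.atom_position(r.residue_i, r.atom_i)
                                   - s.atom_position(r.residue_j, r.atom_j))
                ok += (r.lower_bound <= d <= r.upper_bound + tol)
            assert report.fulfilled_percent[k] == pytest.approx(
                100.0 * ok / len(restraints))

    def test_fractions_sum_to_hundred(self, small_ensemble, hinge_model):
        restraints = syn.synth_noe(hinge_model.template, 9.0)
        report = val.noe_check(small_ensemble, restraints)
        assert np.allclose(report.fulfilled_percent
                           + report.violated_percent, 100.0)

    def test_unresolvable_restraints_excluded_and_counted(self,
                                                          small_ensemble,
                                                          hinge_model):
        restraints = syn.synth_noe(hinge_model.template, 8.0)
        ghost = NoeRestraint(999, "CA", 1000, "CA", 5.0)
        report = val.noe_check(small_ensemble, restraints + [ghost])
        assert report.excluded == [ghost]
        assert report.n_checked == len(restraints)

    def test_r6_averaged_mode_runs(self, small_ensemble, hinge_model):
        restraints = syn.synth_noe(hinge_model.template, 8.0)
        report = val.noe_check(small_ensemble, restraints, r6_averaged=True)
        assert len(set(np.round(report.fulfilled_percent, 9))) == 1


class TestDebyeProfile:
    def test_two_identical_scatterers_closed_form(self):
        d = 7.3
        s = np.linspace(0.01, 0.45, 40)
        ff = val.FormFactorModel()
        prof = val.debye_profile(_beads([[0, 0, 0], [0, 0, d]]), s, ff)
        expected = 2 * ff(s) ** 2 * (1 + np.sin(s * d) / (s * d))
        assert np.allclose(prof.intensity, expected, rtol=1e-12)

    def test_single_scatterer_is_form_factor_squared(self):
        s = np.linspace(0.0, 0.4, 20)  # includes s = 0 (analytic limit)
        ff = val.FormFactorModel(amplitude=10.0)
        prof = val.debye_profile(_beads([[3.0, -1.0, 2.0]]), s, ff)
        assert np.allclose(prof.intensity, ff(s) ** 2)

    def test_dense_ball_approaches_analytic_sphere_factor(self, rng):
        radius = 10.0
        n = 1500
        r = radius * rng.random(n) ** (1 / 3)
        ball = _beads(fibonacci_sphere(n) * r[:, None])
        s = np.linspace(0.02, 0.29, 12)  # sR < 3
        prof = val.debye_profile(ball, s,
                                 val.FormFactorModel(amplitude=1.0, radius=0.0))
        x = s * radius
        analytic = (3 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
        ratio = prof.intensity / prof.intensity[0] / analytic
        assert np.abs(ratio - 1).max() < 0.05

    def test_rigid_body_invariance(self, template):
        s = np.linspace(0.01, 0.4, 25)
        base = val.debye_profile(template, s)
        rot = rotation_matrix([1.0, -2.0, 0.5], 2.2)
        moved = val.debye_profile(
            template.transformed(rotation=rot, translation=[10, -5, 3]), s)
        assert np.allclose(moved.intensity, base.intensity, rtol=1e-10)


class TestEnsembleProfile:
    def test_identical_structures_equal_single_profile(self, template):
        s = np.linspace(0.01, 0.4, 30)
        ens = ConformationEnsemble([template, template, template])
        assert np.allclose(val.ensemble_profile(ens, s).intensity,
                           val.debye_profile(template, s).intensity)

    def test_degenerate_weights_select_one_member(self, hinge_model):
        s = np.linspace(0.01, 0.4, 30)
        s1 = hinge_model.at_angle(90.0)
        s2 = hinge_model.at_angle(150.0)
        ens = ConformationEnsemble([s1, s2], weights=[1.0, 0.0])
        assert np.allclose(val.ensemble_profile(ens, s).intensity,
                           val.debye_profile(s1, s).intensity)

    def test_equals_brute_force_weighted_average(self, small_ensemble):
        s = np.linspace(0.01, 0.4, 20)
        prof = val.ensemble_profile(small_ensemble, s)
        brute = sum(w * val.debye_profile(st, s).intensity
                    for st, w in zip(small_ensemble, small_ensemble.weights))
        assert np.allclose(prof.intensity, brute, rtol=1e-12)


class TestChi2:
    def test_self_fit_is_zero_with_unit_scale(self, template):
        s = np.linspace(0.01, 0.4, 50)
        p = val.debye_profile(template, s)
        exp = SaxsProfile(s, p.intensity, 0.02 * p.intensity)
        fit = val.chi2_fit(p, exp)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-20)
        assert fit.scale == pytest.approx(1.0)

    def test_scale_freedom_absorbs_multiplicative_factor(self, template):
        s = np.linspace(0.01, 0.4, 50)
        p = val.debye_profile(template, s)
        exp = SaxsProfile(s, 2.0 * p.intensity)
        fit = val.chi2_fit(p, exp)
        assert fit.scale == pytest.approx(2.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)

    def test_matched_gaussian_noise_gives_unit_chi2(self, template):
        s = np.linspace(0.01, 0.4, 100)
        p = val.debye_profile(template, s)
        sigma = 0.02 * p.intensity
        chis = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            exp = SaxsProfile(s, p.intensity + rng.normal(0, sigma), sigma)
            chis.append(val.chi2_fit(p, exp).chi2)
        assert np.mean(chis) == pytest.approx(1.0, abs=0.1)
        assert sum(0.7 < c < 1.4 for c in chis) >= 18

    def test_zero_sigma_directs_to_unweighted_mode(self, template):
        s = np.linspace(0.01, 0.4, 10)
        p = val.debye_profile(template, s)
        exp = SaxsProfile(s, p.intensity, np.zeros(10))
        with pytest.raises(ValueError, match="unweighted"):
            val.chi2_fit(p, exp)

    def test_offset_fit_absorbs_additive_constant(self, template):
        s = np.linspace(0.01, 0.4, 50)
        p = val.debye_profile(template, s)
        exp = SaxsProfile(s, 1.5 * p.intensity + 40.0)
        fit = val.chi2_fit(p, exp, fit_offset=True)
        assert fit.scale == pytest.approx(1.5)
        assert fit.offset == pytest.approx(40.0)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_interpolates_calc_onto_experimental_grid(self, template):
        s_fine = np.linspace(0.005, 0.45, 400)
        s_exp = np.linspace(0.01, 0.4, 60)
        p = val.debye_profile(template, s_fine)
        exp = val.debye_profile(template, s_exp)
        fit = val.chi2_fit(p, SaxsProfile(s_exp, exp.intensity,
                                          0.01 * exp.intensity))
        assert fit.chi2 < 0.01


class TestCompareModels:
    def test_generating_ensemble_ranks_first_against_decoy(
            self, hinge_model, small_ensemble):
        s = np.linspace(0.01, 0.4, 80)
        exp = syn.synth_saxs(small_ensemble, s, noise_frac=0.02, seed=5)
        decoy = syn.sample_hinge_ensemble(
            hinge_model, syn.AngleDistributionSpec(145.0, 8.0), 200, seed=8)
        table = val.compare_models(
            {"generating": small_ensemble, "decoy": decoy}, exp)
        assert table.iloc[0]["name"] == "generating"

    def test_single_candidate_table(self, template):
        s = np.linspace(0.01, 0.4, 30)
        exp = val.debye_profile(template, s)
        table = val.compare_models({"only": template},
                                   SaxsProfile(s, exp.intensity))
        assert len(table) == 1

    def test_ranking_invariant_to_experimental_rescaling(
            self, hinge_model, small_ensemble):
        s = np.linspace(0.01, 0.4, 50)
        exp = syn.synth_saxs(small_ensemble, s, noise_frac=0.02, seed=5)
        scaled = SaxsProfile(s, 7.0 * exp.intensity, 7.0 * exp.sigma)
        decoy = syn.sample_hinge_ensemble(
            hinge_model, syn.AngleDistributionSpec(140.0, 10.0), 100, seed=9)
        t1 = val.compare_models({"a": small_ensemble, "b": decoy}, exp)
        t2 = val.compare_models({"a": small_ensemble, "b": decoy}, scaled)
        assert list(t1["name"]) == list(t2["name"])
        assert np.allclose(t1["chi2"], t2["chi2"], rtol=1e-9)

    def test_bootstrap_spread_is_finite_and_small_for_self_fit(
            self, small_ensemble):
        s = np.linspace(0.01, 0.4, 40)
        exp = syn.synth_saxs(small_ensemble, s, noise_frac=0.02, seed=3)
        mean, sd = val.chi2_bootstrap(small_ensemble, exp, n_blocks=5,
                                      n_boot=20, seed=0)
        assert mean > 0 and sd >= 0
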