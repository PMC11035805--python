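"""Synthetic-study generation: determinism, ground-truth structure and the
kinetics round trip."""

import numpy as np
import pandas as pd
import pytest

from cartdoe import kinetics as kin, mlr, synthetic as syn


class TestGenerateResponses:
    def test_degenerate_noiseless_case_is_constant(self, space):
        truth = syn.GroundTruth("resp", intercept=50.0, coefficients={})
        study = syn.make_study(seed=3, truths=[truth])
        table = syn.generate_responses(study)
        np.testing.assert_allclose(table["resp"], 50.0)

    def test_coded_effect_doubles_across_levels(self, space):
        """coefficient -1.2 on activations (coded -1/+1) separates the two
        groups by exactly 2.4 in the noiseless case."""
        truth = syn.GroundTruth("cpd", intercept=3.6,
                                coefficients={("activations",): -1.2})
        study = syn.make_study(seed=5, truths=[truth])
        table = syn.generate_responses(study)
        means = table.groupby("activations")["cpd"].mean()
        assert means[1] - means[2] == pytest.approx(2.4, rel=1e-12)

    def test_same_seed_identical_tables(self, study42):
        a = syn.generate_responses(study42)
        b = syn.generate_responses(study42)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, space):
        s1 = syn.make_study(seed=1)
        s2 = syn.SyntheticStudy(design=s1.design, truths=s1.truths, seed=2,
                                donors=3, space=space)
        assert not syn.generate_responses(s1)["cpd"].equals(
            syn.generate_responses(s2)["cpd"])

    def test_unknown_factor_in_truth_rejected(self, space):
        truth = syn.GroundTruth("resp", 1.0, {("temperature",): 2.0})
        study = syn.make_study(seed=0)
        study.truths = [truth]
        with pytest.raises(syn.SyntheticConfigError):
            syn.generate_responses(study)

    def test_bounded_responses_clipped(self, space):
        truth = syn.GroundTruth("pct", intercept=99.0,
                                coefficients={("activations",): 30.0},
                                bounds=(0.0, 100.0))
        study = syn.make_study(seed=0, truths=[truth])
        table = syn.generate_responses(study)
        assert table["pct"].max() <= 100.0
        assert table["pct"].min() >= 0.0

    def test_fold_derived_from_cpd(self, responses42):
        np.testing.assert_allclose(responses42["fold"],
                                   2.0 ** responses42["cpd"], rtol=1e-12)

    def test_noiseless_recovery_of_ground_truth(self, space):
        """With residual and donor noise at zero, elimination recovers every
        nonzero coefficient to 1e-6 and removes every zero coefficient."""
        truths = syn.default_truths(space, residual_frac=0.0, donor_frac=0.0)
        study = syn.make_study(seed=9, truths=truths)
        table = syn.generate_responses(study)
        truth = study.truth("cpd")
        model = mlr.backward_eliminate(space, table, table["cpd"].to_numpy())
        kept = set(model.terms) - {()}
        assert kept == truth.nonzero_terms()
        for term, coef in truth.coefficients.items():
            if coef != 0.0:
                assert model.coefficient(term) == pytest.approx(coef, abs=1e-6)
        assert model.coefficient(()) == pytest.approx(truth.intercept, abs=1e-6)


class TestGenerateTimeSeries:
    def test_final_density_is_two_to_the_cpd(self):
        run = syn.generate_time_series(target_cpd=3, days=7,
                                       initial_density=0.5e6, seed=0)
        assert run.series.viable_density[-1] == pytest.approx(4.0e6, rel=1e-12)

    def test_pure_glycolysis_stoichiometry(self):
        """lactate_per_glucose = 2, no noise: cumulative lactate rise equals
        twice the cumulative glucose drop, interval by interval."""
        stoich = syn.StoichiometryProfile(lactate_per_glucose=2.0)
        run = syn.generate_time_series(target_cpd=4, days=7, stoich=stoich, seed=0)
        gluc = run.panels["glucose"].concentrations
        lac = run.panels["lactate"].concentrations
        np.testing.assert_allclose(lac - lac[0], 2.0 * (gluc[0] - gluc),
                                   rtol=1e-12)

    def test_kinetics_round_trip_recovers_rates(self):
        """The kinetics stage applied to a noiseless generated series returns
        the generating q within 1e-9 relative error."""
        run = syn.generate_time_series(target_cpd=4.5, days=7, seed=0)
        s = kin.kinetic_summary(run.series, run.panels)
        np.testing.assert_allclose(s.q["glucose"], run.true_q["glucose"],
                                   rtol=1e-9)
        np.testing.assert_allclose(s.p["lactate"], run.true_p["lactate"],
                                   rtol=1e-9)
        np.testing.assert_allclose(s.mu, run.true_mu, rtol=1e-9)

    def test_round_trip_under_perfusion(self):
        run = syn.generate_time_series(target_cpd=3.0, days=7, seed=0,
                                       perfusion=0.3)
        s = kin.kinetic_summary(run.series, run.panels)
        np.testing.assert_allclose(s.q["glucose"], run.true_q["glucose"],
                                   rtol=1e-9)

    def test_concentrations_never_negative_with_cap(self):
        """Excessive demand triggers the availability cap and a warning, not
        negative concentrations."""
        stoich = syn.StoichiometryProfile(lactate_per_glucose=2.0,
                                          glucose_per_doubling=0.1)
        with pytest.warns(UserWarning):
            run = syn.generate_time_series(target_cpd=7, days=7, stoich=stoich,
                                           seed=0)
        assert np.all(run.panels["glucose"].concentrations >= 0)

    def test_deterministic_given_seed(self):
        a = syn.generate_time_series(target_cpd=4, days=7, seed=8, noise_sd=0.05)
        b = syn.generate_time_series(target_cpd=4, days=7, seed=8, noise_sd=0.05)
        np.testing.assert_array_equal(a.series.viable_density,
                                      b.series.viable_density)
        np.testing.assert_array_equal(a.panels["lactate"].concentrations,
                                      b.panels["lactate"].concentrations)

    def test_too_few_days_rejected(self):
        with pytest.raises(syn.SyntheticConfigError):
            syn.generate_time_series(target_cpd=2, days=1)

    def test_stoichiometry_bounds(self):
        with pytest.raises(syn.SyntheticConfigError):
            syn.StoichiometryProfile(lactate_per_glucose=2.5)

    def test_pinned_window_average_glucose_rate(self):
        run = syn.generate_time_series(target_cpd=4, days=7, seed=0,
                                       initial_density=0.1e6, q_gluc_pmol=1.5)
        s = kin.kinetic_summary(run.series, run.panels)
        assert s.q_avg["glucose"] == pytest.approx(1.5, rel=1e-9)


class TestStudyAssembly:
    def test_design_covers_every_factor(self, study42, space):
        for f in space.factors:
            assert study42.design[f.name].nunique() >= 2

    def test_donors_cycle(self, study42):
        assert set(study42.design["donor_id"]) == {"HD1", "HD2", "HD3"}

    def test_study_time_series_consistent_with_responses(self, study42,
                                                         responses42):
        """Noiseless per-run series reproduce the tabulated cpd, window
        glucose rate and lactate yield through the kinetics stage."""
        runs = syn.generate_study_time_series(study42, responses42,
                                              noise_sd=0.0)
        row = responses42.iloc[4]
        s = kin.kinetic_summary(runs[row["run_id"]].series,
                                runs[row["run_id"]].panels)
        assert s.cpd[-1] == pytest.approx(row["cpd"], rel=1e-9)
        assert s.q_avg["glucose"] == pytest.approx(row["q_gluc"], rel=1e-9)
        assert s.dlac_dgluc == pytest.approx(row["dlac_dgluc"], rel=1e-6)
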