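"""OLS fitting, leave-one-out Q2, backward elimination and effect views."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cartdoe import design as dsn, mlr, synthetic as syn


def _loo_press_refit(X, y):
    """Independent oracle: refit n times with one row held out."""
    n = len(y)
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        press += (y[i] - X[i] @ beta) ** 2
    return press


class TestFitOLS:
    def test_coefficients_match_normal_equations(self):
        """Six-run coded dataset against the closed-form (X'X)^-1 X'y."""
        X = np.array([
            [1, -1, -1], [1, -1, 1], [1, 0, -1],
            [1, 0, 1], [1, 1, -1], [1, 1, 1],
        ], dtype=float)
        y = np.array([2.0, 3.5, 4.0, 5.5, 6.0, 8.0])
        terms = [dsn.INTERCEPT, ("a",), ("b",)]
        model = mlr.fit_ols(X, y, terms)
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.coefficients, beta_oracle, rtol=1e-12)

    def test_perfect_linear_fit(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = 3.0 + 2.0 * np.arange(8.0)
        model = mlr.fit_ols(X, y, [dsn.INTERCEPT, ("x",)])
        assert model.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(model.residuals, 0.0, atol=1e-10)

    def test_constant_response_gives_zero_slopes(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        y = np.full(10, 5.0)
        model = mlr.fit_ols(X, y, [dsn.INTERCEPT, ("x",)])
        assert model.coefficients[1] == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_named(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(mlr.RankDeficiencyError):
            mlr.fit_ols(X, np.arange(6.0), [dsn.INTERCEPT, ("a",), ("b",)])

    def test_more_terms_than_runs_rejected(self):
        X = np.ones((2, 3))
        with pytest.raises(mlr.ModelError):
            mlr.fit_ols(X, np.zeros(2), [dsn.INTERCEPT, ("a",), ("b",)])


class TestQSquared:
    def test_noiseless_linear_data(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = 1.0 + 0.5 * np.arange(8.0)
        q2, press = mlr.q_squared(X, y)
        assert q2 == pytest.approx(1.0, abs=1e-10)
        assert press == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_hand_example(self):
        """y = [1,2,3]: LOO means give PRESS = 4.5, SStot = 2, Q2 = -1.25."""
        X = np.ones((3, 1))
        y = np.array([1.0, 2.0, 3.0])
        q2, press = mlr.q_squared(X, y)
        assert press == pytest.approx(4.5)
        assert q2 == pytest.approx(-1.25)

    def test_hat_matrix_equals_refit_oracle(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
        y = rng.normal(size=20)
        _, press = mlr.q_squared(X, y)
        assert press == pytest.approx(_loo_press_refit(X, y), rel=1e-10)

    def test_leverage_one_rejected(self):
        # a saturated run: its own hat diagonal is 1
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(mlr.ModelError):
            mlr.q_squared(X, np.array([1.0, 2.0, 3.0]))

    def test_q2_never_exceeds_r2(self, rng):
        for _ in range(20):
            X = np.column_stack([np.ones(15), rng.normal(size=(15, 4))])
            y = X @ rng.normal(size=5) + rng.normal(size=15)
            terms = [dsn.INTERCEPT] + [(f"x{i}",) for i in range(4)]
            model = mlr.fit_ols(X, y, terms)
            assert model.q2 <= model.r2 + 1e-12


class TestBackwardElimination:
    def _fit(self, space, table, response, **kw):
        return mlr.backward_eliminate(space, table, table[response].to_numpy(),
                                      response_name=response, **kw)

    def test_pure_noise_term_dropped(self, space):
        """IL-2 has a true zero effect; with strong signals elsewhere it is
        eliminated (fixed seed)."""
        study = syn.make_study(seed=11)
        table = syn.generate_responses(study)
        model = self._fit(space, table, "cpd")
        assert ("il2_iu_per_ml",) not in model.terms

    def test_true_signal_terms_retained(self, space, study42, responses42,
                                        growth_model):
        truth = study42.truth("cpd")
        for term in truth.nonzero_terms():
            assert term in growth_model.terms

    def test_hierarchy_forces_parent_mains(self, space, rng):
        """A strong interaction with a null main effect keeps the main in the
        model, flagged as hierarchy-retained."""
        cand = space.candidate_set()
        X, terms = dsn.model_matrix(space, cand)
        # pure interaction signal, no activations main effect
        beta = {t: 0.0 for t in terms}
        beta[("activations", "seed_train_days")] = 3.0
        beta[("seed_train_days",)] = 1.0
        y = X @ np.array([beta[t] for t in terms]) + rng.normal(0, 0.3, len(cand))
        model = mlr.backward_eliminate(space, cand, y)
        assert ("activations", "seed_train_days") in model.terms
        assert ("activations",) in model.terms
        assert ("activations",) in model.hierarchy_terms

    def test_all_signal_model_untouched(self, space, rng):
        cand = space.candidate_set()
        terms = [dsn.INTERCEPT] + dsn.main_effect_terms(space)
        X, terms = dsn.model_matrix(space, cand, terms)
        y = X @ np.array([5.0, 2.0, -1.5, 1.0, 2.5]) + rng.normal(0, 0.1, len(cand))
        model = mlr.backward_eliminate(space, cand, y, terms=terms)
        assert set(model.terms) == set(terms)

    def test_idempotent(self, space, study42, responses42, growth_model):
        again = mlr.backward_eliminate(
            study42.space, responses42, responses42["cpd"].to_numpy(),
            terms=growth_model.terms, response_name="cpd")
        assert again.terms == growth_model.terms
        np.testing.assert_allclose(again.coefficients, growth_model.coefficients)

    def test_retention_monotone_in_alpha(self, space, study42, responses42):
        loose = self._fit(space, responses42, "cpd", alpha=0.5)
        strict = self._fit(space, responses42, "cpd", alpha=0.05)
        assert len(loose.terms) >= len(strict.terms)

    def test_may_return_intercept_only(self, space, rng):
        cand = space.candidate_set()
        y = rng.normal(size=len(cand))
        model = mlr.backward_eliminate(space, cand, y)
        assert dsn.INTERCEPT in model.terms


class TestModelSignificance:
    def test_perfect_fit_p_zero(self, space):
        cand = space.candidate_set()
        X, terms = dsn.model_matrix(space, cand,
                                    [dsn.INTERCEPT] + dsn.main_effect_terms(space))
        y = X @ np.array([1.0, 2.0, 1.0, 0.5, 0.25])
        model = mlr.fit_ols(X, y, terms)
        assert mlr.model_significance(model) == pytest.approx(0.0, abs=1e-12)

    def test_single_factor_anova_hand_oracle(self):
        """Two-level one-factor fit: overall F equals the hand-computed
        between/within ratio."""
        x = np.array([-1, -1, -1, 1, 1, 1], dtype=float)
        y = np.array([2.0, 3.0, 2.5, 6.0, 7.0, 6.5])
        X = np.column_stack([np.ones(6), x])
        model = mlr.fit_ols(X, y, [dsn.INTERCEPT, ("x",)])
        g1, g2 = y[:3], y[3:]
        ssb = 3 * ((g1.mean() - y.mean()) ** 2 + (g2.mean() - y.mean()) ** 2)
        ssw = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        f_hand = (ssb / 1) / (ssw / 4)
        p_hand = stats.f.sf(f_hand, 1, 4)
        assert mlr.model_significance(model) == pytest.approx(p_hand, rel=1e-10)

    def test_intercept_only_signalled(self):
        X = np.ones((5, 1))
        model = mlr.fit_ols(X, np.arange(5.0), [dsn.INTERCEPT])
        with pytest.raises(mlr.ModelError):
            mlr.model_significance(model)


class TestEffectViews:
    def test_zero_interaction_gives_parallel_lines(self, space, rng):
        cand = space.candidate_set()
        terms = [dsn.INTERCEPT, ("activations",), ("seed_train_days",)]
        X, terms = dsn.model_matrix(space, cand, terms)
        y = X @ np.array([3.0, -1.0, -0.5])
        model = mlr.fit_ols(X, y, terms)
        view = mlr.interaction_view(model, space, "seed_train_days", "activations")
        lines = view.pivot(index="seed_train_days", columns="activations",
                           values="predicted")
        gaps = lines[2.0] - lines[1.0]
        assert gaps.std() == pytest.approx(0.0, abs=1e-10)

    def test_main_effects_contour_isolines_straight(self, space):
        cand = space.candidate_set()
        terms = [dsn.INTERCEPT, ("seed_train_days",), ("seeding_density",)]
        X, terms = dsn.model_matrix(space, cand, terms)
        model = mlr.fit_ols(X, X @ np.array([2.0, 1.0, 0.5]), terms)
        grid = mlr.contour_grid(model, space, "seed_train_days", "seeding_density", n=5)
        # additive surface: mixed second difference vanishes
        z = grid.pivot(index="seeding_density", columns="seed_train_days",
                       values="predicted").to_numpy()
        mixed = np.diff(np.diff(z, axis=0), axis=1)
        np.testing.assert_allclose(mixed, 0.0, atol=1e-10)

    def test_training_predictions_equal_fitted_values(self, space, study42,
                                                      responses42, growth_model):
        fitted = growth_model.predict(study42.space, responses42)
        X, _ = dsn.model_matrix(study42.space, responses42, growth_model.terms)
        np.testing.assert_allclose(fitted, X @ growth_model.coefficients, rtol=1e-12)

    def test_factor_not_in_model_rejected(self, space, growth_model):
        with pytest.raises(mlr.ModelError):
            mlr.interaction_view(growth_model, space, "il2_iu_per_ml", "activations")

    def test_coefficient_table_ci_width(self, space, growth_model):
        tab = mlr.coefficient_table(growth_model)
        tcrit = stats.t.ppf(0.975, growth_model.df_resid)
        np.testing.assert_allclose(
            tab["ci_hi"] - tab["ci_lo"], 2 * tcrit * tab["se"], rtol=1e-12)
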