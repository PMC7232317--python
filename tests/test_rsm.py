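import itertools

import numpy as np
import pytest

import rsmkin as rk
from rsmkin.errors import InvalidInputError, SingularDesignError
from rsmkin.rsm import ResponseDataset, quadratic_model_matrix

from conftest import loo_press


def make_dataset(y, n_center=10, se=None, n_rep=3):
    table = rk.generate_ccd(rk.default_factors(), n_center=n_center)
    return ResponseDataset(table.with_responses(y, se, n_rep))


def truth_response(table, beta):
    return quadratic_model_matrix(table.coded) @ np.asarray(beta)


class TestFitQuadratic:
    def test_reference_table_reproduces_published_equation(self, ref_fit):
        """The means fit of the 24-run table gives the published coded equation."""
        assert ref_fit.intercept == pytest.approx(94.23, abs=0.005)
        assert ref_fit.coef("pH") == pytest.approx(-0.1231, abs=0.005)
        assert ref_fit.coef("temperature") == pytest.approx(-0.2929, abs=0.005)
        assert ref_fit.coef("time") == pytest.approx(4.04, abs=0.005)
        assert ref_fit.coef("pH:temperature") == pytest.approx(-1.25, abs=0.005)
        assert ref_fit.coef("temperature:time") == pytest.approx(-4.50, abs=0.005)
        assert abs(ref_fit.coef("pH:time")) == pytest.approx(2.00, abs=0.02)
        assert ref_fit.coef("pH^2") == pytest.approx(-6.74, abs=0.005)

    def test_constant_response_gives_pure_intercept(self):
        ds = make_dataset(np.full(24, 42.0))
        fit = rk.fit_quadratic(ds)
        assert fit.intercept == pytest.approx(42.0, abs=1e-10)
        assert np.allclose(fit.beta[1:], 0.0, atol=1e-10)

    def test_noiseless_surface_recovered_exactly(self):
        truth = np.zeros(10)
        truth[0], truth[1] = 90.0, 2.0
        truth[5] = -1.0  # pH:time interaction slot
        truth[9] = -4.0  # time^2 slot
        table = rk.generate_ccd(rk.default_factors(), n_center=10)
        ds = ResponseDataset(table.with_responses(truth_response(table, truth)))
        fit = rk.fit_quadratic(ds)
        assert np.allclose(fit.beta, truth, atol=1e-10)

    def test_sum_of_squares_decomposition(self, ref_fit):
        assert ref_fit.sst == pytest.approx(ref_fit.ssr + ref_fit.sse, rel=1e-8)
        assert ref_fit.n_params == 10
        assert ref_fit.df_resid == 14

    def test_run_order_invariance(self, ref_dataset, ref_fit):
        shuffled = rk.randomize_runs(ref_dataset.design, seed=3)
        fit2 = rk.fit_quadratic(ResponseDataset(shuffled))
        assert np.allclose(fit2.beta, ref_fit.beta, atol=1e-10)

    def test_replicate_basis_matches_means_basis(self, ref_dataset, ref_fit):
        """On the balanced design, expanding mean +/- SE into pseudo-replicates
        leaves the coefficient estimates unchanged."""
        fit_rep = rk.fit_quadratic(ref_dataset, basis="replicates")
        assert fit_rep.n_obs == 72
        assert np.allclose(fit_rep.beta, ref_fit.beta, atol=1e-8)

    def test_singular_design_names_columns(self):
        table = rk.generate_ccd(rk.default_factors(), n_center=10)
        runs = table.runs.copy()
        runs["x_time"] = runs["x_pH"]  # collinear factor columns
        runs = runs.drop(columns=["X_pH", "X_temperature", "X_time"])
        broken = rk.DesignTable(table.factors, runs).with_responses(np.arange(24.0))
        with pytest.raises(SingularDesignError) as err:
            rk.fit_quadratic(ResponseDataset(broken))
        assert err.value.columns  # names at least one collinear term

    def test_too_few_runs_is_singular(self, ref_dataset):
        small = ResponseDataset(
            rk.DesignTable(
                ref_dataset.design.factors, ref_dataset.design.runs.iloc[:8].copy()
            )
        )
        with pytest.raises(SingularDesignError):
            rk.fit_quadratic(small)


class TestAnova:
    def test_reference_summary_statistics(self, ref_anova):
        assert ref_anova.adj_r2 == pytest.approx(0.9823, abs=0.002)
        assert ref_anova.pred_r2 == pytest.approx(0.9412, abs=0.01)
        assert ref_anova.cv == pytest.approx(1.64, abs=0.05)
        assert ref_anova.f_value == pytest.approx(143.23, rel=0.02)
        assert ref_anova.p_value < 0.05

    def test_press_equals_explicit_loo_refits(self, ref_fit, ref_anova):
        assert ref_anova.press == pytest.approx(loo_press(ref_fit), rel=1e-8)

    def test_predicted_r2_below_r2(self, ref_anova):
        assert 0.0 <= ref_anova.r2 <= 1.0
        assert ref_anova.adj_r2 <= ref_anova.r2
        assert ref_anova.pred_r2 <= ref_anova.r2
        assert ref_anova.press >= 0.0

    def test_press_not_below_sse_on_simulated_datasets(self):
        truth = rk.reference_truth(noise_sd=0.8)
        table = rk.generate_ccd(rk.default_factors(), n_center=10)
        for seed in range(10):
            ds = rk.simulate_response_surface(truth, table, seed)
            fit = rk.fit_quadratic(ds)
            rep = rk.anova(fit)
            assert rep.press >= fit.sse - 1e-9
            assert rep.pred_r2 <= rep.r2 + 1e-12

    def test_perfect_fit_flagged(self):
        truth = np.zeros(10)
        truth[0] = 80.0
        truth[3] = 3.0
        table = rk.generate_ccd(rk.default_factors(), n_center=10)
        ds = ResponseDataset(table.with_responses(truth_response(table, truth)))
        rep = rk.anova(rk.fit_quadratic(ds))
        assert rep.perfect_fit
        assert rep.r2 == pytest.approx(1.0)
        assert np.isinf(rep.f_value)


class TestPredict:
    def test_center_prediction_is_intercept(self, ref_fit):
        assert rk.predict(ref_fit, [0, 0, 0]) == pytest.approx(ref_fit.intercept)
        assert rk.predict(ref_fit, [0, 0, 0]) == pytest.approx(94.23, abs=0.005)

    def test_zero_model_predicts_zero(self):
        table = rk.generate_ccd(rk.default_factors(), n_center=10)
        ds = ResponseDataset(table.with_responses(np.zeros(24)))
        fit = rk.fit_quadratic(ds)
        pts = np.random.default_rng(0).uniform(-1.68, 1.68, size=(20, 3))
        assert np.allclose(rk.predict(fit, pts), 0.0, atol=1e-10)

    def test_published_equation_at_factorial_vertex(self):
        """Hand evaluation of the published coefficients (with the pH:time
        interaction carrying the refit sign -2.00) at (+1, +1, -1)."""
        beta = np.array(
            [94.23, -0.1231, -0.2929, 4.04, -1.25, -2.00, -4.50, -6.74, -6.91, -5.11]
        )
        table = rk.generate_ccd(rk.default_factors(), n_center=10)
        ds = ResponseDataset(table.with_responses(truth_response(table, beta)))
        fit = rk.fit_quadratic(ds)
        assert rk.predict(fit, [1.0, 1.0, -1.0]) == pytest.approx(76.264, abs=1e-6)

    def test_prediction_se_positive(self, ref_fit):
        yhat, se = rk.predict(ref_fit, [0.5, -0.5, 1.0], se=True)
        assert se > 0

    def test_wrong_dimension_rejected(self, ref_fit):
        with pytest.raises(InvalidInputError):
            rk.predict(ref_fit, [0.0, 0.0])


class TestDiagnostics:
    def test_leverage_sums_to_parameter_count(self, ref_fit):
        diag = rk.diagnostics(ref_fit)
        assert diag.leverage.sum() == pytest.approx(10.0, abs=1e-8)
        assert np.all(diag.leverage >= 0) and np.all(diag.leverage <= 1)
        assert np.all(diag.cooks_d >= 0)

    def test_center_replicates_share_leverage(self, ref_dataset, ref_fit):
        diag = rk.diagnostics(ref_fit)
        center = (ref_dataset.design.runs["class"] == "center").to_numpy()
        assert np.ptp(diag.leverage[center]) == pytest.approx(0.0, abs=1e-12)

    def test_external_studentized_matches_loo_refits(self, ref_fit):
        """Each externally studentized residual equals the statistic from an
        explicit refit without that observation."""
        diag = rk.diagnostics(ref_fit)
        X, y = ref_fit.X, ref_fit.y
        n, p = X.shape
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
            resid = y[keep] - X[keep] @ beta
            s2 = resid @ resid / (n - 1 - p)
            xi = X[i]
            var_pred = s2 * (1 + xi @ np.linalg.inv(X[keep].T @ X[keep]) @ xi)
            t_i = (y[i] - xi @ beta) / np.sqrt(var_pred)
            assert diag.table["student_external"].iloc[i] == pytest.approx(
                t_i, rel=1e-8
            )


class TestGroupLetters:
    def test_identical_means_share_one_letter(self):
        letters = rk.group_letters([5.0] * 6, [0.3] * 6, [3] * 6)
        assert letters == ["a"] * 6

    def test_extreme_reference_runs_disjoint(self, ref_dataset):
        """Run 6 (64.0%) and run 10 (95.6%) must not share a letter."""
        letters = rk.group_letters(
            ref_dataset.y_mean, ref_dataset.y_se, ref_dataset.n_rep
        )
        assert not set(letters[5]) & set(letters[9])

    def test_two_well_separated_groups(self):
        """Two synthetic groups 20 pooled SDs apart get exactly two letters,
        consistent with brute-force pairwise LSD tests."""
        means = np.array([10.0, 10.1, 9.9, 30.0, 30.1, 29.9])
        se = np.full(6, 0.5 / np.sqrt(3))  # replicate SD 0.5
        letters = rk.group_letters(means, se, np.full(6, 3))
        assert len(set("".join(letters))) == 2
        assert letters[0] == letters[1] == letters[2]
        assert letters[3] == letters[4] == letters[5]
        assert letters[0] != letters[3]

    def test_letters_consistent_with_all_pairs_tests(self, ref_dataset):
        """Sharing a letter must coincide with pairwise LSD non-significance."""
        from scipy import stats

        means, se, n = ref_dataset.y_mean, ref_dataset.y_se, ref_dataset.n_rep
        letters = rk.group_letters(means, se, n)
        s2 = (se * np.sqrt(n)) ** 2
        df = int(np.sum(n - 1))
        s2p = np.sum((n - 1) * s2) / df
        tcrit = stats.t.ppf(0.975, df)
        for i, j in itertools.combinations(range(len(means)), 2):
            lsd = tcrit * np.sqrt(s2p * (1 / n[i] + 1 / n[j]))
            significant = abs(means[i] - means[j]) > lsd
            shared = bool(set(letters[i]) & set(letters[j]))
            assert shared == (not significant), (i, j, letters[i], letters[j])

    def test_zero_variance_degenerates_to_exact_equality(self):
        letters = rk.group_letters([1.0, 1.0, 2.0], [0.0] * 3, [3] * 3)
        assert letters[0] == letters[1]
        assert not set(letters[0]) & set(letters[2])
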