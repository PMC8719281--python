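"""Quantile regression, region scoring and QRI aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from braindex import (ConfigurationError, DegenerateDesignError,
                      InsufficientDataError, QuantileFit, aggregate_qri,
                      compute_qri, fit_quantile_models,
                      fit_quantile_regression, score_region)

TAUS = (0.05, 0.50, 0.95)


def check_loss(y, age, intercept, slope, tau):
    u = y - intercept - slope * age
    return float(np.sum(u * (tau - (u < 0))))


def vertex_oracle(y, age, tau):
    """Exhaustive search over all two-point interpolating lines (LP vertex
    property): the check-loss minimizer passes through two observations."""
    best = (np.inf, None)
    for i, j in itertools.combinations(range(len(y)), 2):
        if age[i] == age[j]:
            continue
        slope = (y[j] - y[i]) / (age[j] - age[i])
        intercept = y[i] - slope * age[i]
        loss = check_loss(y, age, intercept, slope, tau)
        if loss < best[0]:
            best = (loss, (intercept, slope))
    return best


class TestFitQuantileRegression:
    def test_constant_y_returns_flat_line(self, rng):
        age = rng.uniform(45, 80, 30)
        for tau in TAUS:
            fit = fit_quantile_regression(np.full(30, 3.7), age, tau)
            assert (fit.intercept, fit.slope) == (3.7, 0.0)

    def test_noise_free_line_recovered_at_every_tau(self, rng):
        age = rng.uniform(45, 80, 50)
        y = 2.0 + 0.5 * age
        for tau in TAUS:
            fit = fit_quantile_regression(y, age, tau)
            assert fit.intercept == pytest.approx(2.0, abs=1e-6)
            assert fit.slope == pytest.approx(0.5, abs=1e-8)

    def test_matches_vertex_enumeration_on_small_data(self, rng):
        for _ in range(5):
            age = rng.uniform(45, 80, 12)
            y = 2.5 - 0.01 * age + rng.normal(0, 0.1, 12)
            for tau in TAUS:
                fit = fit_quantile_regression(y, age, tau)
                loss_oracle, coef_oracle = vertex_oracle(y, age, tau)
                loss_fit = check_loss(y, age, fit.intercept, fit.slope, tau)
                assert loss_fit == pytest.approx(loss_oracle, abs=1e-8)
                assert fit.intercept == pytest.approx(coef_oracle[0], abs=1e-6)
                assert fit.slope == pytest.approx(coef_oracle[1], abs=1e-8)

    def test_beats_best_constant_model(self, rng):
        age = rng.uniform(45, 80, 100)
        y = 2.5 - 0.01 * age + rng.normal(0, 0.1, 100)
        for tau in TAUS:
            fit = fit_quantile_regression(y, age, tau)
            const_loss = min(check_loss(y, age, c, 0.0, tau) for c in y)
            assert fit.check_loss(y, age) <= const_loss + 1e-9

    def test_coverage_close_to_tau(self, rng):
        age = rng.uniform(45, 80, 2000)
        y = 2.5 - 0.01 * age + rng.normal(0, 0.1, 2000)
        for tau in TAUS:
            fit = fit_quantile_regression(y, age, tau)
            below = np.mean(y < fit.predict(age))
            assert below == pytest.approx(tau, abs=0.02)

    def test_agrees_with_statsmodels_quantreg(self, rng):
        import statsmodels.api as sm
        age = rng.uniform(45, 80, 500)
        y = 2.5 - 0.01 * age + rng.normal(0, 0.1, 500)
        X = sm.add_constant(age)
        for tau in TAUS:
            fit = fit_quantile_regression(y, age, tau)
            ref = sm.QuantReg(y, X).fit(q=tau)
            # IRLS is approximate; our exact LP loss must not exceed it
            assert fit.check_loss(y, age) <= check_loss(
                y, age, ref.params[0], ref.params[1], tau) + 1e-6
            assert fit.intercept == pytest.approx(ref.params[0], abs=5e-2)
            assert fit.slope == pytest.approx(ref.params[1], abs=1e-3)

    def test_deterministic_given_input_order(self, rng):
        age = rng.uniform(45, 80, 200)
        y = 2.5 - 0.01 * age + rng.normal(0, 0.1, 200)
        a = fit_quantile_regression(y, age, 0.05)
        b = fit_quantile_regression(y, age, 0.05)
        assert (a.intercept, a.slope) == (b.intercept, b.slope)

    def test_preconditions(self, rng):
        age = rng.uniform(45, 80, 30)
        y = rng.normal(size=30)
        with pytest.raises(InsufficientDataError):
            fit_quantile_regression(y[:5], age[:5], 0.5)
        with pytest.raises(DegenerateDesignError):
            fit_quantile_regression(y, np.full(30, 60.0), 0.5)
        with pytest.raises(ConfigurationError):
            fit_quantile_regression(y, age, 1.5)


class TestScoreRegion:
    FIT05 = QuantileFit("p", 0.05, 1.0, 0.0, 100)
    FIT95 = QuantileFit("p", 0.95, 3.0, 0.0, 100)

    def test_boundary_equality_scores_zero(self):
        assert score_region([1.0], self.FIT05, self.FIT95, [60.0])[0] == 0
        assert score_region([3.0], self.FIT05, self.FIT95, [60.0])[0] == 0

    def test_below_lower_quantile_scores_plus_one(self):
        # older-looking structure than expected for this age
        assert score_region([0.9], self.FIT05, self.FIT95, [60.0])[0] == 1

    def test_above_upper_quantile_scores_minus_one(self):
        assert score_region([3.1], self.FIT05, self.FIT95, [60.0])[0] == -1

    def test_missing_value_scores_missing(self):
        out = score_region([np.nan, 2.0], self.FIT05, self.FIT95, [60.0, 60.0])
        assert np.isnan(out[0]) and out[1] == 0

    def test_crossed_quantiles_warn_but_score(self):
        crossed_hi = QuantileFit("p", 0.95, 0.5, 0.0, 100)
        with pytest.warns(UserWarning, match="crossing"):
            out = score_region([0.7], self.FIT05, crossed_hi, [60.0])
        assert out[0] == 1  # below the 5th line, per the same strict rule

    def test_mismatched_phenotypes_rejected(self):
        other = QuantileFit("q", 0.95, 3.0, 0.0, 100)
        with pytest.raises(ConfigurationError):
            score_region([2.0], self.FIT05, other, [60.0])

    def test_label_symmetry_under_negation(self, rng):
        age = rng.uniform(45, 80, 50)
        v = rng.normal(2.0, 1.0, 50)
        f05 = QuantileFit("p", 0.05, 0.5, 0.01, 50)
        f95 = QuantileFit("p", 0.95, 3.5, 0.01, 50)
        plain = score_region(v, f05, f95, age)
        neg05 = QuantileFit("p", 0.05, -3.5, -0.01, 50)
        neg95 = QuantileFit("p", 0.95, -0.5, -0.01, 50)
        assert np.array_equal(score_region(-v, neg05, neg95, age), -plain)


class TestAggregateQri:
    TISSUES = pd.Series({"t1": "thickness", "t2": "thickness",
                         "v1": "subcortical_volume", "f1": "FA"})

    def test_all_zero_scores_give_zero_qris(self):
        scores = pd.DataFrame(0.0, index=["a", "b"],
                              columns=list(self.TISSUES.index))
        out = aggregate_qri(scores, self.TISSUES)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_symmetric_tissues_cancel_in_whole_brain(self):
        scores = pd.DataFrame([[1, 1, 0, -1]], index=["a"],
                              columns=list(self.TISSUES.index))
        out = aggregate_qri(scores, self.TISSUES)
        assert out.loc["a", "qri_thickness"] == 1
        assert out.loc["a", "qri_subcort"] == 0
        assert out.loc["a", "qri_fa"] == -1
        assert out.loc["a", "qri_whole"] == 0

    def test_matches_groupby_mean_oracle(self, rng):
        scores = pd.DataFrame(
            rng.integers(-1, 2, size=(30, 4)).astype(float),
            index=[f"S{i}" for i in range(30)],
            columns=list(self.TISSUES.index))
        out = aggregate_qri(scores, self.TISSUES)
        oracle = scores.T.groupby(self.TISSUES).mean().T
        assert np.allclose(out["qri_thickness"], oracle["thickness"])
        assert np.allclose(out["qri_fa"], oracle["FA"])
        assert np.allclose(
            out["qri_whole"],
            (oracle["thickness"] + oracle["subcortical_volume"]
             + oracle["FA"]) / 3)

    def test_whole_brain_qri_bounded(self, rng):
        scores = pd.DataFrame(
            rng.integers(-1, 2, size=(50, 4)).astype(float),
            columns=list(self.TISSUES.index))
        out = aggregate_qri(scores, self.TISSUES)
        assert out["qri_whole"].between(-1, 1).all()

    def test_empty_tissue_warns_and_blanks_whole_brain(self):
        tissues = pd.Series({"t1": "thickness", "v1": "subcortical_volume"})
        scores = pd.DataFrame([[1.0, 0.0]], columns=["t1", "v1"])
        with pytest.warns(UserWarning, match="FA"):
            out = aggregate_qri(scores, tissues)
        assert np.isnan(out["qri_fa"].iloc[0])
        assert np.isnan(out["qri_whole"].iloc[0])


class TestComputeQri:
    def _toy(self, rng, n=300):
        cov = pd.DataFrame({"age": rng.uniform(45, 80, n),
                            "sex": rng.integers(0, 2, n).astype(float)},
                           index=[f"S{i}" for i in range(n)])
        tissues = pd.Series({"t1": "thickness", "v1": "subcortical_volume",
                             "f1": "FA"})
        phen = pd.DataFrame(
            {k: 2.5 - 0.01 * cov["age"] + rng.normal(0, 0.1, n)
             for k in tissues.index}, index=cov.index)
        return phen, cov, tissues

    def test_scores_and_fits_shapes(self, rng):
        phen, cov, tissues = self._toy(rng)
        res = compute_qri(phen, cov, tissues)
        assert res.region_scores.shape == phen.shape
        assert set(res.region_scores.to_numpy().ravel()) <= {-1.0, 0.0, 1.0}
        assert len(res.fits) == 3 * phen.shape[1]
        assert res.scores["qri_whole"].between(-1, 1).all()

    def test_sex_stratified_fits_double_the_fit_table(self, rng):
        phen, cov, tissues = self._toy(rng)
        res = compute_qri(phen, cov, tissues, stratify_by_sex=True)
        assert len(res.fits) == 6 * phen.shape[1]
        assert set(res.fits["stratum"]) == {"sex=0", "sex=1"}

    def test_wrong_number_of_taus_rejected(self, rng):
        phen, cov, tissues = self._toy(rng)
        with pytest.raises(ConfigurationError):
            compute_qri(phen, cov, tissues, taus=(0.05, 0.95))
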