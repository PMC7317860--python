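"""Random-forest attribution: GVIF, OOB importance, partial dependence."""

import numpy as np
import pandas as pd
import pytest

from effortshift.driver_models import (
    _oob_indices,
    fit_rf,
    gvif,
    partial_dependence,
    permutation_importance,
)
from effortshift.errors import InsufficientDataError
from effortshift.synthetic import SyntheticConfig, generate_covariates


def covariate_table(seed=0, effects_effort=None, noise_ratio=0.5):
    cfg = SyntheticConfig(seed=seed, covariate_noise_ratio=noise_ratio)
    if effects_effort is not None:
        cfg.covariate_effects_effort = effects_effort
    table, _ = generate_covariates(cfg)
    return table


class TestGvif:
    def test_orthogonal_continuous_predictors_give_one(self):
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((60, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # exactly orthogonal columns
        table = pd.DataFrame(q, columns=["a", "b", "c"])
        report = gvif(table, predictors=["a", "b", "c"])
        assert np.allclose(report.table["gvif"].to_numpy(), 1.0, atol=1e-8)
        assert not report.flagged

    def test_duplicated_predictor_is_infinite_and_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(50)
        table = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(50)})
        report = gvif(table, predictors=["a", "b", "c"])
        assert np.isinf(report.table.loc["a", "gvif"])
        assert "a" in report.flagged and "b" in report.flagged

    def test_matches_regression_oracle_for_correlated_design(self):
        # three predictors with pairwise correlation ~0.5; GVIF_j must equal
        # 1 / (1 - R2_j) from an explicit OLS of x_j on the others
        rng = np.random.default_rng(2)
        z = rng.standard_normal((500, 4))
        X = np.column_stack([z[:, 3] + z[:, i] for i in range(3)])
        table = pd.DataFrame(X, columns=["a", "b", "c"])
        report = gvif(table, predictors=["a", "b", "c"])
        for j, name in enumerate(["a", "b", "c"]):
            others = np.column_stack(
                [np.ones(len(X))] + [X[:, i] for i in range(3) if i != j]
            )
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            r2 = 1 - resid.var() / X[:, j].var()
            assert report.table.loc[name, "gvif"] == pytest.approx(1 / (1 - r2), abs=1e-8)

    def test_quarter_factor_enters_as_group(self):
        table = covariate_table()
        report = gvif(table)
        assert report.table.loc["quarter", "df"] == 3
        assert report.table.loc["ssta", "df"] == 1
        scaled = report.table.loc["quarter", "gvif_scaled"]
        assert scaled == pytest.approx(report.table.loc["quarter", "gvif"] ** (1 / 6))

    def test_default_conditions_are_below_threshold(self):
        report = gvif(covariate_table())
        finite = report.table["gvif"][np.isfinite(report.table["gvif"])]
        assert (finite < 6.0).all()


class TestFitRf:
    def test_oob_index_regeneration_matches_sklearn(self):
        table = covariate_table()
        fit = fit_rf(table, "effort", n_trees=150, seed=3)
        n = len(fit.y)
        sums = np.zeros(n)
        counts = np.zeros(n)
        for tree in fit.model.estimators_:
            oob = _oob_indices(tree.random_state, n)
            sums[oob] += tree.predict(fit.X.to_numpy()[oob])
            counts[oob] += 1
        mine = sums / counts
        assert np.allclose(mine, fit.model.oob_prediction_, rtol=1e-12)

    def test_seeded_determinism_is_bitwise(self):
        table = covariate_table()
        f1 = fit_rf(table, "effort", n_trees=120, seed=7)
        f2 = fit_rf(table, "effort", n_trees=120, seed=7)
        assert f1.var_explained == f2.var_explained
        i1 = permutation_importance(f1)
        i2 = permutation_importance(f2)
        assert (i1 == i2).all()

    def test_pure_noise_response_explains_little(self):
        scores = []
        for seed in range(10):
            table = covariate_table(seed=seed)
            rng = np.random.default_rng(1000 + seed)
            table = table.assign(response_effort=rng.standard_normal(len(table)))
            fit = fit_rf(table, "effort", n_trees=300, seed=seed)
            scores.append(fit.var_explained)
        assert np.mean(scores) <= 10.0
        assert max(scores) <= 25.0  # leakage guard

    def test_deterministic_fad_prop_response_is_learned(self):
        table = covariate_table()
        table = table.assign(response_effort=3.0 * table["fad_prop"] ** 2)
        fit = fit_rf(table, "effort", n_trees=400, seed=5)
        assert fit.var_explained >= 80.0

    def test_var_explained_stable_in_tree_count(self):
        table = covariate_table()
        a = fit_rf(table, "effort", n_trees=1000, seed=11).var_explained
        b = fit_rf(table, "effort", n_trees=1500, seed=11).var_explained
        assert abs(a - b) < 1.0

    def test_mtry_defaults_to_third_of_predictors(self):
        fit = fit_rf(covariate_table(), "effort", n_trees=50, seed=0)
        assert fit.mtry == 2

    def test_too_few_rows_refused(self):
        table = covariate_table().iloc[:20]
        with pytest.raises(InsufficientDataError):
            fit_rf(table, "effort", n_trees=50, seed=0)


class TestPermutationImportance:
    def test_single_driver_ranks_first(self):
        table = covariate_table()
        rng = np.random.default_rng(6)
        table = table.assign(
            response_pc1=2.0 * table["ssta"] + rng.normal(0, 0.1, len(table))
        )
        fit = fit_rf(table, "pc1", n_trees=500, seed=6)
        imp = permutation_importance(fit)
        assert imp.index[0] == "ssta"

    def test_irrelevant_predictor_near_zero(self):
        table = covariate_table()
        rng = np.random.default_rng(8)
        table = table.assign(
            response_pc1=2.0 * table["ssta"] + rng.normal(0, 0.1, len(table))
        )
        fit = fit_rf(table, "pc1", n_trees=500, seed=8)
        imp = permutation_importance(fit)
        # predictors unrelated to the response sit near zero importance
        assert abs(imp["agr_num"]) < 5.0
        assert imp["ssta"] > 10 * max(abs(imp.drop("ssta")))


class TestPartialDependence:
    def _fitted(self, seed=9):
        table = covariate_table(seed=seed)
        rng = np.random.default_rng(seed)
        table = table.assign(
            response_pc1=3.0 * table["ssta"] + rng.normal(0, 0.2, len(table))
        )
        return fit_rf(table, "pc1", n_trees=300, seed=seed)

    def test_monotone_signal_gives_monotone_curve(self):
        from scipy.stats import spearmanr

        pdp = partial_dependence(self._fitted(), "ssta")
        rho = spearmanr(pdp["value"], pdp["prediction"]).statistic
        assert rho > 0.9
        assert len(pdp) == 20

    def test_binary_predictor_has_two_points(self):
        pdp = partial_dependence(self._fitted(), "tac")
        assert len(pdp) == 2 and set(pdp["value"]) == {0.0, 1.0}

    def test_quarter_factor_has_four_points(self):
        pdp = partial_dependence(self._fitted(), "quarter")
        assert list(pdp["value"]) == [1.0, 2.0, 3.0, 4.0]

    def test_ignored_predictor_curve_is_flat(self):
        # the ignored predictor must be independent of the true driver:
        # autocorrelated covariates (walks vs AR(1)) correlate spuriously
        # in-sample and the forest would genuinely lean on them
        table = covariate_table(seed=9)
        rng = np.random.default_rng(9)
        table = table.assign(
            agr_vessel=rng.permutation(table["agr_vessel"].to_numpy()),
            response_pc1=3.0 * table["ssta"] + rng.normal(0, 0.1, len(table)),
        )
        # mtry = p so every split sees the true driver; with mtry < p trees
        # are sometimes forced to split on noise, which is not a PDP defect
        fit = fit_rf(table, "pc1", n_trees=500, mtry=9, seed=9)
        pdp = partial_dependence(fit, "agr_vessel")
        span = pdp["prediction"].max() - pdp["prediction"].min()
        assert span < 0.05 * fit.y.std(ddof=1)

    def test_unknown_predictor_raises(self):
        with pytest.raises(ValueError, match="unknown predictor"):
            partial_dependence(self._fitted(), "not_a_column")
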