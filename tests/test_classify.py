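import math

import numpy as np
import pandas as pd
import pytest

from cobind.classify import (
    NBModel,
    PredictorSpec,
    classify,
    cross_validate,
    fit_nb,
    nb_log_ratio,
    nb_ratio,
    predictor_log_terms,
    select_features,
    silverman_bandwidth,
)


class TestSilverman:
    def test_degenerate_sd_zero(self):
        assert silverman_bandwidth([3.0, 3.0, 3.0]) == 0.1

    def test_n_below_two(self):
        assert silverman_bandwidth([5.0]) == 0.1
        assert silverman_bandwidth([]) == 0.1

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=40)
        assert silverman_bandwidth(7.0 * x) == pytest.approx(7.0 * silverman_bandwidth(x), rel=1e-12)

    def test_formula_on_normal_sample(self, rng):
        x = rng.standard_normal(100)
        sd = np.std(x, ddof=1)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        expected = 0.9 * min(sd, iqr / 1.34) * 100 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected, rel=1e-12)


def _training(rng, n=100, p_up=0.6):
    y = (rng.uniform(size=n) < p_up).astype(int)
    X = pd.DataFrame(
        {
            "always": rng.normal(y, 1.0),
            "cont": np.where(rng.uniform(size=n) < 0.3, np.nan, rng.normal(2 * y, 1.0)),
            "ind": np.where(rng.uniform(size=n) < 0.4 + 0.4 * y, rng.normal(size=n), np.nan),
        },
        index=[f"g{i}" for i in range(n)],
    )
    specs = [
        PredictorSpec("always", "always"),
        PredictorSpec("cont", "continuous"),
        PredictorSpec("ind", "indicator"),
    ]
    return X, y, specs


class TestFitNB:
    def test_prior_plain_ratio(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=100)})
        y = np.array([1] * 60 + [0] * 40)
        model = fit_nb(X, y, [PredictorSpec("a", "always")])
        assert model.p1 == pytest.approx(0.6)

    def test_lambda_add_one_smoothing(self):
        X = pd.DataFrame({"f": [np.nan] * 50 + [1.0] * 10})
        y = np.array([1] * 50 + [0] * 10)
        model = fit_nb(X, y, [PredictorSpec("f", "continuous")])
        # class 1 has 0 of 50 present: lambda = (0+1)/(50+2)
        assert model.predictors[0].lam1 == pytest.approx(1 / 52)
        assert model.predictors[0].lam0 == pytest.approx(11 / 12)

    def test_class_absent_errors(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="both classes"):
            fit_nb(X, np.array([1, 1]), [PredictorSpec("a", "always")])

    def test_identical_scores_finite_density(self):
        X = pd.DataFrame({"f": [2.0] * 10})
        y = np.array([1] * 5 + [0] * 5)
        model = fit_nb(X, y, [PredictorSpec("f", "continuous")])
        assert np.isfinite(nb_log_ratio(model, X)).all()


class TestNBRatio:
    def test_zero_predictors_prior_only(self):
        X = pd.DataFrame(index=["g1", "g2"])
        y = np.array([1, 0])
        model = fit_nb(X, y, [])
        np.testing.assert_allclose(nb_ratio(model, X), [1.0, 1.0])  # p1 = 0.5

    def test_indicator_ratio_four(self):
        model = NBModel(p1=0.5, predictors=[])
        from cobind.classify import _PredictorParams

        model.predictors.append(
            _PredictorParams(
                PredictorSpec("f", "indicator"), lam1=0.8, lam0=0.2,
                scores1=np.empty(0), scores0=np.empty(0), h1=0.1, h0=0.1,
            )
        )
        X = pd.DataFrame({"f": [1.0, np.nan]})
        ratios = nb_ratio(model, X)
        assert ratios[0] == pytest.approx(4.0, rel=1e-12)
        assert ratios[1] == pytest.approx(0.2 / 0.8, rel=1e-12)

    def test_oracle_equivalence(self, rng):
        """Brute-force term-by-term evaluation of the posterior ratio."""
        for _ in range(50):
            X, y, specs = _training(rng, n=40)
            model = fit_nb(X, y, specs)
            test_row = pd.DataFrame(
                {
                    "always": [float(rng.normal())],
                    "cont": [float(rng.normal()) if rng.uniform() < 0.5 else np.nan],
                    "ind": [float(rng.normal()) if rng.uniform() < 0.5 else np.nan],
                }
            )
            got = nb_log_ratio(model, test_row)[0]

            def kde(x, train, h):
                if train.size == 0:
                    return 1.0
                return float(
                    np.mean(np.exp(-0.5 * ((x - train) / h) ** 2))
                    / (h * math.sqrt(2 * math.pi))
                )

            log_ratio = math.log(model.p1) - math.log(1 - model.p1)
            for pp in model.predictors:
                x = test_row[pp.spec.name].iloc[0]
                present = not np.isnan(x)
                if pp.spec.kind == "always":
                    num, den = kde(x, pp.scores1, pp.h1), kde(x, pp.scores0, pp.h0)
                elif present:
                    num = pp.lam1 * (kde(x, pp.scores1, pp.h1) if pp.spec.kind == "continuous" else 1.0)
                    den = pp.lam0 * (kde(x, pp.scores0, pp.h0) if pp.spec.kind == "continuous" else 1.0)
                else:
                    num, den = 1 - pp.lam1, 1 - pp.lam0
                log_ratio += math.log(num) - math.log(den)
            assert got == pytest.approx(log_ratio, rel=1e-12, abs=1e-12)

    def test_monotone_prior(self, rng):
        X, y, specs = _training(rng, n=60)
        model = fit_nb(X, y, specs)
        labels_low = classify(model, X)
        model.p1 = min(0.99, model.p1 + 0.3)
        labels_high = classify(model, X)
        # raising the ES-up prior can only flip labels toward ES-up
        assert not ((labels_low == 1) & (labels_high == 0)).any()

    def test_tie_goes_to_up(self):
        X = pd.DataFrame(index=["g1", "g2"])
        model = fit_nb(X, np.array([1, 0]), [])
        assert (classify(model, X) == 1).all()


class TestCrossValidate:
    def test_determinism(self, rng):
        X, y, specs = _training(rng)
        a = cross_validate(X, y, specs, folds=5, seed=4)
        b = cross_validate(X, y, specs, folds=5, seed=4)
        assert a == b

    def test_separable_low_error(self, rng):
        n = 100
        y = np.array([1, 0] * (n // 2))
        X = pd.DataFrame({"a": y * 10.0 + rng.normal(0, 0.1, n)})
        err, se = cross_validate(X, y, [PredictorSpec("a", "always")], seed=0)
        assert err < 0.05

    def test_permuted_labels_near_majority_rate(self, rng):
        n = 120
        y = rng.permutation(np.array([1] * 60 + [0] * 60))
        X = pd.DataFrame({"a": rng.normal(size=n)})
        err, se = cross_validate(X, y, [PredictorSpec("a", "always")], seed=0)
        assert 0.3 < err < 0.7

    def test_fold_reduction_warns(self, rng):
        y = np.array([1] * 3 + [0] * 20)
        X = pd.DataFrame({"a": rng.normal(size=23)})
        with pytest.warns(UserWarning, match="reducing folds"):
            cross_validate(X, y, [PredictorSpec("a", "always")], folds=10, seed=0)


def _selection_problem(rng, n=80, informative=True):
    y = np.array(([1] * (n // 2)) + ([0] * (n // 2)))
    cols, specs_up, specs_down = {}, {}, {}
    cols["assoc:A"] = rng.normal(size=n)
    mf = [PredictorSpec("assoc:A", "always")]
    for w in (0, 1, 2):
        specs_up[w], specs_down[w] = [], []
        for i in range(22):
            up_name, down_name = f"u{w}_{i}", f"d{w}_{i}"
            strength = 2.0 if (informative and i < 3) else 0.0
            cols[up_name] = np.where(
                rng.uniform(size=n) < 0.5, np.nan, rng.normal(strength * y, 1.0)
            )
            cols[down_name] = np.where(
                rng.uniform(size=n) < 0.5, np.nan, rng.normal(strength * (1 - y), 1.0)
            )
            specs_up[w].append(PredictorSpec(up_name, "continuous"))
            specs_down[w].append(PredictorSpec(down_name, "continuous"))
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(n)]), y, mf, specs_up, specs_down


class TestSelectFeatures:
    def test_grid_is_nine_pairs_of_441(self, rng):
        X, y, mf, up, down = _selection_problem(rng, n=30)
        calls = []

        def stub(wu, wd, k1, k2, specs):
            calls.append((wu, wd, k1, k2))
            return 0.5, 0.01

        result = select_features(up, down, X, y, mf, cv_fn=stub, seed=0)
        assert result.n_pairs_evaluated == 9
        assert len({(wu, wd) for wu, wd, _, _ in calls}) == 9
        from collections import Counter

        per_pair = Counter((wu, wd) for wu, wd, _, _ in calls)
        assert all(v == 441 for v in per_pair.values())

    def test_baseline_is_k0_k0(self, rng):
        X, y, mf, up, down = _selection_problem(rng, n=60)
        result = select_features(up, down, X, y, mf, seed=2, folds=5)
        base_err, base_se = cross_validate(X, y, mf, folds=5, seed=2)
        assert result.baseline_error == pytest.approx(base_err)
        assert result.baseline_se == pytest.approx(base_se)

    def test_fast_grid_matches_explicit_cv(self, rng):
        X, y, mf, up, down = _selection_problem(rng, n=60)
        result = select_features(up, down, X, y, mf, seed=7, folds=5)
        specs = mf + result.selected_specs
        err, se = cross_validate(X, y, specs, folds=5, seed=7)
        assert result.cv_error == pytest.approx(err, abs=1e-12)
        assert result.cv_se == pytest.approx(se, abs=1e-12)

    def test_informative_features_beat_baseline(self, rng):
        X, y, mf, up, down = _selection_problem(rng, n=100, informative=True)
        result = select_features(up, down, X, y, mf, seed=1, folds=5)
        assert result.k1 + result.k2 > 0
        assert result.cv_error < result.baseline_error

    def test_pure_noise_within_one_se_of_baseline(self, rng):
        X, y, mf, up, down = _selection_problem(rng, n=100, informative=False)
        result = select_features(up, down, X, y, mf, seed=1, folds=5)
        assert result.cv_error <= result.baseline_error  # min over grid includes baseline
        assert result.baseline_error - result.cv_error <= max(2 * result.baseline_se, 0.25)

    def test_no_candidates_returns_baseline(self, rng):
        X, y, mf, _, _ = _selection_problem(rng, n=40)
        result = select_features({}, {}, X, y, mf, seed=0, folds=5)
        assert result.k1 == 0 and result.k2 == 0
        assert result.cv_error == pytest.approx(result.baseline_error)
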