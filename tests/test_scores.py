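
import numpy as np
import pandas as pd
import pytest

from _oracles import auc_oracle
from scfamet.scores import (
    ScoreModel,
    bootstrap_optimism,
    evaluate_score,
    lasso_select,
    load_packaged_model,
    nagelkerke_r2,
    roc_auc,
)


class TestEvaluateScore:
    def test_ko_intercept_at_zero(self):
        model = load_packaged_model("ko")
        zeros = {f: 0.0 for f in model.coefficients}
        assert evaluate_score(model, zeros) == -1.993

    def test_enzyme_intercept_at_zero(self):
        model = load_packaged_model("enzyme")
        zeros = {f: 0.0 for f in model.coefficients}
        assert evaluate_score(model, zeros) == -2.562

    def test_species_intercept_at_zero(self):
        model = load_packaged_model("species")
        zeros = {f: 0.0 for f in model.coefficients}
        assert evaluate_score(model, zeros) == 0.2773

    def test_ko_single_feature_contribution(self):
        # -1.993 + 6023.7645 * 0.001 = -1.993 + 6.0237645
        model = load_packaged_model("ko")
        sample = {f: 0.0 for f in model.coefficients}
        sample["K00175"] = 0.001
        assert evaluate_score(model, sample) == pytest.approx(4.0307645, abs=1e-12)

    def test_missing_features_warn_and_count_zero(self):
        model = load_packaged_model("species")
        with pytest.warns(UserWarning, match="absent"):
            assert evaluate_score(model, {}) == 0.2773

    def test_order_independent(self, rng):
        model = load_packaged_model("ko")
        feats = list(model.coefficients)
        sample = {f: rng.random() for f in feats}
        shuffled = {f: sample[f] for f in rng.permutation(feats)}
        assert evaluate_score(model, sample) == evaluate_score(model, shuffled)

    def test_json_roundtrip(self, tmp_path):
        model = load_packaged_model("enzyme")
        p = tmp_path / "m.json"
        model.to_json(p)
        back = ScoreModel.from_json(p)
        assert back.intercept == model.intercept
        assert back.coefficients == model.coefficients


def _planted_features(rng, n=100, n_signal=2, n_noise=50, shift=3.0):
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X = rng.normal(0, 1, (n, n_signal + n_noise))
    X[y == 1, :n_signal] += shift
    cols = [f"sig{i}" for i in range(n_signal)] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y


class TestLassoSelect:
    def test_planted_recovery(self, rng):
        X, y = _planted_features(rng)
        model = lasso_select(X, y, cv_folds=5, seed=0, n_lambdas=15)
        selected = set(model.coefficients)
        assert {"sig0", "sig1"} <= selected
        assert len(selected - {"sig0", "sig1"}) <= 8

    def test_infinite_penalty_empty_model(self, rng):
        X, y = _planted_features(rng)
        model = lasso_select(X, y, lambda_fixed=1e9)
        assert model.coefficients == {}

    def test_determinism(self, rng):
        X, y = _planted_features(rng)
        m1 = lasso_select(X, y, cv_folds=5, seed=42, n_lambdas=10)
        m2 = lasso_select(X, y, cv_folds=5, seed=42, n_lambdas=10)
        assert m1.intercept == m2.intercept
        assert m1.coefficients == m2.coefficients

    def test_degenerate_labels_rejected(self, rng):
        X, _ = _planted_features(rng)
        with pytest.raises(ValueError, match="two classes"):
            lasso_select(X, np.zeros(len(X)))

    def test_single_feature_rejected(self, rng):
        with pytest.raises(ValueError, match="2 candidate"):
            lasso_select(pd.DataFrame({"a": rng.random(20)}), [0, 1] * 10)

    def test_standardize_maps_back_to_raw_scale(self, rng):
        X, y = _planted_features(rng, n_noise=10)
        model = lasso_select(X, y, cv_folds=5, seed=0, n_lambdas=10, standardize=True)
        # scores computed on the raw scale must separate the classes
        scores = [evaluate_score(model, row) for _, row in X.iterrows()]
        assert roc_auc(scores, y).auc > 0.9


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]).auc == 1.0

    def test_small_example_and_swap(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]).auc == 0.75

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.normal(0, 1, n), 1)  # ties included
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_auc(scores, labels).auc == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12
            )

    def test_null_calibration(self, rng):
        scores = rng.normal(0, 1, 2000)
        labels = rng.integers(0, 2, 2000)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_constant_scores_warn(self):
        with pytest.warns(UserWarning, match="constant"):
            res = roc_auc([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1])
        assert res.auc == 0.5

    def test_ci_contains_auc(self, rng):
        scores = rng.normal(0, 1, 100) + np.repeat([0, 1], 50)
        res = roc_auc(scores, np.repeat([0, 1], 50))
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0.0 <= res.ci_low and res.ci_high <= 1.0


class TestNagelkerke:
    def test_null_model_zero(self):
        y = np.array([0, 0, 1, 1])
        assert nagelkerke_r2(y, np.full(4, 0.5)) == pytest.approx(0.0, abs=1e-12)

    def test_near_perfect_probs(self):
        y = np.array([0, 0, 1, 1])
        r2 = nagelkerke_r2(y, np.array([1e-9, 1e-9, 1 - 1e-9, 1 - 1e-9]))
        assert r2 > 0.99

    def test_matches_statsmodels_fit(self, rng):
        import statsmodels.api as sm

        x = rng.normal(0, 1, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-x))).astype(float)
        res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        probs = res.predict()
        # independent evaluation from the likelihood-ratio formula
        n = len(y)
        expected = (1 - np.exp(2 * (res.llnull - res.llf) / n)) / (
            1 - np.exp(2 * res.llnull / n)
        )
        # statsmodels refits the null model numerically, hence the tolerance
        assert nagelkerke_r2(y, probs) == pytest.approx(expected, abs=1e-6)

    def test_out_of_range_probs_warn(self):
        with pytest.warns(UserWarning, match="clipped"):
            nagelkerke_r2([0, 1], [0.0, 1.0])


class TestBootstrapOptimism:
    def test_b1_deterministic(self, rng):
        X, y = _planted_features(rng, n=40, n_noise=5)
        kwargs = dict(B=1, seed=9, cv_folds=3, n_lambdas=5)
        r1 = bootstrap_optimism(X, y, **kwargs)
        r2 = bootstrap_optimism(X, y, **kwargs)
        assert r1 == r2

    def test_corrected_below_apparent_with_signal(self, rng):
        X, y = _planted_features(rng, n=60, n_signal=2, n_noise=10, shift=1.0)
        rep = bootstrap_optimism(
            X, y, B=20, seed=0, cv_folds=3, n_lambdas=8, lambda_rule="min"
        )
        assert rep.corrected_auc <= rep.apparent_auc + 1e-12
        assert rep.B == 20
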