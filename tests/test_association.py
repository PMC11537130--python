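import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metamodtrend import (
    ValidationError,
    delta_features,
    fit_logistic,
    improvement_scan,
    logistic_improvement,
    partial_spearman,
)


def _visits(n_p=8, n_v=3):
    # per-patient visit spacing varies so follow-up time is non-constant
    times = [j * (1.0 + 0.05 * (i % 7)) for i in range(n_p) for j in range(n_v)]
    return pd.DataFrame({
        "patient_id": np.repeat([f"P{i}" for i in range(n_p)], n_v),
        "sample_id": [f"P{i}_V{j}" for i in range(n_p) for j in range(n_v)],
        "time_years": times,
    })


class TestDeltaFeatures:
    def test_standardized_to_unit_sd(self):
        rng = np.random.default_rng(0)
        visits = _visits()
        feats = pd.DataFrame(rng.normal(0, 1, (24, 3)),
                             index=visits["sample_id"], columns=list("abc"))
        deltas = delta_features(feats, visits)
        np.testing.assert_allclose(deltas.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(deltas.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_single_patient_left_unstandardized(self):
        visits = _visits(n_p=1)
        feats = pd.DataFrame({"a": [1.0, 2.0, 5.0]}, index=visits["sample_id"])
        deltas = delta_features(feats, visits)
        assert deltas["a"].iloc[0] == pytest.approx(4.0)

    def test_zero_variance_feature_excluded(self):
        visits = _visits()
        feats = pd.DataFrame({
            "flat": np.tile([1.0, 2.0, 3.0], 8),  # identical delta everywhere
            "ok": np.random.default_rng(1).normal(0, 1, 24),
        }, index=visits["sample_id"])
        deltas = delta_features(feats, visits)
        assert list(deltas.columns) == ["ok"]

    def test_patient_without_baseline_excluded(self):
        visits = _visits(n_p=3)
        visits.loc[visits["patient_id"] == "P1", "time_years"] = [0.5, 1.0, 2.0]
        feats = pd.DataFrame({"a": np.arange(9.0)}, index=visits["sample_id"])
        deltas = delta_features(feats, visits)
        assert list(deltas.index) == ["P0", "P2"]


class TestLogistic:
    def test_two_by_two_closed_form(self):
        X = pd.DataFrame({"x": [1.0] * 10 + [0.0] * 10})
        y = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        fit = fit_logistic(X, y)
        assert fit.params["x"] == pytest.approx(np.log(16.0), abs=1e-6)
        assert fit.converged and not fit.separated

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(0, 1, (80, 3)), columns=list("abc"))
        lin = 0.3 + 0.8 * X["a"] - 0.5 * X["b"]
        y = rng.binomial(1, 1 / (1 + np.exp(-lin)))
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(),
                                   ref.params.to_numpy(), atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(),
                                   ref.bse.to_numpy(), rtol=1e-4)

    def test_complete_separation_flagged(self):
        X = pd.DataFrame({"x": np.concatenate([np.ones(10), -np.ones(10)])})
        y = [1] * 10 + [0] * 10
        fit = fit_logistic(X, y)
        assert fit.separated

    def test_one_class_outcome_rejected(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValidationError):
            fit_logistic(X, np.ones(10))

    def test_type_one_error_controlled(self):
        """Covariate independent of outcome: p < 0.05 in roughly 5% of runs."""
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            visits = _visits(n_p=40, n_v=2)
            cohort = pd.DataFrame({
                "patient_id": [f"P{i}" for i in range(40)],
                "age_baseline": rng.normal(41, 10, 40),
                "sex": rng.binomial(1, 0.68, 40),
                "dmt_history": rng.binomial(1, 0.71, 40),
            })
            deltas = pd.Series(rng.normal(0, 1, 40), name="f",
                               index=pd.Index([f"P{i}" for i in range(40)],
                                              name="patient_id"))
            labels = pd.Series(rng.binomial(1, 0.4, 40), index=deltas.index)
            if labels.nunique() < 2:
                continue
            res = logistic_improvement(deltas, labels, cohort, visits)
            if not res["separated"] and res["p"] < 0.05:
                hits += 1
        assert 0.03 * 200 <= hits <= 0.08 * 200


class TestImprovementScan:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        n_p = 40
        visits = _visits(n_p=n_p, n_v=2)
        cohort = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n_p)],
            "age_baseline": rng.normal(41, 10, n_p),
            "sex": rng.binomial(1, 0.68, n_p),
            "dmt_history": rng.binomial(1, 0.71, n_p),
        })
        z = rng.normal(0, 1, n_p)
        labels = pd.Series(
            rng.binomial(1, 1 / (1 + np.exp(-(-0.5 - 1.2 * z)))),
            index=[f"P{i}" for i in range(n_p)])
        base = rng.normal(0, 1, (n_p, 2))
        final = base + np.column_stack([z, rng.normal(0, 1, n_p)])
        feats = pd.DataFrame(
            np.empty((2 * n_p, 2)), index=visits["sample_id"],
            columns=["planted", "null"])
        feats.iloc[0::2] = base
        feats.iloc[1::2] = final
        return feats, labels, cohort, visits

    def test_row_per_feature_and_determinism(self):
        feats, labels, cohort, visits = self._setup()
        deltas = delta_features(feats, visits)
        r1 = improvement_scan(deltas, labels, cohort, visits)
        r2 = improvement_scan(deltas, labels, cohort, visits)
        assert len(r1) == 2
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_feature_outranks_null(self):
        wins, total = 0, 0
        for seed in range(100):
            feats, labels, cohort, visits = self._setup(seed)
            if labels.nunique() < 2:
                continue
            deltas = delta_features(feats, visits)
            res = improvement_scan(deltas, labels, cohort, visits)
            res = res.set_index("feature")
            if res["separated"].any():
                continue
            total += 1
            wins += res.loc["planted", "p"] < res.loc["null", "p"]
        assert wins / total >= 0.95


class TestPartialSpearman:
    def test_monotone_relationship_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
        y = x**3
        rho, p = partial_spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_no_covariates_equals_ordinary_spearman(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(0, 1, 30)
            y = 0.5 * x + rng.normal(0, 1, 30)
            rho, p = partial_spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)

    def test_confound_removed(self):
        rhos = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c = rng.normal(0, 1, 100)
            x = c + rng.normal(0, 0.2, 100)
            y = c.copy()  # y IS the covariate
            rho, _ = partial_spearman(x, y, c)
            rhos.append(abs(rho))
        assert np.mean(rhos) < 0.05

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            "x": rng.normal(0, 1, 60),
            "y": rng.normal(0, 1, 60),
            "c1": rng.normal(0, 1, 60),
            "c2": rng.normal(0, 1, 60),
        })
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        rho, p = partial_spearman(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                                    method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-3)

    def test_invariant_to_monotone_transforms(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0.1, 5, 40)
        y = rng.uniform(0.1, 5, 40)
        c = rng.normal(0, 1, 40)
        rho1, _ = partial_spearman(x, y, c)
        rho2, _ = partial_spearman(np.log(x), y**3, c)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            partial_spearman(np.ones(10), np.arange(10.0))
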