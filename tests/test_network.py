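import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from metamodtrend import (
    AnalysisConfig,
    ModuleDetector,
    ValidationError,
    correlation_adjacency,
    detect_modules,
    eigenmetabolites,
    module_membership,
    preprocess_pipeline,
    tom_similarity,
)
from metamodtrend.network import GREY, Network


def _pair_with_correlation(r, n=8):
    """Two columns with exactly the requested Pearson correlation."""
    rng = np.random.default_rng(0)
    u = rng.standard_normal(n)
    u -= u.mean()
    v = rng.standard_normal(n)
    v -= v.mean()
    v -= u * (u @ v) / (u @ u)
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    y = r * u + np.sqrt(1 - r**2) * v
    return pd.DataFrame({"x": u, "y": y})


class TestAdjacency:
    def test_unsigned_soft_power(self):
        net = correlation_adjacency(_pair_with_correlation(-0.5), beta=12)
        assert net.adjacency.loc["x", "y"] == pytest.approx(0.5**12, rel=1e-9)

    def test_perfect_correlation_gives_one(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
        net = correlation_adjacency(df, beta=7)
        assert net.adjacency.loc["x", "y"] == pytest.approx(1.0)

    def test_signed_anticorrelation_gives_zero(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [-1.0, -2.0, -3.0, -4.0]})
        net = correlation_adjacency(df, beta=12, sign_mode="signed")
        assert net.adjacency.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="flat"):
            correlation_adjacency(df)

    def test_symmetry_bounds_and_unit_diagonal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((10, 6)))
        a = correlation_adjacency(df).adjacency.to_numpy()
        assert np.allclose(a, a.T, atol=1e-12)
        assert ((a >= 0) & (a <= 1)).all()
        assert np.allclose(np.diag(a), 1.0)


def _tom_brute_force(a):
    n = a.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            denom = min(ki, kj) + 1.0 - a[i, j]
            out[i, j] = (l + a[i, j]) / denom if denom > 0 else 1.0
    return out


def _random_adjacency(rng, n=6):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestTom:
    def test_complete_graph(self):
        a = np.ones((3, 3))
        net = Network(pd.DataFrame(a), beta=1, sign_mode="unsigned")
        tom = tom_similarity(net).to_numpy()
        assert np.allclose(tom, 1.0)

    def test_empty_graph(self):
        a = np.eye(4)
        net = Network(pd.DataFrame(a), beta=1, sign_mode="unsigned")
        tom = tom_similarity(net).to_numpy()
        assert np.allclose(tom - np.eye(4), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_adjacency(rng)
        net = Network(pd.DataFrame(a), beta=1, sign_mode="unsigned")
        tom = tom_similarity(net).to_numpy()
        np.testing.assert_allclose(tom, _tom_brute_force(a), atol=1e-12)


def _block_data(block_sizes, n_noise, n_samples=30, seed=0):
    rng = np.random.default_rng(seed)
    cols = {}
    idx = 0
    for b, size in enumerate(block_sizes):
        f = rng.standard_normal(n_samples)
        for _ in range(size):
            cols[f"m{idx:03d}"] = f * rng.uniform(0.5, 2.0) + rng.uniform(-1, 1)
            idx += 1
    for _ in range(n_noise):
        cols[f"m{idx:03d}"] = rng.standard_normal(n_samples)
        idx += 1
    return pd.DataFrame(cols)


class TestDetectModules:
    def test_two_perfect_blocks_recovered(self):
        df = _block_data([20, 20], n_noise=10)
        det = ModuleDetector().fit(df)
        labels = det.modules_
        block1 = set(labels.iloc[:20])
        block2 = set(labels.iloc[20:40])
        assert len(block1) == 1 and len(block2) == 1
        assert block1 != block2 and GREY not in block1 | block2
        assert (labels.iloc[40:] == GREY).all()

    def test_identity_tom_all_grey(self):
        ids = [f"m{i}" for i in range(20)]
        tom = pd.DataFrame(np.eye(20), index=ids, columns=ids)
        assert (detect_modules(tom) == GREY).all()

    def test_single_block_named_turquoise(self):
        df = _block_data([25], n_noise=0)
        labels = detect_modules(tom_similarity(correlation_adjacency(df)))
        assert (labels == "turquoise").all()

    def test_fewer_metabolites_than_min_size_all_grey(self):
        df = _block_data([5], n_noise=0)
        tom = tom_similarity(correlation_adjacency(df))
        assert (detect_modules(tom, min_module_size=10) == GREY).all()

    def test_color_order_by_decreasing_size(self):
        df = _block_data([20, 14, 11], n_noise=5)
        labels = detect_modules(tom_similarity(correlation_adjacency(df)))
        assert set(labels.iloc[:20]) == {"turquoise"}
        assert set(labels.iloc[20:34]) == {"blue"}
        assert set(labels.iloc[34:45]) == {"brown"}


class TestEigenmetabolites:
    def test_rank_one_module(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        df = pd.DataFrame({"a": x, "b": x})
        modules = pd.Series(["turquoise", "turquoise"], index=["a", "b"])
        eig = eigenmetabolites(df, modules)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(eig.scores["turquoise"].to_numpy(), z, atol=1e-12)
        assert eig.variance_explained["turquoise"] == pytest.approx(1.0)

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((12, 4)),
                          columns=["a", "b", "c", "d"])
        modules = pd.Series("blue", index=df.columns)
        e1 = eigenmetabolites(df, modules).scores["blue"].to_numpy()
        e2 = eigenmetabolites(-df, modules).scores["blue"].to_numpy()
        np.testing.assert_allclose(np.abs(e1), np.abs(e2), atol=1e-10)

    def test_orientation_follows_mean_profile(self):
        rng = np.random.default_rng(3)
        f = rng.standard_normal(15)
        df = pd.DataFrame({f"m{i}": f + 0.1 * rng.standard_normal(15)
                           for i in range(5)})
        eig = eigenmetabolites(df, pd.Series("red", index=df.columns))
        z = (df - df.mean()) / df.std(ddof=1)
        assert np.corrcoef(eig.scores["red"], z.mean(axis=1))[0, 1] > 0

    def test_variance_maximizing_combination(self):
        """The eigen-metabolite beats 1000 random unit-norm combinations and
        matches the top eigenvector of the member correlation matrix."""
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((20, 5)))
        df.columns = [f"m{i}" for i in range(5)]
        modules = pd.Series("green", index=df.columns)
        eig = eigenmetabolites(df, modules)
        z = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
        corr = np.corrcoef(z, rowvar=False)
        trace = np.trace(corr)
        for _ in range(1000):
            w = rng.standard_normal(5)
            w /= np.linalg.norm(w)
            assert eig.variance_explained["green"] >= (w @ corr @ w) / trace - 1e-12
        evals, evecs = np.linalg.eigh(corr)
        brute = z @ evecs[:, -1]
        r = np.corrcoef(eig.scores["green"], brute)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)


class TestModuleMembership:
    def test_single_metabolite_module_mm_one(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"solo": rng.standard_normal(10)})
        modules = pd.Series("turquoise", index=["solo"])
        eig = eigenmetabolites(df, modules)
        mm = module_membership(df, eig, modules)
        assert mm["mm"].iloc[0] == pytest.approx(1.0)

    def test_planted_module_membership_dominates(self, small_cohort):
        abundance, *_ , truth = small_cohort
        processed, _ = preprocess_pipeline(abundance, AnalysisConfig())
        det = ModuleDetector().fit(processed.values)
        mm = module_membership(processed.values, det.eigen_, det.modules_)
        assigned = mm[mm["metabolite_id"].map(det.modules_) != GREY]
        own = assigned[assigned["own_module"]]["mm"].abs().mean()
        cross = assigned[~assigned["own_module"]]["mm"].abs().mean()
        assert own > cross


def test_module_detector_is_cloneable_and_deterministic(small_cohort):
    abundance, *_ = small_cohort
    processed, _ = preprocess_pipeline(abundance, AnalysisConfig())
    det = ModuleDetector(cut_height=0.999)
    det2 = clone(det)
    l1 = det.fit(processed.values).modules_
    l2 = det2.fit(processed.values).modules_
    pd.testing.assert_series_equal(l1, l2)
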