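"""Preprocessing: missingness filter, KNN imputation, median scaling, log.

The stages compose in the protocol order — drop metabolites missing in more
than 30% of samples, impute the remainder by K-nearest-neighbor averaging
over metabolites (k=10), then median-scale each metabolite and apply the
natural log.  Each stage is exposed both as a scikit-learn transformer
(usable in a :class:`sklearn.pipeline.Pipeline`) and as a plain function on
:class:`~metamodtrend.datatypes.AbundanceTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import AbundanceTable, AnalysisConfig, ValidationError


@dataclass
class PreprocessReport:
    """Bookkeeping for the preprocessing stages."""

    n_removed: int = 0
    removed_ids: list = field(default_factory=list)
    n_imputed_entries: int = 0
    post_scaling_medians: pd.Series | None = None


# ---------------------------------------------------------------------------
# scikit-learn transformers

class MissingnessFilter(BaseEstimator, TransformerMixin):
    """Drop features whose missing fraction strictly exceeds ``max_frac``."""

    def __init__(self, max_frac: float = 0.30):
        self.max_frac = max_frac

    def fit(self, X, y=None):
        if not 0 <= self.max_frac <= 1:
            raise ValidationError("max_frac must be in [0,1]")
        X = pd.DataFrame(X)
        frac = X.isna().mean(axis=0)
        self.support_ = (frac <= self.max_frac).to_numpy()
        self.removed_ids_ = list(X.columns[~self.support_])
        if not self.support_.any():
            raise ValidationError(
                "all metabolites exceed the missingness cutoff "
                f"({self.max_frac:.0%}); nothing left to analyze"
            )
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X.loc[:, self.support_]


class KNNAbundanceImputer(BaseEstimator, TransformerMixin):
    """Impute missing entries from the k nearest metabolites.

    Neighbors are features (metabolites), the standard omics convention.
    The distance between two metabolites is the root-mean-square difference
    over samples where both are observed; pairs sharing no samples are
    non-neighbors.  A missing entry becomes the unweighted mean of the k
    nearest metabolites observed in that sample (fewer than k available:
    those available; none: the metabolite's own observed median).  Distance
    ties break by metabolite id order.  Observed entries are never changed.
    """

    def __init__(self, k: int = 10):
        self.k = k

    def fit(self, X, y=None):
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        vals = X.to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        if not obs.any(axis=0).all():
            dead = list(X.columns[~obs.any(axis=0)])
            raise ValidationError(
                f"metabolites with zero observed values: {dead} "
                "(run the missingness filter first)"
            )
        if obs.all():
            return X.copy()

        n_s, n_m = vals.shape
        # pairwise RMS distance over shared samples, vectorized
        filled = np.where(obs, vals, 0.0)
        o = obs.astype(float)
        sq = filled ** 2
        shared = o.T @ o                                   # n shared samples
        cross = filled.T @ filled
        sum_sq = sq.T @ o + o.T @ sq - 2.0 * cross          # sum (xi-xj)^2 over shared
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.sqrt(np.maximum(sum_sq, 0.0) / shared)
        dist[shared == 0] = np.inf
        np.fill_diagonal(dist, np.inf)

        # id-order rank as deterministic tie-break
        id_rank = np.argsort(np.argsort(X.columns.to_numpy()))

        out = vals.copy()
        medians = np.array([np.median(vals[obs[:, j], j]) for j in range(n_m)])
        for j in range(n_m):
            missing_rows = np.flatnonzero(~obs[:, j])
            if missing_rows.size == 0:
                continue
            d_j = dist[:, j]
            for s in missing_rows:
                cand = np.flatnonzero(obs[s] & np.isfinite(d_j))
                if cand.size == 0:
                    out[s, j] = medians[j]
                    continue
                order = cand[np.lexsort((id_rank[cand], d_j[cand]))]
                nearest = order[: self.k]
                out[s, j] = vals[s, nearest].mean()
        return pd.DataFrame(out, index=X.index, columns=X.columns)


class MedianLogScaler(BaseEstimator, TransformerMixin):
    """Divide each metabolite by its own median, then take the natural log.

    After scaling (before the log) every metabolite's median is exactly 1;
    the transform is invariant to per-metabolite multiplicative rescaling.
    """

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        self._check_positive(X)
        self.medians_ = X.median(axis=0)
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        self._check_positive(X)
        return np.log(X / self.medians_)

    @staticmethod
    def _check_positive(X):
        vals = X.to_numpy(dtype=float)
        bad = ~(vals > 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-positive value at sample {X.index[i]!r}, "
                f"metabolite {X.columns[j]!r}; cannot median-scale/log"
            )


# ---------------------------------------------------------------------------
# AbundanceTable-level functions

def filter_missingness(table: AbundanceTable, max_frac: float = 0.30):
    """Remove metabolites whose missing fraction strictly exceeds ``max_frac``."""
    f = MissingnessFilter(max_frac).fit(table.values)
    out = AbundanceTable(f.transform(table.values))
    report = PreprocessReport(n_removed=len(f.removed_ids_),
                              removed_ids=f.removed_ids_)
    return out, report


def knn_impute(table: AbundanceTable, k: int = 10) -> AbundanceTable:
    imp = KNNAbundanceImputer(k).fit(table.values)
    return AbundanceTable(imp.transform(table.values))


def normalize(table: AbundanceTable) -> AbundanceTable:
    scaler = MedianLogScaler().fit(table.values)
    return AbundanceTable(scaler.transform(table.values))


def preprocess_pipeline(table: AbundanceTable, config: AnalysisConfig | None = None):
    """filter -> impute -> median-scale/log, with an aggregate report."""
    cfg = config or AnalysisConfig()
    filtered, report = filter_missingness(table, cfg.missing_frac_max)
    report.n_imputed_entries = int(filtered.mask.to_numpy().sum())
    imputed = knn_impute(filtered, cfg.knn_k)
    scaler = MedianLogScaler().fit(imputed.values)
    normalized = AbundanceTable(scaler.transform(imputed.values))
    scaled = imputed.values / scaler.medians_
    report.post_scaling_medians = scaled.median(axis=0)
    return normalized, report
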