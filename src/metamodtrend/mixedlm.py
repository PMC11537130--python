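"""Random-intercept linear mixed models for longitudinal trend testing.

The model for feature value ``y_ij`` of patient ``i`` at visit ``j`` is::

    y_ij = x_ij' beta + b_i + eps_ij,   b_i ~ N(0, s2_b),  eps ~ N(0, s2_e)

with fixed effects for time since baseline (years), age at baseline, sex
and prior disease-modifying-therapy history.  Fitting is by REML: the
variance ratio ``theta = s2_b / s2_e`` is profiled over a bracketed 1-D
optimization, with generalized least squares for ``beta`` at each
``theta``.  The grouped structure makes each evaluation O(n): the
within-group inverse is ``I - theta/(1 + n_i theta) * J``.  Inference on
the time slope uses the Wald normal approximation (estimate +/- 1.96 SE).

``bh_adjust`` implements the Benjamini-Hochberg step-up FDR used across
the per-metabolite scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import ValidationError

_Z95 = 1.959963984540054  # Phi^-1(0.975)
_THETA_MAX = 1e5
_RSS_FLOOR = 1e-12


@dataclass
class LmeFit:
    """Fitted random-intercept model."""

    params: pd.Series          # fixed effects
    bse: pd.Series             # standard errors
    sigma2_b: float            # between-patient intercept variance
    sigma2_e: float            # residual variance
    theta: float               # sigma2_b / sigma2_e
    reml_criterion: float      # -2 * restricted log-likelihood (up to const)
    n_obs: int
    n_patients: int

    def slope(self, name: str = "time_years") -> dict:
        est = float(self.params[name])
        se = float(self.bse[name])
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        return {
            "estimate": est,
            "ci_low": est - _Z95 * se,
            "ci_high": est + _Z95 * se,
            "p": float(p),
        }


def _group_blocks(groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    boundaries = np.flatnonzero(sorted_groups[1:] != sorted_groups[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(groups)]])
    return order, starts, ends


def _profile(theta: float, X: np.ndarray, y: np.ndarray, starts, ends):
    """GLS at fixed theta; returns (criterion, beta, cov_unscaled, rss, logdetV)."""
    p = X.shape[1]
    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    logdet_v = 0.0
    for s, e in zip(starts, ends):
        Xi, yi = X[s:e], y[s:e]
        ni = e - s
        shrink = theta / (1.0 + ni * theta)
        xs, ys = Xi.sum(axis=0), yi.sum()
        xtwx += Xi.T @ Xi - shrink * np.outer(xs, xs)
        xtwy += Xi.T @ yi - shrink * xs * ys
        logdet_v += np.log1p(ni * theta)
    cov_unscaled = np.linalg.inv(xtwx)
    beta = cov_unscaled @ xtwy
    rss = 0.0
    for s, e in zip(starts, ends):
        ri = y[s:e] - X[s:e] @ beta
        ni = e - s
        shrink = theta / (1.0 + ni * theta)
        rss += ri @ ri - shrink * ri.sum() ** 2
    rss = max(rss, _RSS_FLOOR)
    n, = y.shape
    sign, logdet_xwx = np.linalg.slogdet(xtwx)
    crit = (n - p) * np.log(rss) + logdet_v + logdet_xwx
    return crit, beta, cov_unscaled, rss, logdet_v


def fit_random_intercept(y, X: pd.DataFrame, groups) -> LmeFit:
    """REML fit of the random-intercept model.

    ``X`` holds the covariate columns (an intercept is added); ``groups``
    are patient identifiers aligned with the rows of ``X`` and ``y``.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    design = X.copy()
    design.insert(0, "intercept", 1.0)
    Xm = design.to_numpy(dtype=float)
    n, p = Xm.shape
    if len(y) != n or len(groups) != n:
        raise ValidationError("y, X and groups must have equal length")

    counts = pd.Series(groups).value_counts()
    if (counts >= 2).sum() < 2:
        raise ValidationError(
            "need at least 2 patients with at least 2 visits each to "
            "identify the variance components"
        )

    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # name the latest column whose removal restores effective rank,
        # i.e. the redundant addition rather than the original it copies
        for j in range(p - 1, 0, -1):
            sub = np.delete(Xm, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValidationError(
                    f"singular design: column {design.columns[j]!r} is collinear"
                )
        raise ValidationError("singular design matrix")

    order, starts, ends = _group_blocks(groups)
    Xs, ys = Xm[order], y[order]

    def objective(theta):
        return _profile(theta, Xs, ys, starts, ends)[0]

    res = optimize.minimize_scalar(objective, bounds=(0.0, _THETA_MAX),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    theta = float(res.x)
    if objective(0.0) <= res.fun:
        theta = 0.0
    crit, beta, cov_unscaled, rss, _ = _profile(theta, Xs, ys, starts, ends)
    sigma2_e = rss / (n - p)
    bse = np.sqrt(np.maximum(np.diag(cov_unscaled) * sigma2_e, 0.0))
    names = list(design.columns)
    return LmeFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        sigma2_b=theta * sigma2_e,
        sigma2_e=sigma2_e,
        theta=theta,
        reml_criterion=crit,
        n_obs=n,
        n_patients=int(counts.size),
    )


def build_design(visits: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-sample covariates (time_years, age_baseline, sex, dmt_history),
    indexed by sample id, in abundance-table sample order when merged."""
    merged = visits.merge(cohort, on="patient_id", how="left", validate="m:1")
    if merged[["age_baseline", "sex", "dmt_history"]].isna().any().any():
        missing = merged.loc[merged["age_baseline"].isna(), "patient_id"].unique()
        raise ValidationError(f"patients without cohort covariates: {list(missing)}")
    return merged.set_index("sample_id")


def trend_scan(features: pd.DataFrame, visits: pd.DataFrame,
               cohort: pd.DataFrame, adjust: bool = True) -> pd.DataFrame:
    """Per-feature longitudinal trend via the random-intercept model.

    ``features`` is a samples x features matrix (metabolites or
    eigen-metabolites).  Every feature is fit with the same covariate set;
    the time slope, its Wald 95% CI and p-value are reported, BH-adjusted
    across features when ``adjust`` is set, sorted by p ascending.
    Per-feature failures become NA rows rather than silent drops.
    """
    if features.shape[1] == 0:
        return pd.DataFrame(columns=["feature", "estimate", "ci_low",
                                     "ci_high", "p", "error", "q"])
    design = build_design(visits, cohort).loc[features.index]
    X = design[["time_years", "age_baseline", "sex", "dmt_history"]].astype(float)
    groups = design["patient_id"].to_numpy()
    rows = []
    for feat in features.columns:
        y = features[feat].to_numpy(dtype=float)
        try:
            fit = fit_random_intercept(y, X, groups)
            rows.append({"feature": feat, **fit.slope("time_years")})
        except (ValidationError, np.linalg.LinAlgError) as exc:
            rows.append({"feature": feat, "estimate": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "error": str(exc)})
    out = pd.DataFrame(rows)
    if "error" not in out.columns:
        out["error"] = ""
    out["error"] = out["error"].fillna("")
    if adjust:
        ok = out["p"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"].to_numpy())
        out["q"] = q
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0,1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
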