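"""Metabolome change vs clinical change.

Per-patient feature deltas (last visit minus baseline, standardized to unit
SD across patients) enter logistic regression models of improvement status
— one per eigen-metabolite or per metabolite — adjusting for age at
baseline, sex, years of follow-up and prior disease-modifying-therapy
history; the reported effect is the odds ratio of improvement per SD of
feature change.  Partial Spearman correlation (rank, residualize on ranked
covariates, correlate residuals) relates eigen-metabolite deltas to
neuro-QOL item deltas.

The logistic fit is iteratively reweighted least squares with a deviance
convergence tolerance of 1e-8; complete separation is detected (diverging
coefficients or perfect classification) and flagged rather than rescued.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError

logger = logging.getLogger("metamodtrend")

_Z95 = 1.959963984540054
_MAX_ABS_COEF = 30.0


def delta_features(features: pd.DataFrame, visits: pd.DataFrame,
                   standardize: bool = True) -> pd.DataFrame:
    """Per-patient change (last visit minus baseline) for every feature.

    ``features`` is samples x features (processed values or eigen-
    metabolite scores).  Deltas are z-standardized across patients to unit
    sample SD; with a single patient standardization is skipped (flagged in
    the log).  Zero-variance features are dropped with a warning.
    """
    v = visits.sort_values(["patient_id", "time_years"])
    base_rows, last_rows, patients = [], [], []
    for pid, grp in v.groupby("patient_id", sort=True):
        if grp["time_years"].iloc[0] != 0:
            logger.warning("patient %s missing baseline visit; excluded", pid)
            continue
        if len(grp) < 2:
            logger.warning("patient %s has a single visit; excluded", pid)
            continue
        base_rows.append(grp["sample_id"].iloc[0])
        last_rows.append(grp["sample_id"].iloc[-1])
        patients.append(pid)
    delta = (features.loc[last_rows].to_numpy(dtype=float)
             - features.loc[base_rows].to_numpy(dtype=float))
    out = pd.DataFrame(delta, index=pd.Index(patients, name="patient_id"),
                       columns=features.columns)
    if not standardize or len(patients) < 2:
        if len(patients) < 2:
            logger.warning("fewer than 2 patients; deltas left unstandardized")
        return out
    sd = out.std(axis=0, ddof=1)
    dead = list(sd.index[sd == 0])
    if dead:
        logger.warning("zero-variance delta features excluded: %s", dead)
        out = out.drop(columns=dead)
        sd = sd.drop(dead)
    return (out - out.mean(axis=0)) / sd


@dataclass
class LogisticFit:
    """IRLS logistic regression result."""

    params: pd.Series
    bse: pd.Series
    deviance: float
    n_iter: int
    converged: bool
    separated: bool


def fit_logistic(X: pd.DataFrame, y, tol: float = 1e-8,
                 max_iter: int = 100) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    ``X`` holds the covariates (an intercept is added).  Separation is
    flagged when coefficients diverge or the fit classifies perfectly.
    """
    y = np.asarray(y, dtype=float)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValidationError("outcome must be binary 0/1")
    if len(classes) < 2:
        raise ValidationError("both outcome classes must be present")
    design = X.copy()
    design.insert(0, "intercept", 1.0)
    Xm = design.to_numpy(dtype=float)
    n, p = Xm.shape
    beta = np.zeros(p)
    dev_old = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(Xm @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-12)
        z = eta + (y - mu) / w
        wx = Xm * w[:, None]
        beta = np.linalg.solve(Xm.T @ wx, wx.T @ z)
        with np.errstate(divide="ignore"):
            dev = -2.0 * np.sum(y * np.log(np.maximum(mu, 1e-300))
                                + (1 - y) * np.log(np.maximum(1 - mu, 1e-300)))
        if abs(dev_old - dev) < tol:
            converged = True
            break
        dev_old = dev
    eta = np.clip(Xm @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    separated = bool(np.max(np.abs(beta)) > _MAX_ABS_COEF
                     or np.all((mu > 0.5) == (y == 1)) and
                     (np.min(mu[y == 1], initial=1) > 1 - 1e-6
                      or np.max(mu[y == 0], initial=0) < 1e-6))
    w = np.maximum(mu * (1 - mu), 1e-12)
    cov = np.linalg.inv(Xm.T @ (Xm * w[:, None]))
    bse = np.sqrt(np.diag(cov))
    names = list(design.columns)
    return LogisticFit(params=pd.Series(beta, index=names),
                       bse=pd.Series(bse, index=names),
                       deviance=float(dev), n_iter=n_iter,
                       converged=converged, separated=separated)


def _covariate_frame(cohort: pd.DataFrame, visits: pd.DataFrame,
                     patients) -> pd.DataFrame:
    follow_up = visits.groupby("patient_id")["time_years"].max()
    cov = cohort.set_index("patient_id").loc[list(patients),
                                             ["age_baseline", "sex", "dmt_history"]]
    cov["follow_up_years"] = follow_up.reindex(cov.index)
    return cov.astype(float)


def logistic_improvement(deltas: pd.Series, labels: pd.Series,
                         cohort: pd.DataFrame, visits: pd.DataFrame) -> dict:
    """Odds ratio of improvement per SD change in one feature.

    Adjusts for age at baseline, sex, follow-up years and DMT history.
    Separated fits are flagged and report no odds ratio.
    """
    patients = deltas.index
    cov = _covariate_frame(cohort, visits, patients)
    X = cov.copy()
    X.insert(0, "delta", deltas.to_numpy(dtype=float))
    y = labels.reindex(patients).to_numpy(dtype=float)
    fit = fit_logistic(X, y)
    if fit.separated:
        return {"feature": deltas.name, "or": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "p": np.nan, "separated": True}
    coef = float(fit.params["delta"])
    se = float(fit.bse["delta"])
    z = coef / se
    return {
        "feature": deltas.name,
        "or": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - _Z95 * se)),
        "ci_high": float(np.exp(coef + _Z95 * se)),
        "p": float(2.0 * stats.norm.sf(abs(z))),
        "separated": False,
    }


def improvement_scan(deltas: pd.DataFrame, labels: pd.Series,
                     cohort: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """One logistic improvement model per feature (module or metabolite).

    Returns the association table with volcano-plot coordinates
    ``(log_or, neg_log10_p)``; separation-flagged features keep their row
    but carry NaN coordinates so they drop out of the volcano.
    """
    if deltas.shape[1] == 0:
        return pd.DataFrame(columns=["feature", "or", "ci_low", "ci_high",
                                     "p", "separated", "log_or", "neg_log10_p"])
    rows = []
    for feat in deltas.columns:
        try:
            rows.append(logistic_improvement(deltas[feat], labels, cohort, visits))
        except (ValidationError, np.linalg.LinAlgError) as exc:
            rows.append({"feature": feat, "or": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "separated": False,
                         "error": str(exc)})
    out = pd.DataFrame(rows)
    out["log_or"] = np.log(out["or"])
    out["neg_log10_p"] = -np.log10(out["p"])
    return out


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    All vectors are rank-transformed (midranks); ranked x and y are
    residualized on the ranked covariates plus intercept by least squares,
    and rho is the Pearson correlation of the residuals.  The p-value uses
    ``t = rho * sqrt((n - 2 - k) / (1 - rho^2))`` on ``n - 2 - k`` degrees
    of freedom.  Without covariates this is the ordinary Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValidationError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input vector; correlation undefined")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValidationError("need n > k + 2 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack([np.ones(n)]
                         + [stats.rankdata(cov[:, j]) for j in range(k)])
    res_x = rx - rc @ np.linalg.lstsq(rc, rx, rcond=None)[0]
    res_y = ry - rc @ np.linalg.lstsq(rc, ry, rcond=None)[0]
    denom = np.sqrt(np.sum(res_x ** 2) * np.sum(res_y ** 2))
    if denom == 0:
        raise ValidationError("degenerate residuals; correlation undefined")
    rho = float(np.sum(res_x * res_y) / denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho ** 2))
    return rho, float(2.0 * stats.t.sf(abs(t), df))


def qol_correlation(eigen_deltas: pd.DataFrame, qol_deltas: pd.DataFrame,
                    cohort: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Module x neuro-QOL-item partial Spearman table (heat-map layout)."""
    if eigen_deltas.shape[1] == 0 or qol_deltas.shape[1] == 0:
        return pd.DataFrame(columns=["module", "item", "rho", "p"])
    patients = eigen_deltas.index
    cov = _covariate_frame(cohort, visits, patients).to_numpy()
    rows = []
    for mod in eigen_deltas.columns:
        for item in qol_deltas.columns:
            rho, p = partial_spearman(eigen_deltas[mod].to_numpy(),
                                      qol_deltas.loc[patients, item].to_numpy(),
                                      cov)
            rows.append({"module": mod, "item": item, "rho": rho, "p": p})
    return pd.DataFrame(rows)
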