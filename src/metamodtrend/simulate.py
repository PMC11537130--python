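"""Synthetic longitudinal metabolomics cohort generator.

Emulates the statistical structure the analysis pipeline assumes: a small
treated cohort followed over ~3 years, a few hundred log-normal metabolites
with planted correlated modules, per-year treatment slopes on a subset of
modules, left-censored missingness, baseline covariates, and clinical
disability/quality-of-life outcomes in which improvement is linked to one
target module's change through a logistic model with a known odds ratio.

The generating model for metabolite ``m`` (module ``M``), patient ``i``,
visit ``j`` on the log scale is::

    x_mij = mu_m + lambda_m * f_Mij + b_mi + delta_M * t_ij + eps_mij

with a shared per-(module, patient, visit) factor ``f`` inducing a
within-module pairwise correlation of approximately ``rho``; abundances are
emitted as ``exp(x)`` so they are strictly positive.  Ground truth (module
labels, slopes, improvement probabilities and labels, missingness
mechanisms) is returned alongside the tables for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    AbundanceTable,
    NEUROQOL_ITEMS,
    ValidationError,
)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the cohort the pipeline was designed for: 31 patients,
    four roughly annual visits, ~68% female, ~71% previously treated, mean
    baseline age ~41 (SD ~10), improvement prevalence ~0.29, and per-year
    module slopes of -0.10 and -0.12 on the log scale.
    """

    n_patients: int = 31
    visits_per_patient: int = 4
    visit_spacing_years: float = 1.0
    time_jitter_years: float = 0.15
    n_metabolites: int = 300
    module_sizes: tuple = (40, 30, 25, 20)
    within_module_cor: float = 0.6
    #: module index -> per-year slope on the log scale
    affected_modules: dict = field(default_factory=lambda: {0: -0.10, 1: -0.12})
    #: module whose per-patient change drives the improvement outcome
    target_module: int = 1
    patient_sd: float = 0.20
    noise_sd: float = 0.20
    missing_rate: float = 0.10
    censor_share: float = 0.5
    improvement_or: float = 0.3
    improvement_prevalence: float = 0.29
    age_mean: float = 41.0
    age_sd: float = 10.0
    p_female: float = 0.68
    p_prior_dmt: float = 0.71
    qol_drift: dict = field(default_factory=lambda: {item: 0.0 for item in NEUROQOL_ITEMS})
    seed: Optional[int] = None

    def __post_init__(self):
        if sum(self.module_sizes) > self.n_metabolites:
            raise ValidationError("module sizes exceed metabolite count")
        if not 0 <= self.within_module_cor < 1:
            raise ValidationError("within_module_cor must be in [0,1)")
        for p in (self.missing_rate, self.censor_share, self.p_female,
                  self.p_prior_dmt, self.improvement_prevalence):
            if not 0 <= p <= 1:
                raise ValidationError("probabilities must be in [0,1]")
        if self.missing_rate >= 1:
            raise ValidationError("missing_rate must be < 1")
        if self.improvement_or <= 0:
            raise ValidationError("improvement_or must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted structure emitted next to the synthetic tables."""

    module_labels: pd.Series          # metabolite id -> module index (-1 = background)
    module_slopes: dict               # module index -> per-year slope
    target_module: int
    improvement_prob: pd.Series       # patient id -> latent P(improved)
    improvement_label: pd.Series      # patient id -> 0/1
    eigen_delta: pd.Series            # patient id -> standardized target-module change
    missing_mechanism: pd.DataFrame   # (sample_id, metabolite_id, mechanism)

    def to_frames(self) -> dict:
        modules = pd.DataFrame({
            "metabolite_id": self.module_labels.index,
            "true_module": self.module_labels.to_numpy(),
            "true_slope": [
                self.module_slopes.get(int(m), 0.0) if m >= 0 else 0.0
                for m in self.module_labels
            ],
        })
        patients = pd.DataFrame({
            "patient_id": self.improvement_label.index,
            "improvement_prob": self.improvement_prob.to_numpy(),
            "improved": self.improvement_label.to_numpy(),
            "target_eigen_delta": self.eigen_delta.to_numpy(),
        })
        return {
            "ground_truth_modules": modules,
            "ground_truth_patients": patients,
            "ground_truth_missingness": self.missing_mechanism,
        }


def _module_index(cfg: SimConfig) -> np.ndarray:
    labels = np.full(cfg.n_metabolites, -1, dtype=int)
    start = 0
    for m, size in enumerate(cfg.module_sizes):
        labels[start:start + size] = m
        start += size
    return labels


def _visit_times(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_patients, visits) times; baseline exactly 0, later visits jittered."""
    base = np.arange(cfg.visits_per_patient) * cfg.visit_spacing_years
    times = np.tile(base, (cfg.n_patients, 1)).astype(float)
    jitter = rng.uniform(-cfg.time_jitter_years, cfg.time_jitter_years,
                         size=times.shape)
    jitter[:, 0] = 0.0
    times += jitter
    # jitter below half the spacing keeps times strictly increasing
    return times


def generate_cohort(cfg: SimConfig):
    """Generate a full synthetic cohort with ground truth.

    Returns ``(abundance, visits, cohort, pathways, clinical, truth)``.
    The abundance table already carries injected missingness.
    """
    if cfg.seed is None:
        raise ValidationError("SimConfig.seed is required")
    rng = np.random.default_rng(cfg.seed)

    n_p, n_v, n_m = cfg.n_patients, cfg.visits_per_patient, cfg.n_metabolites
    patient_ids = [f"P{i + 1:02d}" for i in range(n_p)]
    times = _visit_times(cfg, rng)
    sample_ids = [f"{patient_ids[i]}_V{j + 1}" for i in range(n_p) for j in range(n_v)]

    module_of = _module_index(cfg)
    rho = cfg.within_module_cor
    sigma_w = np.hypot(cfg.patient_sd, cfg.noise_sd)
    lam = np.sqrt(rho / (1.0 - rho)) * sigma_w if rho > 0 else 0.0

    mu = rng.normal(5.0, 1.0, size=n_m)
    n_modules = len(cfg.module_sizes)
    factors = rng.standard_normal((n_modules, n_p, n_v))
    b = rng.normal(0.0, cfg.patient_sd, size=(n_m, n_p))
    eps = rng.normal(0.0, cfg.noise_sd, size=(n_p, n_v, n_m))

    slopes = np.zeros(n_m)
    for m_idx, delta in cfg.affected_modules.items():
        slopes[module_of == m_idx] = delta

    x = np.empty((n_p, n_v, n_m))
    for m in range(n_m):
        mod = module_of[m]
        f = factors[mod] if mod >= 0 else 0.0
        x[:, :, m] = (mu[m] + lam * (f if mod >= 0 else 0.0)
                      + b[m][:, None] + slopes[m] * times + eps[:, :, m])

    values = pd.DataFrame(
        np.exp(x).reshape(n_p * n_v, n_m),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"met_{k + 1:04d}" for k in range(n_m)],
    )
    abundance = AbundanceTable(values).validate()

    visits = pd.DataFrame({
        "patient_id": np.repeat(patient_ids, n_v),
        "sample_id": sample_ids,
        "time_years": times.reshape(-1),
    })

    cohort = pd.DataFrame({
        "patient_id": patient_ids,
        "age_baseline": np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n_p), 18, 70).round(1),
        "sex": rng.binomial(1, cfg.p_female, n_p),
        "dmt_history": rng.binomial(1, cfg.p_prior_dmt, n_p),
    })

    pathways = _pathway_map(cfg, abundance.metabolite_ids, module_of, rng)

    # Improvement linked to the target module's factor-trajectory change
    tm = cfg.target_module if cfg.target_module < n_modules else 0
    delta_t = cfg.affected_modules.get(tm, 0.0)
    raw_delta = (factors[tm, :, -1] + delta_t * times[:, -1]) - factors[tm, :, 0]
    sd = raw_delta.std(ddof=1)
    z = (raw_delta - raw_delta.mean()) / sd if sd > 0 else raw_delta * 0.0
    logit_prev = np.log(cfg.improvement_prevalence / (1 - cfg.improvement_prevalence))
    prob = 1.0 / (1.0 + np.exp(-(logit_prev + np.log(cfg.improvement_or) * z)))
    labels = rng.binomial(1, prob)

    clinical = generate_clinical_outcomes(
        patient_ids, labels, times, int(rng.integers(2**31)), qol_drift=cfg.qol_drift
    )

    abundance, mechanism = inject_missingness(
        abundance, cfg.missing_rate, cfg.censor_share, int(rng.integers(2**31))
    )

    truth = GroundTruth(
        module_labels=pd.Series(module_of, index=abundance.metabolite_ids),
        module_slopes=dict(cfg.affected_modules),
        target_module=tm,
        improvement_prob=pd.Series(prob, index=patient_ids),
        improvement_label=pd.Series(labels, index=patient_ids),
        eigen_delta=pd.Series(z, index=patient_ids),
        missing_mechanism=mechanism,
    )
    return abundance, visits, cohort, pathways, clinical, truth


def _pathway_map(cfg, metabolite_ids, module_of, rng, bg_size: int = 10) -> pd.DataFrame:
    """Planted modules map to their own sub-pathways; background metabolites
    are chunked into size-``bg_size`` background pathways."""
    sub = np.empty(len(metabolite_ids), dtype=object)
    for m in range(len(cfg.module_sizes)):
        sub[module_of == m] = f"module_pathway_{m + 1}"
    bg_idx = np.flatnonzero(module_of == -1)
    for chunk, start in enumerate(range(0, len(bg_idx), bg_size)):
        sub[bg_idx[start:start + bg_size]] = f"background_pathway_{chunk + 1}"
    super_pw = np.where(module_of >= 0, "planted", "background")
    return pd.DataFrame({
        "metabolite_id": list(metabolite_ids),
        "sub_pathway": sub,
        "super_pathway": super_pw,
    })


def inject_missingness(table: AbundanceTable, rate: float, censor_share: float,
                       seed: int):
    """Mask ~``rate`` of entries; ``censor_share`` of the masked entries are
    drawn from each metabolite's lowest values (left-censoring), the rest
    uniformly at random.  Observed values are untouched.

    Returns ``(masked_table, mechanism)`` where ``mechanism`` tags each
    masked entry as ``censored`` or ``random``.
    """
    if not 0 <= rate < 1:
        raise ValidationError("missing rate must be in [0,1)")
    if not 0 <= censor_share <= 1:
        raise ValidationError("censor_share must be in [0,1]")
    rng = np.random.default_rng(seed)
    vals = table.values.to_numpy(dtype=float).copy()
    n_s, n_m = vals.shape
    n_mask = int(round(rate * vals.size))
    empty = pd.DataFrame(columns=["sample_id", "metabolite_id", "mechanism"])
    if n_mask == 0:
        return table.copy(), empty

    n_cens = int(round(censor_share * n_mask))
    masked = np.zeros_like(vals, dtype=bool)
    records = []

    # left-censored slots: distribute over metabolites, mask within the
    # lowest ~30% of each chosen metabolite's values
    counts = rng.multinomial(n_cens, np.full(n_m, 1.0 / n_m))
    pool_size = max(1, int(np.ceil(0.3 * n_s)))
    for j in np.flatnonzero(counts):
        c = min(int(counts[j]), n_s)
        order = np.argsort(vals[:, j], kind="stable")
        pool = order[: max(pool_size, c)]
        chosen = rng.choice(pool, size=c, replace=False)
        masked[chosen, j] = True
        records.extend((int(s), j, "censored") for s in chosen)

    # remaining slots uniformly at random among still-observed entries
    n_rand = n_mask - int(masked.sum())
    if n_rand > 0:
        flat_open = np.flatnonzero(~masked.reshape(-1))
        chosen = rng.choice(flat_open, size=n_rand, replace=False)
        rows, cols = np.unravel_index(chosen, vals.shape)
        masked[rows, cols] = True
        records.extend((int(r), int(c), "random") for r, c in zip(rows, cols))

    vals[masked] = np.nan
    out = AbundanceTable(pd.DataFrame(vals, index=table.sample_ids,
                                      columns=table.metabolite_ids))
    mechanism = pd.DataFrame(
        [(table.sample_ids[s], table.metabolite_ids[j], tag)
         for s, j, tag in sorted(records)],
        columns=["sample_id", "metabolite_id", "mechanism"],
    )
    return out, mechanism


def generate_clinical_outcomes(patient_ids, improvement_labels, times, seed,
                               qol_drift=None) -> pd.DataFrame:
    """Per-visit clinical outcomes consistent with each patient's label.

    Improved patients are constructed to satisfy the overall disability
    response score (ODRS) positivity condition at the final visit; others
    stay at or below zero (stable, or worsening on one or two components).
    EDSS stays on the 0-10 half-point grid; timed tests stay positive;
    neuro-QOL T-scores are N(50, 8) at baseline with configurable per-item
    per-year drift.
    """
    rng = np.random.default_rng(seed)
    if qol_drift is None:
        qol_drift = {item: 0.0 for item in NEUROQOL_ITEMS}
    times = np.asarray(times, dtype=float)
    n_p, n_v = times.shape
    labels = np.asarray(improvement_labels, dtype=int)

    rows = []
    edss_grid = np.arange(1.0, 5.6, 0.5)
    for i, pid in enumerate(patient_ids):
        edss0 = float(rng.choice(edss_grid, p=_edss_weights(edss_grid)))
        t25fw0 = float(np.exp(rng.normal(np.log(6.5), 0.35)))
        hptd0 = float(np.exp(rng.normal(np.log(27.0), 0.30)))
        hptn0 = float(np.exp(rng.normal(np.log(27.0), 0.30)))
        pst0 = float(rng.normal(50, 12))
        qol0 = {item: float(rng.normal(50, 8)) for item in NEUROQOL_ITEMS}

        if labels[i] == 1:
            # guarantee at least one improving component at the final visit
            t25_rel = -float(rng.uniform(0.18, 0.30))       # >=15% faster: +1
            hptd_rel = float(rng.uniform(-0.10, 0.10))       # neutral
            hptn_rel = float(rng.uniform(-0.10, 0.10))
            edss_change = -1.0 if rng.random() < 0.5 and edss0 >= 1.0 else 0.0
        elif rng.random() < 0.5:
            # stable: every change inside the 15% / 1.0-point bands
            t25_rel = float(rng.uniform(-0.10, 0.10))
            hptd_rel = float(rng.uniform(-0.10, 0.10))
            hptn_rel = float(rng.uniform(-0.10, 0.10))
            edss_change = float(rng.choice([0.0, 0.5]))
        else:
            # worsened on one or two components, none improving
            t25_rel = float(rng.uniform(0.16, 0.30))
            hptd_rel = float(rng.uniform(0.0, 0.10))
            hptn_rel = float(rng.uniform(0.16, 0.30)) if rng.random() < 0.5 else 0.0
            edss_change = 1.0 if rng.random() < 0.3 else 0.0

        edss_f = float(np.clip(edss0 + edss_change, 0.0, 10.0))
        finals = {
            "edss": edss_f,
            "t25fw_s": t25fw0 * (1 + t25_rel),
            "hpt_dom_s": hptd0 * (1 + hptd_rel),
            "hpt_nondom_s": hptn0 * (1 + hptn_rel),
            "pst": pst0 + float(rng.normal(0, 2)),
        }
        base = {"edss": edss0, "t25fw_s": t25fw0, "hpt_dom_s": hptd0,
                "hpt_nondom_s": hptn0, "pst": pst0}

        t_last = times[i, -1]
        for j in range(n_v):
            frac = times[i, j] / t_last if t_last > 0 else 0.0
            row = {"patient_id": pid, "time_years": times[i, j]}
            for key in base:
                val = base[key] + frac * (finals[key] - base[key])
                if key == "edss":
                    if j == 0:
                        val = edss0
                    elif j == n_v - 1:
                        val = edss_f
                    else:
                        val = float(np.clip(np.round(val * 2) / 2, 0.0, 10.0))
                elif 0 < j < n_v - 1:
                    val *= float(np.exp(rng.normal(0, 0.02))) if key != "pst" else 1.0
                row[key] = val
            for item in NEUROQOL_ITEMS:
                drift = qol_drift.get(item, 0.0)
                noise = float(rng.normal(0, 3)) if j > 0 else 0.0
                row[f"nqol_{item}"] = qol0[item] + drift * times[i, j] + noise
            rows.append(row)
    return pd.DataFrame(rows)


def _edss_weights(grid: np.ndarray) -> np.ndarray:
    # mild-disability-heavy distribution (median ~2, IQR ~1.25-3)
    w = np.exp(-0.5 * ((grid - 2.0) / 1.3) ** 2)
    return w / w.sum()
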