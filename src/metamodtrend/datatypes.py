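"""Core data containers and run configuration.

The pipeline operates on a small set of tabular structures:

* :class:`AbundanceTable` — samples x metabolites relative abundances, with
  missing entries encoded as NaN (the missingness mask is derived from NaN).
* visit records, cohort covariates, pathway annotations and per-visit
  clinical outcomes are plain :class:`pandas.DataFrame` objects validated by
  the loaders in :mod:`metamodtrend.io`.
* :class:`AnalysisConfig` — every tunable knob of the analysis with the
  defaults the pipeline was designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

#: Neuro-QOL short-form items and the direction of a favorable change.
#: ``higher_better=False`` means an increase indicates deterioration.
NEUROQOL_ITEMS: dict[str, bool] = {
    "anxiety": False,
    "cognitive_function": True,
    "depression": False,
    "emotional_dyscontrol": False,
    "fatigue": False,
    "lower_extremity": True,
    "positive_affect_wellbeing": True,
    "satisfaction_social_roles": True,
    "participation_social_roles": True,
    "sleep_disturbance": False,
    "stigma": False,
    "upper_extremity": True,
}

#: Placeholder per-item minimal detectable change (T-score points).
#: These are NOT the published conditional MDC values (which are cited
#: externally and not printed anywhere reusable); they are synthetic
#: defaults that must be replaced with the canonical table for real use.
DEFAULT_NEUROQOL_MDC: dict[str, float] = {item: 5.0 for item in NEUROQOL_ITEMS}

CLINICAL_COLUMNS = ["edss", "t25fw_s", "hpt_dom_s", "hpt_nondom_s", "pst"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AbundanceTable:
    """Samples x metabolites matrix of positive relative abundances.

    ``values`` is a DataFrame indexed by sample id with metabolite-id
    columns; missing measurements are NaN.  Observed entries must be
    strictly positive.
    """

    values: pd.DataFrame

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicator (True = missing)."""
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def validate(self) -> "AbundanceTable":
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicated sample ids: {dupes}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicated metabolite ids: {dupes}")
        vals = self.values.to_numpy(dtype=float)
        bad = (vals <= 0) & ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "non-positive abundance at sample "
                f"{self.values.index[i]!r}, metabolite {self.values.columns[j]!r}"
            )
        return self

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.values.copy())


def validate_visits(visits: pd.DataFrame) -> pd.DataFrame:
    """Check visit records: per-patient baseline at t=0, strictly increasing times."""
    required = {"patient_id", "sample_id", "time_years"}
    missing = required - set(visits.columns)
    if missing:
        raise ValidationError(f"visit table missing columns: {sorted(missing)}")
    if visits["sample_id"].duplicated().any():
        raise ValidationError("duplicated sample ids in visit table")
    if (visits["time_years"] < 0).any():
        raise ValidationError("negative time_years in visit table")
    for pid, grp in visits.groupby("patient_id", sort=False):
        t = np.sort(grp["time_years"].to_numpy(dtype=float))
        if t[0] != 0:
            raise ValidationError(f"patient {pid!r} has no baseline (t=0) visit")
        if (np.sum(t == 0)) != 1:
            raise ValidationError(f"patient {pid!r} has multiple baseline visits")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError(f"patient {pid!r} visit times not strictly increasing")
    return visits


def validate_cohort(cohort: pd.DataFrame, visits: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    required = {"patient_id", "age_baseline", "sex", "dmt_history"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValidationError(f"cohort table missing columns: {sorted(missing)}")
    if cohort["patient_id"].duplicated().any():
        raise ValidationError("duplicated patient ids in cohort table")
    for col in ("sex", "dmt_history"):
        vals = set(cohort[col].unique())
        if not vals <= {0, 1}:
            raise ValidationError(f"{col} must be coded 0/1, got {sorted(vals)}")
    if visits is not None:
        unknown = set(visits["patient_id"]) - set(cohort["patient_id"])
        if unknown:
            raise ValidationError(f"visit patients missing from cohort table: {sorted(unknown)}")
    return cohort


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "time_years"} | set(CLINICAL_COLUMNS)
    missing = required - set(clinical.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
    edss = clinical["edss"].to_numpy(dtype=float)
    on_grid = np.isclose(edss * 2, np.round(edss * 2), atol=1e-9)
    in_range = (edss >= 0) & (edss <= 10)
    bad = ~(on_grid & in_range)
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ValidationError(
            f"EDSS value {edss[row]} off the 0-10 half-point grid at row {row}"
        )
    for col in ("t25fw_s", "hpt_dom_s", "hpt_nondom_s"):
        v = clinical[col].to_numpy(dtype=float)
        if np.any(v[~np.isnan(v)] <= 0):
            row = int(np.argwhere((v <= 0) & ~np.isnan(v))[0][0])
            raise ValidationError(f"non-positive {col} at row {row}")
    return clinical


def validate_pathways(pathways: pd.DataFrame) -> pd.DataFrame:
    required = {"metabolite_id", "sub_pathway"}
    missing = required - set(pathways.columns)
    if missing:
        raise ValidationError(f"pathway table missing columns: {sorted(missing)}")
    if pathways["metabolite_id"].duplicated().any():
        raise ValidationError("metabolite mapped to more than one sub-pathway")
    return pathways


@dataclass
class AnalysisConfig:
    """All tunable parameters of the analysis pipeline.

    Defaults mirror the published protocol where one is stated (30%
    missingness cutoff, k=10 imputation neighbors, soft power 12, minimum
    pathway size 5) and explicit artifact choices elsewhere.
    """

    missing_frac_max: float = 0.30
    knn_k: int = 10
    soft_power: float = 12.0
    network_sign: str = "unsigned"  # "unsigned" | "signed"
    tree_cut_height: float = 0.9995
    min_module_size: int = 10
    gsea_min_set: int = 5
    gsea_weight: float = 1.0
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: Optional[int] = None
    neuroqol_mdc: dict = field(default_factory=lambda: dict(DEFAULT_NEUROQOL_MDC))

    def __post_init__(self):
        if not 0 <= self.missing_frac_max <= 1:
            raise ValidationError("missing_frac_max must be in [0,1]")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.soft_power <= 0:
            raise ValidationError("soft_power must be positive")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValidationError("network_sign must be 'unsigned' or 'signed'")
        if not 0 < self.tree_cut_height <= 1:
            raise ValidationError("tree_cut_height must be in (0,1]")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if self.gsea_min_set < 1:
            raise ValidationError("gsea_min_set must be >= 1")
        if self.gsea_weight < 0:
            raise ValidationError("gsea_weight must be >= 0")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0,1)")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValidationError("a seed is required for stochastic stages")
        return int(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
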