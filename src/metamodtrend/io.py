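"""Reading and writing the pipeline's tabular inputs and outputs.

All tables are delimited text (TSV or CSV, chosen by file extension) with a
header row.  Missing abundances are encoded as an empty field or ``NA``.
Writing is deterministic: the same in-memory tables produce byte-identical
files, which underpins the pipeline's reproducibility contract.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Mapping

import pandas as pd

from .datatypes import (
    AbundanceTable,
    AnalysisConfig,
    ValidationError,
    validate_clinical,
    validate_cohort,
    validate_pathways,
    validate_visits,
)

logger = logging.getLogger("metamodtrend")

_NA_TOKENS = ["", "NA", "NaN", "nan"]


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=index_col,
        na_values=_NA_TOKENS,
        keep_default_na=False,
        float_precision="round_trip",
    )


def load_abundance(path) -> AbundanceTable:
    """Load a samples x metabolites abundance matrix (first column = sample id)."""
    df = _read_table(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df.astype(float)).validate()


def load_dataset(
    abundance_path,
    visits_path,
    cohort_path,
    pathways_path,
    clinical_path,
    config: AnalysisConfig | None = None,
):
    """Load and cross-validate the five input tables.

    Returns ``(abundance, visits, cohort, pathways, clinical)``.  Every
    abundance sample must have a visit record; structural violations
    (duplicate ids, EDSS off the half-point grid, orphan samples) raise
    :class:`ValidationError` before any analysis stage can run.
    """
    abundance = load_abundance(abundance_path)
    visits = validate_visits(_read_table(visits_path))
    visits["sample_id"] = visits["sample_id"].astype(str)
    cohort = validate_cohort(_read_table(cohort_path), visits)
    pathways = validate_pathways(_read_table(pathways_path))
    clinical = validate_clinical(_read_table(clinical_path))

    orphans = set(abundance.sample_ids) - set(visits["sample_id"])
    if orphans:
        raise ValidationError(
            f"abundance samples without visit metadata: {sorted(orphans)}"
        )

    logger.info(
        "loaded dataset: %d samples, %d patients, %d metabolites, "
        "missing fraction %.4f",
        abundance.n_samples,
        cohort.shape[0],
        abundance.n_metabolites,
        float(abundance.mask.to_numpy().mean()),
    )
    return abundance, visits, cohort, pathways, clinical


def write_results(
    stage_outputs: Mapping[str, pd.DataFrame],
    out_dir,
    config: AnalysisConfig | None = None,
) -> dict:
    """Write one TSV per result table plus a run manifest.

    ``stage_outputs`` maps a result name (e.g. ``trend_results``) to a
    DataFrame; each is written as ``<name>.tsv``.  An empty DataFrame still
    produces a header-only file.  The manifest records the configuration,
    seed and per-table row counts.  Re-running with identical inputs and
    seed reproduces byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "tables": {},
    }
    for name, df in stage_outputs.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        manifest["tables"][name] = {"path": f"{name}.tsv", "n_rows": int(df.shape[0])}
    manifest_path = os.path.join(out_dir, "run_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["tables"]["run_manifest"] = {"path": "run_manifest.json"}
    return manifest


def write_abundance(table: AbundanceTable, path) -> None:
    """Write an abundance matrix; NaN entries are emitted as ``NA``."""
    table.values.to_csv(
        path, sep=_sep_for(path), na_rep="NA", index_label="sample_id",
        lineterminator="\n",
    )
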