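"""End-to-end orchestration of the analysis stages.

``run_all`` executes preprocess -> module detection -> trend tests ->
pathway enrichment -> clinical scoring -> association on a dataset (loaded
or simulated) and writes one TSV per result table plus a run manifest.
Given the same inputs, configuration and seed, outputs are byte-identical
across runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import association, clinical, enrichment, network, preprocess
from .datatypes import AbundanceTable, AnalysisConfig, ValidationError
from .io import write_results
from .mixedlm import trend_scan
from .simulate import SimConfig, generate_cohort

logger = logging.getLogger("metamodtrend")


def qol_delta_table(clinical_df: pd.DataFrame) -> pd.DataFrame:
    """Per-patient neuro-QOL T-score change (last visit minus baseline)."""
    items = [c for c in clinical_df.columns if c.startswith("nqol_")]
    rows = {}
    for pid, grp in clinical_df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_years")
        rows[pid] = (grp.iloc[-1][items].astype(float)
                     - grp.iloc[0][items].astype(float))
    out = pd.DataFrame(rows).T
    out.index.name = "patient_id"
    out.columns = [c[len("nqol_"):] for c in items]
    return out


def run_all(abundance: AbundanceTable, visits: pd.DataFrame,
            cohort: pd.DataFrame, pathways: pd.DataFrame,
            clinical_df: pd.DataFrame, config: AnalysisConfig,
            improvement: str = "odrs") -> dict:
    """Run every analysis stage; returns a dict of result DataFrames."""
    seed = config.require_seed()
    results: dict[str, pd.DataFrame] = {}

    processed, report = preprocess.preprocess_pipeline(abundance, config)
    results["processed_abundance"] = processed.values.reset_index()
    results["preprocess_report"] = pd.DataFrame({
        "n_removed": [report.n_removed],
        "removed_ids": [";".join(map(str, report.removed_ids))],
        "n_imputed_entries": [report.n_imputed_entries],
    })

    detector = network.ModuleDetector(
        beta=config.soft_power, sign_mode=config.network_sign,
        cut_height=config.tree_cut_height,
        min_module_size=config.min_module_size,
    ).fit(processed.values)
    modules = detector.modules_
    eigen = detector.eigen_
    results["modules"] = modules.rename("module").rename_axis(
        "metabolite_id").reset_index()
    results["eigen"] = eigen.scores.rename_axis("sample_id").reset_index()
    results["module_membership"] = network.module_membership(
        processed.values, eigen, modules)

    trend_mets = trend_scan(processed.values, visits, cohort)
    results["trend_metabolites"] = trend_mets
    results["trend_eigen"] = trend_scan(eigen.scores, visits, cohort)

    ranked = enrichment.rank_statistics(trend_mets)
    results["enrichment"] = enrichment.gsea_scan(
        ranked, pathways, min_set=config.gsea_min_set,
        n_perm=config.n_permutations, seed=seed, weight=config.gsea_weight)

    responses = clinical.compute_disability_responses(clinical_df)
    results["improvement"] = responses
    base_final = []
    for pid, grp in clinical_df.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_years")
        base_final.append((grp["edss"].iloc[0], grp["edss"].iloc[-1]))
    w, p = clinical.wilcoxon_signed_rank([b for b, _ in base_final],
                                         [f for _, f in base_final])
    results["edss_wilcoxon"] = pd.DataFrame({"w": [w], "p": [p]})
    results["qol_change"] = clinical.neuroqol_improvement(
        clinical_df, config.neuroqol_mdc)

    label_col = "odrs_improved" if improvement == "odrs" else "edss_plus_improved"
    labels = responses.set_index("patient_id")[label_col].astype(int)

    eigen_deltas = association.delta_features(eigen.scores, visits)
    met_deltas = association.delta_features(processed.values, visits)
    try:
        results["association_modules"] = association.improvement_scan(
            eigen_deltas, labels, cohort, visits)
        results["association_metabolites"] = association.improvement_scan(
            met_deltas, labels, cohort, visits)
    except ValidationError as exc:
        logger.warning("improvement association skipped: %s", exc)
        results["association_modules"] = pd.DataFrame(
            columns=["feature", "or", "ci_low", "ci_high", "p", "separated"])
        results["association_metabolites"] = results["association_modules"].copy()

    qol_deltas = qol_delta_table(clinical_df)
    results["qol_correlation"] = association.qol_correlation(
        eigen_deltas, qol_deltas, cohort, visits)
    return results


def run_all_synthetic(sim_config: SimConfig, config: AnalysisConfig,
                      out_dir=None, improvement: str = "odrs") -> dict:
    """Simulate a cohort, run every stage, optionally write everything."""
    abundance, visits, cohort, pathways, clinical_df, truth = generate_cohort(sim_config)
    results = run_all(abundance, visits, cohort, pathways, clinical_df,
                      config, improvement=improvement)
    results["visits"] = visits
    results["cohort"] = cohort
    results["pathways"] = pathways
    results["clinical"] = clinical_df
    results.update(truth.to_frames())
    if out_dir is not None:
        write_results(results, out_dir, config)
    return results
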