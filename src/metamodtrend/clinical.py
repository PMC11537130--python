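"""Disability and quality-of-life outcome scoring.

Implements the composite improvement criteria used for relapsing-remitting
MS disability response:

* **EDSS-Plus improvement** — at least a 1.0-point EDSS decrease from a
  baseline of 5.5 or less, a 0.5-point decrease from a baseline over 5.5,
  or at least a 20% reduction in any of the timed tests (T25FW, dominant or
  non-dominant 9HPT) at the last visit versus baseline.
* **ODRS** (overall disability response score) — per-component scores of
  +1 / 0 / -1 for EDSS (the EDSS-Plus thresholds, mirrored for worsening)
  and the three timed tests (15% reduction = +1, 15% increase = -1),
  summed to a total in [-4, +4]; a strictly positive total is improvement.
* **Wilcoxon signed-rank** for paired baseline/final comparisons, exact by
  full sign enumeration at small n.
* **Neuro-QOL improvement** — a favorable-direction T-score change strictly
  exceeding the item's minimal detectable change (MDC).

Threshold comparisons use an absolute tolerance of 1e-9 so boundary cases
("at least 20%", "15% or more") are inclusive under floating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NEUROQOL_ITEMS, ValidationError

logger = logging.getLogger("metamodtrend")

_TOL = 1e-9
TIMED_TESTS = ["t25fw_s", "hpt_dom_s", "hpt_nondom_s"]
REQUIRED_FIELDS = ["edss"] + TIMED_TESTS


@dataclass
class DisabilityResponse:
    """Per-patient composite disability response."""

    patient_id: str
    edss_score: int
    t25fw_score: int
    hpt_dom_score: int
    hpt_nondom_score: int
    odrs_total: int
    odrs_improved: bool
    edss_plus_improved: bool


def _check_record(record: dict, which: str) -> None:
    missing = [f for f in REQUIRED_FIELDS
               if f not in record or record[f] is None
               or (isinstance(record[f], float) and np.isnan(record[f]))]
    if missing:
        raise ValidationError(f"{which} record missing components: {missing}")


def _edss_improved(baseline_edss: float, final_edss: float) -> bool:
    decrease = baseline_edss - final_edss
    if baseline_edss <= 5.5 + _TOL:
        return decrease >= 1.0 - _TOL
    return decrease >= 0.5 - _TOL


def _edss_worsened(baseline_edss: float, final_edss: float) -> bool:
    # mirror of the improvement magnitudes for the same baseline stratum
    increase = final_edss - baseline_edss
    if baseline_edss <= 5.5 + _TOL:
        return increase >= 1.0 - _TOL
    return increase >= 0.5 - _TOL


def _timed_relative_change(baseline_s: float, final_s: float) -> float:
    if baseline_s <= 0 or final_s <= 0:
        raise ValidationError("timed-test durations must be positive")
    return (final_s - baseline_s) / baseline_s


def edss_plus_improved(baseline: dict, final: dict) -> bool:
    """EDSS-Plus improvement at the last visit versus baseline."""
    _check_record(baseline, "baseline")
    _check_record(final, "final")
    if _edss_improved(baseline["edss"], final["edss"]):
        return True
    for test in TIMED_TESTS:
        if -_timed_relative_change(baseline[test], final[test]) >= 0.20 - _TOL:
            return True
    return False


def _timed_component(baseline_s: float, final_s: float) -> int:
    rel = _timed_relative_change(baseline_s, final_s)
    if rel <= -(0.15 - _TOL):
        return 1
    if rel >= 0.15 - _TOL:
        return -1
    return 0


def odrs(baseline: dict, final: dict, patient_id: str = "") -> DisabilityResponse:
    """Overall disability response score from baseline and final records."""
    _check_record(baseline, "baseline")
    _check_record(final, "final")
    if _edss_improved(baseline["edss"], final["edss"]):
        edss_score = 1
    elif _edss_worsened(baseline["edss"], final["edss"]):
        edss_score = -1
    else:
        edss_score = 0
    timed = {t: _timed_component(baseline[t], final[t]) for t in TIMED_TESTS}
    total = edss_score + sum(timed.values())
    return DisabilityResponse(
        patient_id=patient_id,
        edss_score=edss_score,
        t25fw_score=timed["t25fw_s"],
        hpt_dom_score=timed["hpt_dom_s"],
        hpt_nondom_score=timed["hpt_nondom_s"],
        odrs_total=total,
        odrs_improved=total > 0,
        edss_plus_improved=edss_plus_improved(baseline, final),
    )


def compute_disability_responses(clinical: pd.DataFrame) -> pd.DataFrame:
    """ODRS and EDSS-Plus per patient: baseline vs last available visit."""
    rows = []
    for pid, grp in clinical.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_years")
        base = grp.iloc[0].to_dict()
        final = grp.iloc[-1].to_dict()
        if base["time_years"] != 0:
            logger.warning("patient %s has no baseline visit; skipped", pid)
            continue
        resp = odrs(base, final, patient_id=str(pid))
        rows.append(vars(resp))
    return pd.DataFrame(rows)


def wilcoxon_signed_rank(baseline, final) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; midranks handle ties.  The p-value is
    exact (full enumeration of sign assignments) for effective n <= 15,
    otherwise a normal approximation with tie and continuity correction.
    Returns ``(W, p)`` where W is the positive-difference rank sum.
    """
    baseline = np.asarray(baseline, dtype=float)
    final = np.asarray(final, dtype=float)
    if baseline.shape != final.shape or baseline.size == 0:
        raise ValidationError("paired vectors of equal, positive length required")
    d = final - baseline
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= 15:
        return w, _exact_signed_rank_p(ranks, w)
    total = ranks.sum()
    mean = total / 2.0
    var = float(np.sum(ranks ** 2)) / 4.0
    if var == 0:
        return w, 1.0
    cc = 0.5 * np.sign(w - mean)
    z = (w - mean - cc) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _exact_signed_rank_p(ranks: np.ndarray, w: float) -> float:
    """Exact two-sided p by enumerating all 2^n sign assignments.

    The distribution of W is built by convolution over ranks (each rank is
    included with probability 1/2), which is equivalent to enumeration but
    polynomial-time; midranks are handled by doubling to integers.
    """
    doubled = np.round(ranks * 2).astype(int)
    dist = {0: 1.0}
    for r in doubled:
        nxt = {}
        for val, cnt in dist.items():
            nxt[val] = nxt.get(val, 0.0) + cnt
            nxt[val + r] = nxt.get(val + r, 0.0) + cnt
        dist = nxt
    total = 2.0 ** len(ranks)
    w2 = int(round(w * 2))
    p_le = sum(c for v, c in dist.items() if v <= w2) / total
    p_ge = sum(c for v, c in dist.items() if v >= w2) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def neuroqol_improvement(clinical: pd.DataFrame, mdc: dict,
                         directions: dict | None = None) -> pd.DataFrame:
    """Per-patient, per-item neuro-QOL improvement flags.

    Improvement means the change in the item's favorable direction strictly
    exceeds the item's minimal detectable change.  Items without an MDC
    entry are excluded with a warning.
    """
    directions = directions if directions is not None else NEUROQOL_ITEMS
    rows = []
    item_cols = [c for c in clinical.columns if c.startswith("nqol_")]
    for pid, grp in clinical.groupby("patient_id", sort=True):
        grp = grp.sort_values("time_years")
        base, final = grp.iloc[0], grp.iloc[-1]
        for col in item_cols:
            item = col[len("nqol_"):]
            if item not in mdc:
                logger.warning("neuro-QOL item %r lacks an MDC entry; excluded", item)
                continue
            higher_better = directions.get(item)
            if higher_better is None:
                logger.warning("neuro-QOL item %r lacks a direction; excluded", item)
                continue
            change = float(final[col] - base[col])
            favorable = change if higher_better else -change
            rows.append({
                "patient_id": pid,
                "item": item,
                "baseline": float(base[col]),
                "final": float(final[col]),
                "direction": "higher_better" if higher_better else "higher_worse",
                "mdc": float(mdc[item]),
                "improved": favorable > float(mdc[item]),
            })
    return pd.DataFrame(rows)
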