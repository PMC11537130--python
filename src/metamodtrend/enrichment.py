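"""Permutation pathway enrichment of longitudinal trend results.

Metabolites are ranked by a signed significance statistic
``s_m = sign(estimate) * (-log10 p)`` from the per-metabolite mixed-model
scan, and each sub-pathway (minimum size 5 by default) is scored with the
weighted Kolmogorov-Smirnov running-sum enrichment statistic: hits add
``|s|^w`` (normalized over the set), misses subtract ``1/(N - n_set)``; the
enrichment score (ES) is the signed maximum deviation of the running sum.

Significance comes from a metabolite-label permutation null: random same-
size sets drawn from the ranked list.  The nominal p-value is the add-one-
corrected fraction of same-sign permuted scores at least as extreme, and
the normalized enrichment score ``NES = ES / mean(|ES*|)`` over same-sign
permutations, making pathways of different sizes comparable.  Nominal
p-values are Benjamini-Hochberg adjusted across pathways.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ValidationError
from .mixedlm import bh_adjust

_P_FLOOR = np.finfo(float).tiny


def rank_statistics(trend: pd.DataFrame) -> pd.Series:
    """Signed ranking statistic, sorted descending (ties broken by id).

    ``trend`` needs ``feature``, ``estimate`` and ``p`` columns; p-values
    are floored at the smallest positive float so the statistic is finite.
    """
    if trend["feature"].duplicated().any():
        dupes = trend.loc[trend["feature"].duplicated(), "feature"].tolist()
        raise ValidationError(f"duplicate feature ids in trend results: {dupes}")
    usable = trend.dropna(subset=["estimate", "p"])
    p = np.maximum(usable["p"].to_numpy(dtype=float), _P_FLOOR)
    s = np.sign(usable["estimate"].to_numpy(dtype=float)) * (-np.log10(p))
    out = pd.Series(s, index=usable["feature"].to_numpy(), name="s")
    order = sorted(range(len(out)), key=lambda i: (-out.iloc[i], out.index[i]))
    return out.iloc[order]


def enrichment_score(ranked: pd.Series, members, weight: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score for one metabolite set."""
    members = set(members)
    if not members:
        raise ValidationError("empty metabolite set")
    unknown = members - set(ranked.index)
    if unknown:
        raise ValidationError(f"set members not in ranked list: {sorted(unknown)}")
    is_hit = np.fromiter((m in members for m in ranked.index), dtype=bool,
                         count=len(ranked))
    return float(_es_from_positions(ranked.to_numpy(dtype=float),
                                    np.flatnonzero(is_hit), weight))


def _es_from_positions(s: np.ndarray, hit_pos: np.ndarray, weight: float) -> float:
    n, k = s.size, hit_pos.size
    if k >= n:
        return 1.0
    steps = np.full(n, -1.0 / (n - k))
    w = np.abs(s[hit_pos]) ** weight
    total = w.sum()
    steps[hit_pos] = (w / total) if total > 0 else 1.0 / k
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _es_permutations(s: np.ndarray, set_size: int, n_perm: int,
                     rng: np.random.Generator, weight: float) -> np.ndarray:
    """Null ES distribution from random same-size sets, vectorized."""
    n = s.size
    steps = np.full((n_perm, n), -1.0 / (n - set_size))
    # sample without replacement per permutation via argsort of uniforms
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :set_size]
    w = np.abs(s[pos]) ** weight
    totals = w.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, w / np.where(totals == 0, 1, totals),
                    1.0 / set_size)
    np.put_along_axis(steps, pos, safe, axis=1)
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def gsea_scan(ranked: pd.Series, pathways: pd.DataFrame, min_set: int = 5,
              n_perm: int = 1000, seed: int | None = None,
              weight: float = 1.0, level: str = "sub_pathway") -> pd.DataFrame:
    """Enrichment of every pathway of size >= ``min_set`` in the ranked list.

    The permutation null depends only on the set size, so it is computed
    once per distinct size and shared across pathways; this is identical in
    distribution to per-pathway resampling and deterministic for a seed.
    Returns a table sorted by |NES| descending with BH-adjusted p-values.
    """
    if seed is None:
        raise ValidationError("gsea_scan requires a seed")
    ranked_ids = set(ranked.index)
    sets = {}
    for pw, grp in pathways.groupby(level, sort=True):
        members = [m for m in grp["metabolite_id"] if m in ranked_ids]
        if len(members) >= min_set:
            sets[pw] = members
    columns = ["pathway", "size", "es", "nes", "p", "p_adj", "direction"]
    if not sets:
        return pd.DataFrame(columns=columns)

    s = ranked.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    null_by_size = {}
    for size in sorted({len(m) for m in sets.values()}):
        null_by_size[size] = _es_permutations(s, size, n_perm, rng, weight)

    rows = []
    for pw in sorted(sets):
        members = sets[pw]
        es = enrichment_score(ranked, members, weight)
        null = null_by_size[len(members)]
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size == 0:
            same_sign = null  # degenerate: no same-sign permutation
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        denom = np.mean(np.abs(same_sign))
        nes = es / denom if denom > 0 else 0.0
        rows.append({"pathway": pw, "size": len(members), "es": es, "nes": nes,
                     "p": float(p), "direction": "up" if es >= 0 else "down"})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values("nes", key=np.abs, ascending=False,
                          kind="stable").reset_index(drop=True)
    return out[columns]
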