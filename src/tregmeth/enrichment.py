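"""Over-representation and preranked gene-set enrichment statistics.

ORA uses the upper-tail hypergeometric test against a declared gene
universe.  Preranked GSEA uses the weighted Kolmogorov-Smirnov running-sum
enrichment score with a gene-label permutation null, sign-stratified NES
normalization and a +1-corrected empirical p-value.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import bh_adjust


def ora_hypergeometric(
    query: list[str],
    universe: list[str],
    sets: dict[str, list[str]],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per term.

    p = P(X >= k) for overlap k between the query and a term of size K drawn
    from a universe of size N with a query of size n; BH-adjusted across terms.
    """
    query_s = set(query)
    universe_s = set(universe)
    if not query_s:
        raise ValueError("empty query gene list")
    if not query_s <= universe_s:
        raise ValueError("query genes must be a subset of the universe")
    n, big_n = len(query_s), len(universe_s)
    rows = []
    for term, members in sets.items():
        members_u = set(members) & universe_s
        big_k = len(members_u)
        if big_k == 0:
            continue
        k = len(members_u & query_s)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "k": k, "K": big_k, "n": n, "N": big_n, "p": p})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr_threshold
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out


def _running_es(in_set: np.ndarray, scores: np.ndarray, weight: float) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    n = len(in_set)
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        return 0.0
    w = np.abs(scores) ** weight
    hit_inc = np.where(in_set, w, 0.0)
    denom = hit_inc.sum()
    if denom == 0:  # all member scores are zero: fall back to equal steps
        hit_inc = in_set.astype(float)
        denom = hit_inc.sum()
    miss_inc = np.where(in_set, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(hit_inc / denom - miss_inc)
    return float(running[np.argmax(np.abs(running))])


def gsea_preranked(
    scores: pd.Series,
    sets: dict[str, list[str]],
    n_permutations: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``scores`` maps unique gene ids to finite ranking scores (sorted
    internally, descending).  NES is ES divided by the mean absolute null ES
    of the same sign; the empirical p uses the same-sign null tail with a +1
    correction, so p is bounded below by 1/(n_permutations + 1).
    """
    s = scores.dropna()
    if s.index.has_duplicates:
        raise ValueError("gene ids must be unique")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("ranking scores must be finite")
    s = s.sort_values(ascending=False, kind="mergesort")
    genes = s.index.to_numpy()
    vals = s.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(int(seed) % (2**31))

    rows = []
    for term, members in sets.items():
        idx = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos))
        if len(idx) < 2:
            warnings.warn(f"gene set {term!r} has < 2 ranked members; skipped")
            continue
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[idx] = True
        es = _running_es(in_set, vals, weight)
        null_es = np.empty(n_permutations)
        size = len(idx)
        for b in range(n_permutations):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=size, replace=False)] = True
            null_es[b] = _running_es(perm, vals, weight)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if len(same_sign):
            nes = es / np.abs(same_sign).mean()
            p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + len(same_sign))
        else:
            nes = np.nan
            p = 1.0 / (1 + n_permutations)
        rows.append({"term": term, "size": size, "ES": es, "NES": nes, "p": p})
    out = pd.DataFrame(rows, columns=["term", "size", "ES", "NES", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return out
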