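"""Scoring inferred regulons against a TF→target database.

Per TF: ranking quality of |A| as a target predictor (AUC), enrichment of
known targets among the selected downstream genes (one-sided Fisher test,
BH-corrected), and validated-target-rate curves comparing the rate at the
selected cutoff with the best achievable rate.  Whole networks are compared
by correlation-distance hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests


@dataclass
class TFValidation:
    tf: str
    auc: float
    n_selected: int
    n_targets: int
    rate_at_threshold: float | None
    best_rate: float
    best_rank: int
    rate_difference: float | None
    odds_ratio: float | None
    p_raw: float
    p_adj: float | None = None
    background_rate: float | None = None


def auc_targets(scores: np.ndarray, is_target: np.ndarray) -> float:
    """Mann–Whitney AUC of scores for target vs non-target genes.

    Equals the fraction of (target, non-target) pairs where the target
    scores higher, counting ties as 1/2.
    """
    is_target = np.asarray(is_target, bool)
    if is_target.all() or not is_target.any():
        raise ValueError("need at least one target and one non-target")
    return float(roc_auc_score(is_target, np.asarray(scores, float)))


def fisher_enrichment(selected: set, targets: set, universe_size: int):
    """One-sided Fisher exact test for target enrichment in the selection.

    Returns (odds_ratio, p).  The odds ratio is the sample (cross-product)
    ratio of the 2x2 table; an empty selection gives p = 1 and odds ratio
    None.
    """
    if not selected:
        return None, 1.0
    a = len(selected & targets)
    b = len(selected) - a
    c = len(targets) - a
    d = universe_size - a - b - c
    if min(a, b, c, d) < 0:
        raise ValueError("sets are inconsistent with the universe size")
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return (float(odds) if np.isfinite(odds) else float("inf")), float(p)


def bh_adjust(p: list) -> list:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def validated_rate_curve(ranked: list, targets: set, r_star: int):
    """Validated-target rate along the ranking.

    rate(r) = |top-r ∩ targets| / r for r = 1..len(ranked).  Returns
    (rates array, best_rate, best_rank, rate_at_r_star, difference);
    rate_at_r_star and difference are None when r_star = 0.
    """
    n = len(ranked)
    if r_star > n:
        raise ValueError("threshold rank exceeds the ranking length")
    hits = np.cumsum([1 if g in targets else 0 for g in ranked])
    rates = hits / np.arange(1, n + 1)
    best_rank = int(np.argmax(rates)) + 1
    best_rate = float(rates[best_rank - 1])
    if r_star == 0:
        return rates, best_rate, best_rank, None, None
    rate_at = float(rates[r_star - 1])
    return rates, best_rate, best_rank, rate_at, best_rate - rate_at


def validate_regulons(
    A: np.ndarray,
    gene_ids: list,
    regulons,
    tf_db: dict,
    universe: list | None = None,
) -> list[TFValidation]:
    """Score every database TF present in the network.

    The candidate universe for ranking is all genes except the TF itself.
    BH correction is applied across TFs.
    """
    pos = {g: i for i, g in enumerate(gene_ids)}
    universe = list(gene_ids) if universe is None else list(universe)
    reports = []
    for tf, targets in tf_db.items():
        if tf not in pos:
            continue
        targets = set(targets)
        candidates = [g for g in universe if g != tf]
        scores = np.array([abs(A[pos[g], pos[tf]]) for g in candidates])
        labels = np.array([g in targets for g in candidates])
        auc = auc_targets(scores, labels) if labels.any() and not labels.all() \
            else float("nan")
        sel = regulons.selections[tf]
        selected = [g for g in sel.genes if g != tf]
        rank_order = sorted(range(len(candidates)),
                            key=lambda i: (-scores[i], candidates[i]))
        ranked = [candidates[i] for i in rank_order]
        rates, best_rate, best_rank, rate_at, diff = validated_rate_curve(
            ranked, targets, len(selected)
        )
        odds, p = fisher_enrichment(set(selected), targets, len(candidates))
        reports.append(TFValidation(
            tf=tf, auc=auc, n_selected=len(selected), n_targets=len(targets),
            rate_at_threshold=rate_at, best_rate=best_rate, best_rank=best_rank,
            rate_difference=diff, odds_ratio=odds, p_raw=p,
            background_rate=len(targets & set(candidates)) / len(candidates),
        ))
    adj = bh_adjust([r.p_raw for r in reports])
    for r, q in zip(reports, adj):
        r.p_adj = float(q)
    return reports


def grn_similarity_clustering(matrices: list, labels: list | None = None):
    """Average-linkage hierarchical clustering of networks.

    Distance between two networks is 1 - Pearson correlation of their
    flattened A matrices.  Returns (linkage matrix, pairwise distance
    matrix).  A constant matrix has no defined correlation and is an error.
    """
    flats = [np.asarray(m, float).ravel() for m in matrices]
    n = len(flats)
    if n < 2:
        raise ValueError("need at least two networks")
    for k, f in enumerate(flats):
        if f.std() == 0:
            raise ValueError(f"network {k} is constant; correlation undefined")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - np.corrcoef(flats[i], flats[j])[0, 1]
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, dist
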