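"""Ligand–receptor downstream-overlap analysis and co-expression checks.

If the inferred network captures intercellular signaling, the downstream
sets of a pathway's ligand-related genes and receptor-related genes should
largely coincide, with concordant regulatory signs for pathways whose
receptors activate targets only upon ligand binding (and discordant signs
where unliganded receptors act as repressors).  Co-expression across
cell-type average profiles distinguishes intracellular (co-expressed) from
intercellular (non-co-expressed) upstream/downstream relations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import ExprMatrix
from .thresholding import RegulonTable
from .validation import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class PairOverlap:
    pathway: str
    ligand: str
    receptor: str
    n_ligand: int
    n_receptor: int
    n_intersection: int
    frac_of_min: float | None       # |∩| / min(|L|, |R|)
    frac_of_ligand: float | None    # |∩| / |L|
    p_raw: float
    p_adj: float | None = None


@dataclass
class SignConcordanceTable:
    pattern_counts: dict            # membership pattern -> count
    concordance: float | None       # |(L+∩R+) ∪ (L-∩R-)| / |both-selected|
    n_both_selected: int


def family_downstream(regulons: RegulonTable, family: list):
    """Union of downstream sets over a gene family.

    Returns (union set, per-member dict, representative member).  The
    representative is the member with the largest downstream set (ties by
    gene id); members absent from the regulon table are logged and skipped.
    """
    if not family:
        raise ValueError("empty gene family")
    members = {}
    for g in family:
        if g not in regulons.selections:
            logger.warning("family member %s missing from regulons; skipped", g)
            continue
        members[g] = regulons.downstream(g)
    if not members:
        raise ValueError("no family member present in the regulon table")
    union = set().union(*members.values())
    representative = sorted(members, key=lambda g: (-len(members[g]), g))[0]
    return union, members, representative


def overlap_enrichment(
    setA: set,
    setB: set,
    universe_size: int,
    method: str = "hypergeometric",
    n_perm: int = 10_000,
    seed: int = 0,
    universe: list | None = None,
) -> float:
    """P-value for the overlap of two gene sets within a universe.

    ``hypergeometric``: P(|∩| >= observed) when |B| genes are drawn without
    replacement from the universe containing |A| successes (exact, default).
    ``permutation``: resample B uniformly ``n_perm`` times;
    p = (1 + #{|∩_perm| >= observed}) / (1 + n_perm).
    """
    if not setA or not setB:
        return 1.0
    obs = len(setA & setB)
    if method == "hypergeometric":
        return float(hypergeom.sf(obs - 1, universe_size, len(setA), len(setB)))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        pool = np.asarray(universe if universe is not None
                          else np.arange(universe_size), dtype=object)
        inA = np.array([g in setA for g in pool])
        hits = 0
        for _ in range(n_perm):
            draw = rng.choice(pool.size, size=len(setB), replace=False)
            if int(inA[draw].sum()) >= obs:
                hits += 1
        return (1 + hits) / (1 + n_perm)
    raise ValueError(f"unknown method {method!r}")


def sign_concordance(L_pos: set, L_neg: set, R_pos: set, R_neg: set
                     ) -> SignConcordanceTable:
    """Cross-tabulate signed downstream memberships of a ligand/receptor pair.

    Counts every non-empty membership pattern over {L+, L-, R+, R-} (the
    upset-plot counts) and reports the concordance fraction: among genes
    selected downstream of both the ligand and the receptor, the fraction
    regulated in the same direction by both.
    """
    if L_pos & L_neg or R_pos & R_neg:
        raise ValueError("positive and negative sets must be disjoint")
    sets = {"L+": L_pos, "L-": L_neg, "R+": R_pos, "R-": R_neg}
    universe = set().union(*sets.values())
    patterns: dict = {}
    for g in universe:
        key = tuple(sorted(k for k, s in sets.items() if g in s))
        patterns[key] = patterns.get(key, 0) + 1
    both = (L_pos | L_neg) & (R_pos | R_neg)
    if not both:
        return SignConcordanceTable(patterns, None, 0)
    same = ((L_pos & R_pos) | (L_neg & R_neg)) & both
    return SignConcordanceTable(patterns, len(same) / len(both), len(both))


def pathway_overlap_report(
    regulons: RegulonTable,
    annotations,
    universe_size: int,
    method: str = "hypergeometric",
    seed: int = 0,
) -> list[PairOverlap]:
    """Overlap statistics for every annotated ligand–receptor pair,
    BH-corrected across all pairs jointly."""
    reports = []
    for ann in annotations:
        dL, _, repL = family_downstream(regulons, ann.ligand_genes)
        dR, _, repR = family_downstream(regulons, ann.receptor_genes)
        inter = len(dL & dR)
        p = overlap_enrichment(dL, dR, universe_size, method=method, seed=seed)
        reports.append(PairOverlap(
            pathway=ann.name, ligand=repL, receptor=repR,
            n_ligand=len(dL), n_receptor=len(dR), n_intersection=inter,
            frac_of_min=inter / min(len(dL), len(dR)) if dL and dR else None,
            frac_of_ligand=inter / len(dL) if dL else None,
            p_raw=p,
        ))
    adj = bh_adjust([r.p_raw for r in reports])
    for r, q in zip(reports, adj):
        r.p_adj = float(q)
    return reports


def random_pair_overlap(
    regulons: RegulonTable,
    exclude: set,
    n_pairs: int,
    seed: int = 0,
) -> np.ndarray:
    """Overlap fractions (|∩|/min) for random regulator pairs outside
    ``exclude``; the null reference for annotated-pair overlaps."""
    rng = np.random.default_rng(seed)
    pool = [g for g in regulons.selections if g not in exclude
            and regulons.selections[g].genes]
    pairs = list(combinations(pool, 2))
    if not pairs:
        return np.array([])
    idx = rng.choice(len(pairs), size=min(n_pairs, len(pairs)), replace=False)
    fracs = []
    for i in idx:
        a, b = pairs[i]
        da, db = regulons.downstream(a), regulons.downstream(b)
        fracs.append(len(da & db) / min(len(da), len(db)))
    return np.asarray(fracs)


def average_by_celltype(expr: ExprMatrix, labels: list) -> pd.DataFrame:
    """Cell-type x gene averages of de-logged expression exp(x) - 1."""
    if expr.layer != "normalized":
        raise ValueError("average_by_celltype expects the normalized layer")
    if len(labels) != expr.n_samples:
        raise ValueError("one label per sample required")
    delog = np.expm1(expr.values)
    labels = np.asarray(labels, dtype=object)
    rows, names = [], []
    for lv in pd.unique(labels):
        rows.append(delog[:, labels == lv].mean(axis=1))
        names.append(lv)
    return pd.DataFrame(np.vstack(rows), index=names, columns=expr.gene_ids)


def coexpression_filter(
    profiles: pd.DataFrame,
    pairs: list,
    pcc_cut: float = 0.4,
    upstream_class: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Flag upstream/downstream pairs co-expressed across cell types.

    A pair is co-expressed when the Pearson correlation of the two genes'
    cell-type average profiles is strictly greater than ``pcc_cut``.  A
    zero-variance profile has undefined correlation: flagged not
    co-expressed and logged.  Returns the per-pair table and, if
    ``upstream_class`` maps upstream genes to classes (ligand / receptor /
    TF), the per-class co-expressed ratio.
    """
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 cell types")
    rows = []
    for up, down in pairs:
        for g in (up, down):
            if g not in profiles.columns:
                raise KeyError(f"gene {g!r} missing from profiles")
        x = profiles[up].to_numpy(float)
        y = profiles[down].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            logger.warning("zero-variance profile in pair (%s, %s)", up, down)
            pcc, flag = np.nan, False
        else:
            pcc = float(np.corrcoef(x, y)[0, 1])
            flag = pcc > pcc_cut
        rows.append({"upstream": up, "downstream": down, "pcc": pcc,
                     "coexpressed": flag})
    table = pd.DataFrame(rows)
    ratios: dict = {}
    if upstream_class and len(table):
        table["class"] = [upstream_class.get(u) for u in table["upstream"]]
        for cls, sub in table.groupby("class", dropna=True):
            ratios[cls] = float(sub["coexpressed"].mean())
    return table, ratios
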