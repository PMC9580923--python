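"""Per-regulator downstream-gene selection from the inferred network.

For each regulator j, the absolute values of its column of A are sorted in
decreasing order and a straight line is fitted by least squares to the
(rank, |A|) scatter.  Genes whose |A| lies above the fitted line are the
inferred downstream set: a few strong outliers stand above the line that the
bulk of near-zero values pulls down.  By default selection stops at the
first rank that falls on or below the line (a single cutoff rank, "prefix"
mode); "literal" mode instead keeps every rank strictly above the line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class RegulatorSelection:
    regulator: str
    genes: list[str]             # selected downstream genes, rank order
    signs: dict                  # gene -> +1 / -1 from A[i, j]
    intercept: float
    slope: float
    cutoff_rank: int             # r*; selected genes are ranks 1..r*


@dataclass
class RegulonTable:
    """Per-regulator downstream selections for a whole network."""

    selections: dict             # regulator -> RegulatorSelection

    def downstream(self, regulator: str) -> set:
        return set(self.selections[regulator].genes)

    def signed_sets(self, regulator: str) -> tuple[set, set]:
        sel = self.selections[regulator]
        pos = {g for g in sel.genes if sel.signs[g] > 0}
        return pos, set(sel.genes) - pos


def regulator_threshold(
    a_col: np.ndarray,
    gene_ids: list[str],
    mode: str = "prefix",
):
    """Select downstream genes for one regulator by the regressed-line rule.

    Sorts |a_col| descending (ties broken by gene id), fits y = c0 + c1·r
    by ordinary least squares over ranks r = 1..G, and selects genes above
    the line: in "prefix" mode ranks 1..r* where r*+1 is the first rank at
    or below the line; in "literal" mode every rank strictly above it.

    Returns (selected gene list in rank order, (c0, c1), r*).
    """
    a_col = np.asarray(a_col, float)
    G = a_col.size
    if G < 3:
        raise ValueError("need at least 3 genes to fit a threshold line")
    if mode not in ("prefix", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    y_abs = np.abs(a_col)
    if not y_abs.any():
        logger.info("all-zero regulator column: empty selection")
        return [], (0.0, 0.0), 0
    # descending |a|, ties by gene id (lexicographic), for determinism
    order = sorted(range(G), key=lambda i: (-y_abs[i], gene_ids[i]))
    y = y_abs[order]
    r = np.arange(1, G + 1, dtype=float)
    c1, c0 = np.polyfit(r, y, 1)
    fitted = c0 + c1 * r
    above = y > fitted
    if mode == "prefix":
        below = np.flatnonzero(~above)
        r_star = int(below[0]) if below.size else G
        chosen = order[:r_star]
    else:
        chosen = [order[i] for i in np.flatnonzero(above)]
        r_star = len(chosen)
    return [gene_ids[i] for i in chosen], (float(c0), float(c1)), r_star


def sign_partition(A: np.ndarray, gene_ids: list[str], regulator: str,
                   selected: list[str]) -> tuple[set, set]:
    """Split a regulator's selected genes by the sign of A[i, j]."""
    pos_idx = {g: i for i, g in enumerate(gene_ids)}
    j = pos_idx[regulator]
    positive = {g for g in selected if A[pos_idx[g], j] > 0}
    negative = {g for g in selected if A[pos_idx[g], j] < 0}
    return positive, negative


def build_regulons(
    A: np.ndarray,
    gene_ids: list[str],
    regulators: list[str] | None = None,
    mode: str = "prefix",
) -> RegulonTable:
    """Apply the threshold rule to every (or the given) regulator column."""
    pos_idx = {g: i for i, g in enumerate(gene_ids)}
    if regulators is None:
        regulators = list(gene_ids)
    selections = {}
    for reg in regulators:
        j = pos_idx[reg]
        genes, (c0, c1), r_star = regulator_threshold(A[:, j], gene_ids, mode)
        signs = {g: int(np.sign(A[pos_idx[g], j])) for g in genes}
        selections[reg] = RegulatorSelection(reg, genes, signs, c0, c1, r_star)
    return RegulonTable(selections)
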