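"""Count filtering, log-normalization, variable-gene selection and centering.

Mirrors the standard single-cell-style preprocessing applied to bulk
profiles: drop silent genes, log counts-per-10k normalization, mean/variance
("mvp") dispersion-based highly-variable-gene selection with binned
z-scoring, and per-gene centering without variance scaling.
"""

from __future__ import annotations

import numpy as np

from .containers import CountMatrix, ExprMatrix


def filter_expressed(counts: CountMatrix) -> CountMatrix:
    """Keep genes with total count > 0 across samples, preserving order."""
    keep = counts.values.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("no expressed genes: every gene has zero total count")
    if keep.all():
        return counts
    return counts.subset_genes(keep)


def normalize(counts: CountMatrix, scale_factor: float = 1e4) -> ExprMatrix:
    """Log counts-per-``scale_factor`` normalization.

    out[g, s] = ln(1 + scale_factor * c[g, s] / total_s) with total_s the
    sample's total count.  Errors if a sample has zero total.
    """
    totals = counts.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {counts.sample_ids[zero[0]]!r} has zero total count"
        )
    vals = np.log1p(scale_factor * counts.values / totals[None, :])
    return ExprMatrix(vals, list(counts.gene_ids), list(counts.sample_ids),
                      layer="normalized")


def select_hvg(
    norm: ExprMatrix,
    n_bins: int = 20,
    mean_low: float = 0.1,
    mean_high: float = 8.0,
    disp_z_cut: float = 1.0,
) -> list[str]:
    """Mean/variance-plot highly-variable-gene selection.

    Per gene, the mean of the de-logged expression exp(x)-1 and the
    dispersion ln(variance/mean) on that scale are computed; genes are binned
    into ``n_bins`` equal-width bins by mean, dispersions are z-scored within
    bins, and genes with mean in (mean_low, mean_high) and dispersion z-score
    above ``disp_z_cut`` are returned.  Zero-variance or zero-mean genes are
    never selected; a bin that cannot be standardized gets z = 0.
    """
    if norm.n_samples < 2:
        raise ValueError("need at least 2 samples for dispersion")
    x = np.expm1(norm.values)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.log(var / mean)
    valid = np.isfinite(disp)

    z = np.zeros(norm.n_genes)
    if valid.any():
        m = mean[valid]
        edges = np.linspace(m.min(), m.max(), n_bins + 1)
        # right-open bins; the max lands in the last bin
        bin_idx = np.clip(np.digitize(m, edges[1:-1]), 0, n_bins - 1)
        zv = np.zeros(m.size)
        for b in np.unique(bin_idx):
            sel = bin_idx == b
            d = disp[valid][sel]
            sd = d.std(ddof=1) if sel.sum() > 1 else 0.0
            if sd > 0:
                zv[sel] = (d - d.mean()) / sd
        z[valid] = zv

    keep = valid & (mean > mean_low) & (mean < mean_high) & (z > disp_z_cut)
    return [g for g, k in zip(norm.gene_ids, keep) if k]


def center(norm: ExprMatrix, genes: list[str] | None = None) -> ExprMatrix:
    """Subtract each gene's mean; variance is left untouched.

    If ``genes`` is given, only those genes (in the given order) are kept.
    """
    if genes is None:
        idx = np.arange(norm.n_genes)
        ids = list(norm.gene_ids)
    else:
        idx = norm.gene_index(genes)
        ids = list(genes)
    vals = norm.values[idx, :]
    vals = vals - vals.mean(axis=1, keepdims=True)
    return ExprMatrix(vals, ids, list(norm.sample_ids), layer="centered")
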