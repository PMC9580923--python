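"""Trajectory inference and pseudo-time assignment for individual profiles.

Samples are embedded by PCA, a single-lineage principal curve is fitted by
iterated projection / arclength reparametrization / per-coordinate smoothing
(Hastie–Stuetzle style), and each sample's pseudo-time is the arclength of
its projection onto the curve.  A smoothing-spline sum-of-squared-residuals
comparison quantifies how much better pseudo-time explains per-gene
expression dynamics than the discrete sampling stage does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .containers import ExprMatrix, stage_to_numeric


@dataclass
class Trajectory:
    pc_scores: np.ndarray            # S x K embedding used for fitting
    curve_points: np.ndarray         # ordered polyline in the embedding
    pseudotime: np.ndarray           # length S, min = 0 (arclength units)
    orientation: str                 # "forward" | "reversed"
    msd_trace: list = field(default_factory=list)   # mean sq projection dist


@dataclass
class SSRReport:
    ssr_stage: np.ndarray            # per-gene SSR along stage
    ssr_pseudotime: np.ndarray       # per-gene SSR along pseudo-time
    gene_ids: list
    hvg: list
    mean_stage_all: float
    mean_pt_all: float
    pct_decrease_all: float
    mean_stage_hvg: float | None
    mean_pt_hvg: float | None
    pct_decrease_hvg: float | None


def run_pca(centered: ExprMatrix, n_components: int):
    """PCA of samples in gene space.

    Returns (scores S x K, loadings G x K with orthonormal columns,
    explained_variance).  ``n_components`` beyond what the data supports is
    truncated with a warning.
    """
    max_k = min(centered.n_genes, centered.n_samples)
    if n_components > max_k:
        warnings.warn(
            f"n_components={n_components} exceeds min(genes, samples)={max_k}; "
            "truncating"
        )
        n_components = max_k
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(centered.values.T)
    return scores, pca.components_.T, pca.explained_variance_


def spline_ssr(t: np.ndarray, y: np.ndarray, lam: float = 0.001) -> float:
    """SSR of a cubic smoothing spline of y on t.

    The spline minimizes sum_i (y_i - f(t_i))^2 + lam * int f''(u)^2 du with
    knots at the distinct t values; tied t values are aggregated to their
    mean with multiplicity weights (an exact reduction of the criterion).
    Returns sum_i (y_i - f(t_i))^2 over the original points.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.shape != y.shape:
        raise ValueError("t and y must have the same length")
    ux, inv, counts = np.unique(t, return_inverse=True, return_counts=True)
    if ux.size < 4:
        raise ValueError(f"need >= 4 distinct t values, got {ux.size}")
    ybar = np.bincount(inv, weights=y) / counts
    spl = make_smoothing_spline(ux, ybar, w=counts.astype(float), lam=lam)
    resid = y - spl(t)
    return float(resid @ resid)


def _project_to_polyline(X: np.ndarray, P: np.ndarray):
    """Project samples X (S x K) onto polyline P (M x K).

    Returns (arclength parameter per sample, squared distance per sample).
    """
    a = P[:-1]                       # (M-1, K)
    d = P[1:] - P[:-1]
    seg_len2 = (d * d).sum(axis=1)
    seg_len2[seg_len2 == 0] = 1e-300
    # t[s, m] = fractional position of sample s on segment m
    t = np.clip(((X[:, None, :] - a[None]) * d[None]).sum(-1) / seg_len2, 0, 1)
    proj = a[None] + t[..., None] * d[None]
    dist2 = ((X[:, None, :] - proj) ** 2).sum(-1)
    best = dist2.argmin(axis=1)
    s_idx = np.arange(X.shape[0])
    cum = np.concatenate([[0.0], np.cumsum(np.sqrt((d * d).sum(axis=1)))])
    param = cum[best] + t[s_idx, best] * np.sqrt(seg_len2[best])
    return param, dist2[s_idx, best]


def _mst_chain_order(centroids: np.ndarray) -> list[int]:
    """Order centroids along the minimum-spanning-tree path; error if the
    MST is not a simple chain (single-lineage violation)."""
    n = centroids.shape[0]
    if n == 1:
        return [0]
    dist = cdist(centroids, centroids)
    mst = minimum_spanning_tree(dist).toarray()
    adj = (mst > 0) | (mst.T > 0)
    deg = adj.sum(axis=1)
    if (deg > 2).any():
        raise ValueError(
            "stage centroids form a branching minimum-spanning tree; "
            "this fitter assumes a single lineage"
        )
    start = int(np.flatnonzero(deg == 1)[0])
    order, prev, cur = [start], -1, start
    while len(order) < n:
        nxt = [j for j in np.flatnonzero(adj[cur]) if j != prev]
        prev, cur = cur, int(nxt[0])
        order.append(cur)
    return order


def fit_trajectory(
    pc_scores: np.ndarray,
    stage: list,
    n_pcs_used: int = 2,
    max_iter: int = 20,
    tol: float = 1e-4,
    smooth_lambda: float = 0.001,
    curve_points: int = 200,
    init: str = "mst",
) -> Trajectory:
    """Fit a single-lineage principal curve and assign pseudo-time.

    The curve is initialized as the polyline through the per-stage centroids
    ordered along their minimum-spanning-tree path (``init="mst"``; errors if
    the tree branches) or, for ordinal stage labels whose temporal order is
    known, directly by stage rank (``init="stage"``, immune to MST shortcuts
    across strongly curved trajectories).  It is then refined by iterating
    {project samples, reparametrize by arclength, smooth each coordinate
    against arclength}.  Iteration stops when the mean squared projection
    distance changes by less than ``tol`` (relative), would increase, or
    ``max_iter`` is reached; the trace is therefore non-increasing.  The
    curve is oriented so the earliest stage precedes the latest, and
    pseudo-time (arclength from the curve start) is shifted to min 0.
    """
    stage = list(stage)
    levels = sorted(set(stage))
    if len(levels) < 2:
        raise ValueError("need >= 2 distinct stages")
    X = np.asarray(pc_scores, float)[:, :n_pcs_used]
    stage_num = stage_to_numeric(stage)

    centroids = np.vstack([X[[s == lv for s in stage]].mean(axis=0)
                           for lv in levels])
    if init == "mst":
        order = _mst_chain_order(centroids)
    elif init == "stage":
        level_num = stage_to_numeric(levels)
        order = list(np.argsort(level_num, kind="stable"))
    else:
        raise ValueError(f"unknown init {init!r}")
    curve = centroids[order]

    param, dist2 = _project_to_polyline(X, curve)
    msd_trace = [float(dist2.mean())]
    for _ in range(max_iter):
        ux = np.unique(param)
        if ux.size < 4:
            break
        grid = np.linspace(param.min(), param.max(), curve_points)
        new_curve = np.empty((curve_points, X.shape[1]))
        for k in range(X.shape[1]):
            _, inv, counts = np.unique(param, return_inverse=True,
                                       return_counts=True)
            ybar = np.bincount(inv, weights=X[:, k]) / counts
            spl = make_smoothing_spline(ux, ybar, w=counts.astype(float),
                                        lam=smooth_lambda)
            new_curve[:, k] = spl(grid)
        new_param, new_dist2 = _project_to_polyline(X, new_curve)
        new_msd = float(new_dist2.mean())
        if new_msd > msd_trace[-1]:
            break                                    # keep the better curve
        curve, param = new_curve, new_param
        improved = msd_trace[-1] - new_msd
        msd_trace.append(new_msd)
        if improved < tol * max(msd_trace[0], 1e-300):
            break

    early = stage_num == stage_num.min()
    late = stage_num == stage_num.max()
    orientation = "forward"
    if param[early].mean() > param[late].mean():
        orientation = "reversed"
        param = param.max() - param
        curve = curve[::-1]
    pseudotime = param - param.min()
    return Trajectory(np.asarray(pc_scores, float), curve, pseudotime,
                      orientation, msd_trace)


def compare_ssr(
    norm: ExprMatrix,
    stage_numeric: np.ndarray,
    pseudotime: np.ndarray,
    hvg: list,
    lam: float = 0.001,
) -> SSRReport:
    """Per-gene smoothing-spline SSR along stage vs along pseudo-time.

    Reports the mean SSR over all genes and over the highly-variable set,
    and the percent decrease 100*(mean_stage - mean_pt)/mean_stage for both.
    HVG fields are None when ``hvg`` is empty.
    """
    stage_numeric = np.asarray(stage_numeric, float)
    pseudotime = np.asarray(pseudotime, float)
    if not (len(stage_numeric) == len(pseudotime) == norm.n_samples):
        raise ValueError("time axes must match the number of samples")
    ssr_stage = np.array([spline_ssr(stage_numeric, norm.values[g], lam)
                          for g in range(norm.n_genes)])
    ssr_pt = np.array([spline_ssr(pseudotime, norm.values[g], lam)
                       for g in range(norm.n_genes)])
    mean_stage = float(ssr_stage.mean())
    mean_pt = float(ssr_pt.mean())
    pct_all = 100.0 * (mean_stage - mean_pt) / mean_stage if mean_stage > 0 else 0.0
    if hvg:
        idx = norm.gene_index(hvg)
        ms, mp = float(ssr_stage[idx].mean()), float(ssr_pt[idx].mean())
        pct_hvg = 100.0 * (ms - mp) / ms if ms > 0 else 0.0
    else:
        ms = mp = pct_hvg = None
    return SSRReport(ssr_stage, ssr_pt, list(norm.gene_ids), list(hvg),
                     mean_stage, mean_pt, pct_all, ms, mp, pct_hvg)
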