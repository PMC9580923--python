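"""Linear-ODE gene-regulatory-network inference (SCODE-style).

The model assumes expression follows dx/dt = A·x with A of low rank D:
latent dynamics z_d(t) = exp(b_d·t) span the observed trajectories, each
gene's profile is a linear combination W[g,:]·z(t), and the network is
reconstructed as A = W·diag(b)·pinv(W).  Optimization is a greedy random
coordinate search over b (each proposal refits W in closed form and is
accepted only if the residual sum of squares strictly decreases).  Because
single runs are stochastic, an ensemble of runs is averaged after selecting
the runs that agree best with the ensemble mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

PINV_RCOND = 1e-12     # relative singular-value cutoff for pinv


@dataclass
class GRNModel:
    """One fitted linear-ODE model."""

    W: np.ndarray
    b: np.ndarray
    A: np.ndarray
    rss: float
    D: int
    seed: int
    iterations: int
    rss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class EnsembleGRN:
    """Average of the runs most correlated with the ensemble mean."""

    A_avg: np.ndarray
    run_pccs: np.ndarray
    selected_runs: list[int]
    R: int
    top_k: int


def latent_dynamics(b: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Z[d, s] = exp(b[d] * t[s])."""
    b = np.asarray(b, float)
    t = np.asarray(t, float)
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(t))):
        raise ValueError("b and t must be finite")
    return np.exp(np.outer(b, t))


def fit_W(X: np.ndarray, Z: np.ndarray, ridge: float = 1e-8):
    """Per-gene ridge regression of X on the latent dynamics Z.

    Solves min_W ||X - W·Z||^2 + ridge·||W||^2 in closed form; the reported
    rss excludes the penalty.  With ridge = 0 a rank-deficient Z is an error.
    """
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    D, S = Z.shape
    if X.shape[1] != S:
        raise ValueError("X and Z must share the sample axis")
    if S < D:
        raise ValueError(f"need at least D={D} samples, got {S}")
    if ridge == 0:
        if np.linalg.matrix_rank(Z) < D:
            raise np.linalg.LinAlgError(
                "Z is rank-deficient; use ridge > 0 or reduce D"
            )
        W = np.linalg.lstsq(Z.T, X.T, rcond=None)[0].T
    else:
        G = Z @ Z.T + ridge * np.eye(D)
        W = np.linalg.solve(G, Z @ X.T).T
    resid = X - W @ Z
    return W, float((resid * resid).sum())


def assemble_A(W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Reconstruct the network A = W·diag(b)·pinv(W).

    A[i, j] is the regulatory effect on downstream gene i from regulator j;
    positive entries are activation, negative repression.
    """
    return W @ np.diag(np.asarray(b, float)) @ np.linalg.pinv(W, rcond=PINV_RCOND)


def normalize_pseudotime(pseudotime: np.ndarray) -> np.ndarray:
    """Scale pseudo-time into [0, 1] by dividing by its maximum."""
    pt = np.asarray(pseudotime, float)
    m = pt.max()
    if m <= 0:
        raise ValueError("pseudotime must have a positive maximum")
    return pt / m


def optimize_scode(
    X: np.ndarray,
    pseudotime: np.ndarray,
    D: int = 4,
    iterations: int = 100,
    b_range: tuple[float, float] = (-10.0, 2.0),
    seed: int = 0,
    ridge: float = 1e-8,
    scale_pseudotime: bool = True,
) -> GRNModel:
    """One greedy random-search fit of the linear-ODE model.

    b is initialized uniformly in ``b_range``; each iteration redraws one
    coordinate of b, refits W, and keeps the proposal only if the rss
    strictly decreases, so the rss trace is non-increasing.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = np.asarray(X, float)
    t = np.asarray(pseudotime, float)
    if np.ptp(t) == 0:
        raise ValueError("pseudotime is constant; no dynamics to fit")
    if X.shape[1] <= D:
        raise ValueError("need more samples than latent dimensions")
    if scale_pseudotime:
        t = normalize_pseudotime(t)
    rng = np.random.default_rng(seed)
    b = rng.uniform(b_range[0], b_range[1], size=D)
    W, rss = fit_W(X, latent_dynamics(b, t), ridge)
    trace = [rss]
    for _ in range(iterations):
        d = int(rng.integers(D))
        proposal = b.copy()
        proposal[d] = rng.uniform(b_range[0], b_range[1])
        W_new, rss_new = fit_W(X, latent_dynamics(proposal, t), ridge)
        if rss_new < rss:
            b, W, rss = proposal, W_new, rss_new
        trace.append(rss)
    return GRNModel(W=W, b=b, A=assemble_A(W, b), rss=rss, D=D, seed=seed,
                    iterations=iterations, rss_trace=np.asarray(trace))


def scan_D(
    X: np.ndarray,
    pseudotime: np.ndarray,
    D_values: list[int],
    iterations: int = 100,
    seed: int = 0,
    **kwargs,
) -> list[tuple[int, float]]:
    """Fit once per candidate latent dimension and report (D, rss).

    The rss is not guaranteed monotone in D (stochastic optimizer); the
    table is for choosing D by eye, as done with the elbow at D = 4.
    """
    out = []
    for k, D in enumerate(D_values):
        model = optimize_scode(X, pseudotime, D=D, iterations=iterations,
                               seed=seed + k, **kwargs)
        out.append((D, model.rss))
    return out


def ensemble_average(runs: list[GRNModel], top_k: int = 10) -> EnsembleGRN:
    """Average the ``top_k`` runs most correlated with the ensemble mean.

    run_pccs[r] is the Pearson correlation between run r's flattened A and
    the elementwise mean over all runs; a run whose A is constant has
    undefined correlation and is assigned -inf (never selected).  Ties are
    broken by run index.
    """
    if len(runs) < top_k:
        raise ValueError(f"need at least top_k={top_k} runs, got {len(runs)}")
    As = np.stack([r.A for r in runs])
    meanA = As.mean(axis=0)
    flat_mean = meanA.ravel()
    pccs = np.empty(len(runs))
    for r, a in enumerate(As):
        fa = a.ravel()
        if fa.std() == 0 or flat_mean.std() == 0:
            logger.warning("run %d has a constant A; excluded from ensemble", r)
            pccs[r] = -np.inf
        else:
            pccs[r] = np.corrcoef(fa, flat_mean)[0, 1]
    # stable sort on -pcc => ties broken by run index
    selected = list(np.argsort(-pccs, kind="stable")[:top_k])
    A_avg = As[selected].mean(axis=0)
    return EnsembleGRN(A_avg=A_avg, run_pccs=pccs,
                       selected_runs=[int(i) for i in selected],
                       R=len(runs), top_k=top_k)


def infer_ensemble(
    X: np.ndarray,
    pseudotime: np.ndarray,
    D: int = 4,
    runs: int = 20,
    iterations: int = 100,
    top_k: int = 10,
    b_range: tuple[float, float] = (-10.0, 2.0),
    seed: int = 0,
    ridge: float = 1e-8,
) -> tuple[EnsembleGRN, list[GRNModel]]:
    """Full ensemble inference: ``runs`` independent fits, top-k averaging.

    Run seeds are spawned deterministically from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(runs) % (2**31)
    models = [
        optimize_scode(X, pseudotime, D=D, iterations=iterations,
                       b_range=b_range, seed=int(s), ridge=ridge)
        for s in seeds
    ]
    return ensemble_average(models, top_k=top_k), models
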