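"""Ground-truth simulators for benchmarking every stage of the pipeline.

The generator family produces (i) a ground-truth regulatory matrix that is
*exactly realizable* under the linear-ODE inference model dx/dt = A·x with
A = W·diag(b)·pinv(W), (ii) a time-course cohort of individual whole-embryo
count profiles whose samples progress at individually jittered speeds,
(iii) a toy TF→target database, (iv) signaling-pathway annotations whose
ligand and receptor genes share a designated downstream set, and (v)
cell-type average-expression profiles with designated co-expressed pairs.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix

# Canonical names for the major developmental signaling pathways; used to
# label synthetic pathways when nine or fewer are requested.
PATHWAY_NAMES = ["Wnt", "TNF", "TGFb", "Hedgehog", "FGF", "EGF", "Notch", "BMP", "RA"]


@dataclass
class TrueGRN:
    """Ground-truth network: A = W·diag(b)·pinv(W), rank at most D."""

    W_true: np.ndarray          # G x D
    b_true: np.ndarray          # D latent exponential rates
    A_true: np.ndarray          # G x G, downstream i x regulator j
    edge_set: set               # {(i, j, sign)} for |A[i,j]| above quantile
    gene_ids: list[str]
    edge_quantile: float
    seed: int
    abundance: np.ndarray = None  # per-gene expression scale (heavy-tailed)

    @property
    def n_genes(self) -> int:
        return self.W_true.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.W_true.shape[1]


@dataclass
class PathwayAnnotation:
    """One synthetic signaling pathway: ligand/receptor genes sharing a
    designated downstream set, with a recorded sign relation."""

    name: str
    ligand_genes: list[str]
    receptor_genes: list[str]
    shared_downstream: set
    sign: str                   # "same" or "opposite"


@dataclass
class SimulatedCohort:
    """A simulated time-course cohort of individual count profiles."""

    counts: np.ndarray          # G x S non-negative integers
    stage_labels: list[str]
    true_time: np.ndarray       # length S, in [0, 1]
    seed: int
    latent: np.ndarray          # G x S noiseless latent expression W·exp(b·t)
    gene_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def to_count_matrix(self) -> CountMatrix:
        return CountMatrix(
            values=self.counts,
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            stage=list(self.stage_labels),
        )


def _assemble(W: np.ndarray, b: np.ndarray) -> np.ndarray:
    return W @ np.diag(b) @ np.linalg.pinv(W)


def _edge_set(A: np.ndarray, quantile: float) -> set:
    cut = np.quantile(np.abs(A), quantile)
    ii, jj = np.nonzero(np.abs(A) > cut)
    return {(int(i), int(j), int(np.sign(A[i, j]))) for i, j in zip(ii, jj)}


def generate_true_grn(
    G: int,
    D: int,
    seed: int,
    edge_quantile: float = 0.99,
    b_range: tuple[float, float] = (-10.0, 2.0),
    abundance_sigma: float = 2.0,
) -> TrueGRN:
    """Draw a random ground-truth network realizable by the linear-ODE model.

    Each gene's row of W is standard normal scaled by a per-gene abundance
    drawn log-normal(0, ``abundance_sigma``): bulk RNA-Seq expression levels
    are heavy-tailed, with a few genes dominating the library, and making
    that part of the ground truth keeps the latent amplitudes, the counts
    and the \\|A\\|-based edge magnitudes mutually consistent.  The latent
    rates b are uniform on ``b_range``, and A = W·diag(b)·pinv(W) so that
    rank(A) = D.  Edges are entries of \\|A\\| above the ``edge_quantile``
    quantile, with signs.
    """
    if not (G >= D >= 1):
        raise ValueError(f"need G >= D >= 1, got G={G}, D={D}")
    if not (0 < edge_quantile < 1):
        raise ValueError("edge_quantile must be in (0, 1)")
    rng = np.random.default_rng(seed)
    abundance = rng.lognormal(0.0, abundance_sigma, size=G)
    W = rng.normal(size=(G, D)) * abundance[:, None]
    b = rng.uniform(b_range[0], b_range[1], size=D)
    A = _assemble(W, b)
    gene_ids = [f"g{i:04d}" for i in range(G)]
    return TrueGRN(W, b, A, _edge_set(A, edge_quantile), gene_ids,
                   edge_quantile, seed, abundance)


def simulate_timecourse(
    grn: TrueGRN,
    stages: int = 7,
    per_stage: int | Sequence[int] = 11,
    jitter_sd: float = 0.05,
    noise_model: str = "poisson",
    library_size: int = 100_000,
    seed: int = 0,
    nb_dispersion: float = 0.1,
) -> SimulatedCohort:
    """Simulate a cohort of individual profiles along the true dynamics.

    Each sample's developmental progress is its stage fraction plus Gaussian
    jitter (individual differences in developmental speed), clamped to [0,1].
    Latent expression is X[:,s] = W·exp(b·t_s); for count sampling it is
    min-shifted per gene (counts cannot be negative) and globally scaled so
    the expected grand total equals ``library_size`` x n_samples.  The shift
    is per-gene only: relative amplitudes between genes are the heavy-tailed
    scales of the ground truth and are deliberately preserved, mirroring the
    use of unscaled expression downstream.
    """
    if stages < 2:
        raise ValueError("need at least 2 stages")
    if library_size < 0:
        raise ValueError("library_size must be non-negative")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if noise_model not in ("none", "poisson", "negative_binomial"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    if isinstance(per_stage, int):
        if per_stage < 1:
            raise ValueError("per_stage must be >= 1")
        per_stage = [per_stage] * stages
    per_stage = list(per_stage)
    if len(per_stage) != stages:
        raise ValueError("per_stage sequence must have one entry per stage")

    rng = np.random.default_rng(seed)
    stage_labels, true_time, sample_ids = [], [], []
    for k, n_k in enumerate(per_stage):
        label = f"E{7.5 + k:g}"
        frac = k / (stages - 1)
        for r in range(n_k):
            stage_labels.append(label)
            sample_ids.append(f"{label}_r{r + 1:02d}")
            true_time.append(np.clip(frac + rng.normal(0.0, jitter_sd), 0.0, 1.0))
    true_time = np.asarray(true_time)

    # latent dynamics: exact solution of dX/dt = A_true·X in the W-basis
    Z = np.exp(np.outer(grn.b_true, true_time))          # D x S
    latent = grn.W_true @ Z                              # G x S

    # per-gene min-shift (non-negativity only), then global library scaling
    shifted = latent - latent.min(axis=1, keepdims=True)
    total = shifted.sum()
    S = len(sample_ids)
    lam = shifted * (library_size * S / total) if total > 0 else shifted

    if noise_model == "none":
        counts = np.rint(lam).astype(np.int64)
    elif noise_model == "poisson":
        counts = rng.poisson(lam).astype(np.int64)
    else:
        shape = 1.0 / nb_dispersion
        mix = rng.gamma(shape, 1.0, size=lam.shape) / shape
        counts = rng.poisson(lam * mix).astype(np.int64)

    return SimulatedCohort(
        counts=counts,
        stage_labels=stage_labels,
        true_time=true_time,
        seed=seed,
        latent=latent,
        gene_ids=list(grn.gene_ids),
        sample_ids=sample_ids,
    )


def generate_tf_database(
    grn: TrueGRN,
    tf_genes: Sequence[str],
    per_tf_targets: int = 10,
    fp_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Build a toy TF→target database from the true network.

    Per TF the targets are the ``per_tf_targets`` genes with largest
    \\|A_true[., tf]\\| (self excluded); a ``fp_rate`` fraction of them is
    replaced by random non-targets to emulate database noise.
    """
    pos = {g: i for i, g in enumerate(grn.gene_ids)}
    unknown = [g for g in tf_genes if g not in pos]
    if unknown:
        raise KeyError(f"tf_genes not in gene universe: {unknown[:5]}")
    G = grn.n_genes
    if per_tf_targets > G:
        raise ValueError("per_tf_targets exceeds the number of genes")
    rng = np.random.default_rng(seed)
    db: dict[str, list[str]] = {}
    for tf in tf_genes:
        j = pos[tf]
        score = np.abs(grn.A_true[:, j]).copy()
        score[j] = -np.inf                      # no self-target
        order = np.argsort(-score, kind="stable")
        top = [grn.gene_ids[i] for i in order[:per_tf_targets]]
        n_fp = int(round(fp_rate * len(top)))
        if n_fp > 0:
            non_targets = [g for g in grn.gene_ids if g not in top and g != tf]
            swap_at = rng.choice(len(top), size=n_fp, replace=False)
            repl = rng.choice(len(non_targets), size=min(n_fp, len(non_targets)),
                              replace=False)
            for k, idx in enumerate(swap_at[: len(repl)]):
                top[idx] = non_targets[repl[k]]
        db[tf] = top
    return db


def generate_signaling_annotation(
    grn: TrueGRN,
    n_pathways: int = 9,
    seed: int = 0,
    sign: str = "same",
    perturb: float = 0.0,
    downstream_quantile: float = 0.9,
) -> tuple[TrueGRN, list[PathwayAnnotation]]:
    """Plant ligand/receptor pairs with shared downstream sets in the network.

    For each pathway a ligand gene L and a receptor gene R are chosen and the
    receptor's row of W is set to c·W[L,:] (plus a perturbation of relative
    size ``perturb``; 0 by default, making the shared downstream sets exact),
    with c > 0 for ``sign="same"`` and c < 0 for ``sign="opposite"``.  Because
    pinv(W)[:, j] is proportional to W[j, :] through (WᵀW)⁻¹, this makes the
    A columns of L and R (nearly) proportional: both regulators share their
    above-quantile downstream genes with the requested sign relation, while
    A keeps its exact factorization A = W·diag(b)·pinv(W) so the cohort
    simulator remains consistent with the planted network.

    Returns the rewritten network and one annotation record per pathway.
    ``sign`` may be "same", "opposite" or "mixed" (alternating).
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    if sign not in ("same", "opposite", "mixed"):
        raise ValueError(f"unknown sign flag {sign!r}")
    G, D = grn.n_genes, grn.latent_dim
    if 2 * n_pathways > G:
        raise ValueError("not enough genes for the requested pathways")
    rng = np.random.default_rng(seed)
    # pathway members are well-characterized, detectably expressed genes:
    # draw them from the upper half of the abundance distribution
    if grn.abundance is not None and G >= 4 * n_pathways:
        eligible = np.argsort(-np.asarray(grn.abundance))[: G // 2]
    else:
        eligible = np.arange(G)
    chosen = rng.choice(eligible, size=2 * n_pathways, replace=False)
    W = grn.W_true.copy()

    pathway_meta = []
    for k in range(n_pathways):
        L, R = int(chosen[2 * k]), int(chosen[2 * k + 1])
        pw_sign = sign if sign != "mixed" else ("same" if k % 2 == 0 else "opposite")
        c = rng.uniform(0.8, 1.25)
        if pw_sign == "opposite":
            c = -c
        noise = rng.normal(size=D)
        W[R, :] = c * W[L, :] + perturb * np.linalg.norm(W[L, :]) * noise
        pathway_meta.append((k, L, R, pw_sign))

    A = _assemble(W, grn.b_true)
    new_grn = TrueGRN(
        W_true=W,
        b_true=grn.b_true.copy(),
        A_true=A,
        edge_set=_edge_set(A, grn.edge_quantile),
        gene_ids=list(grn.gene_ids),
        edge_quantile=grn.edge_quantile,
        seed=grn.seed,
        abundance=None if grn.abundance is None else grn.abundance.copy(),
    )

    annotations = []
    for k, L, R, pw_sign in pathway_meta:
        down_L = _column_top(A, L, downstream_quantile, exclude=(L, R))
        down_R = _column_top(A, R, downstream_quantile, exclude=(L, R))
        name = PATHWAY_NAMES[k] if k < len(PATHWAY_NAMES) else f"PW{k + 1}"
        annotations.append(
            PathwayAnnotation(
                name=name,
                ligand_genes=[grn.gene_ids[L]],
                receptor_genes=[grn.gene_ids[R]],
                shared_downstream={grn.gene_ids[i] for i in down_L & down_R},
                sign=pw_sign,
            )
        )
    return new_grn, annotations


def _column_top(A: np.ndarray, j: int, quantile: float,
                exclude: tuple = ()) -> set:
    """Above-quantile downstream genes of regulator j (self excluded)."""
    col = np.abs(A[:, j]).copy()
    col[j] = 0.0
    for k in exclude:
        col[k] = 0.0
    cut = np.quantile(col, quantile)
    return {int(i) for i in np.flatnonzero(col > cut)}


def generate_celltype_profiles(
    grn: TrueGRN,
    n_celltypes: int = 98,
    coexpressed_pairs: Sequence[tuple[str, str]] = (),
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type x gene average-expression profiles with planted co-expression.

    Baseline profiles are independent log-normal noise; for each designated
    (upstream, downstream) pair the downstream profile is rewritten as the
    upstream profile plus 10% noise, giving Pearson correlation > 0.9.
    """
    if n_celltypes < 3:
        raise ValueError("need at least 3 cell types for correlation analysis")
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=0.0, sigma=1.0, size=(n_celltypes, grn.n_genes))
    df = pd.DataFrame(values, columns=list(grn.gene_ids),
                      index=[f"celltype{c + 1:03d}" for c in range(n_celltypes)])
    for up, down in coexpressed_pairs:
        if up not in df.columns or down not in df.columns:
            raise KeyError(f"pair ({up}, {down}) not in gene universe")
        base = df[up].to_numpy()
        df[down] = base + 0.1 * base.std() * rng.normal(size=n_celltypes)
    return df
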