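# Methods

## Model

Expression of `G` genes along a developmental trajectory is modeled by the
linear ODE system `dx/dt = A·x`, with the regulatory matrix `A` constrained
to rank `D ≪ G` through the factorization

```
A = W · diag(b) · W⁺ ,      z_d(t) = exp(b_d · t),      x(t) ≈ W · z(t)
```

where `b` holds `D` latent exponential rates, `W` (G × D) holds per-gene
loadings on the latent dynamics, and `W⁺` is the Moore–Penrose
pseudo-inverse. `A[i,j]` is read as the regulatory effect of gene `j` on
gene `i`; its sign distinguishes activation from repression. The model
assumes a single lineage (one trajectory, no branching), time-invariant
regulation, and that `D` basis dynamics suffice — with `D = 4` as the
default, where the residual of the fit flattens in the `scan_D` elbow
analysis.

Fitting alternates a closed-form step and a stochastic step: given `b`, each
gene's loadings are a ridge regression of its profile on `z(t)` (closed
form); `b` itself is refined by a greedy random coordinate search — one
coordinate redrawn uniformly from `b_range` per iteration, accepted only if
the residual sum of squares strictly decreases — for 100 iterations. Because
single runs depend on the random proposals, 20 independent runs are
ensembled: the Pearson correlation of each run's flattened `A` with the
elementwise mean over all runs is computed, and the 10 most-correlated runs
are averaged. A run whose `A` is constant has no defined correlation and is
assigned −∞ (never selected); ties are broken by run index.

## Pseudo-time

Samples are embedded by PCA of the centered expression (samples × genes,
full SVD solver for determinism). The trajectory is a principal curve in the
leading `n_pcs_used = 2` components: initialized as the polyline through the
per-stage centroids, it is refined by iterating (i) project every sample
onto the polyline, (ii) reparametrize by arclength, (iii) smooth each
coordinate against arclength with a cubic smoothing spline. Iteration stops
when the mean squared projection distance improves by less than `tol`
(relative), would increase (the previous curve is kept, making the recorded
trace non-increasing by construction), or after `max_iter = 20` rounds. The
curve is oriented so the earliest stage precedes the latest, and pseudo-time
is the arclength of each sample's projection, shifted to minimum 0. It is
left in arclength units; the network-inference step rescales it to [0, 1]
by dividing by its maximum.

Two centroid orderings are available. `init="mst"` orders centroids along
their minimum-spanning-tree path and raises an error if the tree branches
(a genuine single-lineage violation). `init="stage"` — the pipeline default —
orders them by the ordinal stage rank. The MST ordering is appropriate when
cluster order is unknown, but on strongly curved trajectories the MST can
shortcut across a bend between nearly equidistant centroids, producing a
spurious degree-3 node; in a time-course design the stage order is known, so
using it for initialization is both safer and more faithful to what is known
about the data. The refinement iterations, not the initialization, determine
the final curve.

### Spline SSR comparison

For each gene, a cubic smoothing spline minimizing
`Σ_i (y_i − f(t_i))² + λ ∫ f″(u)² du` with knots at all distinct `t` values
(`λ = 0.001`) is fitted twice: against the numeric stage (embryonic day) and
against pseudo-time. Tied `t` values are aggregated to their mean with
multiplicity weights — an exact reduction of the criterion — and the SSR is
evaluated on the original points. The headline quantity is the percent
decrease of the mean SSR when pseudo-time replaces stage, reported for all
genes and for the highly-variable subset. Note `λ` is applied on the raw
axis scale (R's `smooth.spline` internally rescales its λ, so numeric
equality with R is not expected, only the same penalized-spline contract).
The banded spline solver is well conditioned for `λ` up to ~1e6; beyond
that the large-λ (linear) limit should be computed directly.

## Preprocessing

Counts are filtered to genes with nonzero totals, then log-normalized:
`ln(1 + 10⁴ · c/total)` per sample. Variable genes are selected by the
mean/variance-plot rule: per gene, the mean of the de-logged expression
`exp(x) − 1` and the dispersion `ln(variance/mean)` on that scale; genes are
binned into 20 equal-width bins by mean, dispersions are z-scored within
bins (a bin that cannot be standardized contributes z = 0; zero-variance
genes are never selected), and genes with dispersion z > 1 and mean inside
`(mean_low, mean_high)` are kept. The function defaults (0.1, 8) are the
reference values for genome-scale panels; the pipeline configuration leaves
the upper end open because a small panel concentrates the library on few
genes (with 50 genes the mean counts-per-10k is ~200 by conservation, and
an upper cutoff of 8 would select nothing). Centering subtracts each gene's
mean and deliberately does **not** rescale variance: per-gene rescaling
would amplify technical noise of weakly expressed genes into the network
fit.

The pipeline embeds **all** expressed genes for PCA (`pca_genes="all"`),
using the variable-gene set only for the SSR comparison. With genome-scale
data, restricting PCA to variable genes removes noise dimensions; in the
synthetic desk-scale cohorts every gene carries dynamic signal and the mvp
rule keeps only a handful, so restricting the embedding to them discards
most of the trajectory information. `pca_genes="hvg"` restores the
reference protocol.

## Thresholding

For regulator `j`, `|A[·,j]|` is sorted in decreasing order (ties broken by
gene id for determinism) and a straight line `y = c0 + c1·r` is fitted to
the rank scatter by ordinary least squares (a linear model fitted by
nonlinear least squares has the same optimum). The downstream set is the
prefix of ranks strictly above the line, stopping at the first rank at or
below it (`mode="prefix"`, default): the fitted line passes through the bulk
of near-zero values, so genuine targets stand above it as leading outliers.
The literal reading — every rank above the line, which can re-admit tail
ranks when a steep outlier drags the fitted line negative — is available as
`mode="literal"`. All-zero columns select nothing. Selection is invariant
to positive rescaling of the column.

## Validation

Per database TF, the candidate universe is every gene except the TF itself.
AUC is the Mann–Whitney probability that a true target outranks a non-target
under `|A|` scoring (ties count ½). Enrichment of known targets among the
selected downstream genes uses the one-sided Fisher exact test (the reported
odds ratio is the sample cross-product ratio, not the conditional MLE that
R reports); p-values are Benjamini–Hochberg-adjusted across TFs.
Validated-target-rate curves report `rate(r) = |top-r ∩ targets|/r`, the
best rate over all ranks ≥ 1, and the gap between the best rate and the
rate at the selected cutoff. Whole networks are compared by
`1 − PCC(flattened A)` distance with average-linkage agglomeration.

## Intercellular analysis

For each annotated pathway, the downstream sets of the ligand-related and
receptor-related gene families are unioned per family (the family member
with the most downstream genes is the representative; ties by gene id).
Overlap significance uses the hypergeometric tail
`P(|∩| ≥ observed)` for drawing `|B|` genes from the universe with `|A|`
successes — exact and deterministic; a permutation variant (resample one
set, `p = (1 + #{≥ obs})/(1 + n_perm)`) mirrors resampling-based
implementations. BH correction is applied across all ligand–receptor pairs
jointly. Two overlap fractions are reported, `|∩|/min(|L|,|R|)` and
`|∩|/|L|`, since both denominators are in common use. Sign concordance
cross-tabulates the four sets {L+, L−, R+, R−} over all 15 non-empty
membership patterns; the concordance fraction is, among genes downstream of
both pair members, the fraction regulated in the same direction — near 1
for pathways whose receptors activate targets only upon ligand binding,
near 0 where the unliganded receptor is a repressor.

Cell-type co-expression uses cell-type × gene averages of de-logged
expression (`mean(exp(x) − 1)` per label); an upstream/downstream pair is
co-expressed when the Pearson correlation of the two profiles is strictly
greater than 0.4. Zero-variance profiles have undefined correlation and are
flagged not co-expressed.

## Synthetic data: what it emulates, and what it does not

`generate_true_grn(G, D, seed)` draws `W` with standard-normal rows scaled by
per-gene abundances `~ lognormal(0, 2)` and `b ~ U(−10, 2)`, and defines the
truth `A = W·diag(b)·W⁺` with edges as the entries of `|A|` above the 0.99
quantile. Placing the heavy-tailed abundance inside `W` makes the latent
amplitudes, the simulated counts, and the `|A|`-based edge magnitudes
mutually consistent — the same few genes dominate the library, as in real
bulk RNA-Seq, while most genes sit in the near-linear regime of the log
normalization. The construction guarantees rank(A) = D and exact
realizability: the residual of the inference model at `(W, b)` on a
noiseless cohort is zero to machine precision.

`simulate_timecourse` gives each individual a true time equal to its stage
fraction plus `N(0, jitter_sd²)` (clamped to [0, 1]) — individual variation
in developmental speed — and evaluates the exact latent solution
`X(t) = W·exp(b t)`. Counts are obtained by min-shifting each gene (counts
cannot be negative) and scaling globally so the expected grand total is
`library_size × n_samples`, then sampling Poisson or negative-binomial
(gamma–Poisson, dispersion 0.1) noise. The shift is per-gene only: relative
gene amplitudes are preserved, mirroring the use of *unscaled* expression in
the analysis. Defaults — 7 stages, 10–11 individuals per stage (76
samples), jitter 0.05, Poisson noise, 10⁵ reads per sample, 50 genes — are
the desk-scale analog of the study design this package targets; problem
sizes were chosen so the full test suite and the acceptance script run in
seconds to minutes.

`generate_signaling_annotation` plants each pathway by setting the
receptor's row of `W` to `c` times the ligand's row (`|c| ~ U(0.8, 1.25)`,
positive for `sign="same"`, negative for `"opposite"`). Because
`W⁺[:,j] = (WᵀW)⁻¹W[j,:]ᵀ` for full-column-rank `W`, proportional rows give
exactly proportional `A` columns: the ligand and receptor share their
above-quantile downstream set (quantile 0.9 per column, excluding the pair
itself) with the requested sign relation, while `A` keeps its factorization
so the simulator remains consistent with the planted network. Pathway
members are drawn from the upper half of the abundance distribution,
reflecting that annotated pathway genes are well-characterized, detectably
expressed genes. `generate_tf_database` lists each TF's top-k genes by
`|A[·,tf]|` (self excluded), optionally corrupted by a false-positive rate;
`generate_celltype_profiles` plants designated co-expressed pairs (PCC >
0.9) on an independent log-normal background.

What the generator does **not** emulate: genome-scale gene counts (50 vs
~28k), multi-lineage or branching trajectories, batch and library-prep
effects, gene-length or GC bias, cell-type composition shifts within the
embryo, and any mismatch between the data and the linear-ODE model itself.
Passing recovery tests therefore demonstrates the pipeline's correctness
and its behavior under the model's own assumptions — not performance
guarantees on real embryo data, where model mismatch dominates. One
consequence of the log transform is worth noting: a monotone per-gene
nonlinearity preserves positive proportionality between profiles almost
perfectly but degrades anti-proportionality, so opposite-sign relations are
recovered less reliably than same-sign ones — visible in the wider spread
of the opposite-flag concordance across seeds.

## Numerical choices

- Ridge `1e-8` in the regression step for safety against collinear latent
  dynamics; the reported rss excludes the penalty; `ridge=0` switches to an
  exact least-squares solve and errors on rank-deficient dynamics.
- Pseudo-inverses use SVD with relative cutoff `1e-12`.
- `b_range = (−10, 2)`: the latent-rate sampling range of the reference
  optimizer; on `t ∈ [0,1]`, −10 is a fast decay and 2 a ~7-fold rise.
- Ensemble seeds are spawned from the base seed via `SeedSequence`;
  end-to-end runs are bit-reproducible, with the usual caveat that exotic
  BLAS builds may differ below ~1e-10 (the determinism test uses that
  tolerance).
- Ties: gene-id lexicographic order in thresholding ranks; run index in
  ensemble selection.
- Degenerate inputs: all-zero regulator columns select nothing; empty
  selections give Fisher p = 1 with an undefined odds ratio; empty
  ligand/receptor sets give overlap p = 1; constant matrices are rejected
  where a correlation is required; spline fits require ≥ 4 distinct time
  points.

## Known limitations

- Single lineage only; branching data should be split upstream.
- The greedy 100-iteration search over `b` is coarse by design (it matches
  the reference protocol); per-run quality varies and is exactly why the
  20-run ensemble exists.
- The regressed-line threshold is scale-free but heuristic; at small `G`
  the selected sets are small, and downstream enrichment tests lose power
  for regulators whose columns lack clear outliers.
- The Fisher-test universe defaults to all filtered genes; restricting it
  to database-covered genes is supported via the `universe` argument and
  can change significance calls.
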