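"""End-to-end pipeline: simulate/load -> preprocess -> pseudo-time ->
network inference -> thresholding -> validation -> intercellular analysis.

Every stochastic stage receives a sub-seed derived deterministically from
the base seed, so a full run is bit-reproducible.  A manifest (config,
seeds, file hashes) is written alongside the stage outputs; it contains no
timestamps, so identical runs produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import intercellular as ic
from . import io as gio
from . import preprocess as pp
from . import pseudotime as pt
from . import scode
from . import synthetic as syn
from . import thresholding as th
from . import validation as val
from .containers import stage_to_numeric

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults follow the reference analysis protocol
    (20 optimizations x 100 iterations, D = 4, top-10 averaging, smoothing
    lambda = 0.001, co-expression cut 0.4)."""

    # synthetic cohort
    n_genes: int = 50
    latent_dim_true: int = 4
    stages: int = 7
    per_stage: tuple = (10, 11, 11, 11, 11, 11, 11)
    jitter_sd: float = 0.05
    noise_model: str = "poisson"
    library_size: int = 100_000
    edge_quantile: float = 0.99
    n_pathways: int = 9
    pathway_sign: str = "same"
    n_tfs: int = 10
    per_tf_targets: int = 10
    tf_fp_rate: float = 0.0
    n_celltypes: int = 98
    # preprocessing
    scale_factor: float = 1e4
    n_bins: int = 20
    mean_low: float = 0.1
    # With a small uniformly-expressed gene panel the de-logged mean per gene
    # is ~scale_factor/n_genes, so the genome-scale upper cutoff of 8 would
    # exclude everything; the pipeline default leaves the upper end open.
    mean_high: float = float("inf")
    disp_z_cut: float = 1.0
    # pseudo-time
    n_pcs: int = 10
    n_pcs_used: int = 2
    pca_genes: str = "all"        # "all" | "hvg" (reference protocol)
    spline_lambda: float = 0.001
    traj_max_iter: int = 20
    traj_tol: float = 1e-4
    traj_init: str = "stage"      # stages are ordinal in time-course designs
    # network inference
    D: int = 4
    runs: int = 20
    iterations: int = 100
    top_k: int = 10
    b_range: tuple = (-10.0, 2.0)
    ridge: float = 1e-8
    # thresholding / downstream analyses
    threshold_mode: str = "prefix"
    overlap_method: str = "hypergeometric"
    pcc_cut: float = 0.4
    # reproducibility
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_stage"] = list(d["per_stage"])
        d["b_range"] = list(d["b_range"])
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: Path
    truth: syn.TrueGRN | None
    cohort: syn.SimulatedCohort | None
    trajectory: pt.Trajectory
    ssr_report: pt.SSRReport
    ensemble: scode.EnsembleGRN
    regulons: th.RegulonTable
    tf_reports: list = field(default_factory=list)
    overlap_reports: list = field(default_factory=list)
    concordance: dict = field(default_factory=dict)
    coexpression: object = None
    manifest: dict = field(default_factory=dict)


def _subseeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Run every stage on a synthetic cohort and write stage outputs.

    Raises with a stage-named error on failure; outputs of completed stages
    are retained in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s_grn, s_ann, s_cohort, s_db, s_cells, s_infer = _subseeds(config.seed, 6)

    stage = "simulate"
    try:
        truth = syn.generate_true_grn(config.n_genes, config.latent_dim_true,
                                      seed=s_grn,
                                      edge_quantile=config.edge_quantile)
        truth, annotations = syn.generate_signaling_annotation(
            truth, n_pathways=config.n_pathways, seed=s_ann,
            sign=config.pathway_sign)
        cohort = syn.simulate_timecourse(
            truth, stages=config.stages, per_stage=list(config.per_stage),
            jitter_sd=config.jitter_sd, noise_model=config.noise_model,
            library_size=config.library_size, seed=s_cohort)
        special = {g for a in annotations
                   for g in a.ligand_genes + a.receptor_genes}
        tf_pool = [g for g in truth.gene_ids if g not in special]
        tf_genes = tf_pool[: config.n_tfs]
        tf_db = syn.generate_tf_database(truth, tf_genes,
                                         per_tf_targets=config.per_tf_targets,
                                         fp_rate=config.tf_fp_rate, seed=s_db)
        coexp_pairs = [(a.ligand_genes[0], sorted(a.shared_downstream)[0])
                       for a in annotations if a.shared_downstream]
        profiles = syn.generate_celltype_profiles(
            truth, n_celltypes=config.n_celltypes,
            coexpressed_pairs=coexp_pairs, seed=s_cells)

        counts = cohort.to_count_matrix()
        gio.write_counts_tsv(counts, outdir / "counts.tsv")
        gio.write_metadata_tsv(cohort.sample_ids, cohort.stage_labels,
                               outdir / "metadata.tsv",
                               true_time=cohort.true_time)
        gio.write_matrix_tsv(truth.A_true, truth.gene_ids,
                             outdir / "A_true.tsv")
        gio.write_tf_db_tsv(tf_db, outdir / "tf_db.tsv")
        gio.write_annotation_tsv(annotations, outdir / "annotation.tsv",
                                 outdir / "pathways.tsv")
        profiles.to_csv(outdir / "celltype_profiles.tsv", sep="\t")

        stage = "preprocess"
        counts = pp.filter_expressed(counts)
        norm = pp.normalize(counts, scale_factor=config.scale_factor)
        hvg = pp.select_hvg(norm, n_bins=config.n_bins,
                            mean_low=config.mean_low,
                            mean_high=config.mean_high,
                            disp_z_cut=config.disp_z_cut)
        if not hvg:
            logger.warning("no highly-variable genes selected")
        use_hvg = config.pca_genes == "hvg" and bool(hvg)
        centered = pp.center(norm, hvg if use_hvg else None)
        gio.write_expr_tsv(norm, outdir / "normalized.tsv")
        (outdir / "hvg.txt").write_text("\n".join(hvg) + "\n" if hvg else "")

        stage = "pseudotime"
        scores, _, _ = pt.run_pca(centered,
                                  min(config.n_pcs, centered.n_genes,
                                      centered.n_samples))
        traj = pt.fit_trajectory(scores, counts.stage,
                                 n_pcs_used=config.n_pcs_used,
                                 max_iter=config.traj_max_iter,
                                 tol=config.traj_tol,
                                 smooth_lambda=config.spline_lambda,
                                 init=config.traj_init)
        ssr = pt.compare_ssr(norm, stage_to_numeric(counts.stage),
                             traj.pseudotime, hvg, lam=config.spline_lambda)
        _write_trajectory(traj, counts.sample_ids, outdir / "trajectory.tsv")
        _write_ssr(ssr, outdir / "ssr_report.tsv")

        stage = "infer"
        ensemble, models = scode.infer_ensemble(
            norm.values, traj.pseudotime, D=config.D, runs=config.runs,
            iterations=config.iterations, top_k=config.top_k,
            b_range=tuple(config.b_range), seed=s_infer, ridge=config.ridge)
        gio.write_matrix_tsv(ensemble.A_avg, norm.gene_ids,
                             outdir / "A_avg.tsv")
        gio.write_json(
            {"run_pccs": [float(p) for p in ensemble.run_pccs],
             "selected_runs": ensemble.selected_runs,
             "run_seeds": [m.seed for m in models],
             "run_rss": [m.rss for m in models]},
            outdir / "inference_log.json")

        stage = "threshold"
        regulons = th.build_regulons(ensemble.A_avg, norm.gene_ids,
                                     mode=config.threshold_mode)
        gio.write_regulons_tsv(regulons, outdir / "regulons.tsv",
                               outdir / "threshold_lines.tsv")

        stage = "validate"
        tf_reports = val.validate_regulons(ensemble.A_avg, norm.gene_ids,
                                           regulons, tf_db)
        _write_tf_reports(tf_reports, outdir / "validation.tsv")
        aucs = [r.auc for r in tf_reports if np.isfinite(r.auc)]
        gio.write_json(
            {"mean_auc": float(np.mean(aucs)) if aucs else None,
             "n_tfs": len(tf_reports),
             "n_significant_adj_p_0.01":
                 int(sum(1 for r in tf_reports
                         if r.p_adj is not None and r.p_adj < 0.01))},
            outdir / "validation_summary.json")

        stage = "intercellular"
        overlaps = ic.pathway_overlap_report(regulons, annotations,
                                             universe_size=norm.n_genes,
                                             method=config.overlap_method,
                                             seed=s_infer)
        concordance = {}
        for ann in annotations:
            _, _, repL = ic.family_downstream(regulons, ann.ligand_genes)
            _, _, repR = ic.family_downstream(regulons, ann.receptor_genes)
            Lp, Ln = regulons.signed_sets(repL)
            Rp, Rn = regulons.signed_sets(repR)
            concordance[ann.name] = ic.sign_concordance(Lp, Ln, Rp, Rn)
        coex_pairs = [(a.ligand_genes[0], sorted(a.shared_downstream)[0])
                      for a in annotations if a.shared_downstream]
        upstream_class = {a.ligand_genes[0]: "ligand" for a in annotations}
        coex_table, coex_ratios = ic.coexpression_filter(
            profiles, coex_pairs, pcc_cut=config.pcc_cut,
            upstream_class=upstream_class)
        _write_overlaps(overlaps, outdir / "overlap_report.tsv")
        _write_concordance(concordance, outdir / "sign_concordance.tsv")
        coex_table.to_csv(outdir / "coexpression.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "subseeds": {"grn": s_grn, "annotation": s_ann, "cohort": s_cohort,
                     "tf_db": s_db, "celltypes": s_cells, "inference": s_infer},
        "files": {p.name: _sha256(p)
                  for p in sorted(outdir.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    gio.write_json(manifest, outdir / "manifest.json")
    return PipelineResult(config, outdir, truth, cohort, traj, ssr, ensemble,
                          regulons, tf_reports, overlaps, concordance,
                          coex_table, manifest)


def _write_trajectory(traj, sample_ids, path):
    import pandas as pd

    k = traj.pc_scores.shape[1]
    df = pd.DataFrame(traj.pc_scores, index=sample_ids,
                      columns=[f"pc{i + 1}" for i in range(k)])
    df.insert(0, "sample_id", sample_ids)
    df["pseudotime"] = traj.pseudotime
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _write_ssr(ssr, path):
    import pandas as pd

    df = pd.DataFrame({"gene_id": ssr.gene_ids, "ssr_stage": ssr.ssr_stage,
                       "ssr_pseudotime": ssr.ssr_pseudotime})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _write_tf_reports(reports, path):
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def _write_overlaps(reports, path):
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
        path, sep="\t", index=False, float_format="%.12g")


def _write_concordance(concordance, path):
    import pandas as pd

    rows = []
    for pw, tab in concordance.items():
        rows.append({
            "pathway": pw,
            "concordance": tab.concordance,
            "n_both_selected": tab.n_both_selected,
            "patterns": ";".join(f"{'&'.join(k)}={v}"
                                 for k, v in sorted(tab.pattern_counts.items())),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.12g")
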