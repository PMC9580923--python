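"""File formats: TSV matrices, MatrixMarket with name sidecars, reports.

On disk, expression matrices are genes x samples TSV with the gene id in the
first column; the inferred network A is a genes x genes TSV with rows =
downstream gene i and columns = regulator j.  MatrixMarket counts come with
``<stem>.genes.txt`` / ``<stem>.samples.txt`` sidecars, one id per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .containers import CountMatrix, ExprMatrix


def _read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample id")
    return df


def write_counts_tsv(counts: CountMatrix, path) -> None:
    df = pd.DataFrame(counts.values, index=counts.gene_ids,
                      columns=counts.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path, metadata_path=None) -> CountMatrix:
    df = _read_tsv_matrix(path)
    stage = []
    if metadata_path is not None:
        meta = read_metadata_tsv(metadata_path)
        meta = meta.set_index("sample_id").reindex(df.columns)
        if meta["stage"].isna().any():
            missing = meta.index[meta["stage"].isna()][0]
            raise ValueError(f"metadata missing sample {missing!r}")
        stage = list(meta["stage"])
    return CountMatrix(df.to_numpy(), list(df.index), list(df.columns), stage)


def write_counts_mtx(counts: CountMatrix, stem) -> None:
    stem = Path(stem)
    scipy.io.mmwrite(str(stem.with_suffix(".mtx")),
                     scipy.sparse.csr_matrix(counts.values))
    stem.with_suffix(".genes.txt").write_text("\n".join(counts.gene_ids) + "\n")
    stem.with_suffix(".samples.txt").write_text("\n".join(counts.sample_ids) + "\n")


def read_counts_mtx(stem, metadata_path=None) -> CountMatrix:
    stem = Path(stem)
    mat = scipy.io.mmread(str(stem.with_suffix(".mtx")))
    genes = stem.with_suffix(".genes.txt").read_text().splitlines()
    samples = stem.with_suffix(".samples.txt").read_text().splitlines()
    values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    stage = []
    if metadata_path is not None:
        meta = read_metadata_tsv(metadata_path).set_index("sample_id")
        stage = list(meta.reindex(samples)["stage"])
    return CountMatrix(values.astype(np.int64), genes, samples, stage)


def write_metadata_tsv(sample_ids, stage, path, true_time=None) -> None:
    df = pd.DataFrame({"sample_id": sample_ids, "stage": stage})
    if true_time is not None:
        df["true_time"] = true_time
    df.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expr_tsv(expr: ExprMatrix, path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_expr_tsv(path, layer: str = "normalized") -> ExprMatrix:
    df = _read_tsv_matrix(path)
    return ExprMatrix(df.to_numpy(float), list(df.index), list(df.columns),
                      layer=layer)


def write_matrix_tsv(A: np.ndarray, gene_ids, path, col_ids=None) -> None:
    df = pd.DataFrame(A, index=gene_ids, columns=col_ids or gene_ids)
    df.index.name = "downstream_gene"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix_tsv(path):
    df = _read_tsv_matrix(path)
    return df.to_numpy(float), list(df.index), list(df.columns)


def write_tf_db_tsv(db: dict, path) -> None:
    rows = [{"tf": tf, "target": t} for tf, targets in db.items() for t in targets]
    pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)


def read_tf_db_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    db: dict = {}
    for tf, sub in df.groupby("tf", sort=False):
        db[tf] = list(sub["target"])
    return db


def write_annotation_tsv(annotations, path, pathway_path=None) -> None:
    rows = []
    for ann in annotations:
        for g in ann.ligand_genes:
            rows.append({"pathway": ann.name, "role": "ligand", "gene": g})
        for g in ann.receptor_genes:
            rows.append({"pathway": ann.name, "role": "receptor", "gene": g})
    pd.DataFrame(rows, columns=["pathway", "role", "gene"]).to_csv(
        path, sep="\t", index=False)
    if pathway_path is not None:
        meta = pd.DataFrame(
            [{"pathway": a.name, "sign": a.sign,
              "shared_downstream": ",".join(sorted(a.shared_downstream))}
             for a in annotations])
        meta.to_csv(pathway_path, sep="\t", index=False)


def read_annotation_tsv(path, pathway_path=None):
    from .synthetic import PathwayAnnotation

    df = pd.read_csv(path, sep="\t")
    signs = {}
    if pathway_path is not None:
        meta = pd.read_csv(pathway_path, sep="\t")
        signs = dict(zip(meta["pathway"], meta["sign"]))
    out = []
    for pw, sub in df.groupby("pathway", sort=False):
        out.append(PathwayAnnotation(
            name=pw,
            ligand_genes=list(sub.loc[sub["role"] == "ligand", "gene"]),
            receptor_genes=list(sub.loc[sub["role"] == "receptor", "gene"]),
            shared_downstream=set(),
            sign=signs.get(pw, "same"),
        ))
    return out


def write_regulons_tsv(regulons, path, lines_path=None) -> None:
    rows, line_rows = [], []
    for reg, sel in regulons.selections.items():
        for rank, g in enumerate(sel.genes, start=1):
            rows.append({"regulator": reg, "gene": g,
                         "sign": "+" if sel.signs[g] > 0 else "-",
                         "rank": rank})
        line_rows.append({"regulator": reg, "intercept": sel.intercept,
                          "slope": sel.slope, "cutoff_rank": sel.cutoff_rank})
    pd.DataFrame(rows, columns=["regulator", "gene", "sign", "rank"]).to_csv(
        path, sep="\t", index=False)
    if lines_path is not None:
        pd.DataFrame(line_rows).to_csv(lines_path, sep="\t", index=False,
                                       float_format="%.12g")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
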