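"""In-memory containers shared across the pipeline.

The pipeline works on genes-by-samples matrices throughout.  ``CountMatrix``
holds raw integer read counts with per-sample stage labels; ``ExprMatrix``
holds real-valued expression in one of two layers: ``normalized``
(log counts-per-10k, entrywise >= 0) or ``centered`` (per-gene mean zero,
variance untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ValueError(f"duplicate {what} id: {dup!r}")
    return ids


@dataclass
class CountMatrix:
    """Raw gene x sample counts with stage metadata.

    Parameters
    ----------
    values
        Non-negative integer array of shape ``(n_genes, n_samples)``.
    gene_ids, sample_ids
        Unique row / column identifiers.
    stage
        Per-sample ordinal stage labels (e.g. ``"E7.5"`` ... ``"E13.5"``).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    stage: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        if self.stage and len(self.stage) != len(self.sample_ids):
            raise ValueError("stage labels must match samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Return a gene-subset copy; ``keep`` is a boolean or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return replace(
            self,
            values=self.values[keep, :].copy(),
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            stage=list(self.stage),
        )


@dataclass
class ExprMatrix:
    """Real-valued gene x sample expression in a named layer."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    layer: str = "normalized"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample ids")
        if self.layer not in ("normalized", "centered"):
            raise ValueError(f"unknown layer {self.layer!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)


def stage_to_numeric(stage: Sequence[str]) -> np.ndarray:
    """Map stage labels to numeric time.

    Labels like ``E7.5`` are parsed as embryonic days (7.5); labels that do
    not contain a number fall back to the rank of the label in sorted order.
    """
    vals = []
    ok = True
    for s in stage:
        t = s.lstrip("Ee")
        try:
            vals.append(float(t))
        except ValueError:
            ok = False
            break
    if ok:
        return np.array(vals, dtype=float)
    levels = sorted(set(stage))
    rank = {s: i + 1.0 for i, s in enumerate(levels)}
    return np.array([rank[s] for s in stage], dtype=float)
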