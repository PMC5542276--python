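"""Median discretization of expression and the survival-based binary phenotype.

Expression is binarized gene-by-gene against the per-gene median across all
samples (strictly greater -> 1).  The phenotype splits patients into early
deaths (event before the cutoff, label 1) versus long survivors (followed at
least to the cutoff, label 0); patients censored before the cutoff carry no
usable label and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix

__all__ = [
    "BinaryMatrix",
    "BinaryPhenotype",
    "discretize_expression",
    "discretize_phenotype",
    "DEFAULT_CUTOFF_DAYS",
]

DEFAULT_CUTOFF_DAYS = 1200.0


@dataclass
class BinaryMatrix:
    """0/1 expression matrix, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("bit matrix shape mismatch")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "BinaryMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return BinaryMatrix(list(self.gene_ids), list(sample_ids), self.bits[:, idx])


@dataclass
class BinaryPhenotype:
    """Binary prognosis label for the samples that survive the cutoff rule."""

    sample_ids: list[str]
    labels: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("labels length mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")


def discretize_expression(m: ExpressionMatrix) -> BinaryMatrix:
    """Binarize each gene against its median: strictly above the median -> 1.

    Ties at the median (including constant rows) get 0 — the "otherwise 0"
    branch of the rule.  The result depends only on within-gene ranks, so any
    strictly monotone per-gene transform leaves it unchanged.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to discretize")
    medians = np.median(m.values, axis=1, keepdims=True)
    bits = (m.values > medians).astype(np.int8)
    return BinaryMatrix(list(m.gene_ids), list(m.sample_ids), bits)


def discretize_phenotype(
    c: ClinicalTable, cutoff_days: float = DEFAULT_CUTOFF_DAYS
) -> BinaryPhenotype:
    """Label patients by whether death occurred before ``cutoff_days``.

    label 1 — died before the cutoff; label 0 — survival time reached the
    cutoff (dead or alive); dropped — censored alive before the cutoff, since
    the patient's status at the cutoff is unknown.  A death exactly at the
    cutoff counts as reaching it (label 0).
    """
    days = c.days
    dead = c.dead
    keep0 = days >= cutoff_days
    keep1 = dead & (days < cutoff_days)
    keep = keep0 | keep1
    labels = keep1[keep].astype(np.int8)
    sample_ids = [s for s, k in zip(c.sample_ids, keep) if k]
    return BinaryPhenotype(sample_ids, labels, n_dropped=int((~keep).sum()))
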