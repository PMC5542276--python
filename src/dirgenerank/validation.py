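"""Risk-score stratification and enrichment tests for a prognostic signature.

Each patient's risk score is the sum of the expression of the signature
genes with positive averaged Cox coefficients minus the sum over the genes
with negative coefficients.  Splitting the cohort at the median score gives
a low-risk group (score not above the median) and a high-risk group, whose
survival separation is quantified by the log-rank test and the hazard
ratio.  Overlap of the signature with a curated gene set is scored by the
upper-tail hypergeometric probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .ranking import Signature
from .survival import hazard_ratio, logrank_test

__all__ = [
    "RiskScores",
    "Stratification",
    "risk_score",
    "median_split",
    "stratify",
    "hypergeometric_test",
]

logger = logging.getLogger(__name__)


@dataclass
class RiskScores:
    sample_ids: list[str]
    scores: np.ndarray
    n_genes_used: int
    n_genes_dropped: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name="risk_score")


@dataclass
class Stratification:
    low: list[str]
    high: list[str]
    threshold: float
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci95: tuple[float, float]


def risk_score(m: ExpressionMatrix, sig: Signature, zscore: bool = False) -> RiskScores:
    """Score every sample: sum over positive-coefficient signature genes minus
    the sum over negative-coefficient genes.

    Signature genes absent from the matrix are dropped (logged); with
    ``zscore=True`` each gene is standardized across samples first, which
    helps when transferring a signature across platforms.
    """
    present = set(m.gene_ids)
    pos_genes = [g for g in sig.positive_genes() if g in present]
    neg_genes = [g for g in sig.negative_genes() if g in present]
    dropped = len(sig.genes) - len(pos_genes) - len(neg_genes)
    if not pos_genes and not neg_genes:
        raise ValueError("no signature gene present in the expression matrix")
    if dropped:
        logger.info("risk_score: %d signature genes absent from the matrix", dropped)
    row = {g: i for i, g in enumerate(m.gene_ids)}
    values = m.values
    if zscore:
        sd = values.std(axis=1, keepdims=True)
        values = (values - values.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    scores = np.zeros(m.n_samples)
    if pos_genes:
        scores += values[[row[g] for g in pos_genes]].sum(axis=0)
    if neg_genes:
        scores -= values[[row[g] for g in neg_genes]].sum(axis=0)
    return RiskScores(list(m.sample_ids), scores, len(pos_genes) + len(neg_genes), dropped)


def median_split(rs: RiskScores) -> tuple[list[str], list[str], float]:
    """Split samples at the median score: score <= median -> low risk.

    Returns ``(low_ids, high_ids, threshold)``.  If every score equals the
    median the high group is empty; downstream tests reject that cleanly.
    """
    if len(rs.sample_ids) < 2:
        raise ValueError("need at least 2 samples to split")
    thr = float(np.median(rs.scores))
    low = [s for s, v in zip(rs.sample_ids, rs.scores) if v <= thr]
    high = [s for s, v in zip(rs.sample_ids, rs.scores) if v > thr]
    return low, high, thr


def stratify(m: ExpressionMatrix, sig: Signature, surv, zscore: bool = False) -> Stratification:
    """Score, median-split, and compare the two groups' survival."""
    rs = risk_score(m, sig, zscore=zscore)
    low, high, thr = median_split(rs)
    chi2, p = logrank_test((low, high), surv)
    hr, ci = hazard_ratio((low, high), surv)
    return Stratification(low, high, thr, chi2, p, hr, ci)


def hypergeometric_test(x: int, K: int, N_draw: int, M: int) -> float:
    """Upper-tail hypergeometric overlap probability P(X >= x).

    ``x`` observed overlap, ``K`` signature size, ``N_draw`` size of the
    curated gene set (the draw), ``M`` universe size:
    p = 1 - sum_{i<x} C(K,i) C(M-K, N-i) / C(M, N), evaluated stably.
    """
    if not (0 <= K <= M and 0 <= N_draw <= M):
        raise ValueError("need 0 <= K, N_draw <= M")
    if not 0 <= x <= min(K, N_draw):
        raise ValueError("need 0 <= x <= min(K, N_draw)")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, M, K, N_draw))
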