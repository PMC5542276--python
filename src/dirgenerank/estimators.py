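"""scikit-learn style estimators wrapping the pipeline stages.

`DirGenerankPipeline` is the end-to-end model: ``fit(X, y)`` on an
(samples x genes) expression frame and a survival outcome learns the
dependency network, the resample stabilities, the gene ranking and the
signature, plus the training median risk threshold; ``decision_function``
scores new cohorts and ``predict`` assigns high-risk labels.  The stage
estimators (`DependencyNetworkInference`, `CoxStabilitySelector`,
`DirGenerankRanker`) expose the same computations separately.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .discretize import (
    DEFAULT_CUTOFF_DAYS,
    BinaryPhenotype,
    discretize_expression,
    discretize_phenotype,
)
from .io import ClinicalTable, ExpressionMatrix, PPIEdgeList
from .network import DependencyNetwork, build_network
from .ranking import RankResult, Signature, dirgenerank, select_signature
from .survival import GeneStability, as_survival, resample_stability
from .validation import Stratification, median_split, risk_score, stratify

__all__ = [
    "CoxStabilitySelector",
    "DependencyNetworkInference",
    "DirGenerankRanker",
    "DirGenerankPipeline",
]


def _as_expression(X) -> ExpressionMatrix:
    """Samples x genes input -> genes x samples ExpressionMatrix."""
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        return ExpressionMatrix(
            [str(c) for c in X.columns],
            [str(i) for i in X.index],
            X.to_numpy(dtype=float).T,
        )
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D (samples x genes)")
    genes = [f"g{j}" for j in range(arr.shape[1])]
    samples = [f"s{i}" for i in range(arr.shape[0])]
    return ExpressionMatrix(genes, samples, arr.T)


def _as_clinical(y, sample_ids) -> ClinicalTable:
    if isinstance(y, ClinicalTable):
        return y
    time, event = as_survival(y)
    return ClinicalTable(list(sample_ids), time, event)


def _seed(random_state) -> int:
    if random_state is None:
        return 0
    if isinstance(random_state, numbers.Integral):
        return int(random_state)
    raise ValueError("random_state must be an int or None")


class CoxStabilitySelector(BaseEstimator):
    """Per-gene resample stability of the univariate Cox association.

    Parameters
    ----------
    n_resamples : number of random subsamples (R).
    subsample : fraction of samples drawn without replacement per replicate.
    alpha : per-fit significance level; stability counts fits with p < alpha.
    random_state : seed for the subsample draws.
    """

    def __init__(self, n_resamples=400, subsample=0.9, alpha=0.05, random_state=None):
        self.n_resamples = n_resamples
        self.subsample = subsample
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        expr = _as_expression(X)
        clin = _as_clinical(y, expr.sample_ids)
        self.results_ = resample_stability(
            expr,
            clin,
            n_resamples=self.n_resamples,
            frac=self.subsample,
            alpha=self.alpha,
            rng_seed=_seed(self.random_state),
        )
        self.feature_names_in_ = np.asarray(expr.gene_ids, dtype=object)
        self.n_features_in_ = expr.n_genes
        self.stability_ = np.array([r.stability for r in self.results_])
        self.mean_coef_ = np.array([r.mean_coef for r in self.results_])
        return self


class DependencyNetworkInference(BaseEstimator):
    """Directed dependency network from permutation-tested CMI on PPI pairs.

    ``y`` may be a 0/1 phenotype vector or a survival outcome, in which case
    the early-death / long-survivor discretization at
    ``phenotype_cutoff_days`` is applied first (censored-early samples drop
    out of the network stage).
    """

    def __init__(
        self,
        ppi: PPIEdgeList | None = None,
        n_permutations=1000,
        alpha=0.05,
        sided="two-sided",
        phenotype_cutoff_days=DEFAULT_CUTOFF_DAYS,
        random_state=None,
    ):
        self.ppi = ppi
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.sided = sided
        self.phenotype_cutoff_days = phenotype_cutoff_days
        self.random_state = random_state

    def _phenotype(self, y, sample_ids) -> BinaryPhenotype:
        if isinstance(y, BinaryPhenotype):
            return y
        arr = np.asarray(y) if not isinstance(y, (ClinicalTable, pd.DataFrame)) else None
        if arr is not None and arr.ndim == 1 and np.isin(arr, (0, 1)).all():
            return BinaryPhenotype(list(sample_ids), arr.astype(np.int8))
        return discretize_phenotype(_as_clinical(y, sample_ids), self.phenotype_cutoff_days)

    def fit(self, X, y):
        if self.ppi is None:
            raise ValueError("a PPIEdgeList is required (ppi parameter)")
        expr = _as_expression(X)
        bm = discretize_expression(expr)
        ph = self._phenotype(y, expr.sample_ids)
        self.network_ = build_network(
            bm,
            ph,
            self.ppi,
            n_perm=self.n_permutations,
            alpha=self.alpha,
            rng_seed=_seed(self.random_state),
            sided=self.sided,
        )
        self.edges_ = self.network_.to_frame()
        self.n_features_in_ = expr.n_genes
        return self

    def fit_binary(self, bm, ph):
        """Variant taking an already-discretized matrix and phenotype."""
        if self.ppi is None:
            raise ValueError("a PPIEdgeList is required (ppi parameter)")
        self.network_ = build_network(
            bm,
            ph,
            self.ppi,
            n_perm=self.n_permutations,
            alpha=self.alpha,
            rng_seed=_seed(self.random_state),
            sided=self.sided,
        )
        self.edges_ = self.network_.to_frame()
        return self


class DirGenerankRanker(BaseEstimator):
    """Damped fixed-point ranking of network genes from initial importances.

    ``fit`` takes the dependency network and the per-gene importance (a
    GeneStability list or ``{gene: value}`` mapping) rather than an (X, y)
    pair — the inputs are the outputs of the two upstream stages.
    """

    def __init__(self, damping=0.7, tol=1e-5, max_iter=10000, degree_mode="row",
                 top_fraction=0.01):
        self.damping = damping
        self.tol = tol
        self.max_iter = max_iter
        self.degree_mode = degree_mode
        self.top_fraction = top_fraction

    def fit(self, network: DependencyNetwork, importance):
        self.rank_ = dirgenerank(
            network,
            importance,
            d=self.damping,
            eps=self.tol,
            max_iter=self.max_iter,
            degree_mode=self.degree_mode,
        )
        coefs = (
            importance
            if isinstance(importance, dict)
            else {s.gene_id: s.mean_coef for s in importance}
        )
        if not isinstance(importance, dict):
            self.signature_ = select_signature(self.rank_, importance, self.top_fraction)
        else:
            self.signature_ = select_signature(self.rank_, coefs, self.top_fraction)
        return self


class DirGenerankPipeline(BaseEstimator):
    """End-to-end prognostic-signature model.

    fit(X, y):
      1. binarize expression (median split) and the phenotype (cutoff rule);
      2. infer the directed dependency network over the PPI scaffold;
      3. score resample stabilities (initial importances) on the full cohort;
      4. run the damped fixed-point ranking and take the top fraction as the
         signature;
      5. record the training cohort's median risk score as the threshold.

    decision_function(X) returns risk scores; predict(X) returns 1 for
    samples above the fitted threshold (high risk).
    """

    def __init__(
        self,
        ppi: PPIEdgeList | None = None,
        phenotype_cutoff_days=DEFAULT_CUTOFF_DAYS,
        n_permutations=1000,
        edge_alpha=0.05,
        sided="two-sided",
        n_resamples=400,
        subsample=0.9,
        cox_alpha=0.05,
        damping=0.7,
        tol=1e-5,
        max_iter=10000,
        degree_mode="row",
        top_fraction=0.01,
        zscore=False,
        random_state=None,
    ):
        self.ppi = ppi
        self.phenotype_cutoff_days = phenotype_cutoff_days
        self.n_permutations = n_permutations
        self.edge_alpha = edge_alpha
        self.sided = sided
        self.n_resamples = n_resamples
        self.subsample = subsample
        self.cox_alpha = cox_alpha
        self.damping = damping
        self.tol = tol
        self.max_iter = max_iter
        self.degree_mode = degree_mode
        self.top_fraction = top_fraction
        self.zscore = zscore
        self.random_state = random_state

    def fit(self, X, y):
        expr = _as_expression(X)
        clin = _as_clinical(y, expr.sample_ids)
        seed = _seed(self.random_state)

        net_est = DependencyNetworkInference(
            ppi=self.ppi,
            n_permutations=self.n_permutations,
            alpha=self.edge_alpha,
            sided=self.sided,
            phenotype_cutoff_days=self.phenotype_cutoff_days,
            random_state=seed,
        ).fit(expr, clin)
        self.network_ = net_est.network_

        stab_est = CoxStabilitySelector(
            n_resamples=self.n_resamples,
            subsample=self.subsample,
            alpha=self.cox_alpha,
            random_state=seed + 1,
        ).fit(expr, clin)
        self.stability_ = stab_est.results_

        ranker = DirGenerankRanker(
            damping=self.damping,
            tol=self.tol,
            max_iter=self.max_iter,
            degree_mode=self.degree_mode,
            top_fraction=self.top_fraction,
        ).fit(self.network_, self.stability_)
        self.rank_ = ranker.rank_
        self.signature_ = ranker.signature_

        scores = risk_score(expr, self.signature_, zscore=self.zscore)
        _, _, self.threshold_ = median_split(scores)
        self.n_features_in_ = expr.n_genes
        self.feature_names_in_ = np.asarray(expr.gene_ids, dtype=object)
        return self

    def decision_function(self, X) -> np.ndarray:
        expr = _as_expression(X)
        return risk_score(expr, self.signature_, zscore=self.zscore).scores

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > self.threshold_).astype(int)

    def stratify(self, X, y) -> Stratification:
        """Median-split a cohort by its own risk scores and test separation."""
        expr = _as_expression(X)
        clin = _as_clinical(y, expr.sample_ids)
        return stratify(expr, self.signature_, clin, zscore=self.zscore)
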