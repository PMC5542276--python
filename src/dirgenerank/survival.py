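"""Proportional-hazards utilities: a vectorized univariate Cox solver, the
resampling stability score, and two-group survival comparisons.

The stability score asks how reproducibly a gene's expression predicts
overall survival: across R random 90% subsamples of the cohort, count the
replicates in which the gene's univariate Cox p-value clears 0.05.  That
count (0..R) is the gene's initial importance for the network ranking, and
the per-replicate coefficients are averaged into the sign used by the risk
score.

The solver fits all genes of one subsample simultaneously by Newton
iteration on the Efron partial likelihood; `lifelines` serves as the
reference implementation for single fits (two-group hazard ratios, and the
cross-checks in the test suite) and provides the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io import ClinicalTable, ExpressionMatrix

__all__ = [
    "CoxResult",
    "GeneStability",
    "cox_univariate_batch",
    "univariate_cox",
    "resample_stability",
    "logrank_test",
    "hazard_ratio",
    "as_survival",
]


@dataclass(frozen=True)
class CoxResult:
    coef: float
    p_value: float
    ok: bool  # False: degenerate fit (constant covariate, no events, divergence)


@dataclass(frozen=True)
class GeneStability:
    """Resample stability of a gene's prognostic association."""

    gene_id: str
    stability: int  # replicates with Cox p < alpha, 0..n_resamples
    mean_coef: float  # coefficient averaged over all successful fits
    n_resamples: int


def as_survival(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a survival outcome to ``(time, event)`` float/bool arrays.

    Accepts a :class:`ClinicalTable`, a structured array with a boolean event
    field and a numeric time field (the scikit-survival convention), a
    DataFrame with time/event-like columns, or a plain (n, 2) array ordered
    ``[time, event]``.
    """
    if isinstance(y, ClinicalTable):
        return y.days.astype(float), y.dead.astype(bool)
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        ev = [n for n in names if y.dtype[n].kind == "b"]
        tm = [n for n in names if y.dtype[n].kind in "fiu"]
        if len(ev) != 1 or len(tm) != 1:
            raise ValueError("structured survival array needs one bool and one numeric field")
        return y[tm[0]].astype(float), y[ev[0]].astype(bool)
    if isinstance(y, pd.DataFrame):
        cols = {c.lower(): c for c in y.columns}
        tm = next((cols[k] for k in ("time", "days", "days_to_death") if k in cols), None)
        ev = next((cols[k] for k in ("event", "dead", "death_status") if k in cols), None)
        if tm is None or ev is None:
            raise ValueError("survival DataFrame needs time and event columns")
        return y[tm].to_numpy(float), y[ev].to_numpy().astype(bool)
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected an (n, 2) [time, event] array")
    return arr[:, 0], arr[:, 1].astype(bool)


def cox_univariate_batch(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit an independent single-covariate Cox model to every column of ``X``.

    Newton-Raphson on the Efron-approximation partial likelihood, vectorized
    over covariates.  Returns ``(coef, se, p, ok)``; columns flagged
    ``ok=False`` (constant covariate, no events, or a diverging fit) carry
    ``coef=0, p=1``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x covariates)")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n, g = X.shape
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("time/event length mismatch")

    coef = np.zeros(g)
    se = np.full(g, np.nan)
    pval = np.ones(g)
    ok = np.ones(g, dtype=bool)

    if event.sum() < 2:
        return coef, se, pval, np.zeros(g, dtype=bool)

    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    Xs = X[order]

    sd = Xs.std(axis=0)
    ok &= sd > 0
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (Xs - Xs.mean(axis=0)) / sd_safe  # standardized; beta rescaled at the end

    # tie-group bookkeeping on the sorted times
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    group_of = np.cumsum(np.r_[True, t[1:] != t[:-1]]) - 1
    n_groups = starts.size
    d_per_group = np.bincount(group_of[e], minlength=n_groups)  # deaths per group
    death_idx = np.flatnonzero(e)
    dg = group_of[death_idx]  # group of each death
    # Efron fraction l/d for each death within its tie group
    first_death_in_group = np.r_[0, np.cumsum(d_per_group)][dg]
    l_rank = np.arange(death_idx.size) - first_death_in_group
    frac = l_rank / d_per_group[dg]

    Zd = Z[death_idx]  # covariate values at the deaths
    beta = np.zeros(g)
    alive = ok.copy()
    for _ in range(max_iter):
        lin = Z * beta
        np.clip(lin, -500, 500, out=lin)
        W = np.exp(lin)
        ZW = Z * W
        Z2W = Z * ZW
        # per-group sums, then reversed cumsum = risk-set sums at each group
        G0 = np.add.reduceat(W, starts, axis=0)
        G1 = np.add.reduceat(ZW, starts, axis=0)
        G2 = np.add.reduceat(Z2W, starts, axis=0)
        R0 = np.cumsum(G0[::-1], axis=0)[::-1]
        R1 = np.cumsum(G1[::-1], axis=0)[::-1]
        R2 = np.cumsum(G2[::-1], axis=0)[::-1]
        # tied-death sums per group
        dmask = np.zeros((n, 1))
        dmask[death_idx] = 1.0
        T0 = np.add.reduceat(W * dmask, starts, axis=0)
        T1 = np.add.reduceat(ZW * dmask, starts, axis=0)
        T2 = np.add.reduceat(Z2W * dmask, starts, axis=0)

        f = frac[:, None]
        den = R0[dg] - f * T0[dg]
        num1 = R1[dg] - f * T1[dg]
        num2 = R2[dg] - f * T2[dg]
        mu = num1 / den
        U = (Zd - mu).sum(axis=0)
        info = (num2 / den - mu**2).sum(axis=0)

        bad = ~np.isfinite(U) | ~np.isfinite(info) | (info <= 0)
        alive &= ~bad
        step = np.where(alive, U / np.where(info > 0, info, 1.0), 0.0)
        np.clip(step, -5, 5, out=step)
        beta = beta + np.where(alive, step, 0.0)
        if np.max(np.abs(step), initial=0.0) < tol:
            break

    alive &= np.isfinite(beta)
    info = np.where(info > 0, info, np.nan)
    with np.errstate(invalid="ignore"):
        chi2 = beta**2 * info
    pv = stats.chi2.sf(chi2, df=1)
    coef = np.where(alive, beta / sd_safe, 0.0)
    se = np.where(alive, 1.0 / np.sqrt(info) / sd_safe, np.nan)
    pval = np.where(alive & np.isfinite(pv), pv, 1.0)
    return coef, se, pval, alive


def univariate_cox(expr_row, surv) -> CoxResult:
    """Single-gene proportional-hazards fit; returns coefficient and Wald p.

    Degenerate inputs (constant expression, fewer than 2 events) yield a
    flagged non-fit with ``coef=0, p=1``.
    """
    time, event = as_survival(surv)
    x = np.asarray(expr_row, dtype=float).reshape(-1, 1)
    coef, _, p, ok = cox_univariate_batch(x, time, event)
    return CoxResult(float(coef[0]), float(p[0]), bool(ok[0]))


def resample_stability(
    m: ExpressionMatrix,
    surv,
    n_resamples: int = 400,
    frac: float = 0.9,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> list[GeneStability]:
    """Count, per gene, the subsample replicates with Cox p < ``alpha``.

    Each of the ``n_resamples`` replicates draws floor(frac * n) samples
    without replacement (one subsample shared by all genes) and fits every
    gene's univariate Cox model on it.  The significance count is strict
    (p < alpha); the coefficient is averaged over all successful fits,
    significant or not.
    """
    if n_resamples <= 0:
        raise ValueError("n_resamples must be positive")
    time, event = as_survival(surv)
    if isinstance(surv, ClinicalTable):
        pos = {s: i for i, s in enumerate(surv.sample_ids)}
        idx = np.array([pos[s] for s in m.sample_ids])
        time, event = time[idx], event[idx]
    n = m.n_samples
    k = int(np.floor(frac * n))
    if k < 10:
        raise ValueError("subsample smaller than 10 samples")
    rng = np.random.default_rng(rng_seed)
    X = m.values.T  # samples x genes
    hits = np.zeros(m.n_genes, dtype=int)
    coef_sum = np.zeros(m.n_genes)
    coef_n = np.zeros(m.n_genes, dtype=int)
    for _ in range(n_resamples):
        take = rng.choice(n, size=k, replace=False)
        coef, _, p, ok = cox_univariate_batch(X[take], time[take], event[take])
        hits += ok & (p < alpha)
        coef_sum += np.where(ok, coef, 0.0)
        coef_n += ok
    mean_coef = np.divide(coef_sum, coef_n, out=np.zeros_like(coef_sum), where=coef_n > 0)
    return [
        GeneStability(g, int(hits[i]), float(mean_coef[i]), n_resamples)
        for i, g in enumerate(m.gene_ids)
    ]


def _split_survival(groups, surv):
    time, event = as_survival(surv)
    if isinstance(surv, ClinicalTable):
        pos = {s: i for i, s in enumerate(surv.sample_ids)}
        low, high = groups
        il = np.array([pos[s] for s in low], dtype=int)
        ih = np.array([pos[s] for s in high], dtype=int)
    else:
        low, high = groups  # index arrays
        il = np.asarray(low, dtype=int)
        ih = np.asarray(high, dtype=int)
    if il.size == 0 or ih.size == 0:
        raise ValueError("both groups must be non-empty")
    return time, event, il, ih


def logrank_test(groups, surv) -> tuple[float, float]:
    """Two-group log-rank test; returns ``(chi2, p)``.

    ``groups`` is a (low, high) pair of sample-ID lists (with a
    :class:`ClinicalTable`) or of index arrays.
    """
    time, event, il, ih = _split_survival(groups, surv)
    if event[il].sum() + event[ih].sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(time[il], time[ih], event_observed_A=event[il], event_observed_B=event[ih])
    return float(res.test_statistic), float(res.p_value)


def hazard_ratio(groups, surv) -> tuple[float, tuple[float, float]]:
    """Hazard ratio of the high group vs the low group with a Wald 95% CI."""
    time, event, il, ih = _split_survival(groups, surv)
    df = pd.DataFrame(
        {
            "time": np.r_[time[il], time[ih]],
            "event": np.r_[event[il], event[ih]].astype(int),
            "high": np.r_[np.zeros(il.size), np.ones(ih.size)],
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))
    lo, hi = cph.confidence_intervals_.loc["high"]
    return hr, (float(np.exp(lo)), float(np.exp(hi)))
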