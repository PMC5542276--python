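"""Plug-in mutual information on binary data and the permutation edge test.

The dependency of a gene A on a putative modulator B, given the binary
phenotype P, is measured as CMI(A, P | B): how much information A carries
about P once samples are stratified by B's (discretized) expression.
Significance comes from an empirical null built by permuting B across
samples, which preserves the A-P relationship while destroying any
B-conditioning.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

__all__ = [
    "mutual_information",
    "conditional_mutual_information",
    "permutation_pvalue",
]

Sidedness = Literal["two-sided", "greater", "less"]

# float-equality slack when counting permutation ties
_TIE_TOL = 1e-12


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    out = arr.astype(np.int64)
    if not np.isin(out, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return out


def _cmi_from_counts(counts: np.ndarray) -> np.ndarray:
    """CMI(A,P|B) in bits from joint cell counts.

    ``counts`` has shape (..., 8); cell index is ``4*b + 2*a + p``.  Empty
    strata and empty cells contribute zero (the 0*log(0) convention).
    """
    c = counts.reshape(counts.shape[:-1] + (2, 2, 2)).astype(float)  # (..., b, a, p)
    n = c.sum(axis=(-3, -2, -1), keepdims=True)
    n_b = c.sum(axis=(-2, -1), keepdims=True)  # per-stratum totals
    c_ba = c.sum(axis=-1, keepdims=True)  # marginal over p within stratum
    c_bp = c.sum(axis=-2, keepdims=True)  # marginal over a within stratum
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log2(c * n_b) - np.log2(c_ba * c_bp)
    safe_log = np.where(c > 0, log_term, 0.0)  # empty cells contribute 0
    out = (c / n * safe_log).sum(axis=(-3, -2, -1))
    # clip tiny negative rounding residue: CMI is nonnegative
    return np.maximum(out, 0.0)


def _joint_counts(a: np.ndarray, p: np.ndarray, b: np.ndarray) -> np.ndarray:
    code = 4 * b + 2 * a + p
    return np.bincount(code, minlength=8)


def mutual_information(a, p) -> float:
    """Plug-in mutual information (bits) between two 0/1 vectors.

    Sum over the 2x2 contingency table of f(a,p) * log2[f(a,p)/(f(a)f(p))],
    with empty cells contributing zero.
    """
    a = _as_binary(a, "a")
    p = _as_binary(p, "p")
    if a.shape != p.shape:
        raise ValueError("length mismatch")
    if a.size == 0:
        raise ValueError("empty vectors")
    b = np.zeros_like(a)  # single stratum: CMI collapses to MI
    return float(_cmi_from_counts(_joint_counts(a, p, b)))


def conditional_mutual_information(a, p, b) -> float:
    """CMI(A,P|B) in bits: stratum-weighted mutual information of a and p given b."""
    a = _as_binary(a, "a")
    p = _as_binary(p, "p")
    b = _as_binary(b, "b")
    if not (a.shape == p.shape == b.shape):
        raise ValueError("length mismatch")
    if a.size == 0:
        raise ValueError("empty vectors")
    return float(_cmi_from_counts(_joint_counts(a, p, b)))


def _null_cmi(a, p, b, n_perm, rng) -> np.ndarray:
    """CMI values for ``n_perm`` random permutations of ``b`` (vectorized)."""
    perms = rng.permuted(np.broadcast_to(b, (n_perm, b.size)), axis=1)
    code = (2 * a + p)[None, :] + 4 * perms
    flat = code + 8 * np.arange(n_perm)[:, None]
    counts = np.bincount(flat.ravel(), minlength=8 * n_perm).reshape(n_perm, 8)
    return _cmi_from_counts(counts)


def permutation_pvalue(
    a,
    p,
    b,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    sided: Sidedness = "two-sided",
) -> tuple[float, float]:
    """Permutation test of CMI(A,P|B) against the permuted-B null.

    Returns ``(cmi_obs, p_value)``.  The empirical p uses add-one smoothing,
    p = (1 + #{null at least as extreme}) / (n_perm + 1), so p is never 0; the
    two-sided default doubles the smaller tail (both unusually high CMI,
    synergy, and unusually low CMI, redundancy, indicate dependency).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = _as_binary(a, "a")
    p = _as_binary(p, "p")
    b = _as_binary(b, "b")
    if not (a.shape == p.shape == b.shape):
        raise ValueError("length mismatch")
    rng = np.random.default_rng(rng)
    obs = float(_cmi_from_counts(_joint_counts(a, p, b)))
    null = _null_cmi(a, p, b, n_perm, rng)
    upper = (1 + int((null >= obs - _TIE_TOL).sum())) / (n_perm + 1)
    lower = (1 + int((null <= obs + _TIE_TOL).sum())) / (n_perm + 1)
    if sided == "greater":
        p_val = upper
    elif sided == "less":
        p_val = lower
    elif sided == "two-sided":
        p_val = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return obs, p_val
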