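"""Kendall tau-b correlation with a permutation-calibrated null.

Short, tie-heavy abundance series (eight time points, many exact zeros)
make analytic tau null distributions unreliable, so significance is
calibrated empirically: the whole dataset is permuted (every taxon's
values shuffled independently across time points) many times, all
pairwise taus from the permuted datasets are pooled into one null
vector, and each observed |tau| is assigned the (add-one smoothed)
null tail probability.  Benjamini-Hochberg controls the FDR across all
pairs, and the smallest |tau| still significant defines the critical
tau.

Tau-b is computed through sign-of-difference vectors: for a series x of
length n, let S(x) be the n(n-1)/2 vector of sign(x_b - x_a) over pairs
a < b.  Then

    tau_b(x, y) = <S(x), S(y)> / sqrt(<S(x), S(x)> <S(y), S(y)>)

which is exactly the tie-corrected (C - D) / sqrt((n0 - n1)(n0 - n2))
form, and turns an all-pairs tau matrix into one matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationResult",
    "kendall_tau_b",
    "tau_matrix",
    "permutation_null",
    "tau_pvalues",
    "benjamini_hochberg",
    "bonferroni",
    "adjust_and_threshold",
    "analyze",
]


def _sign_vectors(X: np.ndarray) -> np.ndarray:
    """Rows -> sign(x_b - x_a) over all pairs a < b (shape m x n(n-1)/2)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[-1]
    a, b = np.triu_indices(n, k=1)
    return np.sign(X[..., b] - X[..., a])


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall tau-b; NaN when either series is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need series of length >= 2")
    sx = _sign_vectors(x)
    sy = _sign_vectors(y)
    nx = float(sx @ sx)
    ny = float(sy @ sy)
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float((sx @ sy) / np.sqrt(nx * ny))


def _tau_from_signs(S: np.ndarray) -> np.ndarray:
    """All-pairs tau-b from a stack of sign vectors; constant rows -> NaN."""
    norms = (S * S).sum(axis=1)
    G = S @ S.T
    denom = np.sqrt(np.outer(norms, norms))
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(tau, 1.0)
    return tau


def tau_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Symmetric taxa x taxa tau-b matrix (diagonal 1).

    Pairs involving a constant series are NaN (undefined) and are
    excluded from testing and from the network downstream.
    """
    tau = _tau_from_signs(_sign_vectors(values.to_numpy()))
    return pd.DataFrame(tau, index=values.index, columns=values.index)


def permutation_null(values: pd.DataFrame, n_perm: int = 100,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Pooled pairwise taus from ``n_perm`` row-wise permuted datasets.

    Each null dataset permutes every taxon's values independently across
    time points, destroying cross-taxon association while preserving
    each marginal.  NaN taus (constant rows) are excluded from the pool.
    """
    if values.shape[0] < 2:
        raise ValueError("need at least two taxa for a pairwise null")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    X = values.to_numpy()
    iu = np.triu_indices(X.shape[0], k=1)
    pooled = []
    for _ in range(n_perm):
        shuffled = rng.permuted(X, axis=1)
        tau = _tau_from_signs(_sign_vectors(shuffled))[iu]
        pooled.append(tau[np.isfinite(tau)])
    return np.concatenate(pooled) if pooled else np.empty(0)


def tau_pvalues(tau: pd.DataFrame, null_taus: np.ndarray) -> pd.DataFrame:
    """Two-sided permutation p-values on |tau| with add-one smoothing.

    ``p = (1 + #{|null| >= |tau_obs|}) / (1 + N_null)``; NaN taus give
    NaN p.
    """
    if null_taus.size == 0:
        raise ValueError("empty null vector")
    null_abs = np.sort(np.abs(null_taus))
    obs = np.abs(tau.to_numpy())
    flat = obs.ravel()
    counts = np.full(flat.shape, np.nan)
    finite = np.isfinite(flat)
    # count of null >= obs via position in the ascending sorted null
    idx = np.searchsorted(null_abs, flat[finite] - 1e-12, side="left")
    counts[finite] = null_abs.size - idx
    p = (1.0 + counts) / (1.0 + null_abs.size)
    return pd.DataFrame(p.reshape(obs.shape), index=tau.index, columns=tau.columns)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Standard BH step-up adjustment of a flat p-value vector."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def bonferroni(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.minimum(p * p.size, 1.0)


def adjust_and_threshold(
    p: pd.DataFrame, tau: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """BH-adjust all testable pairs and derive the critical tau.

    Returns (BH-adjusted matrix, Bonferroni matrix, critical tau); the
    critical tau is the smallest |tau| with adjusted p <= alpha, or
    +inf when nothing is significant.
    """
    iu = np.triu_indices(len(p), k=1)
    flat_p = p.to_numpy()[iu]
    flat_tau = np.abs(tau.to_numpy())[iu]
    testable = np.isfinite(flat_p)

    adj = np.full(flat_p.shape, np.nan)
    bon = np.full(flat_p.shape, np.nan)
    adj[testable] = benjamini_hochberg(flat_p[testable])
    bon[testable] = bonferroni(flat_p[testable])

    significant = testable & (adj <= alpha)
    critical_tau = float(flat_tau[significant].min()) if significant.any() \
        else float("inf")

    def _to_matrix(flat: np.ndarray) -> pd.DataFrame:
        mat = np.full(p.shape, np.nan)
        mat[iu] = flat
        mat[(iu[1], iu[0])] = flat
        np.fill_diagonal(mat, 0.0)
        return pd.DataFrame(mat, index=p.index, columns=p.columns)

    return _to_matrix(adj), _to_matrix(bon), critical_tau


@dataclass
class CorrelationResult:
    """All pairwise-correlation evidence for one index table."""

    tau: pd.DataFrame
    null_taus: np.ndarray
    p: pd.DataFrame
    p_adjusted: pd.DataFrame       # Benjamini-Hochberg
    p_bonferroni: pd.DataFrame
    critical_tau: float
    alpha: float
    n_permutations: int
    seed: int
    undefined_taxa: list[str]

    def pair_table(self) -> pd.DataFrame:
        """Long-format (taxon_a, taxon_b, tau, p, p_adj, significant)."""
        iu = np.triu_indices(len(self.tau), k=1)
        ids = self.tau.index.to_numpy()
        adj = self.p_adjusted.to_numpy()[iu]
        return pd.DataFrame({
            "taxon_a": ids[iu[0]],
            "taxon_b": ids[iu[1]],
            "tau": self.tau.to_numpy()[iu],
            "p": self.p.to_numpy()[iu],
            "p_adj": adj,
            "p_bonferroni": self.p_bonferroni.to_numpy()[iu],
            "significant": adj <= self.alpha,
        })


def analyze(values: pd.DataFrame, n_perm: int = 100, alpha: float = 0.05,
            seed: int = 0) -> CorrelationResult:
    """Full calibration: tau matrix, permutation null, p-values, FDR."""
    tau = tau_matrix(values)
    constant = [t for t, v in zip(values.index, _sign_vectors(values.to_numpy()))
                if not (v * v).sum()]
    null = permutation_null(values, n_perm=n_perm, seed=seed)
    p = tau_pvalues(tau, null)
    # undefined pairs are excluded from testing
    mask = values.index.isin(constant)
    p.loc[mask, :] = np.nan
    p.loc[:, mask] = np.nan
    adjusted, bonf, critical = adjust_and_threshold(p, tau, alpha=alpha)
    return CorrelationResult(tau, null, p, adjusted, bonf, critical,
                             alpha=alpha, n_permutations=n_perm, seed=seed,
                             undefined_taxa=constant)
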