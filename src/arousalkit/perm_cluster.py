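"""Permutation-based temporal clustering inference and small-test utilities.

Window-wise tests yield a p-value sequence; maximal runs of consecutive
windows with p < alpha form the observed clusters. A caller-supplied
exchangeability scheme regenerates the analysis on permuted data; the
longest significant run per permutation forms the null distribution, and
the cluster p is the fraction of null maxima at or above the observed
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterResult",
    "find_significant_runs",
    "max_run_length",
    "cluster_permutation_p",
    "cross_correlation",
    "mann_whitney_u",
    "mann_whitney_z",
    "benjamini_hochberg",
    "cohens_kappa",
    "write_cluster_result_csv",
]


@dataclass
class ClusterResult:
    """Observed runs plus the permutation null of maximum run length."""

    runs: List[Tuple[int, int]]
    max_run_len: int
    null_max_runs: np.ndarray
    cluster_p: float
    alpha: float = 0.05
    stat_per_window: Optional[np.ndarray] = None
    p_per_window: Optional[np.ndarray] = None
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)


def find_significant_runs(
    p_values: Sequence[float], alpha: float = 0.05
) -> List[Tuple[int, int]]:
    """Maximal disjoint runs (start, length) of consecutive windows with p < alpha.

    Ties at exactly ``alpha`` are non-significant (strict inequality).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    finite = p[np.isfinite(p)]
    if np.any((finite < 0) | (finite > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sig = np.concatenate([[False], p < alpha, [False]])
    d = np.diff(sig.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def max_run_length(p_values: Sequence[float], alpha: float = 0.05) -> int:
    runs = find_significant_runs(p_values, alpha)
    return max((ln for _, ln in runs), default=0)


def cluster_permutation_p(
    observed_max_run: int,
    permute_fn: Callable[[np.random.Generator], int],
    n_perm: int = 1000,
    seed: int = 0,
    add_one: bool = False,
    runs: Optional[List[Tuple[int, int]]] = None,
    alpha: float = 0.05,
    stat_per_window: Optional[np.ndarray] = None,
    p_per_window: Optional[np.ndarray] = None,
) -> ClusterResult:
    """Bootstrap p for the longest significant run against a permutation null.

    ``permute_fn(rng)`` must rerun the window-wise analysis on one
    permuted dataset and return its maximum significant-run length.
    The default p convention is count/n_perm (10 of 1000 at or above the
    observed value gives p = .01); ``add_one`` switches to the
    (count+1)/(n_perm+1) convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.fromiter(
        (int(permute_fn(rng)) for _ in range(n_perm)), dtype=int, count=n_perm
    )
    count = int(np.sum(null >= observed_max_run))
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return ClusterResult(
        runs=list(runs) if runs is not None else [],
        max_run_len=int(observed_max_run),
        null_max_runs=null,
        cluster_p=float(p),
        alpha=alpha,
        stat_per_window=stat_per_window,
        p_per_window=p_per_window,
        seed=seed,
    )


def cross_correlation(
    x: Sequence[float],
    y: Sequence[float],
    max_lag_bins: int,
    min_overlap: int = 3,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pearson correlation of ``x[t]`` with ``y[t + lag]`` for each lag.

    Positive lag means y lags x. NaNs mark invalid samples; lags with
    fewer than ``min_overlap`` valid pairs, or a zero-variance segment,
    are flagged invalid. Returns ``(lags, r, valid)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        raise ValueError("zero-variance input series")
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    r = np.full(lags.size, np.nan)
    valid = np.zeros(lags.size, dtype=bool)
    n = x.size
    for i, lag in enumerate(lags):
        if lag >= 0:
            a, b = x[: n - lag], y[lag:]
        else:
            a, b = x[-lag:], y[: n + lag]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < min_overlap:
            continue
        aa, bb = a[ok], b[ok]
        if np.std(aa) == 0 or np.std(bb) == 0:
            continue
        r[i] = float(np.corrcoef(aa, bb)[0, 1])
        valid[i] = True
    return lags, r, valid


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
) -> Tuple[float, float]:
    """Mann-Whitney U of ``group_a`` vs ``group_b``.

    Exact p for small untied samples, normal approximation with tie
    correction otherwise (scipy's ``auto`` policy). All values tied
    across both groups gives p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_z(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float, float]:
    """(U, Z, two-sided p) with tie-corrected normal approximation for Z."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    u, p = mann_whitney_u(a, b)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    z = 0.0 if var == 0 else (u - mu) / np.sqrt(var)
    return u, float(z), p


def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Step-up FDR rejection flags, aligned to the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * (np.arange(1, m + 1) / m)
    below = ranked <= thresh
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        flags[order[: k + 1]] = True
    return flags


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("label sequences must be equal-length and non-empty")
    cats, ai = np.unique(a, return_inverse=True)
    cats_b, bi = np.unique(b, return_inverse=True)
    all_cats = np.union1d(cats, cats_b)
    ai = np.searchsorted(all_cats, a)
    bi = np.searchsorted(all_cats, b)
    k = all_cats.size
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1)
    n = a.size
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0)) / n**2)
    if p_e >= 1.0:
        raise ValueError("kappa undefined: a single label used by both raters")
    return float((p_o - p_e) / (1.0 - p_e))


def write_cluster_result_csv(result: ClusterResult, runs_path: str, null_path: str) -> None:
    """One row per observed run; one row per permutation for the null."""
    pd.DataFrame(
        [{"start_index": s, "length": ln} for s, ln in result.runs]
    ).to_csv(runs_path, index=False)
    pd.DataFrame(
        {
            "permutation": np.arange(result.null_max_runs.size),
            "max_run_len": result.null_max_runs,
        }
    ).to_csv(null_path, index=False)
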