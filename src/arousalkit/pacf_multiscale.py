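"""Multiscale partial-autocorrelation profiling of arousal epoch grids.

The PACF is computed by Durbin-Levinson recursion on the biased sample
autocorrelations, so the lag-1 coefficient equals the lag-1
autocorrelation. Masked gaps split the series into contiguous valid
segments; segments long enough to support the requested lags are
combined by length-weighted averaging. Group contrasts across the
ordered epoch-duration axis use the cluster permutation engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .perm_cluster import (
    ClusterResult,
    cluster_permutation_p,
    find_significant_runs,
    mann_whitney_u,
    max_run_length,
)
from .poincare_stability import DegenerateInputError
from .types import ArousalSeries
from .preprocessing import downsample_epochs

__all__ = [
    "PacfProfile",
    "pacf",
    "multiscale_pacf",
    "compare_groups_multiscale",
    "DEFAULT_EPOCH_DURATIONS",
    "write_pacf_csv",
]

#: epoch durations, 1 s through 30 min
DEFAULT_EPOCH_DURATIONS = (1.0, 5.0, 10.0, 30.0, 60.0, 300.0, 600.0, 1200.0, 1800.0)


@dataclass
class PacfProfile:
    epoch_s: float
    coefficients: np.ndarray  # index k-1 holds the lag-k coefficient
    n_effective: int
    threshold: float  # +/- 1.96 / sqrt(n_effective)
    participant_id: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def lags(self) -> np.ndarray:
        return np.arange(1, self.coefficients.size + 1)


def _sample_acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelations r_0..r_max_lag."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise DegenerateInputError("constant segment: PACF undefined")
    r = np.empty(max_lag + 1)
    r[0] = 1.0
    for k in range(1, max_lag + 1):
        r[k] = float(np.dot(x[:-k], x[k:])) / denom
    return r


def _durbin_levinson(r: np.ndarray) -> np.ndarray:
    """PACF coefficients phi_kk for k = 1..len(r)-1 from autocorrelations."""
    max_lag = r.size - 1
    pacf_vals = np.empty(max_lag)
    phi = np.zeros((max_lag + 1, max_lag + 1))
    phi[1, 1] = r[1]
    pacf_vals[0] = r[1]
    for k in range(2, max_lag + 1):
        num = r[k] - np.dot(phi[k - 1, 1:k], r[1:k][::-1])
        den = 1.0 - np.dot(phi[k - 1, 1:k], r[1:k])
        phi[k, k] = num / den if den != 0 else 0.0
        phi[k, 1:k] = phi[k - 1, 1:k] - phi[k, k] * phi[k - 1, 1:k][::-1]
        pacf_vals[k - 1] = phi[k, k]
    return pacf_vals


def _valid_segments(valid: np.ndarray, min_len: int) -> List[slice]:
    padded = np.concatenate([[False], valid, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [slice(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def pacf(
    values: Sequence[float],
    max_lag: int,
    valid: Optional[Sequence[bool]] = None,
) -> np.ndarray:
    """Partial autocorrelation at lags 1..max_lag.

    With a validity mask, each contiguous valid segment of at least
    ``max_lag + 2`` points contributes, and coefficients are combined by
    segment-length-weighted average. Raises :class:`DegenerateInputError`
    on a constant series or when no segment is long enough.
    """
    v = np.asarray(values, dtype=float)
    valid = np.isfinite(v) if valid is None else (np.asarray(valid, bool) & np.isfinite(v))
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    segs = _valid_segments(valid, max_lag + 2)
    if not segs:
        raise DegenerateInputError(
            f"no contiguous valid segment of length >= {max_lag + 2}"
        )
    coefs, weights = [], []
    for sl in segs:
        x = v[sl]
        try:
            coefs.append(_durbin_levinson(_sample_acf(x, max_lag)))
        except DegenerateInputError:
            continue
        weights.append(x.size)
    if not coefs:
        raise DegenerateInputError("constant series: PACF undefined")
    w = np.asarray(weights, dtype=float)
    return np.average(np.vstack(coefs), axis=0, weights=w)


def multiscale_pacf(
    series: ArousalSeries,
    epoch_durations: Sequence[float] = DEFAULT_EPOCH_DURATIONS,
    max_lag: int = 5,
) -> List[PacfProfile]:
    """One PACF profile per epoch duration; unusable durations are dropped."""
    profiles = []
    for es in epoch_durations:
        if es < series.dt_s:
            continue
        grid = downsample_epochs(series, es)
        vals = np.where(grid.valid, grid.values, np.nan)
        try:
            coefs = pacf(vals, max_lag, valid=grid.valid)
        except DegenerateInputError as exc:
            warnings.warn(f"epoch duration {es}s dropped: {exc}")
            continue
        n_eff = int(grid.valid.sum())
        profiles.append(
            PacfProfile(
                epoch_s=es,
                coefficients=coefs,
                n_effective=n_eff,
                threshold=1.96 / np.sqrt(n_eff),
                participant_id=series.participant_id,
            )
        )
    return profiles


def _lag_matrix(
    profiles_by_participant: Dict[str, List[PacfProfile]], lag: int
) -> tuple:
    """(pids, durations, matrix) of lag-k coefficients; NaN where missing."""
    durations = sorted(
        {p.epoch_s for profs in profiles_by_participant.values() for p in profs}
    )
    pids = sorted(profiles_by_participant)
    mat = np.full((len(pids), len(durations)), np.nan)
    for i, pid in enumerate(pids):
        for prof in profiles_by_participant[pid]:
            j = durations.index(prof.epoch_s)
            if lag <= prof.coefficients.size:
                mat[i, j] = prof.coefficients[lag - 1]
    return pids, durations, mat


def _windowwise_p(mat: np.ndarray, is_a: np.ndarray, stat: str) -> np.ndarray:
    p = np.full(mat.shape[1], np.nan)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        a = col[is_a & np.isfinite(col)]
        b = col[~is_a & np.isfinite(col)]
        if a.size < 2 or b.size < 2:
            continue
        if stat == "ttest":
            p[j] = float(stats.ttest_ind(a, b).pvalue)
        else:
            _, p[j] = mann_whitney_u(a, b)
    return p


def compare_groups_multiscale(
    profiles_by_participant: Dict[str, List[PacfProfile]],
    group_labels: Dict[str, str],
    lag: int = 1,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    stat: str = "mannwhitney",
) -> ClusterResult:
    """Cluster-corrected group contrast of lag-k PACF across epoch durations.

    Windows are the ordered epoch durations; exchangeability is
    group-label permutation. ``stat`` selects the window-wise test
    ("mannwhitney" or "ttest").
    """
    pids, durations, mat = _lag_matrix(profiles_by_participant, lag)
    labels = np.asarray([group_labels[p] for p in pids])
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need two groups")
    if min(np.sum(labels == g) for g in groups[:2]) < 2:
        raise ValueError("need at least two participants per group")
    is_a = labels == groups[0]

    p_obs = _windowwise_p(mat, is_a, stat)
    p_for_runs = np.where(np.isfinite(p_obs), p_obs, 1.0)
    runs = find_significant_runs(p_for_runs, alpha)
    obs_max = max((ln for _, ln in runs), default=0)

    def permute(rng: np.random.Generator) -> int:
        perm = rng.permutation(is_a)
        pp = _windowwise_p(mat, perm, stat)
        return max_run_length(np.where(np.isfinite(pp), pp, 1.0), alpha)

    result = cluster_permutation_p(
        obs_max, permute, n_perm=n_perm, seed=seed, runs=runs,
        alpha=alpha, p_per_window=p_obs,
    )
    result.meta["epoch_durations"] = durations
    result.meta["lag"] = lag
    return result


def write_pacf_csv(
    profiles_by_participant: Dict[str, List[PacfProfile]], path: str
) -> None:
    rows = []
    for pid, profs in profiles_by_participant.items():
        for prof in profs:
            for k, c in zip(prof.lags, prof.coefficients):
                rows.append(
                    {
                        "participant_id": pid,
                        "epoch_s": prof.epoch_s,
                        "lag": int(k),
                        "pacf": c,
                        "threshold": prof.threshold,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
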