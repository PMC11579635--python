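"""Lab still-face scoring and validation analyses.

Self-regulation is the mean number of coded regulatory behaviors per
5-s bin; a median split defines the low/high groups used by every
group contrast in the pipeline. Validation analyses are the group
facial-affect trajectory over the still phase and the cluster-corrected
behavior-by-affect cross-correlation.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .perm_cluster import (
    ClusterResult,
    cluster_permutation_p,
    cross_correlation,
    find_significant_runs,
    max_run_length,
)
from .types import StillFaceRecord

__all__ = [
    "self_regulation_score",
    "median_split",
    "affect_trajectory",
    "behavior_affect_crosscorr",
]


def self_regulation_score(
    record: StillFaceRecord, phase_filter: Optional[str] = "still"
) -> float:
    """Mean behavior count per bin over the filtered phase.

    Scored over still-phase bins by default; pass ``None`` to score the
    whole session.
    """
    if phase_filter is None:
        mask = np.ones(len(record), dtype=bool)
    else:
        mask = record.phase == phase_filter
    if not mask.any():
        raise ValueError("no bins after phase filtering")
    return float(np.mean(record.behavior_count[mask]))


def median_split(scores: Dict[str, float]) -> Tuple[Dict[str, str], float]:
    """Split participants at the cohort median score.

    Scores above the median go to "high"; scores at or below it go to
    "low" (documented tie rule). Returns (labels, median).
    """
    if len(scores) < 2:
        raise ValueError("need at least two participants")
    vals = np.asarray(list(scores.values()), dtype=float)
    if np.all(vals == vals[0]):
        raise ValueError("degenerate: all scores equal")
    med = float(np.median(vals))
    labels = {pid: ("high" if s > med else "low") for pid, s in scores.items()}
    return labels, med


def affect_trajectory(
    records: Dict[str, StillFaceRecord],
    groups: Dict[str, str],
    phase: str = "still",
) -> pd.DataFrame:
    """Group-mean facial affect per bin over the given phase.

    Returns a tidy frame (group, bin, mean_affect, se, n); the standard
    error is between participants.
    """
    per_group: Dict[str, List[np.ndarray]] = {}
    for pid, rec in records.items():
        g = groups.get(pid)
        if g is None:
            continue
        per_group.setdefault(g, []).append(rec.affect[rec.phase == phase].astype(float))
    if not per_group:
        raise ValueError("no participants with a group label")
    rows = []
    for g, seqs in sorted(per_group.items()):
        if not seqs:
            raise ValueError(f"group {g!r} is empty")
        n_bins = min(s.size for s in seqs)
        mat = np.vstack([s[:n_bins] for s in seqs])
        mean = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else np.zeros(n_bins)
        for b in range(n_bins):
            rows.append(
                {"group": g, "bin": b, "mean_affect": mean[b], "se": se[b], "n": mat.shape[0]}
            )
    return pd.DataFrame(rows)


def behavior_affect_crosscorr(
    records: Dict[str, StillFaceRecord],
    max_lag_bins: int = 6,
    phase: str = "still",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray, ClusterResult]:
    """Group-level behavior-by-affect cross-correlation with cluster test.

    Per participant, Pearson r of behavior_count at t with affect at
    t+lag over the still phase (positive lag = affect lags behavior).
    Zero-variance participants are excluded with a warning. The group
    test is a one-sample t vs zero per lag, cluster-corrected with a
    sign-flip permutation null.
    """
    lags = np.arange(-max_lag_bins, max_lag_bins + 1)
    per_pid = []
    for pid, rec in sorted(records.items()):
        mask = rec.phase == phase
        x = rec.behavior_count[mask].astype(float)
        y = rec.affect[mask].astype(float)
        try:
            _, r, ok = cross_correlation(x, y, max_lag_bins)
        except ValueError:
            warnings.warn(f"participant {pid} excluded: zero-variance series")
            continue
        per_pid.append(np.where(ok, r, np.nan))
    if len(per_pid) < 2:
        raise ValueError("need at least two usable participants")
    mat = np.vstack(per_pid)

    def lag_p(m: np.ndarray) -> np.ndarray:
        p = np.ones(m.shape[1])
        for j in range(m.shape[1]):
            col = m[:, j][np.isfinite(m[:, j])]
            if col.size < 2:
                continue
            if np.std(col) == 0:
                p[j] = 1.0 if col[0] == 0 else 0.0
                continue
            res = stats.ttest_1samp(col, 0.0)
            if np.isfinite(res.pvalue):
                p[j] = float(res.pvalue)
        return p

    p_obs = lag_p(mat)
    runs = find_significant_runs(p_obs, alpha)
    obs_max = max((ln for _, ln in runs), default=0)

    def permute(rng: np.random.Generator) -> int:
        signs = rng.choice([-1.0, 1.0], size=mat.shape[0])[:, None]
        return max_run_length(lag_p(mat * signs), alpha)

    cluster = cluster_permutation_p(
        obs_max, permute, n_perm=n_perm, seed=seed, runs=runs,
        alpha=alpha, p_per_window=p_obs,
    )
    mean_r = np.nanmean(mat, axis=0)
    return lags, mean_r, cluster
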