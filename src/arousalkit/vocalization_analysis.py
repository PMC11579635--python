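"""Vocalization-arousal coupling analyses.

Covers vocal-type collapsing, RMSSD-style variability of coded affect
and intensity, vocalization likelihood by within-participant arousal
decile versus chance, peri-vocalization arousal averages, and
caregiver response rates around infant vocalizations. Events are
analyzed at their containing 60-s epoch, the grain of the sparse audio
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .perm_cluster import (
    ClusterResult,
    cluster_permutation_p,
    find_significant_runs,
    max_run_length,
)
from .poincare_stability import DegenerateInputError, quantile_bin
from .types import EXCLUDED_TYPES, SPEECH_LIKE_TYPES, EpochGrid, VocalEvent

__all__ = [
    "collapse_vocal_types",
    "affect_variability",
    "likelihood_by_arousal",
    "likelihood_group_test",
    "peri_event_average",
    "peri_event_group_test",
    "caregiver_response_rate",
    "CaregiverResponseResult",
]

_CLASS_OF = {"cry": "cry"}
_CLASS_OF.update({t: "speech_like" for t in SPEECH_LIKE_TYPES})
_CLASS_OF.update({t: "excluded" for t in EXCLUDED_TYPES})


def collapse_vocal_types(events: Iterable[VocalEvent]) -> List[VocalEvent]:
    """Assign each infant event a class: cry, speech_like, or excluded.

    Adult events pass through with class "adult". Unknown morphological
    types raise.
    """
    out = []
    for e in events:
        if e.speaker == "adult":
            out.append(replace(e, vclass="adult"))
            continue
        try:
            out.append(replace(e, vclass=_CLASS_OF[e.morph_type]))
        except KeyError:
            raise ValueError(f"unknown morphological type {e.morph_type!r}") from None
    return out


def affect_variability(
    events: Sequence[VocalEvent],
    epoch_s: float = 60.0,
    field: str = "affect",
) -> float:
    """RMSSD of the concatenated per-epoch mean affect (or intensity).

    Infant events are ordered in time, reduced to one value per 60-s
    epoch (mean of co-epoch events), and successive epoch values are
    differenced regardless of gaps. NaN when fewer than 3 infant events.
    """
    vals, epochs = [], []
    for e in events:
        if e.speaker != "infant" or getattr(e, field) is None:
            continue
        vals.append(float(getattr(e, field)))
        epochs.append(int(e.time_s // epoch_s))
    if len(vals) < 3:
        return float("nan")
    order = np.argsort(epochs, kind="stable")
    epochs = np.asarray(epochs)[order]
    vals = np.asarray(vals)[order]
    uniq, inv = np.unique(epochs, return_inverse=True)
    sums = np.bincount(inv, weights=vals)
    counts = np.bincount(inv)
    seq = sums / counts
    if seq.size < 2:
        return float("nan")
    d = np.diff(seq)
    return float(np.sqrt(np.mean(d**2)))


def _event_epochs(events: Sequence[VocalEvent], epoch_s: float) -> np.ndarray:
    return np.asarray([int(e.time_s // epoch_s) for e in events], dtype=int)


def likelihood_by_arousal(
    events: Sequence[VocalEvent],
    arousal: EpochGrid,
    n_bins: int = 10,
    n_controls_per_event: int = 10,
    seed: int = 0,
) -> Optional[np.ndarray]:
    """Per-decile vocalization likelihood minus control likelihood.

    Deciles are within-participant quantile bins of valid epochs.
    Controls are uniform draws (with replacement) from valid epochs
    containing no event, ``n_controls_per_event`` per event. Returns the
    per-bin difference vector, or None when the participant has no
    usable events (excluded from group tests).
    """
    rng = np.random.default_rng(seed)
    valid_idx = np.flatnonzero(arousal.valid)
    if valid_idx.size < n_bins:
        raise DegenerateInputError("too few valid epochs for decile binning")
    deciles = np.full(len(arousal), -1, dtype=int)
    deciles[valid_idx] = quantile_bin(arousal.values[valid_idx], n_bins=n_bins)

    ev_epochs = _event_epochs(events, arousal.epoch_s)
    ev_epochs = np.unique(ev_epochs[(ev_epochs >= 0) & (ev_epochs < len(arousal))])
    ev_epochs = ev_epochs[arousal.valid[ev_epochs]]
    if ev_epochs.size == 0:
        return None
    non_event = np.setdiff1d(valid_idx, ev_epochs)
    if non_event.size == 0:
        raise ValueError("no valid non-event epochs available for controls")
    controls = rng.choice(non_event, size=n_controls_per_event * ev_epochs.size)

    ev_frac = np.bincount(deciles[ev_epochs], minlength=n_bins) / ev_epochs.size
    ctl_frac = np.bincount(deciles[controls], minlength=n_bins) / controls.size
    return ev_frac - ctl_frac


def _onesample_t_p(mat: np.ndarray) -> np.ndarray:
    """Column-wise one-sample t-test p against zero, NaN-safe."""
    p = np.full(mat.shape[1], 1.0)
    for j in range(mat.shape[1]):
        col = mat[:, j][np.isfinite(mat[:, j])]
        if col.size < 2:
            continue
        if np.std(col) == 0:
            p[j] = 1.0 if col[0] == 0 else 0.0  # degenerate: exact, no spread
            continue
        p[j] = float(stats.ttest_1samp(col, 0.0).pvalue)
    return p


def likelihood_group_test(
    diffs: Sequence[np.ndarray],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-corrected per-bin t-test of likelihood differences vs zero.

    The permutation null sign-flips whole participant difference
    vectors (exchangeable under the no-coupling null because controls
    are drawn from the same epochs as events).
    """
    mat = np.vstack([d for d in diffs if d is not None])
    if mat.shape[0] < 2:
        raise ValueError("need at least two participants with events")
    p_obs = _onesample_t_p(mat)
    runs = find_significant_runs(p_obs, alpha)
    obs_max = max((ln for _, ln in runs), default=0)

    def permute(rng: np.random.Generator) -> int:
        signs = rng.choice([-1.0, 1.0], size=mat.shape[0])[:, None]
        return max_run_length(_onesample_t_p(mat * signs), alpha)

    return cluster_permutation_p(
        obs_max, permute, n_perm=n_perm, seed=seed, runs=runs,
        alpha=alpha, p_per_window=p_obs,
    )


def peri_event_average(
    arousal: EpochGrid,
    events: Sequence[VocalEvent],
    window_s: float = 1200.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-locked mean arousal trajectory over +/- ``window_s``.

    Returns (offsets_s, mean, n_cells); cells with no valid coverage are
    NaN. Partial windows at recording edges contribute their available
    cells only.
    """
    if len(events) == 0:
        raise ValueError("no events")
    w = int(round(window_s / arousal.epoch_s))
    offsets = np.arange(-w, w + 1)
    sums = np.zeros(offsets.size)
    counts = np.zeros(offsets.size, dtype=int)
    n = len(arousal)
    for e0 in _event_epochs(events, arousal.epoch_s):
        idx = e0 + offsets
        ok = (idx >= 0) & (idx < n)
        ok[ok] &= arousal.valid[idx[ok]]
        sums[ok] += arousal.values[idx[ok]]
        counts += ok
    mean = np.full(offsets.size, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    return offsets * arousal.epoch_s, mean, counts


def peri_event_group_test(
    trajectories: Dict[str, np.ndarray],
    group_labels: Dict[str, str],
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-corrected two-sample t per offset between group trajectories."""
    pids = sorted(trajectories)
    mat = np.vstack([trajectories[p] for p in pids])
    labels = np.asarray([group_labels[p] for p in pids])
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need two groups")
    is_a = labels == groups[0]

    def window_p(flags: np.ndarray) -> np.ndarray:
        p = np.ones(mat.shape[1])
        for j in range(mat.shape[1]):
            col = mat[:, j]
            a = col[flags & np.isfinite(col)]
            b = col[~flags & np.isfinite(col)]
            if a.size < 2 or b.size < 2:
                continue
            res = stats.ttest_ind(a, b)
            if np.isfinite(res.pvalue):
                p[j] = float(res.pvalue)
        return p

    p_obs = window_p(is_a)
    runs = find_significant_runs(p_obs, alpha)
    obs_max = max((ln for _, ln in runs), default=0)

    def permute(rng: np.random.Generator) -> int:
        return max_run_length(window_p(rng.permutation(is_a)), alpha)

    return cluster_permutation_p(
        obs_max, permute, n_perm=n_perm, seed=seed, runs=runs,
        alpha=alpha, p_per_window=p_obs,
    )


@dataclass
class CaregiverResponseResult:
    offsets_s: np.ndarray
    rate_per_min: np.ndarray  # adult vocalizations per minute, event-locked
    baseline_per_min: float
    p_per_offset: np.ndarray
    cluster: ClusterResult


def caregiver_response_rate(
    infant_events: Sequence[VocalEvent],
    adult_events: Sequence[VocalEvent],
    arousal: EpochGrid,
    window_s: float = 1200.0,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> CaregiverResponseResult:
    """Event-locked adult vocalization rate versus the whole-day baseline.

    The baseline is the overall adult rate over valid epochs.
    Significance per minute comes from circularly time-shifting the
    adult events over the valid-epoch sequence; the cluster correction
    compares the observed run of below-alpha minutes with each
    permutation's own maximum run.
    """
    if len(infant_events) == 0 or len(adult_events) == 0:
        raise ValueError("both event streams must be non-empty")
    valid_idx = np.flatnonzero(arousal.valid)
    if valid_idx.size == 0:
        raise ValueError("zero-length valid time")
    epoch_s = arousal.epoch_s
    n = len(arousal)
    w = int(round(window_s / epoch_s))
    offsets = np.arange(-w, w + 1)

    inf_epochs = _event_epochs(infant_events, epoch_s)
    inf_epochs = inf_epochs[(inf_epochs >= 0) & (inf_epochs < n)]
    adult_epochs = _event_epochs(adult_events, epoch_s)
    adult_epochs = adult_epochs[(adult_epochs >= 0) & (adult_epochs < n)]
    baseline = adult_epochs.size / valid_idx.size * (60.0 / epoch_s)

    pos_of_epoch = np.full(n, -1, dtype=int)
    pos_of_epoch[valid_idx] = np.arange(valid_idx.size)

    def rates_for(adult_ep: np.ndarray) -> np.ndarray:
        counts = np.bincount(adult_ep, minlength=n).astype(float)
        sums = np.zeros(offsets.size)
        cover = np.zeros(offsets.size, dtype=int)
        for e0 in inf_epochs:
            idx = e0 + offsets
            ok = (idx >= 0) & (idx < n)
            ok[ok] &= arousal.valid[idx[ok]]
            sums[ok] += counts[idx[ok]]
            cover += ok
        out = np.full(offsets.size, np.nan)
        nz = cover > 0
        out[nz] = sums[nz] / cover[nz] * (60.0 / epoch_s)
        return out

    obs = rates_for(adult_epochs)

    rng = np.random.default_rng(seed)
    adult_pos = pos_of_epoch[adult_epochs]
    adult_pos = adult_pos[adult_pos >= 0]
    perm_rates = np.empty((n_perm, offsets.size))
    for i in range(n_perm):
        shift = int(rng.integers(1, valid_idx.size)) if valid_idx.size > 1 else 0
        shifted = valid_idx[(adult_pos + shift) % valid_idx.size]
        perm_rates[i] = rates_for(shifted)

    dev_obs = np.abs(obs - baseline)
    dev_perm = np.abs(perm_rates - baseline)
    with np.errstate(invalid="ignore"):
        p_obs = np.nanmean(dev_perm >= dev_obs[None, :], axis=0)
    p_obs = np.where(np.isfinite(dev_obs), p_obs, 1.0)

    runs = find_significant_runs(p_obs, alpha)
    obs_max = max((ln for _, ln in runs), default=0)
    null_max = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        with np.errstate(invalid="ignore"):
            p_i = np.nanmean(dev_perm >= dev_perm[i][None, :], axis=0)
        p_i = np.where(np.isfinite(dev_perm[i]), p_i, 1.0)
        null_max[i] = max_run_length(p_i, alpha)
    count = int(np.sum(null_max >= obs_max))
    cluster = ClusterResult(
        runs=runs,
        max_run_len=obs_max,
        null_max_runs=null_max,
        cluster_p=count / n_perm,
        alpha=alpha,
        p_per_window=p_obs,
        seed=seed,
    )
    return CaregiverResponseResult(
        offsets_s=offsets * epoch_s,
        rate_per_min=obs,
        baseline_per_min=float(baseline),
        p_per_offset=p_obs,
        cluster=cluster,
    )
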