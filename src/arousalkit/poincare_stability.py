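"""Adapted Poincare analysis of arousal stability.

Arousal epochs are binned within participant into five equal-occupancy
quantile classes; transition counts between consecutive valid epochs
give per-bin stay probabilities, and direction profiles give the
probability of a decrease from above- vs below-mean states. Group
contrasts use Mann-Whitney tests with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .perm_cluster import benjamini_hochberg, mann_whitney_u

__all__ = [
    "DegenerateInputError",
    "StabilityProfile",
    "quantile_bin",
    "quantile_bin_batch",
    "stability_profile",
    "direction_profile",
    "compare_stability_groups",
    "write_stability_csv",
]


class DegenerateInputError(ValueError):
    """Raised when a series has too few distinct values to analyze."""


@dataclass
class StabilityProfile:
    """Per-bin transition statistics of one participant at one epoch duration."""

    epoch_s: float
    n_bins: int
    transition_counts: np.ndarray  # (n_bins, n_bins)
    p_stay: np.ndarray  # NaN where a bin has no outgoing transitions
    p_decrease_above_mean: float = float("nan")
    p_decrease_below_mean: float = float("nan")
    participant_id: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_transitions(self) -> int:
        return int(self.transition_counts.sum())


def quantile_bin(epoch_values: Sequence[float], n_bins: int = 5) -> np.ndarray:
    """Within-participant equal-occupancy bin index (0..n_bins-1) per epoch.

    Rank-based with stable tie order (ties broken by order of occurrence),
    so occupancies differ by at most one plus any tie-block spillover.
    Fewer distinct values than bins is a degenerate input.
    """
    v = np.asarray(epoch_values, dtype=float)
    if v.ndim != 1 or v.size < n_bins:
        raise DegenerateInputError("need at least n_bins values")
    if np.unique(v).size < n_bins:
        raise DegenerateInputError("fewer distinct values than bins")
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=int)
    ranks[order] = np.arange(v.size)
    return (ranks * n_bins) // v.size


def quantile_bin_batch(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Row-wise :func:`quantile_bin` for a (n_series, n_epochs) array."""
    values = np.asarray(values, dtype=float)
    n_series, n = values.shape
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n_series)[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    return (ranks * n_bins) // n


def stability_profile(
    bins: Sequence[int],
    valid: Optional[Sequence[bool]] = None,
    n_bins: int = 5,
    epoch_s: float = 60.0,
    participant_id: str = "",
) -> StabilityProfile:
    """Transition counts and per-bin stay probabilities.

    Transitions are counted only across consecutive valid epochs; pairs
    spanning masked gaps are dropped. Bins with no outgoing transitions
    have NaN stay probability.
    """
    b = np.asarray(bins, dtype=int)
    valid = np.ones(b.size, bool) if valid is None else np.asarray(valid, bool)
    if b.size != valid.size:
        raise ValueError("bins and valid must align")
    pair_ok = valid[:-1] & valid[1:]
    if not pair_ok.any():
        raise ValueError("need at least two consecutive valid epochs")
    src = b[:-1][pair_ok]
    dst = b[1:][pair_ok]
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (src, dst), 1)
    outgoing = counts.sum(axis=1)
    p_stay = np.full(n_bins, np.nan)
    nz = outgoing > 0
    p_stay[nz] = np.diag(counts)[nz] / outgoing[nz]
    return StabilityProfile(
        epoch_s=epoch_s,
        n_bins=n_bins,
        transition_counts=counts,
        p_stay=p_stay,
        participant_id=participant_id,
    )


def direction_profile(
    epoch_values: Sequence[float], valid: Optional[Sequence[bool]] = None
) -> Tuple[float, float]:
    """(p_decrease | above mean, p_decrease | below mean) over valid pairs.

    The mean is the participant's valid-epoch mean; epochs exactly at
    the mean count as above (documented tie rule). Strict decreases are
    counted. A side with no valid source epochs yields NaN.
    """
    v = np.asarray(epoch_values, dtype=float)
    valid = np.ones(v.size, bool) if valid is None else np.asarray(valid, bool)
    if v.size != valid.size:
        raise ValueError("values and valid must align")
    if valid.sum() < 2:
        raise ValueError("need at least two valid epochs")
    mu = float(np.mean(v[valid]))
    pair_ok = valid[:-1] & valid[1:]
    src, nxt = v[:-1][pair_ok], v[1:][pair_ok]
    dec = nxt < src
    above = src >= mu
    out = []
    for side in (above, ~above):
        out.append(float(np.mean(dec[side])) if side.any() else float("nan"))
    return out[0], out[1]


def compare_stability_groups(
    profiles: Dict[str, Dict[float, StabilityProfile]],
    group_labels: Dict[str, str],
    epoch_durations: Sequence[float] = (1.0, 60.0, 600.0),
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-(epoch duration, bin) Mann-Whitney p of stay probabilities between groups.

    Benjamini-Hochberg flags are computed jointly across all cells.
    Returns a tidy frame with columns epoch_s, bin, p, significant.
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) < 2:
        raise ValueError("need two groups")
    ga, gb = groups[:2]
    rows = []
    for es in epoch_durations:
        per_group = {g: [] for g in (ga, gb)}
        for pid, by_dur in profiles.items():
            if es in by_dur and group_labels.get(pid) in per_group:
                per_group[group_labels[pid]].append(by_dur[es].p_stay)
        if min(len(per_group[ga]), len(per_group[gb])) < 2:
            continue
        a = np.vstack(per_group[ga])
        b = np.vstack(per_group[gb])
        for bin_idx in range(a.shape[1]):
            av = a[:, bin_idx][np.isfinite(a[:, bin_idx])]
            bv = b[:, bin_idx][np.isfinite(b[:, bin_idx])]
            if av.size < 2 or bv.size < 2:
                p = np.nan
            else:
                _, p = mann_whitney_u(av, bv)
            rows.append({"epoch_s": es, "bin": bin_idx, "p": p})
    df = pd.DataFrame(rows, columns=["epoch_s", "bin", "p"])
    if df.empty:
        df["significant"] = pd.Series(dtype=bool)
        return df
    flags = np.zeros(len(df), dtype=bool)
    finite = df["p"].notna().to_numpy()
    if finite.any():
        flags[finite] = benjamini_hochberg(df.loc[finite, "p"].to_numpy(), q=q)
    df["significant"] = flags
    return df


def write_stability_csv(
    profiles: Dict[str, Dict[float, StabilityProfile]], path: str
) -> None:
    rows = []
    for pid, by_dur in profiles.items():
        for es, prof in sorted(by_dur.items()):
            for b in range(prof.n_bins):
                rows.append(
                    {
                        "participant_id": pid,
                        "epoch_s": es,
                        "bin": b,
                        "p_stay": prof.p_stay[b],
                        "n_transitions": int(prof.transition_counts[b].sum()),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
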