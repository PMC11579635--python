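"""Episode-duration statistics and simulation-grid fitting of the
asymmetric mean-reversion process.

A hyper-arousal episode is a maximal run of epochs above the
participant's mean, a hypo-arousal episode a maximal run below it, and
an average-arousal episode a maximal run inside the middle quintile bin
of the five-bin within-participant classification. Mean hyper and hypo
durations are expressed as ratios to the mean average-arousal duration
to control for overall autocorrelation. Fitting simulates the process
over an 11x11 grid of (beta_pos, beta_neg) and selects, per axis, the
weight whose simulated episode-duration ratio is closest to the
observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .perm_cluster import mann_whitney_z
from .poincare_stability import DegenerateInputError, quantile_bin, quantile_bin_batch
from .synthetic_data import simulate_arousal_batch
from .types import ModelParams

try:  # compiled fast path for the grid search; numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]

__all__ = [
    "EpisodeStats",
    "FitSurface",
    "episode_durations",
    "batch_episode_ratios",
    "goodness_of_fit",
    "fit_surface",
    "best_fit",
    "fit_participant",
    "compare_fit_groups",
    "DEFAULT_BETA_GRID",
]

DEFAULT_BETA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))

#: epochs discarded before episode statistics so simulations start near
#: the stationary regime
DEFAULT_BURN_IN = 50


@dataclass
class EpisodeStats:
    """Mean durations (epochs) of completed hyper/hypo/mid episodes."""

    mean_hyper_dur: float
    mean_hypo_dur: float
    mean_mid_dur: float
    n_hyper: int
    n_hypo: int
    n_mid: int

    @property
    def hyper_ratio(self) -> float:
        if not np.isfinite(self.mean_mid_dur) or self.mean_mid_dur == 0:
            return float("nan")
        return self.mean_hyper_dur / self.mean_mid_dur

    @property
    def hypo_ratio(self) -> float:
        if not np.isfinite(self.mean_mid_dur) or self.mean_mid_dur == 0:
            return float("nan")
        return self.mean_hypo_dur / self.mean_mid_dur


@dataclass
class FitSurface:
    """Signed observed-minus-simulated discrepancy over the beta grid.

    ``hyper_discrepancy[i, j]`` corresponds to ``beta_grid[i]`` on the
    beta_pos axis and ``beta_grid[j]`` on the beta_neg axis. Positive
    discrepancy means the observed episodes were longer than simulated.
    """

    beta_grid: np.ndarray
    hyper_discrepancy: np.ndarray
    hypo_discrepancy: np.ndarray
    n_sim: int
    seed: int
    meta: dict = field(default_factory=dict)


def _complete_run_stats(cond: np.ndarray, valid: np.ndarray) -> Tuple[float, int]:
    """Mean length and count of maximal True-runs of ``cond`` that are
    bounded on both sides by valid epochs where the condition fails.

    Runs truncated by the series edges or by masked gaps are excluded.
    """
    n = cond.size
    c = cond & valid
    padded = np.concatenate([[False], c, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = []
    for s, e in zip(starts, ends):
        if s == 0 or e == n:
            continue  # truncated by a series edge
        if not (valid[s - 1] and valid[e]):
            continue  # truncated by a masked gap
        lengths.append(e - s)
    if not lengths:
        return float("nan"), 0
    return float(np.mean(lengths)), len(lengths)


def episode_durations(
    epoch_values: Sequence[float],
    valid: Optional[Sequence[bool]] = None,
    mu: Optional[float] = None,
    n_bins: int = 5,
) -> EpisodeStats:
    """Episode statistics of one epoch series.

    ``mu`` defaults to the valid-epoch mean. Classes with no completed
    episode are flagged with NaN means.
    """
    v = np.asarray(epoch_values, dtype=float)
    valid = np.ones(v.size, bool) if valid is None else np.asarray(valid, bool)
    if valid.sum() < 2:
        raise ValueError("need at least two valid epochs")
    if mu is None:
        mu = float(np.mean(v[valid]))

    hyper_mean, n_hyper = _complete_run_stats(v > mu, valid)
    hypo_mean, n_hypo = _complete_run_stats(v < mu, valid)

    mid_cond = np.zeros(v.size, dtype=bool)
    try:
        bins = quantile_bin(v[valid], n_bins=n_bins)
        mid_cond[np.flatnonzero(valid)] = bins == n_bins // 2
    except DegenerateInputError:
        pass
    mid_mean, n_mid = _complete_run_stats(mid_cond, valid)

    return EpisodeStats(hyper_mean, hypo_mean, mid_mean, n_hyper, n_hypo, n_mid)


def _batch_run_means(cond: np.ndarray) -> np.ndarray:
    """Per-row mean length of interior True-runs for a fully valid batch."""
    n_series, n = cond.shape
    padded = np.zeros((n_series, n + 2), dtype=bool)
    padded[:, 1:-1] = cond
    d = np.diff(padded.astype(np.int8), axis=1)
    srow, scol = np.nonzero(d == 1)
    _, ecol = np.nonzero(d == -1)
    lengths = ecol - scol
    interior = (scol > 0) & (ecol < n)
    sums = np.bincount(srow[interior], weights=lengths[interior], minlength=n_series)
    counts = np.bincount(srow[interior], minlength=n_series)
    out = np.full(n_series, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def batch_episode_ratios(values: np.ndarray, n_bins: int = 5) -> Tuple[np.ndarray, np.ndarray]:
    """(hyper_ratio, hypo_ratio) per row of a fully valid (S, N) batch.

    Vectorized equivalent of :func:`episode_durations` on each row with
    its own row mean; NaN where a ratio is undefined.
    """
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    hyper = _batch_run_means(values > mu)
    hypo = _batch_run_means(values < mu)
    bins = quantile_bin_batch(values, n_bins=n_bins)
    mid = _batch_run_means(bins == n_bins // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return hyper / mid, hypo / mid


def goodness_of_fit(
    observed: EpisodeStats,
    params: ModelParams,
    n_sim: int = 1000,
    n_epochs: int = 220,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    burn_in: int = DEFAULT_BURN_IN,
) -> Tuple[float, float]:
    """Signed (hyper, hypo) discrepancy: observed minus mean simulated ratio.

    Simulated series with undefined ratios are excluded; if every
    simulation is undefined the cell is flagged with NaN.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    sims = simulate_arousal_batch(params, n_epochs + burn_in, n_sim, params.mu, rng)
    sims = sims[:, burn_in:]
    hyper_r, hypo_r = batch_episode_ratios(sims)
    out = []
    for obs, sim in ((observed.hyper_ratio, hyper_r), (observed.hypo_ratio, hypo_r)):
        sim = sim[np.isfinite(sim)]
        out.append(float(obs - np.mean(sim)) if sim.size else float("nan"))
    return out[0], out[1]


def _simulate_row_batch(
    beta_pos: float,
    beta_neg_vec: np.ndarray,
    mu: float,
    sigma: float,
    n_sim: int,
    n_epochs: int,
    burn_in: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate every (beta_pos, beta_neg[j]) cell of one grid row at once.

    Returns shape (len(beta_neg_vec) * n_sim, n_epochs), cells contiguous.
    Chunking one row at a time keeps peak memory modest even for long
    series.
    """
    bn = np.repeat(beta_neg_vec, n_sim)
    width = bn.size
    theta = np.full(width, mu)
    out = np.empty((width, n_epochs))
    for t in range(burn_in):
        dev = mu - theta
        beta = np.where(dev <= 0.0, beta_pos, bn)
        theta = theta + beta * dev + sigma * rng.standard_normal(width)
    out[:, 0] = theta
    for t in range(1, n_epochs):
        dev = mu - theta
        beta = np.where(dev <= 0.0, beta_pos, bn)
        theta = theta + beta * dev + sigma * rng.standard_normal(width)
        out[:, t] = theta
    return out


@njit(cache=False)
def _interior_run_mean(cond):  # pragma: no cover - exercised via kernels
    """Mean length and count of True-runs not touching either series end."""
    n = cond.size
    total = 0
    count = 0
    run_start = -1
    for t in range(n):
        if cond[t]:
            if run_start < 0:
                run_start = t
        else:
            if run_start >= 0:
                if run_start > 0:
                    total += t - run_start
                    count += 1
                run_start = -1
    if count == 0:
        return np.nan, 0
    return total / count, count


@njit(cache=False)
def _row_ratio_means_kernel(
    beta_pos, grid, mu, sigma, n_sim, n_epochs, burn_in, seed
):  # pragma: no cover - compiled
    """Mean simulated (hyper, hypo) episode-duration ratios for one grid row."""
    np.random.seed(seed)
    k = grid.size
    out = np.full((k, 2), np.nan)
    buf = np.empty(n_epochs)
    cond = np.empty(n_epochs, dtype=np.bool_)
    rank_min = (2 * n_epochs + 4) // 5
    rank_max = (3 * n_epochs + 4) // 5 - 1
    for j in range(k):
        bn = grid[j]
        sum_h = 0.0
        n_h = 0
        sum_l = 0.0
        n_l = 0
        for _ in range(n_sim):
            theta = mu
            for t in range(burn_in):
                dev = mu - theta
                b = beta_pos if dev <= 0.0 else bn
                theta = theta + b * dev + sigma * np.random.normal()
            for t in range(n_epochs):
                buf[t] = theta
                dev = mu - theta
                b = beta_pos if dev <= 0.0 else bn
                theta = theta + b * dev + sigma * np.random.normal()
            mu_hat = buf.mean()
            lo = np.partition(buf, rank_min)[rank_min]
            hi = np.partition(buf, rank_max)[rank_max]
            for t in range(n_epochs):
                cond[t] = lo <= buf[t] <= hi
            mid_mean, mid_n = _interior_run_mean(cond)
            if mid_n == 0 or mid_mean <= 0.0:
                continue
            for t in range(n_epochs):
                cond[t] = buf[t] > mu_hat
            h_mean, h_n = _interior_run_mean(cond)
            if h_n > 0:
                sum_h += h_mean / mid_mean
                n_h += 1
            for t in range(n_epochs):
                cond[t] = buf[t] < mu_hat
            l_mean, l_n = _interior_run_mean(cond)
            if l_n > 0:
                sum_l += l_mean / mid_mean
                n_l += 1
        if n_h > 0:
            out[j, 0] = sum_h / n_h
        if n_l > 0:
            out[j, 1] = sum_l / n_l
    return out


def _row_ratio_means_numpy(
    beta_pos, grid, mu, sigma, n_sim, n_epochs, burn_in, rng
):
    """Numpy fallback with the same contract as the compiled kernel."""
    k = grid.size
    out = np.full((k, 2), np.nan)
    sims = _simulate_row_batch(beta_pos, grid, mu, sigma, n_sim, n_epochs, burn_in, rng)
    h, l = batch_episode_ratios(sims)
    for j in range(k):
        sl = slice(j * n_sim, (j + 1) * n_sim)
        for col, vals in ((0, h[sl]), (1, l[sl])):
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[j, col] = np.mean(vals)
    return out


def fit_surface(
    observed: EpisodeStats,
    grid: Sequence[float] = DEFAULT_BETA_GRID,
    n_sim: int = 1000,
    n_epochs: int = 220,
    seed: int = 0,
    mu: float = 0.0,
    sigma: float = 1.0,
    burn_in: int = DEFAULT_BURN_IN,
    accelerate: Optional[bool] = None,
) -> FitSurface:
    """Goodness-of-fit discrepancies over the (beta_pos, beta_neg) grid.

    Episode-duration ratios are invariant to affine rescaling of the
    process, so ``mu`` and ``sigma`` only need to be on a sensible
    scale; they default to a standardized process. When numba is
    available a compiled kernel is used (identical semantics, its own
    RNG stream); ``accelerate=False`` forces the numpy path.
    """
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    k = grid.size
    hyper = np.full((k, k), np.nan)
    hypo = np.full((k, k), np.nan)
    use_numba = _HAVE_NUMBA if accelerate is None else (accelerate and _HAVE_NUMBA)
    for i, bp in enumerate(grid):
        row_seed = int(rng.integers(2**31))
        if use_numba:
            means = _row_ratio_means_kernel(
                float(bp), grid, float(mu), float(sigma),
                int(n_sim), int(n_epochs), int(burn_in), row_seed,
            )
        else:
            means = _row_ratio_means_numpy(
                bp, grid, mu, sigma, n_sim, n_epochs, burn_in,
                np.random.default_rng(row_seed),
            )
        hyper[i] = observed.hyper_ratio - means[:, 0]
        hypo[i] = observed.hypo_ratio - means[:, 1]
    return FitSurface(grid, hyper, hypo, n_sim=n_sim, seed=seed)


def best_fit(surface: FitSurface, joint: bool = True) -> Tuple[float, float]:
    """(beta_pos_hat, beta_neg_hat) minimizing the absolute discrepancies.

    The default minimizes the summed absolute discrepancy jointly over
    the full grid, which is self-consistent (the discrepancy zero
    contours of the two maps intersect at the generating parameters).
    ``joint=False`` instead reads each weight off its own map,
    marginalizing the other axis by mean absolute discrepancy; this
    variant is biased for strongly asymmetric processes because each
    episode class depends on both weights through the shared
    episode-threshold mean. Ties resolve to the smaller weight.
    """
    ah = np.abs(surface.hyper_discrepancy)
    al = np.abs(surface.hypo_discrepancy)
    if np.all(np.isnan(ah)) or np.all(np.isnan(al)):
        raise ValueError("all grid cells are flagged")
    if joint:
        tot = ah + al
        i, j = np.unravel_index(np.nanargmin(tot), tot.shape)
        return float(surface.beta_grid[i]), float(surface.beta_grid[j])
    with np.errstate(invalid="ignore"):
        pos_profile = np.nanmean(ah, axis=1)  # marginalize over beta_neg
        neg_profile = np.nanmean(al, axis=0)  # marginalize over beta_pos
    bp = float(surface.beta_grid[np.nanargmin(pos_profile)])
    bn = float(surface.beta_grid[np.nanargmin(neg_profile)])
    return bp, bn


def fit_participant(
    epoch_values: Sequence[float],
    valid: Optional[Sequence[bool]] = None,
    grid: Sequence[float] = DEFAULT_BETA_GRID,
    n_sim: int = 1000,
    seed: int = 0,
    sigma_method: str = "diff_sd",
    accelerate: Optional[bool] = None,
) -> Tuple[FitSurface, Tuple[float, float]]:
    """Observed episode stats -> grid surface -> best-fit weights.

    ``sigma_method`` chooses the plug-in noise scale: "diff_sd" (standard
    deviation of epoch-to-epoch differences, default) or "sd" (plain
    standard deviation of the valid epochs).
    """
    v = np.asarray(epoch_values, dtype=float)
    valid = np.ones(v.size, bool) if valid is None else np.asarray(valid, bool)
    observed = episode_durations(v, valid)
    mu = float(np.mean(v[valid]))
    if sigma_method == "diff_sd":
        pair_ok = valid[:-1] & valid[1:]
        sigma = float(np.std(v[1:][pair_ok] - v[:-1][pair_ok]))
    elif sigma_method == "sd":
        sigma = float(np.std(v[valid]))
    else:
        raise ValueError(f"unknown sigma_method {sigma_method!r}")
    surface = fit_surface(
        observed, grid=grid, n_sim=n_sim, n_epochs=int(valid.sum()),
        seed=seed, mu=mu, sigma=sigma, accelerate=accelerate,
    )
    return surface, best_fit(surface)


def compare_fit_groups(
    fits: Dict[str, Tuple[float, float]], group_labels: Dict[str, str]
) -> pd.DataFrame:
    """Mann-Whitney contrasts of best-fit beta_pos and beta_neg between groups."""
    if not fits:
        raise ValueError("no fits supplied")
    groups = sorted(set(group_labels[p] for p in fits))
    if len(groups) < 2:
        raise ValueError("need two groups")
    ga, gb = groups[:2]
    rows = []
    for axis, idx in (("beta_pos", 0), ("beta_neg", 1)):
        a = [fits[p][idx] for p in fits if group_labels[p] == ga]
        b = [fits[p][idx] for p in fits if group_labels[p] == gb]
        u, z, p = mann_whitney_z(a, b)
        rows.append({"parameter": axis, "group_a": ga, "group_b": gb,
                     "U": u, "Z": z, "p": p})
    return pd.DataFrame(rows)
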