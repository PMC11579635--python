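"""Raw channels to masked composite arousal and multi-resolution epoch grids.

Heart rate and RMSSD are computed over 60-s windows from inter-beat
intervals, movement is low-pass filtered actigraphy; the three channels
are z-scored within participant (RMSSD sign-inverted: higher variability
means lower arousal) and averaged into a single composite.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .types import ArousalSeries, EpochGrid

__all__ = [
    "window_heart_rate",
    "rmssd",
    "window_rmssd",
    "lowpass_movement",
    "window_movement",
    "composite_arousal",
    "apply_masks",
    "downsample_epochs",
    "preprocess_participant",
    "read_rr_csv",
    "read_movement_csv",
    "read_masks_csv",
    "write_arousal_csv",
]

#: inter-beat interval plausibility bounds for infant data, ms
INFANT_RR_BOUNDS = (300.0, 750.0)

#: minimum fraction of valid samples for an epoch to count as valid
MIN_EPOCH_COVERAGE = 0.5


def _window_index(times_s: np.ndarray, window_s: float, n_windows: int) -> np.ndarray:
    idx = np.floor(times_s / window_s).astype(int)
    idx[(idx < 0) | (idx >= n_windows)] = -1
    return idx


def window_heart_rate(
    beat_times_s: np.ndarray,
    rr_ms: np.ndarray,
    window_s: float = 60.0,
    duration_s: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean heart rate (bpm) per window: ``60000 / mean(rr)``.

    Returns ``(hr, valid)``; windows containing no beats are invalid.
    Raises if beat times are not sorted.
    """
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    rr_ms = np.asarray(rr_ms, dtype=float)
    if beat_times_s.size and np.any(np.diff(beat_times_s) < 0):
        raise ValueError("beat times must be ordered")
    if np.any(rr_ms <= 0):
        raise ValueError("rr intervals must be positive")
    if duration_s is None:
        duration_s = float(beat_times_s[-1]) if beat_times_s.size else 0.0
    n_windows = max(int(np.ceil(duration_s / window_s)), 1)
    idx = _window_index(beat_times_s, window_s, n_windows)
    ok = idx >= 0
    sums = np.bincount(idx[ok], weights=rr_ms[ok], minlength=n_windows)
    counts = np.bincount(idx[ok], minlength=n_windows)
    valid = counts > 0
    hr = np.full(n_windows, np.nan)
    hr[valid] = 60000.0 / (sums[valid] / counts[valid])
    return hr, valid


def rmssd(rr_ms: np.ndarray, bounds: Tuple[float, float] = INFANT_RR_BOUNDS) -> float:
    """Root mean square of successive differences of in-bounds intervals.

    Out-of-bounds intervals are removed before differencing. Returns NaN
    (window invalid) when fewer than 3 in-bounds intervals remain.
    """
    rr = np.asarray(rr_ms, dtype=float)
    lo, hi = bounds
    rr = rr[(rr >= lo) & (rr <= hi)]
    if rr.size < 3:
        return float("nan")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d**2)))


def window_rmssd(
    beat_times_s: np.ndarray,
    rr_ms: np.ndarray,
    window_s: float = 60.0,
    duration_s: Optional[float] = None,
    bounds: Tuple[float, float] = INFANT_RR_BOUNDS,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-window RMSSD with the in-bounds exclusion rule applied per window."""
    beat_times_s = np.asarray(beat_times_s, dtype=float)
    rr_ms = np.asarray(rr_ms, dtype=float)
    if beat_times_s.size and np.any(np.diff(beat_times_s) < 0):
        raise ValueError("beat times must be ordered")
    if duration_s is None:
        duration_s = float(beat_times_s[-1]) if beat_times_s.size else 0.0
    n_windows = max(int(np.ceil(duration_s / window_s)), 1)
    idx = _window_index(beat_times_s, window_s, n_windows)
    out = np.full(n_windows, np.nan)
    for k in range(n_windows):
        out[k] = rmssd(rr_ms[idx == k], bounds=bounds)
    return out, np.isfinite(out)


def lowpass_movement(
    magnitude: np.ndarray,
    fs_hz: float,
    cutoff_hz: float = 0.1,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (DC gain 1) of uniformly sampled actigraphy."""
    magnitude = np.asarray(magnitude, dtype=float)
    if cutoff_hz >= fs_hz / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, magnitude)


def window_movement(
    times_s: np.ndarray,
    magnitude: np.ndarray,
    window_s: float = 60.0,
    duration_s: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean (filtered) movement magnitude per window."""
    times_s = np.asarray(times_s, dtype=float)
    magnitude = np.asarray(magnitude, dtype=float)
    if duration_s is None:
        duration_s = float(times_s[-1]) if times_s.size else 0.0
    n_windows = max(int(np.ceil(duration_s / window_s)), 1)
    idx = _window_index(times_s, window_s, n_windows)
    ok = idx >= 0
    sums = np.bincount(idx[ok], weights=magnitude[ok], minlength=n_windows)
    counts = np.bincount(idx[ok], minlength=n_windows)
    valid = counts > 0
    out = np.full(n_windows, np.nan)
    out[valid] = sums[valid] / counts[valid]
    return out, valid


def _zscore_channel(values: np.ndarray, valid: np.ndarray, name: str) -> np.ndarray:
    """Z-score over valid windows; a zero-variance channel is dropped (all-NaN)."""
    z = np.full(values.shape, np.nan)
    if not valid.any():
        return z
    v = values[valid]
    sd = float(np.std(v))
    if sd == 0.0:
        warnings.warn(f"channel {name!r} has zero variance and was dropped")
        return z
    z[valid] = (v - float(np.mean(v))) / sd
    return z


def composite_arousal(
    hr: np.ndarray,
    rmssd_vals: np.ndarray,
    movement: Optional[np.ndarray] = None,
    participant_id: str = "",
    window_s: float = 60.0,
    invert_rmssd: bool = True,
) -> ArousalSeries:
    """Collapse the autonomic channels into one composite z-score series.

    Each channel is z-scored within participant over its valid (finite)
    windows; the RMSSD z is sign-inverted (higher HRV = lower arousal)
    before averaging. The composite at a window is the mean of available
    channel z-scores, invalid only when every channel is missing.
    """
    hr = np.asarray(hr, dtype=float)
    chans = [_zscore_channel(hr, np.isfinite(hr), "hr")]
    rz = _zscore_channel(np.asarray(rmssd_vals, float), np.isfinite(rmssd_vals), "rmssd")
    chans.append(-rz if invert_rmssd else rz)
    if movement is not None:
        movement = np.asarray(movement, dtype=float)
        chans.append(_zscore_channel(movement, np.isfinite(movement), "movement"))
    stack = np.vstack(chans)
    if stack.shape[1] == 0:
        raise ValueError("no windows")
    n_avail = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        comp = np.nanmean(stack, axis=0)
    valid = n_avail > 0
    comp[~valid] = np.nan
    return ArousalSeries(
        participant_id=participant_id, t0_s=0.0, dt_s=window_s, values=comp, valid=valid
    )


def apply_masks(
    series: ArousalSeries, home_mask: np.ndarray, awake_mask: np.ndarray
) -> ArousalSeries:
    """Restrict validity to at-home, awake samples; values are untouched."""
    home_mask = np.asarray(home_mask, dtype=bool)
    awake_mask = np.asarray(awake_mask, dtype=bool)
    if home_mask.shape != series.valid.shape or awake_mask.shape != series.valid.shape:
        raise ValueError("masks must align 1:1 with the series")
    return replace(series, valid=series.valid & home_mask & awake_mask)


def downsample_epochs(
    series: ArousalSeries,
    epoch_s: float,
    min_coverage: float = MIN_EPOCH_COVERAGE,
) -> EpochGrid:
    """Per-epoch mean of valid samples over half-open epochs.

    An epoch is invalid when its fraction of valid samples is below
    ``min_coverage``. Only complete epochs are produced.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    if epoch_s < series.dt_s:
        raise ValueError("epoch_s must be at least the sample spacing")
    per_epoch = int(round(epoch_s / series.dt_s))
    n_epochs = len(series) // per_epoch
    if n_epochs == 0:
        return EpochGrid(epoch_s, np.empty(0), np.empty(0, bool), np.empty(0),
                         participant_id=series.participant_id)
    n_used = n_epochs * per_epoch
    vals = series.values[:n_used].reshape(n_epochs, per_epoch)
    ok = series.valid[:n_used].reshape(n_epochs, per_epoch)
    counts = ok.sum(axis=1)
    coverage = counts / per_epoch
    sums = np.where(ok, vals, 0.0).sum(axis=1)
    means = np.full(n_epochs, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    valid = coverage >= min_coverage
    means[~nz] = np.nan
    return EpochGrid(
        epoch_s, means, valid & nz, coverage, participant_id=series.participant_id
    )


# ---------------------------------------------------------------------------
# CSV interfaces and participant-level driver
# ---------------------------------------------------------------------------

def read_rr_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def read_movement_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def read_masks_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def preprocess_participant(
    rr: pd.DataFrame,
    movement: pd.DataFrame,
    masks: pd.DataFrame,
    participant_id: str,
    window_s: float = 60.0,
    movement_fs_hz: Optional[float] = None,
    lowpass_cutoff_hz: float = 0.1,
) -> ArousalSeries:
    """rr + movement + masks tables -> masked composite ArousalSeries (60-s grid)."""
    m = masks[masks["participant_id"] == participant_id].sort_values("time_s")
    if m.empty:
        raise ValueError(f"no mask rows for {participant_id}")
    duration_s = float(m["time_s"].max()) + window_s

    r = rr[rr["participant_id"] == participant_id]
    hr, _ = window_heart_rate(
        r["beat_time_s"].to_numpy(), r["rr_ms"].to_numpy(), window_s, duration_s
    )
    rms, _ = window_rmssd(
        r["beat_time_s"].to_numpy(), r["rr_ms"].to_numpy(), window_s, duration_s
    )

    mv = movement[movement["participant_id"] == participant_id].sort_values("time_s")
    mt = mv["time_s"].to_numpy()
    mag = mv["magnitude"].to_numpy(dtype=float)
    if mt.size >= 2:
        fs = movement_fs_hz or 1.0 / float(np.median(np.diff(mt)))
        if lowpass_cutoff_hz < fs / 2.0:
            mag = lowpass_movement(mag, fs, cutoff_hz=lowpass_cutoff_hz)
    mov_w, _ = window_movement(mt, mag, window_s, duration_s)

    series = composite_arousal(hr, rms, mov_w, participant_id, window_s)
    n = len(series)
    win_of = np.floor(m["time_s"].to_numpy() / window_s).astype(int)
    home = np.ones(n, dtype=bool)
    awake = np.ones(n, dtype=bool)
    inside = (win_of >= 0) & (win_of < n)
    home[win_of[inside]] = m["home"].to_numpy()[inside].astype(bool)
    awake[win_of[inside]] = m["awake"].to_numpy()[inside].astype(bool)
    return apply_masks(series, home, awake)


def write_arousal_csv(series_by_pid: dict, path: str, epoch_s: float = 60.0) -> None:
    rows = []
    for pid, s in series_by_pid.items():
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "epoch_index": np.arange(len(s)),
                    "epoch_s": epoch_s,
                    "value": s.values,
                    "valid": s.valid.astype(int),
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
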