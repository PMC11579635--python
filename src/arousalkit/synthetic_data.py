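"""Ground-truth-known synthetic recordings.

Generates day-long composite-arousal series from an asymmetric
mean-reversion process, derived raw channels (inter-beat intervals,
movement), home/awake masks, sparsely sampled vocal events, and
still-face sessions, so that every downstream analysis stage can be
tested without external data.

The latent process is

    theta[t+1] = theta[t] + beta * (mu - theta[t]) + sigma * eps[t]

with ``eps`` i.i.d. standard normal (the Wiener increment at a unit
epoch step) and ``beta = beta_pos`` when ``theta[t] >= mu`` else
``beta_neg``.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    ArousalSeries,
    DayRecording,
    ModelParams,
    SPEECH_LIKE_TYPES,
    StillFaceRecord,
    VocalEvent,
)

__all__ = [
    "simulate_arousal_batch",
    "simulate_arousal_series",
    "simulate_vocal_events",
    "simulate_day_recording",
    "simulate_stillface_session",
    "simulate_cohort",
    "write_cohort_csvs",
    "MasksConfig",
    "VocalConfig",
    "GROUP_LABELS",
]

GROUP_LABELS = ("low_sr", "high_sr")


# ---------------------------------------------------------------------------
# latent arousal process
# ---------------------------------------------------------------------------

def simulate_arousal_batch(
    params: ModelParams,
    n_epochs: int,
    n_series: int,
    theta0: float = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Simulate ``n_series`` independent realizations, shape (n_series, n_epochs).

    Vectorized across series; the time loop is unavoidable because the
    reversion weight depends on the sign of the current deviation.
    States exactly at ``mu`` take ``beta_pos`` (deterministic tie-break).
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    if theta0 is None:
        theta0 = params.mu
    if not np.isfinite(theta0):
        raise ValueError("theta0 must be finite")
    rng = np.random.default_rng() if rng is None else rng

    out = np.empty((n_series, n_epochs), dtype=float)
    theta = np.full(n_series, float(theta0))
    out[:, 0] = theta
    if n_epochs == 1:
        return out
    eps = rng.standard_normal((n_series, n_epochs - 1))
    bp, bn, mu, sigma = params.beta_pos, params.beta_neg, params.mu, params.sigma
    for t in range(n_epochs - 1):
        dev = mu - theta
        beta = np.where(dev <= 0.0, bp, bn)  # dev<=0 <=> theta>=mu
        theta = theta + beta * dev + sigma * eps[:, t]
        out[:, t + 1] = theta
    return out


def simulate_arousal_series(
    params: ModelParams,
    n_epochs: int,
    theta0: float = None,
    seed: int = 0,
    participant_id: str = "sim",
) -> ArousalSeries:
    """One realization of the latent process as an :class:`ArousalSeries`."""
    rng = np.random.default_rng(seed)
    values = simulate_arousal_batch(params, n_epochs, 1, theta0, rng)[0]
    return ArousalSeries(
        participant_id=participant_id,
        t0_s=0.0,
        dt_s=params.epoch_s,
        values=values,
        valid=np.ones(n_epochs, dtype=bool),
    )


# ---------------------------------------------------------------------------
# vocal events
# ---------------------------------------------------------------------------

#: snapshot length of the sparse audio sampling scheme (5 s of every 60 s)
AUDIO_SNAPSHOT_S = 5.0

_CRY_AFFECT = (1, 2)
_CRY_INTENSITY = (4, 5)
_SPEECH_AFFECT = (3, 4, 5)
_SPEECH_INTENSITY = (1, 2, 3)


def _arousal_deciles(values: np.ndarray) -> np.ndarray:
    """Within-participant decile index (0..9); uniform mid-bin if degenerate."""
    from .poincare_stability import DegenerateInputError, quantile_bin

    try:
        return quantile_bin(values, n_bins=10)
    except DegenerateInputError:
        return np.full(values.size, 4, dtype=int)


def simulate_vocal_events(
    arousal: ArousalSeries,
    profile: str,
    rates: Optional[Dict[str, float]] = None,
    seed: int = 0,
    audio_sample_windows: Optional[Sequence[Tuple[float, float]]] = None,
) -> List[VocalEvent]:
    """Generate arousal-coupled infant vocal events inside audio windows.

    Cry probability rises monotonically with the within-participant
    arousal decile under both profiles; speech-like probability is
    additionally elevated in deciles 6-9 (1-based) under ``high_sr``.
    """
    if profile not in GROUP_LABELS:
        raise ValueError(f"unknown profile {profile!r}")
    if len(arousal) == 0:
        raise ValueError("arousal series is empty")
    rates = {"cry": 0.02, "speech_like": 0.05} if rates is None else dict(rates)
    rng = np.random.default_rng(seed)

    epoch_s = arousal.dt_s
    valid_idx = np.flatnonzero(arousal.valid)
    if audio_sample_windows is None:
        audio_sample_windows = [
            (arousal.t0_s + k * epoch_s, arousal.t0_s + k * epoch_s + AUDIO_SNAPSHOT_S)
            for k in valid_idx
        ]
    win_by_epoch = {
        int(round((w[0] - arousal.t0_s) / epoch_s)): w for w in audio_sample_windows
    }
    usable = np.array([k for k in valid_idx if k in win_by_epoch], dtype=int)
    if usable.size == 0:
        return []

    deciles = np.full(len(arousal), -1, dtype=int)
    deciles[usable] = _arousal_deciles(arousal.values[usable])

    # monotone non-decreasing cry coupling; speech coupling only for high_sr
    cry_w = 0.25 + 1.75 * deciles / 9.0
    speech_w = np.ones(len(arousal))
    if profile == "high_sr":
        speech_w = np.where((deciles >= 5) & (deciles <= 8), 2.5, 1.0)

    events: List[VocalEvent] = []
    for cls, base in (("cry", rates.get("cry", 0.0)),
                      ("speech_like", rates.get("speech_like", 0.0))):
        if base <= 0:
            continue
        w = cry_w if cls == "cry" else speech_w
        p = np.clip(base * w[usable], 0.0, 1.0)
        hits = usable[rng.random(usable.size) < p]
        for k in hits:
            w0, w1 = win_by_epoch[int(k)]
            t = float(rng.uniform(w0, w1))
            if cls == "cry":
                morph = "cry"
                affect = int(rng.choice(_CRY_AFFECT))
                intensity = int(rng.choice(_CRY_INTENSITY))
            else:
                morph = str(rng.choice(SPEECH_LIKE_TYPES))
                affect = int(rng.choice(_SPEECH_AFFECT))
                intensity = int(rng.choice(_SPEECH_INTENSITY))
            events.append(
                VocalEvent(
                    participant_id=arousal.participant_id,
                    time_s=t,
                    speaker="infant",
                    morph_type=morph,
                    affect=affect,
                    intensity=intensity,
                )
            )
    events.sort(key=lambda e: e.time_s)
    return events


# ---------------------------------------------------------------------------
# full day recording
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MasksConfig:
    """Recording duration and sleep/out-of-home segments (seconds)."""

    duration_s: float = 6 * 3600.0
    nap_windows: Tuple[Tuple[float, float], ...] = ((7200.0, 9600.0),)
    away_windows: Tuple[Tuple[float, float], ...] = ((14400.0, 15600.0),)
    movement_hz: float = 2.0  # nominal hardware rate is 30 Hz; kept low for speed


@dataclass(frozen=True)
class VocalConfig:
    """Event rates (per 60-s epoch) and caregiver-response behavior."""

    profile: str = "high_sr"
    cry_rate: float = 0.02
    speech_rate: float = 0.05
    adult_rate: float = 0.08
    response_prob: float = 0.4
    response_lag_s: Tuple[float, float] = (60.0, 360.0)


# linear latent-to-channel gains (simplest monotone links)
_HR_BASE_BPM = 140.0
_HR_GAIN_BPM = 8.0
_HR_NOISE_BPM = 1.0
_RMSSD_BASE_MS = 22.0
_RMSSD_GAIN_MS = 6.0
_RMSSD_FLOOR_MS = 3.0
_MOVE_BASE = 1.0
_MOVE_GAIN = 0.5
_MOVE_NOISE = 0.25


def _mask_from_windows(n: int, epoch_s: float, windows) -> np.ndarray:
    """True outside the given (start_s, end_s) windows."""
    t = np.arange(n) * epoch_s
    mask = np.ones(n, dtype=bool)
    for w0, w1 in windows:
        mask &= ~((t >= w0) & (t < w1))
    return mask


def simulate_day_recording(
    params: ModelParams,
    masks_config: Optional[MasksConfig] = None,
    vocal_config: Optional[VocalConfig] = None,
    seed: int = 0,
    participant_id: str = "sim",
) -> DayRecording:
    """Simulate every channel of a day-long home recording.

    Heart rate rises and RMSSD falls linearly with the latent arousal;
    movement magnitude rises with it. Masks are False during naps and
    out-of-home segments; every vocal event falls inside the 5-s audio
    snapshot of its 60-s epoch.
    """
    masks_config = masks_config or MasksConfig()
    vocal_config = vocal_config or VocalConfig()
    rng = np.random.default_rng(seed)

    epoch_s = params.epoch_s
    n_epochs = int(masks_config.duration_s // epoch_s)
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch")

    latent = simulate_arousal_batch(params, n_epochs, 1, params.mu, rng)[0]
    awake = _mask_from_windows(n_epochs, epoch_s, masks_config.nap_windows)
    home = _mask_from_windows(n_epochs, epoch_s, masks_config.away_windows)

    arousal = ArousalSeries(
        participant_id=participant_id,
        t0_s=0.0,
        dt_s=epoch_s,
        values=latent,
        valid=np.ones(n_epochs, dtype=bool),
    )

    # --- inter-beat intervals: HR up / RMSSD down with latent arousal
    beat_times: List[np.ndarray] = []
    rr_all: List[np.ndarray] = []
    for k in range(n_epochs):
        hr = _HR_BASE_BPM + _HR_GAIN_BPM * latent[k] + rng.normal(0, _HR_NOISE_BPM)
        hr = float(np.clip(hr, 90.0, 190.0))
        rr_mean = 60000.0 / hr
        rmssd_target = max(_RMSSD_BASE_MS - _RMSSD_GAIN_MS * latent[k], _RMSSD_FLOOR_MS)
        jitter_sd = rmssd_target / np.sqrt(2.0)
        n_beats = int(epoch_s * 1000.0 / rr_mean) + 2
        rr = rr_mean + rng.normal(0.0, jitter_sd, n_beats)
        rr = np.clip(rr, 310.0, 745.0)
        t = k * epoch_s + np.cumsum(rr) / 1000.0
        keep = t < (k + 1) * epoch_s
        beat_times.append(t[keep])
        rr_all.append(rr[keep])
    beat_times_s = np.concatenate(beat_times)
    rr_ms = np.concatenate(rr_all)

    # --- movement channel at masks_config.movement_hz
    fs = masks_config.movement_hz
    n_move = int(masks_config.duration_s * fs)
    move_t = np.arange(n_move) / fs
    latent_at_move = latent[np.minimum((move_t // epoch_s).astype(int), n_epochs - 1)]
    movement = np.clip(
        _MOVE_BASE + _MOVE_GAIN * latent_at_move + rng.normal(0, _MOVE_NOISE, n_move),
        0.0,
        None,
    )

    # --- sparse audio windows cover 5 s of every awake-at-home 60-s epoch
    usable = awake & home
    audio_windows = [
        (k * epoch_s, k * epoch_s + AUDIO_SNAPSHOT_S) for k in np.flatnonzero(usable)
    ]

    masked = replace(arousal, valid=arousal.valid & usable)
    infant_events = simulate_vocal_events(
        masked,
        vocal_config.profile,
        {"cry": vocal_config.cry_rate, "speech_like": vocal_config.speech_rate},
        seed=int(rng.integers(2**31)),
        audio_sample_windows=audio_windows,
    )

    # --- caregiver events: baseline Poisson-like + responses to infant speech
    win_start = {int(w[0] // epoch_s): w for w in audio_windows}
    adult_events: List[VocalEvent] = []
    for k in np.flatnonzero(usable):
        if rng.random() < vocal_config.adult_rate:
            w0, w1 = win_start[int(k)]
            adult_events.append(
                VocalEvent(participant_id, float(rng.uniform(w0, w1)), "adult", "adult_cdv")
            )
    lag_lo, lag_hi = vocal_config.response_lag_s
    for ev in infant_events:
        if ev.morph_type == "cry":
            continue
        if rng.random() < vocal_config.response_prob:
            lag = rng.uniform(lag_lo, lag_hi)
            k = int((ev.time_s + lag) // epoch_s)
            if k in win_start:
                w0, w1 = win_start[k]
                adult_events.append(
                    VocalEvent(participant_id, float(rng.uniform(w0, w1)), "adult", "adult_cdv")
                )
    adult_events.sort(key=lambda e: e.time_s)

    return DayRecording(
        arousal=arousal,
        beat_times_s=beat_times_s,
        rr_ms=rr_ms,
        movement_times_s=move_t,
        movement=movement,
        home_mask=home,
        awake_mask=awake,
        infant_events=infant_events,
        adult_events=adult_events,
        audio_sample_windows=audio_windows,
        ground_truth={
            "params": asdict(params),
            "profile": vocal_config.profile,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# still-face sessions
# ---------------------------------------------------------------------------

# Poisson behavior rates per 5-s bin, tuned so the cohort median score
# lands near the observed cohort median (~3.84) under a balanced split.
_STILL_RATES = {"low_sr": 3.1, "high_sr": 4.7}
_PLAY_RATE = 1.0
_AFFECT_DECLINE = {"low_sr": 2.6, "high_sr": 1.0}


def simulate_stillface_session(
    group: str,
    seed: int = 0,
    participant_id: str = "sim",
    n_play1: int = 48,
    n_still: int = 24,
    n_play2: int = 24,
    behavior_rate_still: Optional[float] = None,
    affect_coupling: float = 0.25,
    coupling_lag_bins: int = 0,
) -> StillFaceRecord:
    """Simulate one still-face session coded in 5-s bins.

    High self-regulation sessions show more regulatory behaviors and a
    shallower affect decline during the still phase. ``affect_coupling``
    ties affect to behavior counts ``coupling_lag_bins`` bins earlier,
    giving the behavior-affect cross-correlation a known peak lag.
    """
    if group not in GROUP_LABELS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)

    phases = (["play1"] * n_play1) + (["still"] * n_still) + (["play2"] * n_play2)
    n = len(phases)
    still_rate = _STILL_RATES[group] if behavior_rate_still is None else behavior_rate_still
    rates = np.where(np.asarray(phases, dtype=object) == "still", still_rate, _PLAY_RATE)
    counts = rng.poisson(rates.astype(float))

    progress = np.zeros(n)
    still_idx = np.flatnonzero(np.asarray(phases, dtype=object) == "still")
    if still_idx.size:
        progress[still_idx] = np.linspace(0, 1, still_idx.size)
    base = 4.0 - _AFFECT_DECLINE[group] * progress
    coupled = np.zeros(n)
    if affect_coupling and still_rate > 0:
        centered = (counts - rates) / np.sqrt(np.maximum(rates, 1.0))
        shifted = np.roll(centered, coupling_lag_bins)
        if coupling_lag_bins > 0:
            shifted[:coupling_lag_bins] = 0.0
        coupled = affect_coupling * shifted
    affect = np.clip(np.rint(base + coupled + rng.normal(0, 0.4, n)), 1, 5).astype(int)

    return StillFaceRecord(
        participant_id=participant_id,
        phase=np.asarray(phases, dtype=object),
        behavior_count=counts,
        affect=affect,
    )


# ---------------------------------------------------------------------------
# cohort generation and CSV output
# ---------------------------------------------------------------------------

#: generating reversion weights per self-regulation group
GROUP_BETAS = {"low_sr": (0.5, 0.2), "high_sr": (0.5, 0.5)}


def simulate_cohort(
    n_participants: int,
    seed: int = 0,
    masks_config: Optional[MasksConfig] = None,
    vocal_config_by_group: Optional[Dict[str, VocalConfig]] = None,
    beta_jitter: float = 0.0,
) -> Tuple[Dict[str, DayRecording], Dict[str, StillFaceRecord]]:
    """Simulate a balanced cohort; even indices low_sr, odd high_sr."""
    if n_participants < 2:
        raise ValueError("need at least two participants")
    rng = np.random.default_rng(seed)
    recordings: Dict[str, DayRecording] = {}
    stillface: Dict[str, StillFaceRecord] = {}
    for i in range(n_participants):
        group = GROUP_LABELS[i % 2]
        pid = f"p{i + 1:03d}"
        bp, bn = GROUP_BETAS[group]
        if beta_jitter:
            bp = float(np.clip(bp + rng.uniform(-beta_jitter, beta_jitter), 0, 1))
            bn = float(np.clip(bn + rng.uniform(-beta_jitter, beta_jitter), 0, 1))
        params = ModelParams(beta_pos=bp, beta_neg=bn, mu=0.0, sigma=1.0)
        vc = (vocal_config_by_group or {}).get(group, VocalConfig(profile=group))
        rec = simulate_day_recording(
            params,
            masks_config=masks_config,
            vocal_config=vc,
            seed=int(rng.integers(2**31)),
            participant_id=pid,
        )
        rec.ground_truth["group"] = group
        recordings[pid] = rec
        stillface[pid] = simulate_stillface_session(
            group, seed=int(rng.integers(2**31)), participant_id=pid
        )
    return recordings, stillface


def events_to_frame(events: Sequence[VocalEvent]) -> pd.DataFrame:
    """Tabulate events with the vocal_events.csv schema."""
    df = pd.DataFrame(
        [
            {
                "participant_id": e.participant_id,
                "time_s": e.time_s,
                "speaker": e.speaker,
                "morph_type": e.morph_type,
                "affect": e.affect,
                "intensity": e.intensity,
            }
            for e in events
        ],
        columns=["participant_id", "time_s", "speaker", "morph_type", "affect", "intensity"],
    )
    # adult rows carry no coding; keep the columns numeric for clean concat
    df["affect"] = df["affect"].astype(float)
    df["intensity"] = df["intensity"].astype(float)
    return df


def write_cohort_csvs(
    recordings: Dict[str, DayRecording],
    stillface: Dict[str, StillFaceRecord],
    outdir: str,
) -> Dict[str, str]:
    """Write the cohort to the CSV schemas consumed by downstream modules.

    Emits rr.csv, movement.csv, masks.csv, vocal_events.csv,
    stillface.csv and a ground_truth.json sidecar; returns the paths.
    """
    os.makedirs(outdir, exist_ok=True)
    rr_rows, move_rows, mask_rows, ev_frames, sf_rows = [], [], [], [], []
    truth = {}
    for pid, rec in recordings.items():
        rr_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "beat_time_s": rec.beat_times_s,
                    "rr_ms": rec.rr_ms,
                }
            )
        )
        move_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "time_s": rec.movement_times_s,
                    "magnitude": rec.movement,
                }
            )
        )
        mask_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "time_s": rec.arousal.times,
                    "home": rec.home_mask.astype(int),
                    "awake": rec.awake_mask.astype(int),
                }
            )
        )
        ev_frames.append(events_to_frame(rec.infant_events + rec.adult_events))
        truth[pid] = rec.ground_truth
    for pid, sf in stillface.items():
        sf_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "bin_index": np.arange(len(sf)),
                    "phase": sf.phase,
                    "behavior_count": sf.behavior_count,
                    "affect": sf.affect,
                }
            )
        )
    schemas = {
        "rr": ["participant_id", "beat_time_s", "rr_ms"],
        "movement": ["participant_id", "time_s", "magnitude"],
        "masks": ["participant_id", "time_s", "home", "awake"],
        "vocal_events": ["participant_id", "time_s", "speaker", "morph_type",
                         "affect", "intensity"],
        "stillface": ["participant_id", "bin_index", "phase", "behavior_count",
                      "affect"],
    }
    paths = {}
    for name, frames in (
        ("rr", rr_rows),
        ("movement", move_rows),
        ("masks", mask_rows),
        ("vocal_events", ev_frames),
        ("stillface", sf_rows),
    ):
        path = os.path.join(outdir, f"{name}.csv")
        frames = [f for f in frames if not f.empty]
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        else:
            pd.DataFrame(columns=schemas[name]).to_csv(path, index=False)
        paths[name] = path
    truth_path = os.path.join(outdir, "ground_truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    paths["ground_truth"] = truth_path
    return paths
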