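# arousalkit

Analysis pipeline for day-long infant autonomic-arousal dynamics, exercised
end-to-end on a synthetic-data generator with known ground truth. The package
covers:

- **synthetic_data** — ground-truth-known day-long recordings: an asymmetric
  mean-reversion arousal process (`theta[t+1] = theta[t] + beta*(mu-theta[t]) +
  sigma*eps`, with `beta_pos` above the mean and `beta_neg` below it), derived
  inter-beat-interval / movement channels, home/awake masks, sparsely sampled
  (5 s of every 60 s) arousal-coupled vocal events, and still-face sessions.
- **preprocessing** — 60-s-window heart rate and RMSSD (inter-beat bounds
  300–750 ms), zero-phase Butterworth low-pass on movement (0.1 Hz), a z-scored
  composite arousal series (RMSSD sign-inverted), home/awake masking, and
  down-sampling to epoch grids from 1 s to 30 min.
- **perm_cluster** — the inference engine: contiguous significant-run
  detection, permutation null of the maximum run length with a bootstrap p
  (count/n convention: 10 of 1000 → p = .01), cross-correlation, Mann–Whitney
  U, Benjamini–Hochberg, and Cohen's kappa.
- **pacf_multiscale** — partial-autocorrelation profiles across epoch
  durations (Durbin–Levinson on biased autocorrelations; gap-aware), with
  cluster-corrected group comparison across the duration axis.
- **poincare_stability** — within-participant quantile binning (5 bins),
  transition/stay probabilities, direction profiles, Mann–Whitney +
  Benjamini–Hochberg group contrasts.
- **mean_reversion_model** — episode-duration statistics (hyper/hypo runs
  around the participant mean, normalized by middle-quintile run durations),
  an 11×11 simulation-grid goodness-of-fit surface over
  (beta_pos, beta_neg), best-fit selection, and group comparison. A numba
  kernel accelerates the grid search when available.
- **vocalization_analysis** — vocal-type collapsing (cry / speech-like /
  excluded), RMSSD-style affect/intensity variability, vocalization likelihood
  by arousal decile versus control draws, peri-event arousal averages, and
  caregiver response rates versus baseline.
- **stillface_lab** — self-regulation scoring of 5-s-binned still-face
  sessions, median split, affect trajectories, and the behavior-by-affect
  cross-correlation with cluster correction.
- **cli_pipeline** — configuration, input-schema validation, per-stage seed
  derivation, and orchestration of simulate → preprocess → analyses → report.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (parameter-recovery,
permutation-p worked example, type-I calibration of the cluster test, oracle
equivalences, closed-form limits, hand-worked examples, end-to-end
determinism); the heavier simulations there run at reduced but decisive scale.

## CLI

```sh
arousalkit simulate --seed 1 --out results        # synthetic cohort CSVs
arousalkit validate --data results/data           # schema report
arousalkit report --seed 1 --out results          # full pipeline + summary.json
```

Subcommands `preprocess`, `pacf`, `poincare`, `fit-model`, `vocal`,
`stillface` run the corresponding stage; all accept `--config` (YAML),
`--seed`, `--out`, `--n-perm`, `--n-sim`. Every stage seed is derived from the
master seed by stable hashing, so reruns with the same config are
bit-identical.

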