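# ercflow

Event-related causality (ERC) analysis of directed high-gamma (60–180 Hz)
interactions between subthalamic and cortical recording sites during a
cued reading task — implemented as a tested, reusable pipeline together
with a synthetic-cohort generator whose ground-truth couplings make every
stage verifiable without patient data.

## What it does

1. **Simulate** (`ercflow.synthetic`) — cohorts of sessions from stable
   MVAR networks with time-localized, condition-dependent directed
   couplings (e.g. an STG→STN burst at −450…−400 ms before speech onset,
   with word coupling gain > pseudoword gain), task-event schedules with
   alternating word/pseudoword trials, and per-channel task-evoked power
   augmentation.
2. **Preprocess** (`ercflow.preprocess`) — resampling to the 1250 Hz
   analysis rate, zero-phase 60–180 Hz FIR band-pass, cue-aligned baseline
   (520 ms) and speech-onset-aligned response (1 s) epoching, robust-SD
   artifact rejection, common average reference.
3. **Screen** (`ercflow.selection`) — keep only channels with
   statistically significant event-related high-gamma power increases
   (paired t tests vs. per-trial baseline means, BH-FDR per channel).
4. **Estimate** (`ercflow.mvar`) — multi-trial Yule–Walker MVAR fits in
   sliding 140 ms windows shifted by 5.6 ms, AIC order selection, the
   sample-sufficiency guard `K(p+1)/(Ns·nt) < 0.1`, spectral transfer
   matrices and partial coherence, and the short-time direct directed
   transfer function (SdDTF) `z_kl(f, t) ∈ [0, 1]`.
5. **Test** (`ercflow.stats`) — 2D moving-average smoothing,
   task-vs-baseline significance with BH-FDR (increases only), group
   pooling across sessions by directed region-pair class (STG→STN, …),
   word-vs-pseudoword contrasts, and integration of significant flows
   into directed graphs over named time windows.
6. **Report** (`ercflow.pipeline` / CLI) — end-to-end session and group
   runs, flow diagrams (smallest 15 % of edges trimmed), group time
   courses with phoneme-epoch shading, CSV/JSON/HDF5 outputs with
   config-hash provenance.

`ercflow.behavior` adds the behavioral analyses: reading latencies
(speech onset − stimulus onset), C1/V/C2 durations, paired Wilcoxon
signed-rank tests, and mean ± SEM descriptives using the population-SD
convention.

## CLI

```sh
# write a 10-session synthetic cohort to session directories
ercflow simulate --seed 1 --out scratch/cohort

# analyze one session (selection, flows, ERC, behavior, provenance)
ercflow run-session scratch/cohort/session_00 --out scratch/s00

# pool sessions into group statistics, contrasts, figures
ercflow run-group scratch/cohort/session_* --out scratch/group
```

A session directory holds `signals.h5` (channels × samples, with
sampling rate and channel-region attrs), `events.csv` (one row per trial:
condition, cue/stimulus/speech onsets, phoneme durations), `truth.json`
(the generating network, for simulated data) and `meta.json`.

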