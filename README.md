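# progreplay

Synthetic-MEG pipeline for studying neural **replay during mental program
execution**: a deterministic reasoning task over a 12-location operation
graph, a sensor-space MEG generator with ground-truth injections, multivariate
decoding, temporally delayed linear modeling (TDLM) of replay sequenceness,
replay-onset detection, and time-resolved / replay-aligned representational
similarity analysis (RSA).  The acceptance surface is parameter recovery:
every effect the generator injects (replay lags, data-update contrasts,
program-similarity patterns) must be recovered by the analysis chain, and
no effect may appear when nothing was injected.

## What is in here

| module | contents |
| --- | --- |
| `progreplay.task` | Task worlds (12 locations + END, six swap/branch operations over a 3-bit face), deterministic program execution, trial/probe sampling, path-similarity matrices, trial-wise transition matrices, behavioral summaries |
| `progreplay.simulate` | Pattern banks, AR(1) sensor noise, functional/operation localizer runs, the reasoning run with injected replay chains and sustained RSA patterns, behavior simulation, exhaustive injection logs with exact signal reconstruction |
| `progreplay.decoding` | L1-logistic one-vs-rest state decoders (objects, face-attribute values), held-out-object abstract operation decoders (type / attribute / compound), reactivation probability matrices, cluster-permutation significance, confusion matrices, peak-latency ordering |
| `progreplay.sequenceness` | Two-stage TDLM with trial-wise theoretical matrices, state-relabeling permutation nulls with max-over-lag correction, correct/incorrect/shallow/deep path splits, multi-step TDLM with data-update (output − input) contrasts, replay-onset detection, event-locked reactivation, session-trend regression |
| `progreplay.rsa` | Time-resolved similarity GLM (program / object / shallow / deep / face-path / length regressors), cluster permutation via neural-data shuffles, replay-aligned RSA with matched random-time controls |
| `progreplay.pipeline` | Study configuration and validation, per-participant orchestration, recovery report |
| `progreplay.io` | HDF5 round-trip storage with lazy per-participant access; CSV/YAML side files |
| `progreplay.cli` | `progreplay` command-line interface |

## CLI

```bash
progreplay simulate  --seed 1 --participants 2 --out out/        # raw study
progreplay decode    --seed 1 --participants 2 --out out/        # decoding curves
progreplay sequenceness --which correct --seed 1 --out out/      # TDLM
progreplay rsa       --epoch end --seed 1 --out out/             # similarity GLM
progreplay run-all   --seed 1 --participants 2 --out out/        # full pipeline + report
progreplay report    --out out/                                  # summarize report.json
```

All commands accept `--config config.yaml` (see `progreplay.pipeline.StudyConfig`
for every knob; `StudyConfig.desk_scale()` is a small fast preset).  One master
seed derives all stage seeds, so every output is a deterministic function of
the configuration.

## Notes on the generator

The synthetic data are a stand-in for real recordings and are deliberately
transparent: the injection log enumerates every non-noise component, and
`simulate.reconstruct_injections` rebuilds the clean signal bit-exactly from
the log — analyses can therefore be scored against ground truth.  Replay
direction defaults to backward (location chains reversed in time) while
location → operation-code links always run forward within an event, since a
code trails its own location.  A converter note for real sensor data lives at
the bottom of `progreplay/io.py`.
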