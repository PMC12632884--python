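# File schemas

All tables are plain CSV (one header row); arrays live in HDF5
(`data.h5`, one group per participant, one dataset per trial, schema
version in the file attributes); configuration is YAML echoing
`StudyConfig.to_dict()` verbatim, including the master seed.

## trials_pNNN.csv  (one row per reasoning trial)

| column | meaning |
| --- | --- |
| `trial_id` | 0-based trial index |
| `start_location` | on-screen start location |
| `start_face` | start face as `shape-limb-hat` value triple |
| `path` | correct execution path, `>`-joined locations (start included, END excluded) |
| `length` | number of operations (3 or 4) |
| `n_branch`, `n_swap` | operation-type counts along the path |
| `thinking_time_s` | simulated reasoning duration (5–20 s) |

## behavior_pNNN.csv  (one row per probe; two per trial)

| column | meaning |
| --- | --- |
| `trial_id`, `probe_index` | trial and probe order (0 = shown first) |
| `q_type` | `END` or `PATH` |
| `modality` | `object` or `face` (shared within a trial) |
| `depth_of_probe` | `shallow`, `deep`, or `end` |
| `attribute_distance` | face probes: Hamming distance of the probe face from the correct face (0 for matches); empty for object probes |
| `is_match` | whether the probe showed the correct stimulus |
| `correct` | simulated response correctness |
| `thinking_time_s` | trial-level thinking time (repeated on both rows) |

## injection_log_pNNN.csv  (one row per injected signal component)

| column | meaning |
| --- | --- |
| `trial`, `event` | trial id and event index (−1 for trial-level components) |
| `kind` | `seq` (replay-chain transient), `stim` (start stimulus), `rsa_event` / `rsa_end` (sustained path pattern) |
| `state` | pattern-bank state injected |
| `sample` | onset sample within the trial |
| `duration` | samples covered |
| `gain` | multiplicative gain applied to the pattern |
| `link` | for `seq` rows: which lag produced this element (`obj_obj`, `loc_type`, `loc_attr`, `loc_op`, `op_data`; empty for chain anchors) |
| `lag_ms` | the drawn lag in ms (NaN where not applicable) |
| `direction` | replay direction of the parent event |
| `position` | aligned path position tag for sustained patterns (1 = first, 2 = middle, 3 = last; −1 otherwise) |

`progreplay.simulate.reconstruct_injections` rebuilds the exact clean signal
from this table; adding the per-trial AR(1) noise regenerated from the logged
`noise_seed` (in the trial metadata) reproduces the stored data bit-exactly.

## decoding_curves.csv

`participant`, `decoder` (objects / face_attributes / type / attribute /
compound), `time_ms`, `accuracy`, `chance`.

## rsa_{start,end}.csv

`participant`, `time_ms`, `program_beta`, `significant` (mass-corrected
cluster membership).
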