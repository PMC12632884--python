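"""HDF5 / CSV / YAML storage for synthetic studies.

Arrays go to HDF5 (one group per participant, one dataset per trial so
variable-length reasoning trials round-trip bit-exactly); injection logs and
behavior tables to CSV; configuration to YAML.  Every file carries a schema
version and the generating seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd
import yaml

from progreplay.simulate import SensorTimeseries

SCHEMA_VERSION = 1


def save_timeseries(group: h5py.Group, ts: SensorTimeseries) -> None:
    group.attrs["fs"] = ts.fs
    group.attrs["run"] = ts.run
    group.attrs["n_trials"] = ts.n_trials
    group.attrs["trial_meta"] = ts.trial_meta.to_json(orient="table")
    for i, data in enumerate(ts.trials):
        group.create_dataset(f"trial_{i:04d}", data=data)


def load_timeseries(group: h5py.Group) -> SensorTimeseries:
    n = int(group.attrs["n_trials"])
    trials = [np.asarray(group[f"trial_{i:04d}"]) for i in range(n)]
    meta = pd.read_json(
        __import__("io").StringIO(group.attrs["trial_meta"]), orient="table"
    )
    return SensorTimeseries(trials, int(group.attrs["fs"]), str(group.attrs["run"]), meta)


def save_dataset(path, runs_by_participant: dict, config: dict | None = None) -> None:
    """Write ``{participant: {run_name: SensorTimeseries}}`` to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        if config is not None:
            fh.attrs["config"] = json.dumps(config)
        for p, runs in runs_by_participant.items():
            pg = fh.create_group(f"participant_{int(p):03d}")
            for name, ts in runs.items():
                save_timeseries(pg.create_group(name), ts)


class StudyDataset:
    """Lazy per-participant reader for a saved study HDF5 file."""

    def __init__(self, path):
        self.path = Path(path)
        self._fh = h5py.File(self.path, "r")
        version = self._fh.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"schema version mismatch: file has {version!r}, "
                f"reader expects {SCHEMA_VERSION}"
            )
        self.participants = sorted(
            int(k.split("_")[1]) for k in self._fh if k.startswith("participant_")
        )

    @property
    def config(self) -> dict | None:
        raw = self._fh.attrs.get("config")
        return json.loads(raw) if raw is not None else None

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self) -> Iterator[int]:
        return iter(self.participants)

    def __getitem__(self, participant: int) -> dict:
        key = f"participant_{int(participant):03d}"
        if key not in self._fh:
            raise KeyError(f"no participant {participant} in {self.path}")
        return {name: load_timeseries(self._fh[key][name]) for name in self._fh[key]}

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "StudyDataset":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def load_dataset(path) -> StudyDataset:
    return StudyDataset(path)


def save_config_yaml(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def load_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


# A note on real recordings: sensor-space data exported from FIF (e.g. via
# mne.io.read_raw_fif, picking magnetometer/gradiometer channels, epoched
# per trial) can be mapped into SensorTimeseries(trials=list of
# channels x samples arrays, fs, run, trial_meta) and fed through the same
# decoders and analyses; that import path is deliberately untested here.
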