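"""Synthetic sensor-space MEG generator with exhaustive ground-truth logs.

Three runs are emulated: a functional localizer (objects and faces), an
operation localizer (objects plus their operation codes), and the reasoning
run.  Signals are multivariate discrimination patterns active on a small
fraction of sensors, embedded in temporally autocorrelated Gaussian noise.
The reasoning run additionally carries injected replay chains
(location -> type / attribute / operation -> data-update patterns at
configurable lags), sustained end-of-trial path patterns for RSA, and the
on-screen start stimulus.  Every non-noise component is recorded in an
injection log from which the clean signal can be rebuilt sample-exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from progreplay.task import (
    ALL_OPERATIONS,
    ATTRIBUTE_VALUES,
    ATTRIBUTES,
    OP_TYPES,
    TaskGraph,
    TrialSpec,
)

#: names of the five replay-chain links whose lags are configurable
LINKS = ("obj_obj", "loc_type", "loc_attr", "loc_op", "op_data")

FACE_VALUE_STATES = tuple(v for a in ATTRIBUTES for v in ATTRIBUTE_VALUES[a])
OP_TYPE_STATES = OP_TYPES
OP_ATTRIBUTE_STATES = ATTRIBUTES
COMPOUND_OP_STATES = tuple(op.name for op in ALL_OPERATIONS)


def state_dimension(state: str) -> str:
    """Which representational dimension a pattern-bank state belongs to."""
    if state in OP_TYPE_STATES:
        return "type"
    if state in OP_ATTRIBUTE_STATES:
        return "attribute"
    if state in COMPOUND_OP_STATES:
        return "compound"
    if state in FACE_VALUE_STATES:
        return "face_value"
    return "object"


def decodable_states(graph: TaskGraph) -> tuple[str, ...]:
    """All pattern-bank states: 12 objects, 6 face values, 2 types,
    3 attributes, 6 compound operations (29 in total)."""
    return (
        tuple(graph.locations)
        + FACE_VALUE_STATES
        + OP_TYPE_STATES
        + OP_ATTRIBUTE_STATES
        + COMPOUND_OP_STATES
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_lag_means() -> dict[str, float]:
    return {
        "obj_obj": 80.0,
        "loc_type": 30.0,
        "loc_attr": 60.0,
        "loc_op": 60.0,
        "op_data": 120.0,
    }


def _default_lag_sds() -> dict[str, float]:
    return {k: 0.0 for k in LINKS}


@dataclass
class SimulationConfig:
    """All generator knobs; every randomness source derives from ``seed``."""

    n_participants: int = 20
    n_sensors: int = 270
    fs: int = 100  # Hz; must divide 1000 into an integer ms per sample
    ar_coefficient: float = 0.8
    noise_sd: float = 1.0
    amplitude: float = 1.2  # localizer object/face pattern magnitude (noise-SD units)
    # relative gain of operation codes in the operation localizer; the
    # default supports reliable abstract decoding and lag recovery, while
    # `validation_regime` reproduces the barely-above-chance setting
    op_gain: float = 0.6
    active_fraction: float = 0.10
    lag_means_ms: dict[str, float] = field(default_factory=_default_lag_means)
    lag_sds_ms: dict[str, float] = field(default_factory=_default_lag_sds)
    events_per_trial: int = 5
    event_min_onset_s: float = 1.0  # replay starts after stimulus uptake
    replay_amplitude: float = 2.0
    replay_direction: str = "backward"  # or "forward"
    rsa_pattern_gain: float = 1.0
    rsa_positions: str = "all"  # which path positions carry the pattern: all|shallow|deep
    rsa_event_window_ms: tuple[float, float] = (180.0, 360.0)
    rsa_end_window_s: float = 1.0
    stim_window_ms: tuple[float, float] = (50.0, 500.0)
    # response windows of the operation codes in the operation localizer are
    # staggered so the three dimensions' patterns are temporally separable
    # at classifier-training time (they always co-occur within a trial)
    op_code_windows_ms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "type": (100.0, 250.0),
            "attribute": (225.0, 375.0),
            "compound": (350.0, 500.0),
        }
    )
    transient_ms: float = 20.0
    reasoning_stimulus: bool = True
    op_localizer_op_only: bool = False  # embed only the operation pattern
    n_trials: int = 90
    # behavior model
    base_error: float = 0.10
    error_per_length: float = 0.08
    error_per_branch: float = 0.05
    error_per_swap: float = 0.05
    tt_base_s: float = 7.0
    tt_per_length_s: float = 2.0
    tt_per_branch_s: float = 1.0
    tt_sd_s: float = 1.0
    tt_bounds_s: tuple[float, float] = (5.0, 20.0)
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        problems = []
        if self.fs <= 0 or 1000 % self.fs != 0:
            problems.append(f"fs={self.fs} must divide 1000 into integer ms/sample")
        if not 0 <= abs(self.ar_coefficient) < 1:
            problems.append("|ar_coefficient| must be < 1")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be positive")
        if not 0 < self.active_fraction <= 1:
            problems.append("active_fraction must lie in (0, 1]")
        if set(self.lag_means_ms) != set(LINKS):
            problems.append(f"lag_means_ms must have keys {LINKS}")
        if any(v < 0 for v in self.lag_means_ms.values()):
            problems.append("lag means must be non-negative")
        if any(v < 0 for v in self.lag_sds_ms.values()):
            problems.append("lag sds must be non-negative")
        if self.replay_direction not in ("forward", "backward"):
            problems.append("replay_direction must be 'forward' or 'backward'")
        if problems:
            raise ValueError("; ".join(problems))
        return self

    @property
    def ms_per_sample(self) -> int:
        return 1000 // self.fs

    @classmethod
    def validation_regime(cls, **overrides) -> "SimulationConfig":
        """Weak-decoding validation setting: the operation localizer embeds
        only the presented operation's pattern, at an amplitude calibrated
        so cross-validated operation decoding sits ~2% above chance."""
        defaults = dict(op_gain=0.22, op_localizer_op_only=True, op_code_windows_ms={})
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rsa_event_window_ms"] = list(self.rsa_event_window_ms)
        d["stim_window_ms"] = list(self.stim_window_ms)
        d["tt_bounds_s"] = list(self.tt_bounds_s)
        d["op_code_windows_ms"] = {
            k: list(v) for k, v in self.op_code_windows_ms.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("rsa_event_window_ms", "stim_window_ms", "tt_bounds_s"):
            if key in d:
                d[key] = tuple(d[key])
        if "op_code_windows_ms" in d:
            d["op_code_windows_ms"] = {
                k: tuple(v) for k, v in d["op_code_windows_ms"].items()
            }
        return cls(**d).validate()


# ---------------------------------------------------------------------------
# pattern bank
# ---------------------------------------------------------------------------


@dataclass
class PatternBank:
    """Per-state multivariate sensor patterns.

    Each state's pattern is nonzero on ``round(active_fraction * n_sensors)``
    sensors, with active sets drawn independently per state and Gaussian
    weights scaled by ``amplitude`` (in noise-SD units).
    """

    n_sensors: int
    patterns: dict[str, np.ndarray]
    active_fraction: float
    amplitude: float
    seed: int

    def __getitem__(self, state: str) -> np.ndarray:
        return self.patterns[state]

    def matrix(self, states: Sequence[str]) -> np.ndarray:
        return np.stack([self.patterns[s] for s in states])

    @property
    def states(self) -> tuple[str, ...]:
        return tuple(self.patterns)


def make_pattern_bank(
    states: Sequence[str],
    n_sensors: int,
    active_fraction: float,
    amplitude: float,
    seed: int,
) -> PatternBank:
    """Draw one sparse pattern per state, deterministically from ``seed``."""
    if not 0 < active_fraction <= 1:
        raise ValueError("active_fraction must lie in (0, 1]")
    k = int(round(active_fraction * n_sensors))
    if k < 1:
        raise ValueError(
            f"active_fraction={active_fraction} yields zero active sensors "
            f"for n_sensors={n_sensors}"
        )
    rng = np.random.default_rng(seed)
    patterns: dict[str, np.ndarray] = {}
    for state in states:
        vec = np.zeros(n_sensors)
        active = rng.choice(n_sensors, size=k, replace=False)
        vec[active] = amplitude * rng.normal(size=k)
        patterns[state] = vec
    return PatternBank(n_sensors, patterns, active_fraction, amplitude, seed)


def bank_for_graph(graph: TaskGraph, cfg: SimulationConfig, seed: int) -> PatternBank:
    return make_pattern_bank(
        decodable_states(graph),
        cfg.n_sensors,
        cfg.active_fraction,
        cfg.amplitude,
        seed,
    )


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def simulate_noise(
    n_sensors: int,
    n_samples: int,
    ar_coefficient: float,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Order-1 autoregressive Gaussian noise per sensor.

    Stationary, with variance ``noise_sd**2 / (1 - ar**2)``; the first sample
    is drawn from the stationary distribution.
    """
    if not abs(ar_coefficient) < 1:
        raise ValueError("|ar_coefficient| must be < 1 for stationarity")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eps = rng.normal(scale=noise_sd, size=(n_sensors, n_samples))
    stat_sd = noise_sd / np.sqrt(1.0 - ar_coefficient**2)
    eps[:, 0] = rng.normal(scale=stat_sd, size=n_sensors)
    # x_t = ar * x_{t-1} + eps_t  ==  IIR filter 1 / (1 - ar z^-1)
    return sps.lfilter([1.0], [1.0, -ar_coefficient], eps, axis=1)


# ---------------------------------------------------------------------------
# timeseries containers
# ---------------------------------------------------------------------------


@dataclass
class SensorTimeseries:
    """Per-trial sensor arrays (sensors x samples; lengths may vary)."""

    trials: list[np.ndarray]
    fs: int
    run: str  # functional_localizer | operation_localizer | reasoning
    trial_meta: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_sensors(self) -> int:
        return self.trials[0].shape[0]

    def stacked(self) -> np.ndarray:
        """3-D (trials, sensors, samples) view; requires equal lengths."""
        lengths = {t.shape[1] for t in self.trials}
        if len(lengths) != 1:
            raise ValueError("trials have unequal lengths; cannot stack")
        return np.stack(self.trials)


def _stim_envelope(n_samples: int, fs: int, window_ms: tuple[float, float],
                   shift_ms: float = 0.0) -> np.ndarray:
    """Raised-cosine (Hann) stimulus envelope over ``window_ms`` post-onset."""
    env = np.zeros(n_samples)
    a = int(round((window_ms[0] + shift_ms) / 1000 * fs))
    b = int(round((window_ms[1] + shift_ms) / 1000 * fs))
    a, b = max(a, 0), min(b, n_samples)
    if b > a:
        env[a:b] = np.hanning(b - a + 2)[1:-1]
    return env


def _transient_kernel(fs: int, transient_ms: float) -> np.ndarray:
    """Half-cosine reactivation transient."""
    n = max(1, int(round(transient_ms / 1000 * fs)))
    return np.sin(np.pi * (np.arange(1, n + 1)) / (n + 1))


# ---------------------------------------------------------------------------
# localizer schedules
# ---------------------------------------------------------------------------


def functional_localizer_schedule(
    graph: TaskGraph,
    seed: int,
    n_per_object: int = 38,
    n_per_face_value: int = 44,
    trial_s: float = 1.0,
) -> pd.DataFrame:
    """Default functional-localizer trial table.

    Each object appears ``n_per_object`` times; each face appears
    ``n_per_face_value / 4`` times so that every binary attribute value is
    shown ``n_per_face_value`` times (each value occurs on 4 of the 8 faces).
    """
    if n_per_face_value % 4:
        raise ValueError("n_per_face_value must be divisible by 4")
    from progreplay.task import ALL_FACES

    rows = []
    for loc in graph.locations:
        for _ in range(n_per_object):
            rows.append(
                {"kind": "object", "state": loc, "states": (loc,), "gains": (1.0,)}
            )
    n_per_face = n_per_face_value // 4
    for face in ALL_FACES:
        values = tuple(face.value(a) for a in ATTRIBUTES)
        for _ in range(n_per_face):
            rows.append(
                {
                    "kind": "face",
                    "state": face.name,
                    "states": values,
                    "gains": (1.0,) * len(values),
                }
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    out = pd.DataFrame([rows[i] for i in order])
    out.insert(0, "trial", np.arange(len(out)))
    out["duration_s"] = trial_s
    return out


def operation_localizer_schedule(
    graph: TaskGraph,
    seed: int,
    n_per_object: int = 22,
    trial_s: float = 1.8,
    op_gain: float | None = None,
    op_only: bool = False,
) -> pd.DataFrame:
    """Default operation-localizer trial table.

    Each object appears ``n_per_object`` times (so each operation, assigned
    to two objects, is probed ``2 * n_per_object`` times).  Each trial embeds
    the object pattern plus the object's operation-type, operation-attribute
    and compound-operation patterns at gain ``op_gain``; with ``op_only``
    just the compound operation pattern is embedded (the weak-decoding
    validation setting).
    """
    rows = []
    for loc in graph.locations:
        op = graph.op_of[loc]
        gain = 1.0 if op_gain is None else op_gain
        for _ in range(n_per_object):
            if op_only:
                states, gains = (op.name,), (gain,)
            else:
                states = (loc, op.op_type, op.attribute, op.name)
                gains = (1.0, gain, gain, gain)
            rows.append(
                {
                    "kind": "operation",
                    "state": loc,
                    "states": states,
                    "gains": gains,
                    "op_type": op.op_type,
                    "op_attribute": op.attribute,
                    "operation": op.name,
                }
            )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(rows))
    out = pd.DataFrame([rows[i] for i in order])
    out.insert(0, "trial", np.arange(len(out)))
    out["duration_s"] = trial_s
    return out


def simulate_localizer(
    bank: PatternBank,
    schedule: pd.DataFrame,
    cfg: SimulationConfig,
    seed: int,
    latency_shifts_ms: Mapping[str, float] | None = None,
) -> SensorTimeseries:
    """Noise plus stimulus-locked patterns for every scheduled trial.

    Each row's ``states`` are embedded during the configured stimulus
    response window (raised-cosine envelope) scaled by the row's ``gains``.
    ``latency_shifts_ms`` optionally delays individual states' envelopes —
    used to stagger response latencies across representational dimensions.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    shifts = dict(latency_shifts_ms or {})
    trials: list[np.ndarray] = []
    for row in schedule.itertuples():
        n_samples = int(round(row.duration_s * cfg.fs))
        data = simulate_noise(
            bank.n_sensors, n_samples, cfg.ar_coefficient, cfg.noise_sd, rng
        )
        for state, gain in zip(row.states, row.gains):
            if state not in bank.patterns:
                raise KeyError(f"schedule state {state!r} missing from pattern bank")
            window = cfg.op_code_windows_ms.get(
                state_dimension(state), cfg.stim_window_ms
            )
            env = _stim_envelope(n_samples, cfg.fs, window, shifts.get(state, 0.0))
            data += gain * np.outer(bank[state], env)
        trials.append(data)
    run = str(schedule["kind"].iloc[0])
    run = {"object": "functional_localizer", "face": "functional_localizer"}.get(
        run, "operation_localizer" if run == "operation" else run
    )
    return SensorTimeseries(trials, cfg.fs, run, schedule.copy())


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def simulate_behavior(
    trials: Sequence[TrialSpec], cfg: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Simulate probe responses and thinking times.

    Error probability grows with program length and, for object-modality
    probes, with the number of branches (face modality: number of swaps).
    Thinking time grows with length and branch count and is clipped to the
    configured bounds.  Fills ``thinking_time_s`` on the trial specs and
    returns one row per probe.
    """
    rng = np.random.default_rng(seed)
    lo, hi = cfg.tt_bounds_s
    rows = []
    for trial in trials:
        tt = (
            cfg.tt_base_s
            + cfg.tt_per_length_s * (trial.length - 3)
            + cfg.tt_per_branch_s * trial.trace.n_branch
            + rng.normal(scale=cfg.tt_sd_s)
        )
        trial.thinking_time_s = float(np.clip(tt, lo, hi))
        for i, probe in enumerate(trial.probes):
            p_err = cfg.base_error + cfg.error_per_length * (trial.length - 3)
            if probe.modality == "object":
                p_err += cfg.error_per_branch * trial.trace.n_branch
            else:
                p_err += cfg.error_per_swap * trial.trace.n_swap
            p_err = float(np.clip(p_err, 0.0, 0.95))
            correct = bool(rng.random() >= p_err)
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "probe_index": i,
                    "q_type": probe.q_type,
                    "modality": probe.modality,
                    "depth_of_probe": probe.depth_of_probe,
                    "attribute_distance": probe.attribute_distance,
                    "is_match": probe.is_match,
                    "correct": correct,
                    "thinking_time_s": trial.thinking_time_s,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reasoning run with injected replay
# ---------------------------------------------------------------------------

LOG_COLUMNS = (
    "trial",
    "event",
    "kind",
    "state",
    "sample",
    "duration",
    "gain",
    "link",
    "lag_ms",
    "direction",
    "position",
)


def position_pattern(bank: PatternBank, state: str, position: int) -> np.ndarray:
    """Deterministic sparse pattern for a (location, path position) pair.

    The sustained RSA pattern is position-dependent: each (location,
    aligned-position) conjunction gets its own independent sparse pattern,
    so two trials share sustained signal only where they hold the same
    location at the same aligned path position.  (Sign-flipping one shared
    pattern would not work: with ~10 active sensors the chance correlation
    between two sign-codings of the same pattern is often large.)
    """
    key = zlib.crc32(f"{state}|{position}".encode("utf8"))
    rng = np.random.default_rng(np.random.SeedSequence([bank.seed, key]))
    k = max(1, int(round(bank.active_fraction * bank.n_sensors)))
    vec = np.zeros(bank.n_sensors)
    active = rng.choice(bank.n_sensors, size=k, replace=False)
    vec[active] = bank.amplitude * rng.normal(size=k)
    return vec


def _draw_lag_samples(rng, cfg: SimulationConfig, link: str) -> tuple[int, float]:
    """Sample a link lag; returns (samples, ms actually used)."""
    mean = cfg.lag_means_ms[link]
    sd = cfg.lag_sds_ms.get(link, 0.0)
    ms = mean if sd == 0 else max(0.0, rng.normal(mean, sd))
    samples = int(round(ms / cfg.ms_per_sample))
    return samples, samples * cfg.ms_per_sample


def simulate_reasoning(
    bank: PatternBank,
    trials: Sequence[TrialSpec],
    cfg: SimulationConfig,
    seed: int,
) -> tuple[SensorTimeseries, pd.DataFrame]:
    """Reasoning-run data with injected replay chains and an exhaustive log.

    Per trial, ``events_per_trial`` replay events are placed at random times.
    An event is a chain of the trial's correct-path location patterns at the
    object-to-object lag (order reversed for backward replay); every
    location is accompanied by its operation-type, operation-attribute and
    compound-operation patterns at their own lags, and — for swap steps
    only — by the post-update face-value ("output") pattern at the
    operation-to-data lag after the compound pattern.  A sustained path
    pattern (sum of non-start path-location patterns) is added in the final
    ``rsa_end_window_s`` of each trial and in a short window after each
    event.  The returned log has one row per injected component and fully
    determines the clean signal (see :func:`reconstruct_injections`).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    kernel = _transient_kernel(cfg.fs, cfg.transient_ms)
    nk = len(kernel)
    data_trials: list[np.ndarray] = []
    log_rows: list[dict] = []
    meta_rows: list[dict] = []

    for trial in trials:
        tt = trial.thinking_time_s if trial.thinking_time_s is not None else 8.0
        n_samples = int(round(tt * cfg.fs))
        noise_seed = int(rng.integers(2**31 - 1))
        noise = simulate_noise(
            bank.n_sensors, n_samples, cfg.ar_coefficient, cfg.noise_sd, noise_seed
        )
        signal = np.zeros_like(noise)

        def add_transient(state, sample, gain, *, event, kind, link, lag_ms):
            end = min(sample + nk, n_samples)
            if sample < 0 or sample >= n_samples:
                return
            signal[:, sample:end] += gain * np.outer(bank[state], kernel[: end - sample])
            log_rows.append(
                dict(
                    trial=trial.trial_id,
                    event=event,
                    kind=kind,
                    state=state,
                    sample=sample,
                    duration=end - sample,
                    gain=gain,
                    link=link,
                    lag_ms=lag_ms,
                    direction=cfg.replay_direction,
                    position=-1,
                )
            )

        def add_sustained(state, sample, duration, gain, *, event, kind, position):
            a = max(sample, 0)
            b = min(sample + duration, n_samples)
            if b <= a:
                return
            vec = position_pattern(bank, state, position)
            signal[:, a:b] += gain * vec[:, None]
            log_rows.append(
                dict(
                    trial=trial.trial_id,
                    event=event,
                    kind=kind,
                    state=state,
                    sample=a,
                    duration=b - a,
                    gain=gain,
                    link="",
                    lag_ms=np.nan,
                    direction="",
                    position=position,
                )
            )

        # on-screen start stimulus
        if cfg.reasoning_stimulus:
            env = _stim_envelope(n_samples, cfg.fs, cfg.stim_window_ms)
            stim_states = (trial.start_location,) + tuple(
                trial.start_face.value(a) for a in ATTRIBUTES
            )
            for state in stim_states:
                signal += cfg.amplitude * np.outer(bank[state], env)
                log_rows.append(
                    dict(
                        trial=trial.trial_id,
                        event=-1,
                        kind="stim",
                        state=state,
                        sample=0,
                        duration=n_samples,
                        gain=cfg.amplitude,
                        link="",
                        lag_ms=np.nan,
                        direction="",
                        position=-1,
                    )
                )

        # replay events
        steps = list(trial.trace.steps)
        if cfg.replay_direction == "backward":
            steps = steps[::-1]
        rsa_a = int(round(cfg.rsa_event_window_ms[0] / 1000 * cfg.fs))
        rsa_b = int(round(cfg.rsa_event_window_ms[1] / 1000 * cfg.fs))
        # (location, aligned position tag) pairs carrying the sustained
        # pattern; tags use first/middle/last coordinates so that paths of
        # different lengths share codes exactly where the position-dependent
        # similarity model aligns them
        last = len(trial.path) - 1
        path_states = [
            (loc, 1 if p == 1 else (3 if p == last else 2))
            for p, loc in enumerate(trial.path)
            if p >= 1 and (
                cfg.rsa_positions == "all"
                or (cfg.rsa_positions == "shallow" and p == 1)
                or (cfg.rsa_positions == "deep" and p >= 2)
            )
        ]

        for event in range(cfg.events_per_trial):
            # draw per-link lags for this event
            chain: list[tuple] = []  # (state, offset, link, lag_ms, kind)
            offset = 0
            ok = True
            for k, step in enumerate(steps):
                if k > 0:
                    d, ms = _draw_lag_samples(rng, cfg, "obj_obj")
                    if d == 0:
                        d = 1
                    offset += d
                chain.append((step.location, offset, "obj_obj" if k else "", np.nan, "seq"))
                for link, state in (
                    ("loc_type", step.operation.op_type),
                    ("loc_attr", step.operation.attribute),
                    ("loc_op", step.operation.name),
                ):
                    d, ms = _draw_lag_samples(rng, cfg, link)
                    chain.append((state, offset + d, link, ms, "seq"))
                    if link == "loc_op" and step.operation.op_type == "swap":
                        d2, ms2 = _draw_lag_samples(rng, cfg, "op_data")
                        out_state = step.face_after.value(step.operation.attribute)
                        chain.append(
                            (out_state, offset + d + d2, "op_data", ms2, "seq")
                        )
            span = max(off for _, off, *_ in chain) + nk
            min_start = int(round(cfg.event_min_onset_s * cfg.fs))
            max_start = n_samples - span - rsa_b - 1
            if max_start <= min_start:
                raise RuntimeError(
                    f"trial {trial.trial_id}: replay chain span {span} samples "
                    f"does not fit in {n_samples} trial samples"
                )
            start = int(rng.integers(min_start, max_start))
            for state, off, link, lag_ms, kind in chain:
                add_transient(
                    state,
                    start + off,
                    cfg.replay_amplitude,
                    event=event,
                    kind=kind,
                    link=link,
                    lag_ms=lag_ms,
                )
            # sustained path pattern shortly after the event
            chain_end = start + span
            for state, pos in path_states:
                add_sustained(
                    state,
                    chain_end + rsa_a,
                    rsa_b - rsa_a,
                    cfg.rsa_pattern_gain,
                    event=event,
                    kind="rsa_event",
                    position=pos,
                )

        # sustained path pattern in the final window of the trial
        end_samples = int(round(cfg.rsa_end_window_s * cfg.fs))
        for state, pos in path_states:
            add_sustained(
                state,
                n_samples - end_samples,
                end_samples,
                cfg.rsa_pattern_gain,
                event=-1,
                kind="rsa_end",
                position=pos,
            )

        data_trials.append(noise + signal)
        meta_rows.append(
            {
                "trial": trial.trial_id,
                "start_location": trial.start_location,
                "start_face": trial.start_face.name,
                "path": ">".join(trial.path),
                "length": trial.length,
                "n_samples": n_samples,
                "thinking_time_s": tt,
                "noise_seed": noise_seed,
            }
        )

    log = pd.DataFrame(log_rows, columns=list(LOG_COLUMNS))
    meta = pd.DataFrame(meta_rows)
    return SensorTimeseries(data_trials, cfg.fs, "reasoning", meta), log


def reconstruct_injections(
    bank: PatternBank,
    log: pd.DataFrame,
    trial_lengths: Mapping[int, int],
    cfg: SimulationConfig,
) -> dict[int, np.ndarray]:
    """Rebuild the clean injected signal per trial from the log.

    The result added to the (seed-reproducible) noise equals the generated
    data exactly; used to assert ground-truth completeness.
    """
    kernel = _transient_kernel(cfg.fs, cfg.transient_ms)
    out = {
        t: np.zeros((bank.n_sensors, n)) for t, n in trial_lengths.items()
    }
    for row in log.itertuples():
        sig = out[row.trial]
        n_samples = sig.shape[1]
        if row.kind == "seq":
            sig[:, row.sample : row.sample + row.duration] += row.gain * np.outer(
                bank[row.state], kernel[: row.duration]
            )
        elif row.kind == "stim":
            env = _stim_envelope(n_samples, cfg.fs, cfg.stim_window_ms)
            sig += row.gain * np.outer(bank[row.state], env)
        else:  # sustained rsa windows, position-tagged
            vec = position_pattern(bank, row.state, int(row.position))
            sig[:, row.sample : row.sample + row.duration] += row.gain * vec[:, None]
    return out
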