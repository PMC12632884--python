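"""Deterministic program-execution task world.

A task world is a directed graph of 12 locations plus a terminal ``END``
token.  Each location carries one of six operations — a *swap* or a
*branch* over one of three binary face attributes — and each operation is
assigned to exactly two locations.  Executing a program from a (start
location, start face) pair walks the graph deterministically: swap steps
flip the operated attribute and have a single successor, branch steps
leave the face untouched and choose their successor by the current value
of the operated attribute.

This module generates valid worlds, executes programs, samples trial
tables with probe questions, and derives the model quantities used by the
downstream analyses (path similarity matrices, trial-wise transition
matrices, behavioral summaries).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

END = "END"

OP_TYPES = ("swap", "branch")
ATTRIBUTES = ("shape", "limb", "hat")
ATTRIBUTE_VALUES: Mapping[str, tuple[str, str]] = {
    "shape": ("round", "spiky"),
    "limb": ("hands", "feet"),
    "hat": ("crown", "fedora"),
}

DEFAULT_N_LOCATIONS = 12
DEFAULT_LENGTH_SET = frozenset({3, 4})
DEFAULT_MAX_DEPTH = 8


@dataclass(frozen=True)
class OperationSpec:
    """One of the six (op_type, attribute) operations."""

    op_type: str
    attribute: str

    def __post_init__(self) -> None:
        if self.op_type not in OP_TYPES:
            raise ValueError(f"unknown op_type {self.op_type!r}")
        if self.attribute not in ATTRIBUTES:
            raise ValueError(f"unknown attribute {self.attribute!r}")

    @property
    def name(self) -> str:
        return f"{self.op_type}_{self.attribute}"

    @classmethod
    def from_name(cls, name: str) -> "OperationSpec":
        op_type, _, attribute = name.partition("_")
        return cls(op_type, attribute)


#: All six operations, in a canonical order.
ALL_OPERATIONS: tuple[OperationSpec, ...] = tuple(
    OperationSpec(t, a) for t in OP_TYPES for a in ATTRIBUTES
)


@dataclass(frozen=True)
class FaceState:
    """A 3-bit face: one binary value per attribute (shape, limb, hat)."""

    shape: str
    limb: str
    hat: str

    def __post_init__(self) -> None:
        for attr in ATTRIBUTES:
            if getattr(self, attr) not in ATTRIBUTE_VALUES[attr]:
                raise ValueError(f"invalid value {getattr(self, attr)!r} for {attr}")

    def value(self, attribute: str) -> str:
        return getattr(self, attribute)

    def swapped(self, attribute: str) -> "FaceState":
        """Return a copy with ``attribute`` flipped to its other value."""
        lo, hi = ATTRIBUTE_VALUES[attribute]
        new = hi if self.value(attribute) == lo else lo
        return replace(self, **{attribute: new})

    def hamming(self, other: "FaceState") -> int:
        return sum(self.value(a) != other.value(a) for a in ATTRIBUTES)

    @property
    def name(self) -> str:
        return "-".join(self.value(a) for a in ATTRIBUTES)

    @classmethod
    def from_name(cls, name: str) -> "FaceState":
        return cls(*name.split("-"))


#: All eight faces (2 x 2 x 2), canonical order.
ALL_FACES: tuple[FaceState, ...] = tuple(
    FaceState(s, l, h)
    for s in ATTRIBUTE_VALUES["shape"]
    for l in ATTRIBUTE_VALUES["limb"]
    for h in ATTRIBUTE_VALUES["hat"]
)


@dataclass
class TaskGraph:
    """The program world: locations, their operations, and successors.

    ``succ_swap`` maps each swap location to its single successor
    (a location or :data:`END`); ``succ_branch`` maps each branch location
    to a value->successor table over the operated attribute's two values.
    """

    locations: tuple[str, ...]
    op_of: dict[str, OperationSpec]
    succ_swap: dict[str, str]
    succ_branch: dict[str, dict[str, str]]
    max_depth: int = DEFAULT_MAX_DEPTH
    seed: int | None = None

    def __post_init__(self) -> None:
        self.locations = tuple(self.locations)

    def operation(self, location: str) -> OperationSpec:
        return self.op_of[location]

    def successors(self, location: str) -> tuple[str, ...]:
        op = self.op_of[location]
        if op.op_type == "swap":
            return (self.succ_swap[location],)
        table = self.succ_branch[location]
        return tuple(table[v] for v in ATTRIBUTE_VALUES[op.attribute])

    def edges(self, include_end: bool = False) -> set[tuple[str, str]]:
        """All distinct directed edges; END targets excluded by default."""
        out: set[tuple[str, str]] = set()
        for loc in self.locations:
            for succ in self.successors(loc):
                if succ != END or include_end:
                    out.add((loc, succ))
        return out

    def index(self, location: str) -> int:
        return self.locations.index(location)

    def validate(self) -> None:
        """Raise ``ValueError`` on any structural invariant violation."""
        if len(set(self.locations)) != len(self.locations):
            raise ValueError("duplicate locations")
        counts: dict[str, int] = {}
        for loc in self.locations:
            counts[self.op_of[loc].name] = counts.get(self.op_of[loc].name, 0) + 1
        expected = len(self.locations) // len(ALL_OPERATIONS)
        if sorted(counts) != sorted(op.name for op in ALL_OPERATIONS) or any(
            c != expected for c in counts.values()
        ):
            raise ValueError(f"operations not balanced: {counts}")
        for loc in self.locations:
            op = self.op_of[loc]
            if op.op_type == "swap":
                if loc not in self.succ_swap:
                    raise ValueError(f"swap location {loc} lacks a successor")
            else:
                table = self.succ_branch.get(loc)
                if table is None or set(table) != set(ATTRIBUTE_VALUES[op.attribute]):
                    raise ValueError(f"branch location {loc} has bad successor table")
                if len(set(table.values())) != 2:
                    raise ValueError(f"branch location {loc} successors not distinct")
        # termination over the full (start, face) product
        for start, face in itertools.product(self.locations, ALL_FACES):
            execute_program(self, start, face)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "locations": list(self.locations),
            "end_token": END,
            "op_of": {loc: op.name for loc, op in self.op_of.items()},
            "succ_swap": dict(self.succ_swap),
            "succ_branch": {loc: dict(t) for loc, t in self.succ_branch.items()},
            "max_depth": self.max_depth,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskGraph":
        return cls(
            locations=tuple(d["locations"]),
            op_of={loc: OperationSpec.from_name(n) for loc, n in d["op_of"].items()},
            succ_swap=dict(d["succ_swap"]),
            succ_branch={loc: dict(t) for loc, t in d["succ_branch"].items()},
            max_depth=d.get("max_depth", DEFAULT_MAX_DEPTH),
            seed=d.get("seed"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TaskGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class Step:
    """One executed operation: where, what, and the face before/after."""

    location: str
    operation: OperationSpec
    face_before: FaceState
    face_after: FaceState
    next: str  # location or END


@dataclass(frozen=True)
class ExecutionTrace:
    """The unique execution path of one (graph, start, face) triple."""

    steps: tuple[Step, ...]

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def path(self) -> tuple[str, ...]:
        return tuple(s.location for s in self.steps)

    @property
    def faces(self) -> tuple[FaceState, ...]:
        """Face state on arrival at each path location."""
        return tuple(s.face_before for s in self.steps)

    @property
    def final_face(self) -> FaceState:
        return self.steps[-1].face_after

    @property
    def n_branch(self) -> int:
        return sum(s.operation.op_type == "branch" for s in self.steps)

    @property
    def n_swap(self) -> int:
        return sum(s.operation.op_type == "swap" for s in self.steps)


def execute_program(graph: TaskGraph, start: str, face: FaceState) -> ExecutionTrace:
    """Deterministically execute the program starting at ``start`` with ``face``.

    Swap steps flip exactly the operation's attribute; branch steps pick the
    successor keyed by the current value of the operation's attribute and
    leave the face unchanged.  Raises ``RuntimeError`` if END is not reached
    within ``graph.max_depth`` steps (an invalid graph).
    """
    if start not in graph.locations:
        raise ValueError(f"unknown start location {start!r}")
    steps: list[Step] = []
    loc = start
    while loc != END:
        if len(steps) >= graph.max_depth:
            raise RuntimeError(
                f"execution from ({start}, {face.name}) exceeded max_depth="
                f"{graph.max_depth} without reaching END"
            )
        op = graph.op_of[loc]
        if op.op_type == "swap":
            new_face = face.swapped(op.attribute)
            nxt = graph.succ_swap[loc]
        else:
            new_face = face
            nxt = graph.succ_branch[loc][face.value(op.attribute)]
        steps.append(Step(loc, op, face, new_face, nxt))
        face = new_face
        loc = nxt
    return ExecutionTrace(tuple(steps))


def _default_location_names(n: int) -> tuple[str, ...]:
    return tuple(f"obj{i:02d}" for i in range(n))


def generate_task_graph(
    seed: int,
    n_locations: int = DEFAULT_N_LOCATIONS,
    length_set: Iterable[int] = DEFAULT_LENGTH_SET,
    max_depth: int = DEFAULT_MAX_DEPTH,
    location_names: Sequence[str] | None = None,
    max_attempts: int = 5000,
) -> TaskGraph:
    """Generate a valid task graph by seeded rejection sampling.

    Locations are placed on a random linear order and successors always point
    to strictly later locations (or END), which guarantees termination; a
    candidate is accepted when every one of the ``n_locations x 8`` (start,
    face) executions terminates within ``max_depth`` and every length in
    ``length_set`` is realized by at least one execution.
    """
    length_set = frozenset(length_set)
    if n_locations % len(ALL_OPERATIONS):
        raise ValueError("n_locations must be a multiple of 6")
    if not length_set:
        raise ValueError("length_set must be non-empty")
    names = (
        tuple(location_names)
        if location_names is not None
        else _default_location_names(n_locations)
    )
    if len(names) != n_locations:
        raise ValueError("location_names length mismatch")
    rng = np.random.default_rng(seed)
    per_op = n_locations // len(ALL_OPERATIONS)

    for _ in range(max_attempts):
        order = list(rng.permutation(n_locations))
        ordered = [names[i] for i in order]
        op_pool = [op for op in ALL_OPERATIONS for _ in range(per_op)]
        rng.shuffle(op_pool)  # type: ignore[arg-type]
        op_of = dict(zip(ordered, op_pool))

        succ_swap: dict[str, str] = {}
        succ_branch: dict[str, dict[str, str]] = {}
        ok = True
        for rank, loc in enumerate(ordered):
            later = ordered[rank + 1 :]
            op = op_of[loc]
            if op.op_type == "swap":
                choices = later + [END]
                succ_swap[loc] = choices[rng.integers(len(choices))]
            else:
                # two distinct successors, at most one of which is END
                if not later:
                    ok = False
                    break
                choices = later + [END]
                pick = list(rng.choice(len(choices), size=2, replace=False))
                targets = [choices[i] for i in pick]
                vals = ATTRIBUTE_VALUES[op.attribute]
                succ_branch[loc] = dict(zip(vals, targets))
        if not ok:
            continue

        graph = TaskGraph(
            locations=names,
            op_of=op_of,
            succ_swap=succ_swap,
            succ_branch=succ_branch,
            max_depth=max_depth,
            seed=seed,
        )
        lengths = set()
        try:
            for start, face in itertools.product(names, ALL_FACES):
                lengths.add(execute_program(graph, start, face).length)
        except RuntimeError:
            continue
        if length_set <= lengths:
            return graph
    raise RuntimeError(
        f"no valid graph found in {max_attempts} attempts; "
        "parameters are likely over-constrained"
    )


@dataclass(frozen=True)
class ProbeQuestion:
    """One END or PATH probe with its ground-truth answer."""

    q_type: str  # "END" | "PATH"
    modality: str  # "object" | "face"
    probe_stimulus: str  # location name or face name
    is_match: bool
    correct_response: str  # "accept" | "reject"
    depth_of_probe: str  # "shallow" | "deep" | "end"
    attribute_distance: int | None = None  # face probes only (0-3)

    def __post_init__(self) -> None:
        expected = "accept" if self.is_match else "reject"
        if self.correct_response != expected:
            raise ValueError("correct_response inconsistent with is_match")


@dataclass
class TrialSpec:
    """One reasoning trial: start pair, its unique trace, and two probes."""

    trial_id: int
    start_location: str
    start_face: FaceState
    trace: ExecutionTrace
    probes: tuple[ProbeQuestion, ProbeQuestion] | None = None
    thinking_time_s: float | None = None

    @property
    def length(self) -> int:
        return self.trace.length

    @property
    def path(self) -> tuple[str, ...]:
        return self.trace.path


def _probe_positions(trace: ExecutionTrace) -> list[int]:
    """Path positions eligible for a PATH probe (start and final excluded)."""
    return list(range(1, trace.length - 1))


def generate_probes(trial: TrialSpec, seed: int) -> tuple[ProbeQuestion, ProbeQuestion]:
    """Attach one END and one PATH probe, shared modality, random order.

    Probes match the correct path with probability 0.5.  Face probes record
    the Hamming distance between the probed face and the correct face
    (0 for matches); PATH probes record whether they target a shallow
    (first successor) or deep element.
    """
    trace = trial.trace
    if trace.length < 3:
        raise ValueError("trial trace too short for probing")
    rng = np.random.default_rng(seed)
    modality = "object" if rng.random() < 0.5 else "face"
    all_locs = _all_locations_from_trace(trial)

    def face_probe(correct: FaceState, depth: str) -> ProbeQuestion:
        is_match = bool(rng.random() < 0.5)
        if is_match:
            probe, dist = correct, 0
        else:
            dist = int(rng.integers(1, len(ATTRIBUTES) + 1))
            flips = rng.choice(len(ATTRIBUTES), size=dist, replace=False)
            probe = correct
            for i in flips:
                probe = probe.swapped(ATTRIBUTES[i])
        return ProbeQuestion(
            q_type="END" if depth == "end" else "PATH",
            modality="face",
            probe_stimulus=probe.name,
            is_match=is_match,
            correct_response="accept" if is_match else "reject",
            depth_of_probe=depth,
            attribute_distance=dist,
        )

    def object_probe(correct: str, depth: str) -> ProbeQuestion:
        is_match = bool(rng.random() < 0.5)
        if is_match:
            probe = correct
        else:
            off_path = [l for l in all_locs if l not in trace.path]
            probe = off_path[rng.integers(len(off_path))]
        return ProbeQuestion(
            q_type="END" if depth == "end" else "PATH",
            modality="object",
            probe_stimulus=probe,
            is_match=is_match,
            correct_response="accept" if is_match else "reject",
            depth_of_probe=depth,
        )

    positions = _probe_positions(trace)
    pos = positions[rng.integers(len(positions))]
    depth = "shallow" if pos == 1 else "deep"
    if modality == "object":
        end_probe = object_probe(trace.path[-1], "end")
        path_probe = object_probe(trace.path[pos], depth)
    else:
        end_probe = face_probe(trace.final_face, "end")
        path_probe = face_probe(trace.faces[pos], depth)
    probes = (end_probe, path_probe)
    if rng.random() < 0.5:
        probes = (path_probe, end_probe)
    return probes


def _all_locations_from_trace(trial: TrialSpec) -> tuple[str, ...]:
    # the graph's location set is recoverable from context; trials keep a
    # reference when sampled via sample_trials
    graph = getattr(trial, "_graph", None)
    if graph is not None:
        return graph.locations
    return _default_location_names(DEFAULT_N_LOCATIONS)


def sample_trials(
    graph: TaskGraph,
    n_trials: int,
    seed: int,
    length_set: Iterable[int] = DEFAULT_LENGTH_SET,
    with_replacement: bool = True,
) -> list[TrialSpec]:
    """Sample a trial table of (start location, start face) pairs.

    Pairs are drawn uniformly from those whose execution trace length lies
    in ``length_set``; immediate repetitions of the same pair are forbidden.
    Each trial gets one END and one PATH probe.
    """
    length_set = frozenset(length_set)
    rng = np.random.default_rng(seed)
    admissible: list[tuple[str, FaceState, ExecutionTrace]] = []
    for start, face in itertools.product(graph.locations, ALL_FACES):
        trace = execute_program(graph, start, face)
        if trace.length in length_set:
            admissible.append((start, face, trace))
    if not admissible:
        raise RuntimeError("no admissible (start, face) pairs for the length set")
    if not with_replacement and n_trials > len(admissible):
        raise ValueError(
            f"requested {n_trials} trials without replacement but only "
            f"{len(admissible)} admissible pairs exist"
        )

    trials: list[TrialSpec] = []
    if with_replacement:
        prev = -1
        for t in range(n_trials):
            while True:
                i = int(rng.integers(len(admissible)))
                if i != prev or len(admissible) == 1:
                    break
            prev = i
            start, face, trace = admissible[i]
            trials.append(TrialSpec(t, start, face, trace))
    else:
        order = rng.permutation(len(admissible))[:n_trials]
        for t, i in enumerate(order):
            start, face, trace = admissible[int(i)]
            trials.append(TrialSpec(t, start, face, trace))

    probe_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    for trial in trials:
        trial._graph = graph  # type: ignore[attr-defined]
        trial.probes = generate_probes(trial, int(probe_seeds[trial.trial_id]))
    return trials


# ---------------------------------------------------------------------------
# path similarity
# ---------------------------------------------------------------------------

SIMILARITY_MODES = ("program", "object", "shallow", "deep", "face_path", "length_diff")


def _aligned_pairs(la: int, lb: int, strict: bool = False) -> list[tuple[int, int]]:
    """Position pairs compared between two start-excluded paths.

    Default alignment: first with first, last with last, middles pairwise in
    order; an unmatched middle slot of the longer path is ignored.  With
    ``strict`` the paths are compared position-by-position up to the shorter
    length.
    """
    if la == 0 or lb == 0:
        return []
    if strict:
        return [(i, i) for i in range(min(la, lb))]
    if la == lb:
        return [(i, i) for i in range(la)]
    m = min(la, lb)
    pairs = [(0, 0)]
    pairs += [(i, i) for i in range(1, m - 1)]
    if m > 1:
        pairs.append((la - 1, lb - 1))
    return pairs


def path_similarity(
    trials: Sequence[TrialSpec],
    mode: str,
    strict_positions: bool = False,
) -> np.ndarray:
    """Trial-by-trial similarity matrix for the requested ``mode``.

    program
        position-dependent count of shared locations, start excluded.
    object
        position-independent overlap (set intersection), start excluded.
    shallow / deep
        program similarity restricted to the first successor of the start,
        or to everything after it.
    face_path
        position-dependent count of matching full face states along the
        path, start location's face excluded.
    length_diff
        absolute difference of trace lengths.
    """
    if not trials:
        raise ValueError("empty trial list")
    if mode not in SIMILARITY_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(trials)
    out = np.zeros((n, n))
    # start-excluded paths and face sequences
    paths = [t.path[1:] for t in trials]
    faces = [tuple(f.name for f in t.trace.faces[1:]) for t in trials]
    lengths = [t.length for t in trials]

    for a in range(n):
        for b in range(a, n):
            if mode == "length_diff":
                v = abs(lengths[a] - lengths[b])
            elif mode == "object":
                v = len(set(paths[a]) & set(paths[b]))
            else:
                pa = faces[a] if mode == "face_path" else paths[a]
                pb = faces[b] if mode == "face_path" else paths[b]
                pairs = _aligned_pairs(len(pa), len(pb), strict=strict_positions)
                if mode == "shallow":
                    pairs = [(i, j) for i, j in pairs if i == 0 and j == 0]
                elif mode == "deep":
                    pairs = [(i, j) for i, j in pairs if i >= 1 and j >= 1]
                v = sum(pa[i] == pb[j] for i, j in pairs)
            out[a, b] = out[b, a] = v
    return out


def transition_matrices(
    graph: TaskGraph, trial: TrialSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-wise (correct, incorrect) 12x12 binary transition matrices.

    ``correct[i, j] = 1`` for each consecutive path pair i -> j (END
    excluded); ``incorrect`` holds every other location-to-location edge of
    the graph.  The two matrices are disjoint by construction.
    """
    n = len(graph.locations)
    idx = {loc: i for i, loc in enumerate(graph.locations)}
    correct = np.zeros((n, n))
    for a, b in zip(trial.path[:-1], trial.path[1:]):
        correct[idx[a], idx[b]] = 1.0
    incorrect = np.zeros((n, n))
    for a, b in graph.edges():
        incorrect[idx[a], idx[b]] = 1.0
    incorrect[correct > 0] = 0.0
    return correct, incorrect


def path_link_matrices(
    graph: TaskGraph, trial: TrialSpec, which: str
) -> np.ndarray:
    """Shallow or deep sub-matrix of the trial's correct transition matrix.

    The shallow link is the edge out of the on-screen start location; deep
    links are all later edges of the correct path.
    """
    n = len(graph.locations)
    idx = {loc: i for i, loc in enumerate(graph.locations)}
    out = np.zeros((n, n))
    links = list(zip(trial.path[:-1], trial.path[1:]))
    if which == "shallow":
        links = links[:1]
    elif which == "deep":
        links = links[1:]
    else:
        raise ValueError(f"which must be 'shallow' or 'deep', got {which!r}")
    for a, b in links:
        out[idx[a], idx[b]] = 1.0
    return out


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def trials_to_frame(trials: Sequence[TrialSpec]) -> pd.DataFrame:
    """One row per trial: start pair, path, lengths, counts, thinking time."""
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "start_location": t.start_location,
                "start_face": t.start_face.name,
                "path": ">".join(t.path),
                "length": t.length,
                "n_branch": t.trace.n_branch,
                "n_swap": t.trace.n_swap,
                "thinking_time_s": t.thinking_time_s,
            }
        )
    return pd.DataFrame(rows)


def _within_length_slope(df: pd.DataFrame, x: str, y: str) -> float:
    """OLS slope of y on x computed within each length, then averaged."""
    slopes = []
    for _, g in df.groupby("length"):
        if g[x].nunique() < 2:
            continue
        xv = g[x].to_numpy(float)
        yv = g[y].to_numpy(float)
        slopes.append(np.polyfit(xv, yv, 1)[0])
    return float(np.mean(slopes)) if slopes else float("nan")


def behavioral_summary(
    trials: Sequence[TrialSpec], responses: pd.DataFrame
) -> dict[str, pd.DataFrame | float]:
    """Summarize probe accuracy and thinking time.

    ``responses`` has one row per probe with columns ``trial_id``,
    ``q_type``, ``modality``, ``depth_of_probe``, ``attribute_distance``,
    ``correct`` plus a per-trial ``thinking_time_s``.  Quantities that
    depend on path composition (branch/swap counts) are first computed
    across trials of identical program length and then averaged across
    lengths.
    """
    meta = trials_to_frame(trials).drop(columns=["thinking_time_s"])
    df = responses.merge(meta, on="trial_id", how="left", suffixes=("", "_meta"))
    lengths = sorted(df["length"].unique())
    for length in DEFAULT_LENGTH_SET:
        if length in set(l for t in trials for l in [t.length]) and length not in lengths:
            raise ValueError(f"no responses for program length {length}")
    if df["correct"].isna().any():
        raise ValueError("responses contain missing correctness values")

    by_qtype_modality = (
        df.groupby(["q_type", "modality"])["correct"].mean().rename("accuracy").reset_index()
    )
    per_trial = df.groupby("trial_id").agg(
        accuracy=("correct", "mean"),
        thinking_time_s=("thinking_time_s", "first"),
        length=("length", "first"),
    )
    by_length = per_trial.groupby("length").agg(
        accuracy=("accuracy", "mean"),
        thinking_time_s=("thinking_time_s", "mean"),
        n_trials=("accuracy", "size"),
    )
    if by_length["n_trials"].eq(0).any():
        raise ValueError("a program length has zero trials")

    probe_level = df.assign(correct=df["correct"].astype(float))
    branch_effect_acc = _within_length_slope(
        probe_level[(probe_level.q_type == "PATH") & (probe_level.modality == "object")],
        "n_branch",
        "correct",
    )
    swap_effect_acc = _within_length_slope(
        probe_level[probe_level.modality == "face"], "n_swap", "correct"
    )
    tt = per_trial.reset_index().merge(meta[["trial_id", "n_branch"]], on="trial_id")
    branch_effect_tt = _within_length_slope(tt, "n_branch", "thinking_time_s")

    path_obj = df[(df.q_type == "PATH") & (df.modality == "object")]
    depth_effect = (
        path_obj.groupby("depth_of_probe")["correct"].mean().rename("accuracy").reset_index()
    )
    end_face = df[(df.q_type == "END") & (df.modality == "face") & (~df.is_match)]
    attr_distance_effect = (
        end_face.groupby("attribute_distance")["correct"].mean().rename("accuracy").reset_index()
    )

    return {
        "accuracy_by_qtype_modality": by_qtype_modality,
        "by_length": by_length.reset_index(),
        "branch_effect_on_path_object_accuracy": branch_effect_acc,
        "swap_effect_on_face_accuracy": swap_effect_acc,
        "branch_effect_on_thinking_time": branch_effect_tt,
        "depth_effect": depth_effect,
        "attribute_distance_effect": attr_distance_effect,
        "overall_accuracy": float(df["correct"].mean()),
    }
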