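"""Temporally delayed linear modeling (TDLM) and replay-event analyses.

Two-stage GLM: stage 1 regresses every state's reactivation series at
``t + lag`` onto all states' series at ``t`` (per trial, per lag up to
200 ms), producing empirical transition matrices; stage 2 regresses the
vectorized empirical matrices on hypothesized transition structures while
controlling for the transposed structure, self-transitions, and a bias
term.  Permutation nulls shuffle the state identities of the theoretical
matrices — one relabeling applied coherently to every trial within a
shuffle — and the multiple-comparison threshold is the maximum over lags
of the null's 95th percentile.

Directionality: the *backward* curve is obtained by running the identical
forward machinery on time-reversed reactivations, which makes the
time-reversal identity (reversing the data exchanges forward and backward
betas) hold exactly; the transposed-structure beta of each run is also
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from progreplay._cluster import cluster_mass_mask
from progreplay.decoding import ReactivationMatrix
from progreplay.task import TaskGraph, TrialSpec, path_link_matrices, transition_matrices

DEFAULT_MAX_LAG_MS = 200.0


# ---------------------------------------------------------------------------
# first stage
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalTransitionTensor:
    """Per-trial (n_lags, S, S) first-stage coefficient matrices.

    ``tensors[k][l, i, j]`` is the coefficient of state ``i`` at time ``t``
    in the regression of state ``j``'s series at ``t + lag_l`` (trial k).
    """

    tensors: list[np.ndarray]
    lags_ms: np.ndarray
    states: tuple[str, ...]

    @property
    def n_lags(self) -> int:
        return len(self.lags_ms)

    @property
    def n_states(self) -> int:
        return len(self.states)


def first_stage(
    react: ReactivationMatrix,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    reverse_time: bool = False,
) -> EmpiricalTransitionTensor:
    """Empirical transition matrices at every lag, per trial.

    For each lag ``d`` (one bin per sample up to ``max_lag_ms``), each
    state's series at ``t + d`` is regressed onto all states' series at
    ``t`` plus an intercept; the slope coefficients form the lag-``d``
    matrix.  Raises on rank-deficient designs (constant series).
    """
    ms_per_sample = 1000 / react.fs
    max_lag = int(round(max_lag_ms / 1000 * react.fs))
    if max_lag < 1:
        raise ValueError("max_lag_ms shorter than one sample")
    lags_ms = np.arange(1, max_lag + 1) * ms_per_sample
    tensors = []
    for Y in react.trials:
        if reverse_time:
            Y = Y[::-1]
        T, S = Y.shape
        if T <= max_lag:
            raise ValueError(f"trial too short ({T} samples) for max lag {max_lag}")
        if np.any(np.ptp(Y, axis=0) == 0):
            raise ValueError("constant reactivation series: rank-deficient design")
        out = np.zeros((max_lag, S, S))
        for li, d in enumerate(range(1, max_lag + 1)):
            X = np.column_stack([Y[:-d], np.ones(T - d)])
            B, *_ = np.linalg.lstsq(X, Y[d:], rcond=None)
            out[li] = B[:-1]
        tensors.append(out)
    return EmpiricalTransitionTensor(tensors, lags_ms, react.states)


# ---------------------------------------------------------------------------
# second stage
# ---------------------------------------------------------------------------


def _stage2_design(theoreticals: Sequence[np.ndarray]) -> np.ndarray:
    """Columns: [T_k, T_k^T]..., identity, constant — all vectorized."""
    S = theoreticals[0].shape[0]
    cols = []
    for T in theoreticals:
        cols.append(T.ravel())
        cols.append(T.T.ravel())
    cols.append(np.eye(S).ravel())
    cols.append(np.ones(S * S))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear theoretical regressor set")
    return X


def second_stage(
    emp: EmpiricalTransitionTensor,
    theoreticals: Sequence[Sequence[np.ndarray]] | Sequence[np.ndarray],
) -> np.ndarray:
    """Per-trial stage-2 betas, shape (n_trials, n_lags, 2K + 2).

    ``theoreticals`` is either one matrix list shared by all trials or a
    per-trial list of matrix lists; for each theoretical matrix the design
    holds the matrix and its transpose, plus identity and constant columns.
    """
    n_trials = len(emp.tensors)
    per_trial = (
        theoreticals
        if theoreticals and isinstance(theoreticals[0], (list, tuple))
        else [theoreticals] * n_trials
    )
    if len(per_trial) != n_trials:
        raise ValueError("theoretical matrices do not match trial count")
    out = None
    for k, tensor in enumerate(emp.tensors):
        X = _stage2_design(per_trial[k])
        Y = tensor.reshape(emp.n_lags, -1).T  # (S², n_lags)
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)  # (n_cols, n_lags)
        if out is None:
            out = np.zeros((n_trials, emp.n_lags, X.shape[1]))
        out[k] = B.T
    return out


def neighbor_average(curve: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean of adjacent lag bins (length n-1 along ``axis``)."""
    a = np.take(curve, range(curve.shape[axis] - 1), axis=axis)
    b = np.take(curve, range(1, curve.shape[axis]), axis=axis)
    return (a + b) / 2.0


@dataclass
class SequencenessCurve:
    """Lag-resolved second-stage betas, forward and backward."""

    lags_ms: np.ndarray
    forward: np.ndarray  # (n_lags, K)
    backward: np.ndarray  # (n_lags, K) — forward machinery on reversed data
    regressor_names: tuple[str, ...]
    forward_transpose: np.ndarray | None = None
    backward_transpose: np.ndarray | None = None

    def averaged(self) -> "SequencenessCurve":
        return SequencenessCurve(
            neighbor_average(self.lags_ms),
            neighbor_average(self.forward),
            neighbor_average(self.backward),
            self.regressor_names,
        )

    def peak_lag_ms(self, direction: str = "backward", regressor: int = 0) -> float:
        curve = getattr(self, direction)[:, regressor]
        return float(self.lags_ms[int(np.argmax(curve))])


@dataclass
class NullDistribution:
    """State-relabeling null betas and the max-over-lag corrected threshold.

    The corrected threshold is the 95th percentile of each shuffle's
    maximum beta across lags, which calibrates the family-wise rate of the
    observed curve's peak against the many tested lags.
    """

    null_forward: np.ndarray  # (n_shuffles, n_lags)
    null_backward: np.ndarray
    lags_ms: np.ndarray
    percentile: float = 95.0

    @property
    def threshold_forward(self) -> float:
        return float(
            np.percentile(self.null_forward.max(axis=1), self.percentile)
        )

    @property
    def threshold_backward(self) -> float:
        return float(
            np.percentile(self.null_backward.max(axis=1), self.percentile)
        )

    def zscore(self, curve: np.ndarray, direction: str = "forward") -> np.ndarray:
        null = self.null_forward if direction == "forward" else self.null_backward
        sd = null.std(axis=0)
        sd[sd == 0] = 1.0
        return (curve - null.mean(axis=0)) / sd


def _random_permutations(
    n_states: int, n_shuffles: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct non-identity relabelings; exhaustive if the space is small."""
    import itertools as it
    import math

    total = math.factorial(n_states) - 1
    if total < n_shuffles:
        perms = [
            np.array(p)
            for p in it.permutations(range(n_states))
            if tuple(p) != tuple(range(n_states))
        ]
        return perms
    seen = {tuple(range(n_states))}
    out = []
    while len(out) < n_shuffles:
        p = tuple(rng.permutation(n_states))
        if p not in seen:
            seen.add(p)
            out.append(np.array(p))
    return out


def sequenceness(
    react: ReactivationMatrix,
    theoreticals,
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    regressor_names: tuple[str, ...] = ("structure",),
) -> tuple[SequencenessCurve, EmpiricalTransitionTensor, EmpiricalTransitionTensor]:
    """Forward and backward sequenceness curves averaged across trials."""
    emp_f = first_stage(react, max_lag_ms)
    emp_b = first_stage(react, max_lag_ms, reverse_time=True)
    bf = second_stage(emp_f, theoreticals).mean(axis=0)
    bb = second_stage(emp_b, theoreticals).mean(axis=0)
    K = (bf.shape[1] - 2) // 2
    curve = SequencenessCurve(
        lags_ms=emp_f.lags_ms,
        forward=bf[:, 0 : 2 * K : 2],
        backward=bb[:, 0 : 2 * K : 2],
        regressor_names=regressor_names,
        forward_transpose=bf[:, 1 : 2 * K : 2],
        backward_transpose=bb[:, 1 : 2 * K : 2],
    )
    return curve, emp_f, emp_b


def permutation_null(
    emp_forward: EmpiricalTransitionTensor,
    emp_backward: EmpiricalTransitionTensor,
    theoreticals,
    n_shuffles: int = 1000,
    seed: int = 0,
    regressor: int = 0,
) -> NullDistribution:
    """Null betas from coherent state relabelings of the theoretical matrices.

    Each shuffle draws one permutation of state identities (identity
    excluded), applies it to every trial's theoretical matrices, recomputes
    the second stage, and averages betas across trials.  The corrected
    threshold is the maximum over lags of the null's 95th percentile.
    """
    n_trials = len(emp_forward.tensors)
    per_trial = (
        theoreticals
        if theoreticals and isinstance(theoreticals[0], (list, tuple))
        else [theoreticals] * n_trials
    )
    rng = np.random.default_rng(seed)
    S = emp_forward.n_states
    perms = _random_permutations(S, n_shuffles, rng)
    n_lags = emp_forward.n_lags
    null_f = np.zeros((len(perms), n_lags))
    null_b = np.zeros((len(perms), n_lags))
    # flatten tensors once
    Yf = [t.reshape(n_lags, -1).T for t in emp_forward.tensors]
    Yb = [t.reshape(n_lags, -1).T for t in emp_backward.tensors]
    col = 2 * regressor
    for si, perm in enumerate(perms):
        acc_f = np.zeros(n_lags)
        acc_b = np.zeros(n_lags)
        for k in range(n_trials):
            theos = [T[np.ix_(perm, perm)] for T in per_trial[k]]
            X = _stage2_design(theos)
            XtX = X.T @ X
            Bf = np.linalg.solve(XtX, X.T @ Yf[k])
            Bb = np.linalg.solve(XtX, X.T @ Yb[k])
            acc_f += Bf[col]
            acc_b += Bb[col]
        null_f[si] = acc_f / n_trials
        null_b[si] = acc_b / n_trials
    return NullDistribution(null_f, null_b, emp_forward.lags_ms)


def combine_nulls(nulls: Sequence[NullDistribution]) -> NullDistribution:
    """Average shuffle-matched nulls across participants (same seed/perms)."""
    return NullDistribution(
        np.mean([n.null_forward for n in nulls], axis=0),
        np.mean([n.null_backward for n in nulls], axis=0),
        nulls[0].lags_ms,
        nulls[0].percentile,
    )


# ---------------------------------------------------------------------------
# entropy-style trial filter
# ---------------------------------------------------------------------------


def entropy_filter(
    react_trial: np.ndarray,
    path_indices: Sequence[int],
    bounds: tuple[float, float] = (0.025, 0.05),
) -> bool:
    """Keep a trial unless a correct-path state almost never reactivates.

    A state "reactivates" at a sample when it is the argmax across the
    object probabilities; the trial is dropped when any correct-path
    state's reactivation frequency falls below the lower bound.
    """
    winners = np.argmax(react_trial, axis=1)
    n = len(winners)
    for idx in set(path_indices):
        if np.count_nonzero(winners == idx) / n < bounds[0]:
            return False
    return True


def filter_trials(
    react: ReactivationMatrix,
    trials: Sequence[TrialSpec],
    graph: TaskGraph,
    bounds: tuple[float, float] = (0.025, 0.05),
) -> tuple[list[int], float]:
    """Indices of kept trials and the dropped fraction."""
    keep = []
    for i, trial in enumerate(trials):
        path_idx = [react.state_index(loc) for loc in trial.path]
        if entropy_filter(react.trials[i], path_idx, bounds):
            keep.append(i)
    return keep, 1.0 - len(keep) / len(trials)


# ---------------------------------------------------------------------------
# path-level wrapper
# ---------------------------------------------------------------------------


def path_sequenceness(
    react: ReactivationMatrix,
    graph: TaskGraph,
    trials: Sequence[TrialSpec],
    which: str = "correct",
    max_lag_ms: float = DEFAULT_MAX_LAG_MS,
    n_shuffles: int = 1000,
    seed: int = 0,
    entropy_bounds: tuple[float, float] | None = (0.025, 0.05),
    trial_subset: Sequence[int] | None = None,
) -> dict:
    """Sequenceness against trial-wise correct/incorrect/shallow/deep paths.

    Returns a dict with the curve, the permutation null (max-over-lag
    corrected), z-scored curves, and the entropy-filter drop fraction.
    """
    if trial_subset is not None:
        trials = [trials[i] for i in trial_subset]
        react = ReactivationMatrix(
            [react.trials[i] for i in trial_subset], react.states, react.fs
        )
    drop_fraction = 0.0
    if entropy_bounds is not None:
        keep, drop_fraction = filter_trials(react, trials, graph, entropy_bounds)
        trials = [trials[i] for i in keep]
        react = ReactivationMatrix(
            [react.trials[i] for i in keep], react.states, react.fs
        )
    if not trials:
        raise ValueError("no trials left after filtering")

    theos = []
    for trial in trials:
        if which in ("correct", "incorrect"):
            correct, incorrect = transition_matrices(graph, trial)
            theos.append([correct if which == "correct" else incorrect])
        elif which in ("shallow", "deep"):
            theos.append([path_link_matrices(graph, trial, which)])
        else:
            raise ValueError(f"unknown path kind {which!r}")

    curve, emp_f, emp_b = sequenceness(
        react, theos, max_lag_ms, regressor_names=(which,)
    )
    null = permutation_null(emp_f, emp_b, theos, n_shuffles=n_shuffles, seed=seed)
    return {
        "curve": curve,
        "null": null,
        "z_forward": null.zscore(curve.forward[:, 0], "forward"),
        "z_backward": null.zscore(curve.backward[:, 0], "backward"),
        "drop_fraction": drop_fraction,
        "n_trials": len(trials),
    }


def split_by_accuracy(
    per_participant_accuracy: Sequence[float],
) -> tuple[list[int], list[int]]:
    """Median split of participant indices by overall probe accuracy."""
    acc = np.asarray(per_participant_accuracy, dtype=float)
    med = np.median(acc)
    high = [i for i, a in enumerate(acc) if a > med]
    low = [i for i, a in enumerate(acc) if a <= med]
    return high, low


# ---------------------------------------------------------------------------
# multi-step TDLM
# ---------------------------------------------------------------------------


def multistep_regression(
    upstream: Sequence[np.ndarray],
    terminal: np.ndarray,
    lags: Sequence[int],
    extra_controls: Sequence[np.ndarray] = (),
) -> float:
    """Beta of the compound regressor for one chain on one trial.

    ``upstream[k]`` is the k-th chain series; ``lags[k]`` is the lag (in
    samples) from series k to series k+1 (the last entry leads to
    ``terminal``).  The compound regressor is the product of the upstream
    series at their cumulative lags; controls are each upstream series
    alone at its cumulative lag, the first (location) series at the
    missing-middle lag, any ``extra_controls``, and a constant.
    """
    if len(lags) != len(upstream):
        raise ValueError("need one lag per upstream series")
    total = int(np.sum(lags))
    T = len(terminal)
    if total >= T:
        raise ValueError("cumulative lags exceed trial length")
    n = T - total
    cum = np.concatenate([[0], np.cumsum(lags[:-1])]).astype(int)
    parts = [s[c : c + n] for s, c in zip(upstream, cum)]
    compound = np.prod(parts, axis=0)
    y = terminal[total : total + n]
    cols = [compound] + parts
    # location series shifted to where the middle element would sit
    if len(upstream) >= 2:
        miss = int(cum[1])
        cols.append(upstream[0][miss : miss + n])
    cols.extend([c[:n] for c in extra_controls])
    cols.append(np.ones(n))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[0])


def data_update_contrast(
    react: ReactivationMatrix,
    graph: TaskGraph,
    trials: Sequence[TrialSpec],
    loc_op_lag_ms: float,
    scan_lags_ms: Sequence[float] | None = None,
    step_type: str = "swap",
    op_states: str = "compound",
    exclude_repeated_attribute: bool = True,
) -> dict:
    """Output-minus-input face-update contrast after Location -> Operation.

    For each path step of the requested type, the step's face-value series
    after the hypothetical update ("output") and before it ("input") are
    each regressed on the compound Location x Operation regressor at the
    fixed location-to-operation lag, scanning the operation-to-data lag
    over ``scan_lags_ms``; the two compound betas are subtracted
    (output - input) and averaged across steps and trials.  Branch steps
    serve as the no-update control (their "update" flips nothing, so input
    and output series coincide and the contrast is structurally zero; we
    use the would-be swapped value as the hypothetical output).

    With ``exclude_repeated_attribute`` (default) steps whose operated
    attribute is swapped elsewhere on the same path are skipped: there one
    step's input value is the other's output, which entangles the two
    series at chain offsets and contaminates the contrast.
    """
    fs = react.fs
    d1 = int(round(loc_op_lag_ms / 1000 * fs))
    if d1 < 0 or (loc_op_lag_ms > 0 and d1 == 0):
        raise ValueError(f"loc_op_lag_ms={loc_op_lag_ms} not representable at fs={fs}")
    if scan_lags_ms is None:
        scan_lags_ms = np.arange(1, int(DEFAULT_MAX_LAG_MS / 1000 * fs) + 1) * (1000 / fs)
    scan = [int(round(ms / 1000 * fs)) for ms in scan_lags_ms]
    out_betas = np.zeros(len(scan))
    in_betas = np.zeros(len(scan))
    count = 0
    for i, trial in enumerate(trials):
        R = react.trials[i]
        swap_attr_counts: dict[str, int] = {}
        for s in trial.trace.steps:
            if s.operation.op_type == "swap":
                a = s.operation.attribute
                swap_attr_counts[a] = swap_attr_counts.get(a, 0) + 1
        for step in trial.trace.steps:
            if step.operation.op_type != step_type:
                continue
            attr_ = step.operation.attribute
            others = swap_attr_counts.get(attr_, 0) - (step_type == "swap")
            if exclude_repeated_attribute and others > 0:
                continue
            loc_s = R[:, react.state_index(step.location)]
            op_key = (
                step.operation.name if op_states == "compound" else step.operation.op_type
            )
            op_s = R[:, react.state_index(op_key)]
            attr = step.operation.attribute
            in_val = step.face_before.value(attr)
            out_val = step.face_before.swapped(attr).value(attr)
            in_s = R[:, react.state_index(in_val)]
            out_s = R[:, react.state_index(out_val)]
            for li, d2 in enumerate(scan):
                out_betas[li] += multistep_regression([loc_s, op_s], out_s, [d1, d2])
                in_betas[li] += multistep_regression([loc_s, op_s], in_s, [d1, d2])
            count += 1
    if count == 0:
        raise ValueError(f"no {step_type} steps in the trial set")
    out_betas /= count
    in_betas /= count
    return {
        "scan_lags_ms": np.asarray(scan_lags_ms, dtype=float),
        "output_beta": out_betas,
        "input_beta": in_betas,
        "contrast": out_betas - in_betas,
        "n_steps": count,
    }


def odd_even_split(n_trials: int) -> tuple[list[int], list[int]]:
    """Odd/even trial-index halves for cross-split robustness checks."""
    idx = list(range(n_trials))
    return idx[1::2], idx[0::2]


# ---------------------------------------------------------------------------
# replay onsets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReplayEvent:
    trial: int
    sample: int
    step: int  # index into the trial's correct path
    location: str
    operation: str
    score: float


def detect_replay_onsets(
    react: ReactivationMatrix,
    graph: TaskGraph,
    trials: Sequence[TrialSpec],
    lag_ms: float,
    n_shuffles: int = 1000,
    min_sep_ms: float = 200.0,
    percentile: float = 95.0,
    seed: int = 0,
    op_states: str = "compound",
) -> list[ReplayEvent]:
    """Time points with significant Location -> Operation co-reactivation.

    The joint score at sample t is the path location's reactivation times
    its operation's reactivation ``lag_ms`` later.  The null shuffles the
    identities of the multiplied elements (random wrong location/operation
    pairings) before multiplication; the per-trial threshold is the maximum
    over time of the null's 95th percentile.  Suprathreshold samples closer
    than ``min_sep_ms`` are pruned greedily by descending score.
    """
    fs = react.fs
    lag = int(round(lag_ms / 1000 * fs))
    if lag < 1:
        raise ValueError(f"lag {lag_ms} ms not representable at fs={fs} Hz")
    min_sep = int(round(min_sep_ms / 1000 * fs))
    rng = np.random.default_rng(seed)
    loc_states = list(graph.locations)
    op_keys = sorted(
        {
            graph.op_of[l].name if op_states == "compound" else graph.op_of[l].op_type
            for l in graph.locations
        }
    )
    events: list[ReplayEvent] = []
    for i, trial in enumerate(trials):
        R = react.trials[i]
        T = R.shape[0]
        n = T - lag
        if n <= 0:
            continue
        loc_cols = np.array([react.state_index(l) for l in loc_states])
        op_cols = np.array([react.state_index(k) for k in op_keys])
        L = R[:n][:, loc_cols]  # (n, 12)
        O = R[lag:][:, op_cols]  # (n, n_ops)
        steps = trial.trace.steps
        step_loc_idx = [loc_states.index(s.location) for s in steps]
        step_op_idx = [
            op_keys.index(
                s.operation.name if op_states == "compound" else s.operation.op_type
            )
            for s in steps
        ]
        scores = np.stack(
            [L[:, li] * O[:, oi] for li, oi in zip(step_loc_idx, step_op_idx)]
        )  # (n_steps, n)
        # identity-shuffle null: random wrong pairings per shuffle per step
        # (on-path location/operation pairings are excluded, otherwise the
        # null reproduces the true score at genuine events)
        forbidden = set(zip(step_loc_idx, step_op_idx))
        null = np.zeros((n_shuffles, n))
        for s in range(n_shuffles):
            acc = np.zeros(n)
            for _ in steps:
                while True:
                    li = int(rng.integers(len(loc_states)))
                    oi = int(rng.integers(len(op_keys)))
                    if (li, oi) not in forbidden:
                        break
                acc = np.maximum(acc, L[:, li] * O[:, oi])
            null[s] = acc
        threshold = float(np.max(np.percentile(null, percentile, axis=0)))
        cand = []
        for k in range(len(steps)):
            for t in np.flatnonzero(scores[k] > threshold):
                cand.append((float(scores[k, t]), int(t), k))
        cand.sort(reverse=True)
        taken: list[int] = []
        for score, t, k in cand:
            if all(abs(t - u) >= min_sep for u in taken):
                taken.append(t)
                events.append(
                    ReplayEvent(
                        trial=trial.trial_id,
                        sample=t,
                        step=k,
                        location=steps[k].location,
                        operation=steps[k].operation.name,
                        score=score,
                    )
                )
    return sorted(events, key=lambda e: (e.trial, e.sample))


def event_locked_reactivation(
    events: Sequence[ReplayEvent],
    react: ReactivationMatrix,
    trials: Sequence[TrialSpec],
    window_ms: tuple[float, float] = (-100.0, 400.0),
    n_shuffles: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> dict:
    """Event-locked input/output face-value reactivation time courses.

    Input and output series (the operated attribute's value before/after
    the step's update; swap steps only) are epoched around each event,
    baseline-subtracted by the pre-event mean, averaged within trial then
    across trials, and the output-minus-input difference is tested with a
    label-shuffle (sign-flip) mass-corrected cluster permutation.
    """
    if not events:
        raise ValueError("no replay events supplied")
    fs = react.fs
    a = int(round(window_ms[0] / 1000 * fs))
    b = int(round(window_ms[1] / 1000 * fs))
    trial_by_id = {t.trial_id: (i, t) for i, t in enumerate(trials)}
    per_trial_in: dict[int, list[np.ndarray]] = {}
    per_trial_out: dict[int, list[np.ndarray]] = {}
    for ev in events:
        i, trial = trial_by_id[ev.trial]
        step = trial.trace.steps[ev.step]
        if step.operation.op_type != "swap":
            continue
        # skip steps whose attribute is swapped twice on this path (input
        # and output values swap roles at the other step)
        if (
            sum(
                s.operation.op_type == "swap"
                and s.operation.attribute == step.operation.attribute
                for s in trial.trace.steps
            )
            > 1
        ):
            continue
        R = react.trials[i]
        lo, hi = ev.sample + a, ev.sample + b
        if lo < 0 or hi > R.shape[0]:
            continue
        attr = step.operation.attribute
        in_s = R[lo:hi, react.state_index(step.face_before.value(attr))]
        out_s = R[lo:hi, react.state_index(step.face_after.value(attr))]
        base = slice(0, max(1, -a))
        per_trial_in.setdefault(ev.trial, []).append(in_s - in_s[base].mean())
        per_trial_out.setdefault(ev.trial, []).append(out_s - out_s[base].mean())
    if not per_trial_in:
        raise ValueError("no swap-step events fall inside trial bounds")
    trials_in = np.stack([np.mean(v, axis=0) for v in per_trial_in.values()])
    trials_out = np.stack([np.mean(v, axis=0) for v in per_trial_out.values()])
    diff = trials_out - trials_in  # (n_trials, n_samples)
    observed = diff.mean(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_shuffles, diff.shape[0]))
    null = signs @ diff / diff.shape[0]
    mask = cluster_mass_mask(observed, null, percentile=percentile)
    times = (np.arange(a, b) / fs) * 1000
    return {
        "times_ms": times,
        "input": trials_in.mean(axis=0),
        "output": trials_out.mean(axis=0),
        "difference": observed,
        "cluster_mask": mask,
        "n_trials": diff.shape[0],
    }


# ---------------------------------------------------------------------------
# session trend
# ---------------------------------------------------------------------------


def session_trend(
    per_trial_effect: Sequence[float], window_fraction: float = 1 / 3
) -> dict:
    """Slope of a sliding-window mean of a per-trial effect series.

    The window spans ``window_fraction`` of the session, advances one trial
    at a time, and an OLS trial-index regressor is fit to the window means;
    positive betas indicate increasing strength.
    """
    x = np.asarray(per_trial_effect, dtype=float)
    n = len(x)
    w = max(1, int(round(n * window_fraction)))
    if n - w + 1 < 3:
        raise ValueError("need at least 3 sliding windows")
    means = np.convolve(x, np.ones(w) / w, mode="valid")
    idx = np.arange(len(means), dtype=float)
    if np.ptp(means) == 0:
        return {"beta": 0.0, "constant": True, "window": w}
    beta = float(np.polyfit(idx, means, 1)[0])
    return {"beta": beta, "constant": False, "window": w}
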