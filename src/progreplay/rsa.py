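"""Time-resolved and replay-aligned representational similarity analysis.

At each time point the empirical similarity between two trials is the
correlation over sensors of their smoothed activity; a GLM predicts the
vectorized (upper-triangle) empirical matrix from model similarity
regressors — program, object, shallow, deep, face-path and length-
difference structure from the task model — plus a bias term.  Cluster
significance uses neural-data shuffles with mass correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from progreplay._cluster import cluster_mass_mask
from progreplay.simulate import SensorTimeseries

DEFAULT_SMOOTHING_MS = 50.0
MAX_CONDITION_NUMBER = 1e6


@dataclass
class RSATimecourse:
    """Per-time-point GLM betas for each model regressor."""

    times_ms: np.ndarray
    betas: np.ndarray  # (n_times, n_regressors)
    regressor_names: tuple[str, ...]
    cluster_masks: dict[str, np.ndarray] = field(default_factory=dict)
    null_summary: dict = field(default_factory=dict)
    condition_number: float = float("nan")

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.regressor_names.index(name)]


def _align_trials(
    run: SensorTimeseries, epoch: str, n_samples: int
) -> np.ndarray:
    """Stack trials aligned to onset ('start') or offset ('end')."""
    out = []
    for data in run.trials:
        if data.shape[1] < n_samples:
            raise ValueError("trial shorter than requested epoch")
        if epoch == "start":
            out.append(data[:, :n_samples])
        elif epoch == "end":
            out.append(data[:, -n_samples:])
        else:
            raise ValueError(f"unknown epoch {epoch!r}")
    return np.stack(out)  # (trials, sensors, samples)


def empirical_similarity(
    run: SensorTimeseries,
    smoothing_ms: float = DEFAULT_SMOOTHING_MS,
    epoch: str = "start",
    epoch_s: float = 1.0,
    aligned: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial sensor-pattern correlations at each time point.

    Returns ``(times_ms, sim)`` where ``sim[t]`` is the trials x trials
    correlation matrix of temporally smoothed activity at time ``t``.
    """
    if aligned is None:
        n_samples = int(round(epoch_s * run.fs))
        aligned = _align_trials(run, epoch, n_samples)
    n_trials, n_sensors, n_samples = aligned.shape
    sd = smoothing_ms / 1000 * run.fs
    if sd > 0:
        aligned = gaussian_filter1d(aligned, sd, axis=2)
    sims = np.zeros((n_samples, n_trials, n_trials))
    for t in range(n_samples):
        X = aligned[:, :, t]
        sd_x = X.std(axis=1)
        if np.any(sd_x == 0):
            raise ValueError("zero-variance sensor vector: degenerate trial")
        Z = (X - X.mean(axis=1, keepdims=True)) / sd_x[:, None]
        sims[t] = Z @ Z.T / n_sensors
    times_ms = np.arange(n_samples) / run.fs * 1000
    if epoch == "end":
        times_ms = times_ms - times_ms[-1]
    return times_ms, sims


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[-1], k=1)
    return mat[..., iu[0], iu[1]]


def rsa_glm(
    times_ms: np.ndarray,
    empirical: np.ndarray,
    model: Mapping[str, np.ndarray],
) -> RSATimecourse:
    """Per-time-point OLS of empirical similarity on model regressors.

    ``model`` maps regressor names to trials x trials similarity matrices;
    a bias column is appended.  Only the upper triangle (diagonal excluded)
    enters the regression.  Raises when the model design is collinear or
    badly conditioned.
    """
    names = tuple(model) + ("bias",)
    cols = [_upper(m).astype(float) for m in model.values()]
    cols.append(np.ones_like(cols[0]))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear model regressor set")
    cond = float(np.linalg.cond(X))
    if cond > MAX_CONDITION_NUMBER:
        raise ValueError(f"model design condition number {cond:.3g} too high")
    Y = _upper(empirical).T  # (n_pairs, n_times)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return RSATimecourse(
        times_ms=np.asarray(times_ms),
        betas=B.T,
        regressor_names=names,
        condition_number=cond,
    )


def rsa_significance(
    run: SensorTimeseries,
    model: Mapping[str, np.ndarray],
    regressor: str,
    smoothing_ms: float = DEFAULT_SMOOTHING_MS,
    epoch: str = "start",
    epoch_s: float = 1.0,
    n_shuffles: int = 1000,
    percentile: float = 97.5,
    seed: int = 0,
) -> RSATimecourse:
    """Observed betas plus a mass-corrected cluster mask for ``regressor``.

    The null shuffles the trial correspondence of the neural data (a random
    permutation applied to the rows/columns of the empirical similarity
    matrices) before recomputing the GLM.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    times, sims = empirical_similarity(run, smoothing_ms, epoch, epoch_s)
    tc = rsa_glm(times, sims, model)
    rng = np.random.default_rng(seed)
    n_trials = sims.shape[1]
    ri = list(tc.regressor_names).index(regressor)
    null = np.zeros((n_shuffles, len(times)))
    for s in range(n_shuffles):
        perm = rng.permutation(n_trials)
        shuffled = sims[:, perm][:, :, perm]
        null[s] = rsa_glm(times, shuffled, model).betas[:, ri]
    observed = tc.betas[:, ri]
    tc.cluster_masks[regressor] = cluster_mass_mask(observed, null, percentile)
    tc.null_summary[regressor] = {
        "null_mean": float(null.mean()),
        "null_sd": float(null.std()),
        "percentile": percentile,
        "n_shuffles": n_shuffles,
    }
    return tc


# ---------------------------------------------------------------------------
# replay-aligned RSA
# ---------------------------------------------------------------------------


def _event_aligned_activity(
    run: SensorTimeseries,
    events_by_trial: Mapping[int, Sequence[int]],
    window_s: tuple[float, float],
    smoothing_ms: float,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Smooth, epoch and average activity around each trial's events."""
    fs = run.fs
    a = int(round(window_s[0] * fs))
    b = int(round(window_s[1] * fs))
    sd = smoothing_ms / 1000 * fs
    ids = []
    mats = []
    id_col = "trial" if "trial" in run.trial_meta.columns else "trial_id"
    trial_ids = list(run.trial_meta[id_col])
    for i, data in enumerate(run.trials):
        tid = trial_ids[i]
        samples = [
            s for s in events_by_trial.get(tid, []) if s + a >= 0 and s + b <= data.shape[1]
        ]
        if not samples:
            continue
        smoothed = gaussian_filter1d(data, sd, axis=1) if sd > 0 else data
        epochs = np.stack([smoothed[:, s + a : s + b] for s in samples])
        mats.append(epochs.mean(axis=0))
        ids.append(i)
    if not mats:
        raise ValueError("no trials with in-bounds events")
    times_ms = np.arange(a, b) / fs * 1000
    return times_ms, np.stack(mats), ids


def replay_aligned_rsa(
    events: Sequence,
    run: SensorTimeseries,
    model: Mapping[str, np.ndarray],
    regressor: str = "program",
    window_s: tuple[float, float] = (0.0, 0.5),
    smoothing_ms: float = DEFAULT_SMOOTHING_MS,
    n_shuffles: int = 1000,
    percentile: float = 95.0,
    n_control_repeats: int = 5,
    seed: int = 0,
) -> tuple[RSATimecourse, RSATimecourse]:
    """RSA time-locked to replay events, plus a matched control analysis.

    Neural activity is smoothed, epoched around every replay event, and
    averaged within trial before entering :func:`rsa_glm` per peri-event
    time point; trials without events are dropped (model matrices are
    subset to match).  The control repeats the full analysis with randomly
    sampled time points (as many per trial as real events, overlap
    allowed), ``n_control_repeats`` times, and averages the betas.
    """
    events_by_trial: dict[int, list[int]] = {}
    for ev in events:
        events_by_trial.setdefault(ev.trial, []).append(ev.sample)
    times, mats, kept = _event_aligned_activity(
        run, events_by_trial, window_s, smoothing_ms
    )

    def glm_for(mats_: np.ndarray, kept_: list[int]) -> RSATimecourse:
        sub_model = {k: v[np.ix_(kept_, kept_)] for k, v in model.items()}
        n_samples = mats_.shape[2]
        _, sims = empirical_similarity(
            SensorTimeseries(list(mats_), run.fs, run.run, run.trial_meta.iloc[kept_]),
            smoothing_ms=0.0,  # already smoothed before epoching
            aligned=mats_,
        )
        return rsa_glm(times, sims, sub_model)

    tc = glm_for(mats, kept)
    ri = list(tc.regressor_names).index(regressor)
    rng = np.random.default_rng(seed)
    # data-shuffle null for the observed analysis
    null = np.zeros((n_shuffles, len(times)))
    sub_model = {k: v[np.ix_(kept, kept)] for k, v in model.items()}
    _, sims = empirical_similarity(
        SensorTimeseries(list(mats), run.fs, run.run, run.trial_meta.iloc[kept]),
        smoothing_ms=0.0,
        aligned=mats,
    )
    for s in range(n_shuffles):
        perm = rng.permutation(len(kept))
        null[s] = rsa_glm(times, sims[:, perm][:, :, perm], sub_model).betas[:, ri]
    tc.cluster_masks[regressor] = cluster_mass_mask(tc.betas[:, ri], null, percentile)

    # matched random-time control, averaged over repeats
    id_col = "trial" if "trial" in run.trial_meta.columns else "trial_id"
    trial_ids = list(run.trial_meta[id_col])
    lengths = {trial_ids[i]: d.shape[1] for i, d in enumerate(run.trials)}
    a = int(round(window_s[0] * run.fs))
    b = int(round(window_s[1] * run.fs))
    control_betas = []
    for _ in range(n_control_repeats):
        ctrl_events: dict[int, list[int]] = {}
        for tid, evs in events_by_trial.items():
            hi = lengths[tid] - b
            lo = -a
            if hi <= lo:
                continue
            ctrl_events[tid] = list(rng.integers(lo, hi, size=len(evs)))
        _, cmats, ckept = _event_aligned_activity(
            run, ctrl_events, window_s, smoothing_ms
        )
        control_betas.append(glm_for(cmats, ckept).betas)
    control = RSATimecourse(
        times_ms=times,
        betas=np.mean(control_betas, axis=0),
        regressor_names=tc.regressor_names,
    )
    return tc, control
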