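import numpy as np
import pytest

from progreplay import simulate, task
from progreplay import sequenceness as sq
from progreplay.decoding import ReactivationMatrix
from progreplay.task import transition_matrices


def noise_react(n_trials, n_samples, n_states, seed, states=None, fs=100):
    rng = np.random.default_rng(seed)
    trials = [
        np.clip(0.1 + 0.05 * rng.normal(size=(n_samples, n_states)), 0, 1)
        for _ in range(n_trials)
    ]
    states = states or tuple(f"s{i}" for i in range(n_states))
    return ReactivationMatrix(trials, tuple(states), fs)


def inject_chain(react, graph, trials, lag_samples, n_events, amp=1.0,
                 backward=True, seed=0):
    """Add path-location impulse chains directly into probability series."""
    rng = np.random.default_rng(seed)
    for i, trial in enumerate(trials):
        Y = react.trials[i]
        idx = [react.state_index(l) for l in trial.path]
        if backward:
            idx = idx[::-1]
        span = lag_samples * len(idx) + 2
        for _ in range(n_events):
            s = int(rng.integers(0, Y.shape[0] - span))
            for k, ix in enumerate(idx):
                Y[s + k * lag_samples, ix] = np.clip(Y[s + k * lag_samples, ix] + amp, 0, 1)
    return react


class TestFirstStage:
    def test_oracle_equivalence(self):
        """First-stage coefficients match explicit normal equations to 1e-10."""
        rng = np.random.default_rng(0)
        Y = rng.random((100, 3))
        react = ReactivationMatrix([Y], ("a", "b", "c"), 100)
        emp = sq.first_stage(react, max_lag_ms=50)
        for li, d in enumerate(range(1, 6)):
            X = np.column_stack([Y[:-d], np.ones(100 - d)])
            B = np.linalg.solve(X.T @ X, X.T @ Y[d:])
            assert np.abs(emp.tensors[0][li] - B[:-1]).max() < 1e-10

    def test_shifted_copy_identified(self):
        rng = np.random.default_rng(1)
        T = 600
        a = rng.random(T)
        Y = rng.random((T, 3)) * 0.3
        Y[:, 0] = a
        Y[3:, 1] = a[:-3] + 0.02 * rng.normal(size=T - 3)
        emp = sq.first_stage(ReactivationMatrix([Y], ("a", "b", "c"), 100), 100)
        lag30 = emp.tensors[0][2]
        assert lag30[0, 1] > 0.9
        assert np.abs(np.delete(lag30.ravel(), 1)).max() < 0.2

    def test_white_noise_near_zero(self):
        react = noise_react(1, 2000, 4, seed=2)
        emp = sq.first_stage(react, 100)
        assert np.abs(emp.tensors[0]).max() < 0.1

    def test_constant_series_raises(self):
        Y = np.ones((100, 3)) * 0.5
        with pytest.raises(ValueError, match="constant"):
            sq.first_stage(ReactivationMatrix([Y], ("a", "b", "c"), 100), 50)

    def test_short_trial_raises(self):
        react = noise_react(1, 10, 3, seed=0)
        with pytest.raises(ValueError, match="short"):
            sq.first_stage(react, 200)


class TestSecondStage:
    def test_exact_theoretical_recovery(self):
        rng = np.random.default_rng(3)
        T = (rng.random((6, 6)) < 0.3).astype(float)
        np.fill_diagonal(T, 0)
        emp = sq.EmpiricalTransitionTensor(
            [np.stack([T] * 4)], np.arange(1, 5) * 10.0, tuple("abcdef")
        )
        betas = sq.second_stage(emp, [T])
        assert np.allclose(betas[0, :, 0], 1.0, atol=1e-10)
        assert np.allclose(betas[0, :, 1], 0.0, atol=1e-10)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(4)
        M = rng.random((5, 5))
        T = (rng.random((5, 5)) < 0.4).astype(float)
        emp = sq.EmpiricalTransitionTensor(
            [M[None]], np.array([10.0]), tuple("abcde")
        )
        beta = sq.second_stage(emp, [T])[0, 0]
        X = np.column_stack([T.ravel(), T.T.ravel(), np.eye(5).ravel(), np.ones(25)])
        expected = np.linalg.solve(X.T @ X, X.T @ M.ravel())
        assert np.abs(beta - expected).max() < 1e-10

    def test_collinear_raises(self):
        T = np.eye(4)
        emp = sq.EmpiricalTransitionTensor(
            [np.zeros((1, 4, 4))], np.array([10.0]), tuple("abcd")
        )
        with pytest.raises(ValueError, match="collinear"):
            sq.second_stage(emp, [T])

    def test_neighbor_average(self):
        x = np.array([1.0, 3.0, 5.0])
        assert np.allclose(sq.neighbor_average(x), [2.0, 4.0])


class TestTimeReversal:
    def test_exact_swap(self, graph, trials):
        react = noise_react(4, 300, 12, seed=5, states=graph.locations)
        theos = [[transition_matrices(graph, t)[0]] for t in trials[:4]]
        fwd, *_ = sq.sequenceness(react, theos, 100)
        rev = ReactivationMatrix(
            [y[::-1] for y in react.trials], react.states, react.fs
        )
        bwd, *_ = sq.sequenceness(rev, theos, 100)
        assert np.array_equal(fwd.forward, bwd.backward)
        assert np.array_equal(fwd.backward, bwd.forward)


class TestPermutationNull:
    def test_deterministic(self, graph, trials):
        react = noise_react(3, 250, 12, seed=6, states=graph.locations)
        theos = [[transition_matrices(graph, t)[0]] for t in trials[:3]]
        _, ef, eb = sq.sequenceness(react, theos, 100)
        n1 = sq.permutation_null(ef, eb, theos, 50, seed=1)
        n2 = sq.permutation_null(ef, eb, theos, 50, seed=1)
        assert np.array_equal(n1.null_forward, n2.null_forward)

    def test_null_mean_near_zero_on_noise(self, graph, trials):
        react = noise_react(3, 400, 12, seed=7, states=graph.locations)
        theos = [[transition_matrices(graph, t)[0]] for t in trials[:3]]
        _, ef, eb = sq.sequenceness(react, theos, 100)
        null = sq.permutation_null(ef, eb, theos, 100, seed=2)
        assert abs(null.null_forward.mean()) < 0.01

    def test_exhaustive_fallback_small_state_space(self):
        react = noise_react(1, 200, 3, seed=8)
        theos = [np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]], float)]
        _, ef, eb = sq.sequenceness(react, [theos[0:1]], 80)
        null = sq.permutation_null(ef, eb, [theos[0:1]], 1000, seed=3)
        assert null.null_forward.shape[0] == 5  # 3! - 1


class TestPathSequenceness:
    def test_backward_injection_recovered(self, graph, trials):
        react = noise_react(8, 700, 12, seed=9, states=graph.locations)
        inject_chain(react, graph, trials[:8], lag_samples=8, n_events=10, seed=10)
        res = sq.path_sequenceness(react, graph, trials[:8], "correct",
                                   n_shuffles=150, seed=0)
        curve, null = res["curve"], res["null"]
        assert curve.peak_lag_ms("backward") == 80.0
        assert curve.backward[:, 0].max() > null.threshold_backward

    def test_incorrect_path_flat(self, graph, trials):
        react = noise_react(8, 700, 12, seed=9, states=graph.locations)
        inject_chain(react, graph, trials[:8], lag_samples=8, n_events=10, seed=10)
        res = sq.path_sequenceness(react, graph, trials[:8], "incorrect",
                                   n_shuffles=150, seed=0)
        assert res["curve"].backward[:, 0].max() <= res["null"].threshold_backward

    def test_wrong_branch_injection_hits_incorrect(self, graph, trials):
        """Injecting walks along non-path graph edges drives the
        incorrect-path regressor instead."""
        react = noise_react(8, 700, 12, seed=11, states=graph.locations)
        rng = np.random.default_rng(12)
        for i, trial in enumerate(trials[:8]):
            _, incorrect = transition_matrices(graph, trial)
            edges = np.argwhere(incorrect > 0)
            Y = react.trials[i]
            for _ in range(25):
                a, b = edges[rng.integers(len(edges))]
                s = int(rng.integers(0, Y.shape[0] - 10))
                Y[s, a] = min(Y[s, a] + 1.0, 1.0)
                Y[s + 8, b] = min(Y[s + 8, b] + 1.0, 1.0)
        res = sq.path_sequenceness(react, graph, trials[:8], "incorrect",
                                   n_shuffles=150, seed=0)
        assert res["curve"].forward[:, 0].max() > res["null"].threshold_forward

    def test_shallow_only_injection(self, graph, trials):
        react = noise_react(8, 700, 12, seed=13, states=graph.locations)
        rng = np.random.default_rng(14)
        for i, trial in enumerate(trials[:8]):
            a = react.state_index(trial.path[0])
            b = react.state_index(trial.path[1])
            Y = react.trials[i]
            for _ in range(25):
                s = int(rng.integers(0, Y.shape[0] - 10))
                Y[s, a] = min(Y[s, a] + 1.0, 1.0)
                Y[s + 8, b] = min(Y[s + 8, b] + 1.0, 1.0)
        res_sh = sq.path_sequenceness(react, graph, trials[:8], "shallow",
                                      n_shuffles=150, seed=0)
        res_dp = sq.path_sequenceness(react, graph, trials[:8], "deep",
                                      n_shuffles=150, seed=0)
        assert res_sh["curve"].forward[:, 0].max() > res_sh["null"].threshold_forward
        assert res_dp["curve"].forward[:, 0].max() <= res_dp["null"].threshold_forward


class TestEntropyFilter:
    def test_never_reactivated_dropped(self):
        react = np.zeros((100, 12))
        react[:, 0] = 1.0  # state 0 always wins
        assert not sq.entropy_filter(react, path_indices=[0, 1, 2])

    def test_uniform_kept(self):
        rng = np.random.default_rng(0)
        react = rng.random((1200, 12))  #每 state wins ~8.3% of the time
        assert sq.entropy_filter(react, path_indices=list(range(12)))

    def test_drop_fraction_small_on_default_synthetic(self, desk_material):
        react = desk_material["react"].subset(
            desk_material["material"]["graph"].locations
        )
        keep, frac = sq.filter_trials(
            react, desk_material["material"]["trials"],
            desk_material["material"]["graph"],
        )
        assert frac < 0.2


class TestMultistep:
    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        T = 200
        loc, op, out = rng.random(T), rng.random(T), rng.random(T)
        beta = sq.multistep_regression([loc, op], out, [4, 6])
        n = T - 10
        comp = loc[:n] * op[4 : 4 + n]
        X = np.column_stack(
            [comp, loc[:n], op[4 : 4 + n], loc[4 : 4 + n], np.ones(n)]
        )
        expected = np.linalg.lstsq(X, out[10 : 10 + n], rcond=None)[0][0]
        assert abs(beta - expected) < 1e-10

    def test_zero_aux_series_zero_beta(self):
        rng = np.random.default_rng(1)
        loc = rng.random(200)
        op = np.zeros(200)
        out = rng.random(200)
        assert sq.multistep_regression([loc, op], out, [3, 5]) == pytest.approx(0.0)

    def test_lags_exceeding_trial_raise(self):
        with pytest.raises(ValueError):
            sq.multistep_regression([np.ones(10), np.ones(10)], np.ones(10), [6, 6])

    def test_swap_contrast_recovers_lag(self, graph, trials):
        states = (
            tuple(graph.locations)
            + simulate.FACE_VALUE_STATES
            + simulate.COMPOUND_OP_STATES
        )
        react = noise_react(10, 900, len(states), seed=2, states=states)
        rng = np.random.default_rng(3)
        for i, trial in enumerate(trials[:10]):
            Y = react.trials[i]
            for _ in range(8):
                s = int(rng.integers(0, Y.shape[0] - 400))
                off = 0
                for k, step in enumerate(trial.trace.steps[::-1]):
                    if k:
                        off += 8
                    Y[s + off, react.state_index(step.location)] += 0.8
                    Y[s + off + 6, react.state_index(step.operation.name)] += 0.8
                    if step.operation.op_type == "swap":
                        a = step.operation.attribute
                        Y[s + off + 18, react.state_index(step.face_after.value(a))] += 0.8
            np.clip(Y, 0, 1, out=Y)
        res = sq.data_update_contrast(react, graph, trials[:10], 60.0, step_type="swap")
        peak = res["scan_lags_ms"][int(np.argmax(res["contrast"]))]
        assert abs(peak - 120.0) <= 10.0
        resb = sq.data_update_contrast(react, graph, trials[:10], 60.0, step_type="branch")
        assert res["contrast"].max() > 3 * abs(
            resb["contrast"][np.argmin(np.abs(resb["scan_lags_ms"] - 120.0))]
        )


class TestReplayOnsets:
    def test_min_separation_pruning(self, graph, trials):
        states = tuple(graph.locations) + simulate.COMPOUND_OP_STATES
        react = noise_react(1, 600, len(states), seed=4, states=states)
        trial = trials[0]
        Y = react.trials[0]
        step = trial.trace.steps[0]
        li = react.state_index(step.location)
        oi = react.state_index(step.operation.name)
        for s in (100, 110):  # two strong co-reactivations 100 ms apart
            Y[s, li] = 1.0
            Y[s + 6, oi] = 1.0
        events = sq.detect_replay_onsets(
            react, graph, [trial], lag_ms=60.0, n_shuffles=100, seed=0
        )
        near = [e for e in events if 90 <= e.sample <= 120]
        assert len(near) == 1

    def test_no_injection_low_event_count(self, graph, trials):
        states = tuple(graph.locations) + simulate.COMPOUND_OP_STATES
        react = noise_react(6, 600, len(states), seed=5, states=states)
        events = sq.detect_replay_onsets(
            react, graph, trials[:6], lag_ms=60.0, n_shuffles=100, seed=0
        )
        assert len(events) / 6 < 3

    def test_injected_events_recovered(self, graph, trials):
        states = tuple(graph.locations) + simulate.COMPOUND_OP_STATES
        react = noise_react(6, 900, len(states), seed=6, states=states)
        rng = np.random.default_rng(7)
        injected = {}
        for i, trial in enumerate(trials[:6]):
            Y = react.trials[i]
            samples = []
            for e in range(4):
                s = 100 + e * 180
                step = trial.trace.steps[0]
                Y[s, react.state_index(step.location)] = 1.0
                Y[s + 6, react.state_index(step.operation.name)] = 1.0
                samples.append(s)
            injected[trial.trial_id] = samples
        events = sq.detect_replay_onsets(
            react, graph, trials[:6], lag_ms=60.0, n_shuffles=200, seed=0
        )
        hits = 0
        total = sum(len(v) for v in injected.values())
        for tid, samples in injected.items():
            evs = [e.sample for e in events if e.trial == tid]
            for s in samples:
                if any(abs(s - e) <= 2 for e in evs):
                    hits += 1
        assert hits / total > 0.5

    def test_unrepresentable_lag_raises(self, graph, trials):
        react = noise_react(1, 300, 12, seed=0, states=graph.locations)
        with pytest.raises(ValueError):
            sq.detect_replay_onsets(react, graph, trials[:1], lag_ms=3.0)


class TestEventLocked:
    def test_identical_series_zero_difference(self, graph, trials):
        states = (
            tuple(graph.locations)
            + simulate.FACE_VALUE_STATES
            + simulate.COMPOUND_OP_STATES
        )
        react = noise_react(4, 600, len(states), seed=8, states=states)
        # make every input series equal its output series
        for i, trial in enumerate(trials[:4]):
            Y = react.trials[i]
            for step in trial.trace.steps:
                if step.operation.op_type != "swap":
                    continue
                a = step.operation.attribute
                i_in = react.state_index(step.face_before.value(a))
                i_out = react.state_index(step.face_after.value(a))
                Y[:, i_in] = Y[:, i_out]
        events = [
            sq.ReplayEvent(t.trial_id, 200, 0, t.path[0],
                           t.trace.steps[0].operation.name, 1.0)
            for t in trials[:4]
        ]
        res = sq.event_locked_reactivation(events, react, trials[:4],
                                           n_shuffles=100, seed=0)
        assert np.allclose(res["difference"], 0.0, atol=1e-12)
        assert not res["cluster_mask"].any()

    def test_output_injection_detected(self, graph, trials):
        states = (
            tuple(graph.locations)
            + simulate.FACE_VALUE_STATES
            + simulate.COMPOUND_OP_STATES
        )
        react = noise_react(8, 600, len(states), seed=9, states=states)
        events = []
        for i, trial in enumerate(trials[:8]):
            Y = react.trials[i]
            # choose a swap step whose attribute is unique on the path
            for k, step in enumerate(trial.trace.steps):
                if step.operation.op_type != "swap":
                    continue
                if sum(
                    s.operation.op_type == "swap"
                    and s.operation.attribute == step.operation.attribute
                    for s in trial.trace.steps
                ) > 1:
                    continue
                a = step.operation.attribute
                out_ix = react.state_index(step.face_after.value(a))
                for s in (150, 300, 450):
                    Y[s + 12 : s + 15, out_ix] = 1.0  # output at +120 ms
                    events.append(
                        sq.ReplayEvent(trial.trial_id, s, k, step.location,
                                       step.operation.name, 1.0)
                    )
                break
        res = sq.event_locked_reactivation(events, react, trials[:8],
                                           n_shuffles=200, seed=0)
        mask = res["cluster_mask"]
        times = res["times_ms"]
        assert mask.any()
        assert mask[(times >= 100) & (times <= 160)].any()


class TestSessionTrend:
    def test_increasing_series_positive(self):
        res = sq.session_trend(np.arange(30, dtype=float))
        assert res["beta"] > 0

    def test_constant_series_zero(self):
        res = sq.session_trend(np.ones(30))
        assert res["beta"] == 0.0
        assert res["constant"]

    def test_linear_recovery_against_closed_form(self):
        s = 0.37
        x = s * np.arange(60)
        res = sq.session_trend(x, window_fraction=1 / 3)
        # sliding-window means of a linear series keep the same slope
        assert res["beta"] == pytest.approx(s, rel=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            sq.session_trend([1.0, 2.0], window_fraction=1.0)


class TestSplits:
    def test_accuracy_median_split(self):
        high, low = sq.split_by_accuracy([0.9, 0.5, 0.7, 0.6])
        assert set(high) | set(low) == {0, 1, 2, 3}
        assert not set(high) & set(low)

    def test_odd_even(self):
        odd, even = sq.odd_even_split(5)
        assert odd == [1, 3]
        assert even == [0, 2, 4]
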