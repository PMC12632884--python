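import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from progreplay import task
from progreplay.task import (
    ALL_FACES,
    ALL_OPERATIONS,
    END,
    FaceState,
    execute_program,
    generate_task_graph,
    path_similarity,
    sample_trials,
    transition_matrices,
)

from conftest import make_trial


class TestGraphGeneration:
    def test_deterministic(self):
        a = generate_task_graph(seed=0)
        b = generate_task_graph(seed=0)
        assert a.to_dict() == b.to_dict()

    def test_different_seeds_differ(self):
        assert generate_task_graph(0).to_dict() != generate_task_graph(1).to_dict()

    def test_operation_balance(self, graph):
        counts = {}
        for loc in graph.locations:
            counts[graph.op_of[loc].name] = counts.get(graph.op_of[loc].name, 0) + 1
        assert len(counts) == 6
        assert all(c == 2 for c in counts.values())
        n_swap = sum(graph.op_of[l].op_type == "swap" for l in graph.locations)
        assert n_swap == 6

    def test_twelve_locations(self, graph):
        assert len(graph.locations) == 12
        assert END not in graph.locations

    def test_branch_out_degree(self, graph):
        for loc in graph.locations:
            succs = graph.successors(loc)
            if graph.op_of[loc].op_type == "swap":
                assert len(succs) == 1
            else:
                assert len(succs) == 2
                assert len(set(succs)) == 2
                assert sum(s == END for s in succs) <= 1

    def test_all_96_executions_terminate(self, graph):
        # brute-force oracle over the full (start, face) product
        for start, face in itertools.product(graph.locations, ALL_FACES):
            trace = execute_program(graph, start, face)
            assert trace.length <= graph.max_depth
            assert trace.steps[-1].next == END

    def test_both_lengths_realized(self, graph):
        lengths = {
            execute_program(graph, s, f).length
            for s, f in itertools.product(graph.locations, ALL_FACES)
        }
        assert {3, 4} <= lengths

    def test_validate_passes(self, graph):
        graph.validate()

    def test_overconstrained_raises(self):
        with pytest.raises(RuntimeError):
            generate_task_graph(seed=0, max_depth=1, max_attempts=50)


class TestExecution:
    def test_swap_flips_exactly_one_attribute(self, graph):
        for start, face in itertools.product(graph.locations, ALL_FACES):
            for step in execute_program(graph, start, face).steps:
                d = step.face_before.hamming(step.face_after)
                if step.operation.op_type == "swap":
                    assert d == 1
                    assert (
                        step.face_before.value(step.operation.attribute)
                        != step.face_after.value(step.operation.attribute)
                    )
                else:
                    assert d == 0

    def test_swap_is_involution(self):
        face = FaceState("round", "hands", "crown")
        for attr in ("shape", "limb", "hat"):
            assert face.swapped(attr).swapped(attr) == face

    def test_branch_selects_by_attribute_value(self, graph):
        branch_locs = [l for l in graph.locations if graph.op_of[l].op_type == "branch"]
        loc = branch_locs[0]
        attr = graph.op_of[loc].attribute
        f0 = ALL_FACES[0]
        f1 = f0.swapped(attr)
        t0 = execute_program(graph, loc, f0)
        t1 = execute_program(graph, loc, f1)
        assert t0.steps[0].next == graph.succ_branch[loc][f0.value(attr)]
        assert t1.steps[0].next == graph.succ_branch[loc][f1.value(attr)]

    def test_fixture_graph_example(self):
        # hand-built single-path world mirroring the worked example:
        # a swap-hat start flips crown->fedora and moves on; the following
        # branch-on-hat location picks its successor by the new hat value
        locs = ["newspaper", "spaceship", "piano", "chemistry"] + [
            f"x{i}" for i in range(8)
        ]
        ops = {
            "newspaper": task.OperationSpec("swap", "hat"),
            "spaceship": task.OperationSpec("branch", "hat"),
            "piano": task.OperationSpec("swap", "shape"),
            "chemistry": task.OperationSpec("swap", "limb"),
        }
        filler = [op for op in ALL_OPERATIONS for _ in range(2)]
        for op in ops.values():
            filler.remove(op)
        for name, op in zip([f"x{i}" for i in range(8)], filler):
            ops[name] = op
        succ_swap = {
            "newspaper": "spaceship",
            "piano": "chemistry",
            "chemistry": END,
        }
        succ_branch = {"spaceship": {"crown": "x0", "fedora": "piano"}}
        for name in [f"x{i}" for i in range(8)]:
            if ops[name].op_type == "swap":
                succ_swap[name] = END
            else:
                vals = task.ATTRIBUTE_VALUES[ops[name].attribute]
                succ_branch[name] = {vals[0]: "chemistry", vals[1]: END}
        g = task.TaskGraph(tuple(locs), ops, succ_swap, succ_branch)
        face = FaceState("round", "hands", "crown")
        trace = execute_program(g, "newspaper", face)
        assert trace.steps[0].face_after.hat == "fedora"
        assert trace.steps[0].next == "spaceship"
        assert trace.steps[1].next == "piano"
        assert trace.path == ("newspaper", "spaceship", "piano", "chemistry")

    def test_max_depth_enforced(self, graph):
        bad = task.TaskGraph.from_dict(graph.to_dict())
        bad.max_depth = 1
        with pytest.raises(RuntimeError):
            for s, f in itertools.product(bad.locations, ALL_FACES):
                execute_program(bad, s, f)


class TestSampling:
    def test_lengths_in_set(self, graph):
        for t in sample_trials(graph, 90, seed=1):
            assert t.length in (3, 4)

    def test_deterministic(self, graph):
        a = sample_trials(graph, 40, seed=5)
        b = sample_trials(graph, 40, seed=5)
        assert [(t.start_location, t.start_face) for t in a] == [
            (t.start_location, t.start_face) for t in b
        ]

    def test_no_immediate_repeats(self, graph):
        ts = sample_trials(graph, 200, seed=2)
        pairs = [(t.start_location, t.start_face) for t in ts]
        assert all(a != b for a, b in zip(pairs, pairs[1:]))

    def test_both_lengths_present_in_large_sample(self, graph):
        lengths = {t.length for t in sample_trials(graph, 1000, seed=3)}
        assert lengths == {3, 4}

    def test_without_replacement_limit(self, graph):
        with pytest.raises(ValueError):
            sample_trials(graph, 10_000, seed=0, with_replacement=False)


class TestProbes:
    def test_match_implies_accept(self, graph):
        for t in sample_trials(graph, 50, seed=4):
            for p in t.probes:
                assert p.correct_response == ("accept" if p.is_match else "reject")

    def test_one_end_one_path_shared_modality(self, graph):
        for t in sample_trials(graph, 50, seed=4):
            kinds = sorted(p.q_type for p in t.probes)
            assert kinds == ["END", "PATH"]
            assert len({p.modality for p in t.probes}) == 1

    def test_match_fraction_near_half(self, graph):
        probes = [
            p for t in sample_trials(graph, 2500, seed=6) for p in t.probes
        ]
        frac = np.mean([p.is_match for p in probes])
        assert abs(frac - 0.5) < 0.02

    def test_face_probe_attribute_distance(self, graph):
        for t in sample_trials(graph, 300, seed=8):
            for p in t.probes:
                if p.modality != "face":
                    continue
                correct = (
                    t.trace.final_face
                    if p.q_type == "END"
                    else None
                )
                if correct is not None:
                    dist = correct.hamming(task.FaceState.from_name(p.probe_stimulus))
                    assert dist == p.attribute_distance
                    assert p.is_match == (dist == 0)

    def test_path_probe_depth_tags(self, graph):
        seen = set()
        for t in sample_trials(graph, 400, seed=9):
            for p in t.probes:
                if p.q_type == "PATH":
                    assert p.depth_of_probe in ("shallow", "deep")
                    seen.add(p.depth_of_probe)
                else:
                    assert p.depth_of_probe == "end"
        assert seen == {"shallow", "deep"}


class TestSimilarity:
    def test_worked_example(self):
        # [Anchor, Elephant, Broccoli] vs [Broccoli, Elephant, Anchor]
        # (starts excluded by construction): only the middle object shares
        # its position, but all three objects overlap
        a = make_trial(0, ["s0", "anchor", "elephant", "broccoli"])
        b = make_trial(1, ["s1", "broccoli", "elephant", "anchor"])
        prog = path_similarity([a, b], "program")
        obj = path_similarity([a, b], "object")
        assert prog[0, 1] == 1
        assert obj[0, 1] == 3

    def test_self_similarity(self, trials):
        prog = path_similarity(trials, "program")
        obj = path_similarity(trials, "object")
        for i, t in enumerate(trials):
            assert prog[i, i] == t.length - 1  # start excluded
            assert obj[i, i] == t.length - 1

    def test_program_le_object(self, trials):
        prog = path_similarity(trials, "program")
        obj = path_similarity(trials, "object")
        assert (prog <= obj + 1e-12).all()

    def test_shallow_plus_deep_equals_program(self, trials):
        prog = path_similarity(trials, "program")
        sh = path_similarity(trials, "shallow")
        dp = path_similarity(trials, "deep")
        assert np.allclose(sh + dp, prog)

    def test_symmetry(self, trials):
        for mode in task.SIMILARITY_MODES:
            m = path_similarity(trials, mode)
            assert np.allclose(m, m.T)

    def test_length_diff(self, trials):
        m = path_similarity(trials, "length_diff")
        for i, a in enumerate(trials):
            for j, b in enumerate(trials):
                assert m[i, j] == abs(a.length - b.length)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            path_similarity([], "program")

    def test_strict_alignment_flag(self):
        a = make_trial(0, ["s", "p", "q", "r"])  # excluded-start length 3
        b = make_trial(1, ["t", "p", "r"])  # excluded-start length 2
        default = path_similarity([a, b], "program")
        strict = path_similarity([a, b], "program", strict_positions=True)
        # default aligns last<->last (r==r); strict compares position 2 vs 2
        assert default[0, 1] == 2  # p at first, r at last
        assert strict[0, 1] == 1  # only p matches


class TestTransitionMatrices:
    def test_correct_count(self, graph, trials):
        for t in trials:
            correct, _ = transition_matrices(graph, t)
            assert correct.sum() == t.length - 1

    def test_disjoint(self, graph, trials):
        for t in trials:
            correct, incorrect = transition_matrices(graph, t)
            assert not np.any((correct > 0) & (incorrect > 0))

    def test_edge_count_conserved(self, graph, trials):
        n_edges = len(graph.edges())
        for t in trials:
            correct, incorrect = transition_matrices(graph, t)
            assert correct.sum() + incorrect.sum() == n_edges

    def test_shallow_deep_partition(self, graph, trials):
        for t in trials:
            correct, _ = transition_matrices(graph, t)
            sh = task.path_link_matrices(graph, t, "shallow")
            dp = task.path_link_matrices(graph, t, "deep")
            assert np.allclose(sh + dp, correct)
            assert sh.sum() == 1


class TestBehavioralSummary:
    @staticmethod
    def _responses(trials, correct_fn, tt=6.0):
        rows = []
        for t in trials:
            for i, p in enumerate(t.probes):
                rows.append(
                    {
                        "trial_id": t.trial_id,
                        "probe_index": i,
                        "q_type": p.q_type,
                        "modality": p.modality,
                        "depth_of_probe": p.depth_of_probe,
                        "attribute_distance": p.attribute_distance,
                        "is_match": p.is_match,
                        "correct": correct_fn(t, p),
                        "thinking_time_s": tt,
                    }
                )
        return pd.DataFrame(rows)

    def test_perfect_agent(self, graph):
        ts = task.sample_trials(graph, 60, seed=10)
        summary = task.behavioral_summary(ts, self._responses(ts, lambda t, p: True))
        assert summary["overall_accuracy"] == 1.0
        assert (summary["by_length"]["accuracy"] == 1.0).all()

    def test_chance_responder(self, graph):
        ts = task.sample_trials(graph, 400, seed=11)
        rng = np.random.default_rng(0)
        summary = task.behavioral_summary(
            ts, self._responses(ts, lambda t, p: bool(rng.random() < 0.5))
        )
        assert abs(summary["overall_accuracy"] - 0.5) < 0.06

    def test_accuracy_table_shape(self, graph):
        ts = task.sample_trials(graph, 120, seed=12)
        summary = task.behavioral_summary(ts, self._responses(ts, lambda t, p: True))
        table = summary["accuracy_by_qtype_modality"]
        assert set(table["q_type"]) == {"END", "PATH"}
        assert set(table["modality"]) == {"object", "face"}


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_face_walk_property(seed):
    """Any execution is a walk on the 3-cube: swap edges have Hamming
    distance 1, branch edges distance 0 (property over random graphs)."""
    g = generate_task_graph(seed % 20)  # reuse a small pool of graphs
    rng = np.random.default_rng(seed)
    start = g.locations[rng.integers(12)]
    face = ALL_FACES[rng.integers(8)]
    trace = execute_program(g, start, face)
    for step in trace.steps:
        expected = 1 if step.operation.op_type == "swap" else 0
        assert step.face_before.hamming(step.face_after) == expected
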