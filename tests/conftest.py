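import numpy as np
import pytest

from progreplay import decoding, pipeline, simulate, task


@pytest.fixture(scope="session")
def graph():
    return task.generate_task_graph(seed=0)


@pytest.fixture(scope="session")
def trials(graph):
    return task.sample_trials(graph, 30, seed=1)


@pytest.fixture(scope="session")
def sim_cfg():
    return simulate.SimulationConfig(
        n_sensors=64, n_trials=12, events_per_trial=6
    ).validate()


@pytest.fixture(scope="session")
def bank(graph, sim_cfg):
    return simulate.bank_for_graph(graph, sim_cfg, seed=3)


@pytest.fixture(scope="session")
def reasoning_run(graph, sim_cfg, bank):
    trials12 = task.sample_trials(graph, sim_cfg.n_trials, seed=7)
    simulate.simulate_behavior(trials12, sim_cfg, seed=8)
    run, log = simulate.simulate_reasoning(bank, trials12, sim_cfg, seed=9)
    return {"trials": trials12, "run": run, "log": log}


@pytest.fixture(scope="session")
def desk_material():
    """One fully simulated desk-scale participant plus decoded reactivations."""
    cfg = pipeline.StudyConfig.desk_scale(master_seed=11)
    cfg.sim.events_per_trial = 8
    material = pipeline.simulate_participant(cfg, 0)
    react, curves = pipeline.build_reactivations(cfg, 0, material)
    return {"cfg": cfg, "material": material, "react": react, "curves": curves}


def make_trace(path, faces=None):
    """Fabricate an ExecutionTrace from a location path (tests only)."""
    if faces is None:
        faces = [task.ALL_FACES[0]] * len(path)
    steps = []
    for i, loc in enumerate(path):
        nxt = path[i + 1] if i + 1 < len(path) else task.END
        steps.append(
            task.Step(loc, task.ALL_OPERATIONS[0], faces[i], faces[i], nxt)
        )
    return task.ExecutionTrace(tuple(steps))


def make_trial(trial_id, path, faces=None):
    trace = make_trace(path, faces)
    return task.TrialSpec(trial_id, path[0], trace.faces[0], trace)
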