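"""Shared fixtures: simulated subjects, belief series, labelled trials."""

import numpy as np
import pytest

from entroscope import behavior, observer, task_env


@pytest.fixture(scope="session")
def task_config():
    return task_env.TaskConfig()


@pytest.fixture(scope="session")
def subject_data(task_config):
    """One softmax-agent subject at study scale: trials, beliefs, labels."""
    rng = task_env.subject_rng(1234, 0)
    trials = task_env.simulate_subject(task_config, "softmax", rng)
    beliefs = observer.run_observer(trials, available_ids=task_config.available_ids)
    labeled = behavior.label_phases(trials)
    return {"trials": trials, "beliefs": beliefs, "labeled": labeled}


@pytest.fixture(scope="session")
def small_subject_data():
    """A 2-runs-of-100-trials subject for fast pipeline tests."""
    cfg = task_env.TaskConfig(n_trials_per_run=100)
    rng = task_env.subject_rng(77, 0)
    trials = task_env.simulate_subject(cfg, "softmax", rng)
    beliefs = observer.run_observer(trials, available_ids=cfg.available_ids)
    labeled = behavior.label_phases(trials)
    return {"config": cfg, "trials": trials, "beliefs": beliefs, "labeled": labeled}


def make_coupled_subject(seed, subject, n_voxels=120, noise_sd=1.0,
                         flattening_c=0.6, coupling_a=50.0, n_trials_per_run=200):
    """Full per-subject chain with the planted pupil coupling; returns the
    dict consumed by glm.delta_coupling_regression."""
    from entroscope import glm, mvpa, pupil as pp, synthetic

    cfg = task_env.TaskConfig(n_trials_per_run=n_trials_per_run)
    pcfg = synthetic.PupilGenConfig(extra_flattening_c=flattening_c, coupling_a=coupling_a)
    rng = task_env.subject_rng(seed, subject)
    trials = task_env.simulate_subject(cfg, "softmax", rng)
    bel = observer.run_observer(trials, available_ids=cfg.available_ids)
    lab = behavior.label_phases(trials)
    pulses = synthetic.entropy_pulses(trials, bel, rng, pcfg.pulse_gain_sd)
    ncfg = synthetic.NeuralGenConfig(n_voxels=n_voxels, region_kind="state_mixture",
                                     noise_sd=noise_sd)
    pm = synthetic.generate_state_region_patterns(
        trials, bel, ncfg, rng, pulses=pulses, flattening_c=pcfg.extra_flattening_c
    )
    rs = mvpa.repstrength_series(pm, cfg.available_ids)
    trace = synthetic.generate_pupil_trace(trials, bel, pcfg, rng, pulses=pulses)
    base = pp.preprocess(trace["trace"], trace["feedback_ms"], lab)
    return {
        "rs": rs,
        "pupil_baseline": base["baseline"].to_numpy(),
        "entropy": bel["entropy"].to_numpy(),
        "run": trials["run"].to_numpy(),
        "outcome": trials["outcome"].to_numpy(),
        "core_exploit": lab["core_exploit"].to_numpy(),
        "valid": ~base["excluded"].to_numpy(),
        "trials": trials,
        "beliefs": bel,
        "labeled": lab,
    }
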