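"""Restless four-armed bandit environment and agent simulation.

The task environment has eight options in total, four of which are available
in any given run. Exactly one available option pays out at a high rate (70%
or 90%); the other three pay out at 20%. The identity of the high-reward
option jumps to one of the other three available options after a variable
number of trials (regime lengths ~ round(Normal(20, 5)), truncated at 1),
independently of the agent's behaviour. At each jump the high payout rate is
re-drawn uniformly from {0.7, 0.9}.

Agents interact with the environment under one of several policies; the
belief-based policies consult the Bayesian observer (:mod:`entroscope.observer`)
online, using the prior belief entering each trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "EnvironmentTimeline",
    "generate_environment",
    "run_agent",
    "simulate_cohort",
    "TRIAL_COLUMNS",
]

#: Schema of a trial table (one row per trial).
TRIAL_COLUMNS = ["run", "t", "chosen", "outcome", "true_high", "payout_high", "iti_jitter"]


def _default_available_ids() -> list[tuple[int, ...]]:
    # Each option appears in exactly two runs so that the two cross-run pairs
    # used by the decoder each cover all eight options.
    return [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 2, 3), (4, 5, 6, 7)]


@dataclass
class TaskConfig:
    """Parameters of the bandit task.

    Defaults reproduce the study conditions: 8 options, 4 available per run,
    payout 0.2 for low options and {0.7, 0.9} for the high option, regime
    lengths ~ N(20, 5) rounded, four runs of 200 trials.
    """

    n_options_total: int = 8
    n_available: int = 4
    available_ids: list[tuple[int, ...]] = field(default_factory=_default_available_ids)
    payout_low: float = 0.2
    payout_high_set: tuple[float, ...] = (0.7, 0.9)
    regime_mean: float = 20.0
    regime_sd: float = 5.0
    n_trials_per_run: int = 200
    n_runs: int = 4
    seed: int = 0
    iti_jitter_max: float = 4.0  # uniform ITI jitter in seconds, unused by analyses

    def validate(self) -> None:
        if not (0 < self.payout_low < min(self.payout_high_set) <= 1):
            raise ValueError(
                "require 0 < payout_low < min(payout_high_set) <= 1, got "
                f"{self.payout_low} / {self.payout_high_set}"
            )
        if self.n_available > self.n_options_total:
            raise ValueError("n_available exceeds n_options_total")
        if self.regime_mean <= 0:
            raise ValueError("regime_mean must be positive")
        if len(self.available_ids) != self.n_runs:
            raise ValueError("available_ids must list one option set per run")
        for ids in self.available_ids:
            if len(set(ids)) != self.n_available:
                raise ValueError(f"each run needs {self.n_available} distinct options, got {ids}")
            if any(i < 0 or i >= self.n_options_total for i in ids):
                raise ValueError(f"option ids out of range in {ids}")


@dataclass
class EnvironmentTimeline:
    """Hidden state of the environment for one run.

    ``true_high[t]`` is the high-reward option on trial t, ``payout_high[t]``
    its payout rate; ``regime_boundaries`` lists the trial indices at which a
    new regime begins (always including 0).
    """

    run: int
    available: tuple[int, ...]
    true_high: np.ndarray
    payout_high: np.ndarray
    regime_boundaries: list[int]


def generate_environment(config: TaskConfig, rng: np.random.Generator, run: int = 0) -> EnvironmentTimeline:
    """Draw the hidden regime sequence for one run.

    Regime lengths are round(Normal(regime_mean, regime_sd)) truncated below
    at 1 trial. At each boundary the new high option is drawn uniformly from
    the other three available options and the payout rate uniformly from
    ``payout_high_set``.
    """
    config.validate()
    available = tuple(config.available_ids[run % config.n_runs])
    n = config.n_trials_per_run
    true_high = np.empty(n, dtype=int)
    payout_high = np.empty(n, dtype=float)
    boundaries: list[int] = []

    t = 0
    current = int(rng.choice(available))
    while t < n:
        boundaries.append(t)
        rate = float(rng.choice(config.payout_high_set))
        length = max(1, int(np.round(rng.normal(config.regime_mean, config.regime_sd))))
        end = min(n, t + length)
        true_high[t:end] = current
        payout_high[t:end] = rate
        t = end
        # next regime: move to one of the other three available options
        others = [o for o in available if o != current]
        current = int(rng.choice(others))
    return EnvironmentTimeline(run=run, available=available, true_high=true_high,
                               payout_high=payout_high, regime_boundaries=boundaries)


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    e = np.exp(z)
    return e / e.sum()


def run_agent(
    env: EnvironmentTimeline,
    policy: str,
    rng: np.random.Generator,
    config: TaskConfig | None = None,
    beta_explore: float = 4.0,
    beta_exploit: float = 12.0,
    fixed_choices: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate one agent on one run; returns a trial table.

    Policies
    --------
    ``random``
        uniform over the four available options.
    ``greedy``
        argmax of the observer's prior option beliefs entering the trial.
    ``softmax``
        p(choice=i) proportional to exp(beta * p(H_i)) over available options,
        with a higher inverse temperature once the believed-best option was
        rewarded on the previous trial (crude exploit sharpening; produces
        alternating explore/exploit phases like human play).
    ``replay``
        replays ``fixed_choices`` verbatim.

    Outcomes are Bernoulli(payout_high) when the chosen option is the current
    high-reward option and Bernoulli(payout_low) otherwise.
    """
    from . import observer  # deferred to avoid import cycle

    config = config or TaskConfig()
    n = len(env.true_high)
    available = np.asarray(env.available)
    chosen = np.empty(n, dtype=int)
    outcome = np.empty(n, dtype=int)

    needs_beliefs = policy in ("greedy", "softmax")
    if needs_beliefs:
        obs_cfg = observer.ObserverConfig(payout_low=config.payout_low)
        belief = observer.init_belief(obs_cfg)
    if policy == "replay":
        if fixed_choices is None or len(fixed_choices) != n:
            raise ValueError("replay policy requires fixed_choices of run length")
    elif policy not in ("random", "greedy", "softmax"):
        raise ValueError(f"unknown policy {policy!r}")

    last_rewarded_best = False
    for t in range(n):
        if policy == "random":
            c = int(rng.choice(available))
        elif policy == "replay":
            c = int(fixed_choices[t])
        else:
            marg = belief.mass.sum(axis=1)  # prior option beliefs entering t
            if policy == "greedy":
                c = int(available[int(np.argmax(marg))])
            else:
                beta = beta_exploit if last_rewarded_best else beta_explore
                p = _softmax(beta * marg)
                c = int(available[rng.choice(4, p=p)])
        rate = env.payout_high[t] if c == env.true_high[t] else config.payout_low
        o = int(rng.random() < rate)
        chosen[t] = c
        outcome[t] = o
        if needs_beliefs:
            pos = int(np.where(available == c)[0][0])
            belief = observer.update_with_outcome(belief, pos, o)
            last_rewarded_best = bool(o) and pos == int(np.argmax(belief.mass.sum(axis=1)))
            belief = observer.apply_leak(belief, obs_cfg.s)

    return pd.DataFrame(
        {
            "run": env.run,
            "t": np.arange(n),
            "chosen": chosen,
            "outcome": outcome,
            "true_high": env.true_high,
            "payout_high": env.payout_high,
            "iti_jitter": rng.uniform(0.0, config.iti_jitter_max, size=n),
        }
    )


def subject_rng(master_seed: int, subject: int) -> np.random.Generator:
    """Independent, reproducible substream for one subject."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, subject]))


def simulate_subject(config: TaskConfig, policy: str, rng: np.random.Generator, **policy_kw) -> pd.DataFrame:
    """Simulate all runs of one subject; returns the concatenated trial table."""
    frames = []
    for run in range(config.n_runs):
        env = generate_environment(config, rng, run=run)
        frames.append(run_agent(env, policy, rng, config=config, **policy_kw))
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(
    config: TaskConfig,
    n_subjects: int,
    policy: str = "softmax",
    master_seed: int = 0,
    **policy_kw,
) -> list[pd.DataFrame]:
    """Simulate ``n_subjects`` independent subjects, one trial table each."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config.validate()
    return [
        simulate_subject(config, policy, subject_rng(master_seed, s), **policy_kw)
        for s in range(n_subjects)
    ]
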