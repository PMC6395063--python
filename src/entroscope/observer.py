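"""Normative Bayesian observer for the restless bandit.

The observer maintains a joint posterior over two latent variables: which of
the four available options is currently the high-reward option (hypothesis
h in {0..3}, indexing positions within the run's available set) and what its
payout rate P is (a discrete grid p = 0.30, 0.31, ..., 1.00; 71 values).
Low-payout options always pay at a fixed 0.2, so the likelihood of a reward
under hypothesis h after choosing position L at rate p is

    M[h, L, p] = p   if h == L
                 0.2 otherwise

After each outcome the joint is updated by Bayes' rule and renormalised; the
prior entering the next trial mixes the posterior with a uniform grid
("leak"): prior = (1 - s) * posterior + s * uniform, with switch probability
s = 1/20 by default. The leak keeps a floor under the model's uncertainty so
beliefs never freeze.

Per-trial summaries: the option marginals p(H_i), their entropy
-sum_i p(H_i) log p(H_i) (the model-entropy regressor; natural log by
default), a relative-uncertainty scalar, and expected values
EV(i) = sum_{h,p} mass[h,p] * M[h,i,p].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ObserverConfig",
    "BeliefGrid",
    "init_belief",
    "update_with_outcome",
    "apply_leak",
    "run_observer",
    "entropy",
    "belief_summaries",
]

N_HYPOTHESES = 4


def _default_grid() -> np.ndarray:
    return np.round(np.arange(0.30, 1.0 + 1e-9, 0.01), 10)


@dataclass
class ObserverConfig:
    """Observer parameters. Defaults are the study's fixed values."""

    s: float = 1.0 / 20.0
    p_grid: np.ndarray = field(default_factory=_default_grid)
    payout_low: float = 0.2
    log_base: float = np.e

    def validate(self) -> None:
        if not (0 <= self.s < 1):
            raise ValueError("leak s must lie in [0, 1)")
        g = np.asarray(self.p_grid, dtype=float)
        if g.ndim != 1 or len(g) < 1 or np.any(np.diff(g) <= 0):
            raise ValueError("p_grid must be strictly increasing")
        if g[0] <= 0 or g[-1] > 1:
            raise ValueError("p_grid values must lie in (0, 1]")


@dataclass
class BeliefGrid:
    """Joint belief p(H = h and P = p) on a 4 x len(p_grid) grid."""

    mass: np.ndarray  # (4, n_grid), sums to 1
    config: ObserverConfig

    @property
    def n_cells(self) -> int:
        return self.mass.size

    def copy(self) -> "BeliefGrid":
        return BeliefGrid(self.mass.copy(), self.config)


def init_belief(config: ObserverConfig | None = None) -> BeliefGrid:
    """Uniform joint belief: 1/(4 * n_grid) per cell."""
    config = config or ObserverConfig()
    config.validate()
    n_grid = len(config.p_grid)
    mass = np.full((N_HYPOTHESES, n_grid), 1.0 / (N_HYPOTHESES * n_grid))
    return BeliefGrid(mass, config)


def _likelihood(config: ObserverConfig, chosen: int, outcome: int) -> np.ndarray:
    """Likelihood matrix over the (h, p) grid for one observation."""
    grid = np.asarray(config.p_grid, dtype=float)
    lik = np.full((N_HYPOTHESES, len(grid)), config.payout_low)
    lik[chosen, :] = grid
    if outcome == 0:
        lik = 1.0 - lik
    return lik


def update_with_outcome(belief: BeliefGrid, chosen: int, outcome: int) -> BeliefGrid:
    """Bayes update of the joint belief after observing one outcome.

    ``chosen`` is the hypothesis index (position of the chosen option within
    the available set), ``outcome`` 1 for reward, 0 for omission.
    """
    if not 0 <= chosen < N_HYPOTHESES:
        raise ValueError(f"chosen hypothesis index {chosen} out of range")
    if outcome not in (0, 1):
        raise ValueError("outcome must be 0 or 1")
    post = belief.mass * _likelihood(belief.config, chosen, outcome)
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError("zero or non-finite total likelihood")
    return BeliefGrid(post / total, belief.config)


def apply_leak(belief: BeliefGrid, s: float | None = None) -> BeliefGrid:
    """Mix the belief with the uniform grid: (1-s)*belief + s*uniform."""
    s = belief.config.s if s is None else s
    if not (0 <= s < 1):
        raise ValueError("leak s must lie in [0, 1)")
    uniform = 1.0 / belief.n_cells
    return BeliefGrid((1.0 - s) * belief.mass + s * uniform, belief.config)


def entropy(marginals: np.ndarray, log_base: float = np.e) -> float:
    """Shannon entropy -sum p log p with 0 log 0 := 0."""
    p = np.asarray(marginals, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative probabilities")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if log_base != np.e:
        h /= np.log(log_base)
    return h


def belief_summaries(belief: BeliefGrid) -> dict:
    """Marginals over options, relative uncertainty, and per-option EVs.

    Relative uncertainty here is 1 - max_i p(H_i): zero when the model is
    certain, 0.75 under a uniform belief. EV(i) marginalises the payout
    matrix over the joint belief.
    """
    cfg = belief.config
    marg = belief.mass.sum(axis=1)
    grid = np.asarray(cfg.p_grid, dtype=float)
    # EV(i) = sum_p mass[i,p]*p + (1 - marg[i]) * payout_low
    ev = belief.mass @ grid + (1.0 - marg) * cfg.payout_low
    return {
        "marginals": marg,
        "relative_uncertainty": float(1.0 - marg.max()),
        "expected_value": ev,
        "entropy": entropy(marg, cfg.log_base),
    }


def run_observer(
    trials: pd.DataFrame,
    config: ObserverConfig | None = None,
    available_ids: list[tuple[int, ...]] | None = None,
    keep_posteriors: bool = False,
) -> pd.DataFrame:
    """Run the observer over a trial table; one summary row per trial.

    Runs are processed independently, each starting from a uniform belief.
    Reported quantities come from the posterior AFTER incorporating that
    trial's outcome (the model state at the point of feedback); the leak is
    applied between trial t's posterior and trial t+1's prior. The prior
    option marginals entering each trial are also reported (``prior_pH*``),
    since choice policies act on them.

    ``available_ids`` maps run id -> available option tuple; by default the
    hypothesis index of a choice is looked up there. If omitted, option ids
    are assumed to already be hypothesis indices 0..3.
    """
    config = config or ObserverConfig()
    config.validate()
    rows = []
    posteriors = []
    for run, sub in trials.groupby("run", sort=True):
        belief = init_belief(config)
        avail = None
        if available_ids is not None:
            avail = list(available_ids[int(run) % len(available_ids)])
        ts = sub["t"].to_numpy()
        chosen_arr = sub["chosen"].to_numpy()
        outcome_arr = sub["outcome"].to_numpy()
        for k in range(len(sub)):
            c = int(chosen_arr[k])
            if avail is not None:
                if c not in avail:
                    raise ValueError(f"chosen option {c} not available in run {run}")
                h = avail.index(c)
            else:
                h = c
            prior_marg = belief.mass.sum(axis=1)
            belief = update_with_outcome(belief, h, int(outcome_arr[k]))
            s = belief_summaries(belief)
            row = {
                "run": int(run),
                "t": int(ts[k]),
                "chosen": c,
                "chosen_h": h,
                "outcome": int(outcome_arr[k]),
                "entropy": s["entropy"],
                "relative_uncertainty": s["relative_uncertainty"],
                "ev_chosen": float(s["expected_value"][h]),
            }
            for i in range(N_HYPOTHESES):
                row[f"pH{i + 1}"] = float(s["marginals"][i])
                row[f"prior_pH{i + 1}"] = float(prior_marg[i])
                row[f"ev{i + 1}"] = float(s["expected_value"][i])
            rows.append(row)
            if keep_posteriors:
                posteriors.append(belief.mass.copy())
            belief = apply_leak(belief)
    out = pd.DataFrame(rows)
    if keep_posteriors:
        out.attrs["posteriors"] = np.array(posteriors)
    return out
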