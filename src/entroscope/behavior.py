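"""Explore/exploit segmentation, softmax policy fits, switch regressions.

An exploit block starts on the first trial where the agent selects the true
high-reward option and is rewarded, and ends on the last trial before the
choice switches to a different option (so within a block all choices are for
one option). Everything else is explore. "Core exploit" trials additionally
sit at least k trials (default 5) from both the preceding and the following
choice switch, with run boundaries counting as switches — these are the
trials on which the overt action is stable and only the latent belief moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "label_phases",
    "core_exploit_mask",
    "fit_softmax_policy",
    "switch_logistic",
    "SoftmaxFit",
]

BETA_MAX = 100.0


def _label_run(chosen: np.ndarray, outcome: np.ndarray, true_high: np.ndarray,
               block_offset: int) -> tuple[np.ndarray, np.ndarray]:
    """Label one run. Returns (phase bool exploit, block ids with -1 = none)."""
    n = len(chosen)
    exploit = np.zeros(n, dtype=bool)
    block_id = np.full(n, -1, dtype=int)
    bid = block_offset
    t = 0
    while t < n:
        if chosen[t] == true_high[t] and outcome[t] == 1:
            # block runs while the choice stays the same (even if the
            # environment switches away mid-block: the end rule is choice-based)
            end = t
            while end + 1 < n and chosen[end + 1] == chosen[t]:
                end += 1
            exploit[t : end + 1] = True
            block_id[t : end + 1] = bid
            bid += 1
            t = end + 1
        else:
            t += 1
    return exploit, block_id


def label_phases(trials: pd.DataFrame) -> pd.DataFrame:
    """Append phase, exploit_block_id and core_exploit columns to a trial table."""
    required = {"run", "chosen", "outcome", "true_high"}
    if not required <= set(trials.columns):
        raise ValueError(f"trial table missing columns {required - set(trials.columns)}")
    out = trials.copy()
    exploit = np.zeros(len(out), dtype=bool)
    block_id = np.full(len(out), -1, dtype=int)
    offset = 0
    for _, idx in out.groupby("run", sort=True).indices.items():
        idx = np.sort(idx)
        ex, bid = _label_run(
            out["chosen"].to_numpy()[idx],
            out["outcome"].to_numpy()[idx],
            out["true_high"].to_numpy()[idx],
            offset,
        )
        exploit[idx] = ex
        block_id[idx] = bid
        if bid.max() >= 0:
            offset = bid.max() + 1
    out["phase"] = np.where(exploit, "exploit", "explore")
    out["exploit_block_id"] = block_id
    out["core_exploit"] = core_exploit_mask(out)
    return out


def core_exploit_mask(labels: pd.DataFrame, k: int = 5) -> np.ndarray:
    """Exploit trials >= k trials from both surrounding choice switches.

    A switch at trial s means chosen[s] != chosen[s-1]; run start counts as a
    switch at trial 0 and run end as a switch one past the last trial.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    mask = np.zeros(len(labels), dtype=bool)
    exploit = (labels["phase"].to_numpy() == "exploit") if "phase" in labels else np.ones(len(labels), bool)
    for _, idx in labels.groupby("run", sort=True).indices.items():
        idx = np.sort(idx)
        chosen = labels["chosen"].to_numpy()[idx]
        n = len(chosen)
        switches = [0] + [s for s in range(1, n) if chosen[s] != chosen[s - 1]] + [n]
        switches = np.asarray(switches)
        for j, t in enumerate(range(n)):
            prev_sw = switches[switches <= t].max()
            next_sw = switches[switches > t].min()
            mask[idx[t]] = (t - prev_sw >= k) and (next_sw - t >= k)
    return mask & exploit


@dataclass
class SoftmaxFit:
    beta_explore: float
    beta_exploit: float
    accuracy_explore: float
    accuracy_exploit: float
    log_likelihood: float
    explore_at_bound: bool = False
    exploit_at_bound: bool = False
    explore_skipped: bool = False
    exploit_skipped: bool = False


def _neg_loglik(beta: float, beliefs: np.ndarray, chosen_h: np.ndarray) -> float:
    z = beta * beliefs
    z -= z.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return -float(logp[np.arange(len(chosen_h)), chosen_h].sum())


def _fit_phase(beliefs: np.ndarray, chosen_h: np.ndarray) -> tuple[float, float, float, bool]:
    res = optimize.minimize_scalar(
        _neg_loglik, bounds=(0.0, BETA_MAX), method="bounded", args=(beliefs, chosen_h)
    )
    beta = float(res.x)
    # accuracy of the fitted policy's modal prediction; argmax ties -> lowest id
    pred = np.argmax(beliefs, axis=1) if beta > 0 else np.zeros(len(chosen_h), int)
    acc = float(np.mean(pred == chosen_h))
    return beta, acc, -float(res.fun), beta >= BETA_MAX - 1e-3


def fit_softmax_policy(trials: pd.DataFrame, beliefs: pd.DataFrame,
                       min_trials: int = 5) -> SoftmaxFit:
    """Fit one softmax inverse temperature per phase by maximum likelihood.

    The policy for trial t acts on the option beliefs entering the trial
    (post-leak prior marginals, ``prior_pH*`` in the belief series):
    p(choice=i) is proportional to exp(beta * p(H_i)) over the four
    available options.
    """
    if "phase" not in trials.columns:
        raise ValueError("trials must carry phase labels (run label_phases first)")
    prior_cols = [f"prior_pH{i}" for i in range(1, 5)]
    b = beliefs[prior_cols].to_numpy()
    chosen_h = beliefs["chosen_h"].to_numpy()
    phase = trials["phase"].to_numpy()
    if len(b) != len(phase):
        raise ValueError("trials and beliefs misaligned")

    results = {}
    ll = 0.0
    for name in ("explore", "exploit"):
        sel = phase == name
        if sel.sum() < min_trials:
            results[name] = (np.nan, np.nan, 0.0, False, True)
            continue
        beta, acc, loglik, at_bound = _fit_phase(b[sel], chosen_h[sel])
        results[name] = (beta, acc, loglik, at_bound, False)
        ll += loglik
    return SoftmaxFit(
        beta_explore=results["explore"][0],
        beta_exploit=results["exploit"][0],
        accuracy_explore=results["explore"][1],
        accuracy_exploit=results["exploit"][1],
        log_likelihood=ll,
        explore_at_bound=results["explore"][3],
        exploit_at_bound=results["exploit"][3],
        explore_skipped=results["explore"][4],
        exploit_skipped=results["exploit"][4],
    )


def _subject_switch_slope(trials: pd.DataFrame, beliefs: pd.DataFrame,
                          predictor: str) -> float | None:
    """Logistic slope of next-trial switching on the predictor, one subject.

    Analysis set: exploit trials with reward omission that are not the last
    trial of their run. Returns None when the subject must be excluded
    (no omission trials, or all-same outcomes).
    """
    import statsmodels.api as sm

    phase = trials["phase"].to_numpy()
    chosen = trials["chosen"].to_numpy()
    run = trials["run"].to_numpy()
    outcome = trials["outcome"].to_numpy()
    x = beliefs[predictor].to_numpy()

    n = len(trials)
    not_last = np.arange(n) < n - 1
    same_run_next = np.zeros(n, bool)
    same_run_next[:-1] = run[:-1] == run[1:]
    sel = (phase == "exploit") & (outcome == 0) & not_last & same_run_next
    if sel.sum() < 3:
        return None
    switch_next = np.zeros(n, bool)
    switch_next[:-1] = chosen[1:] != chosen[:-1]
    y = switch_next[sel].astype(float)
    if y.min() == y.max():
        return None
    X = sm.add_constant(x[sel])
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.params[1]) or abs(fit.params[1]) > 50:
            raise RuntimeError("separation")
        return float(fit.params[1])
    except Exception:
        # complete or quasi-separation: ridge-penalised fallback
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0).fit(x[sel].reshape(-1, 1), y)
        return float(clf.coef_[0, 0])


def switch_logistic(cohort_trials: list[pd.DataFrame], cohort_beliefs: list[pd.DataFrame],
                    predictor: str = "entropy") -> dict:
    """Does belief uncertainty predict abandoning exploitation?

    Per subject, a logistic regression of "next trial initiates exploration"
    on the predictor (entropy or relative_uncertainty), restricted to exploit
    trials with reward omission; the subject slopes are then tested against
    zero with a one-sample t-test.
    """
    if predictor not in ("entropy", "relative_uncertainty"):
        raise ValueError(f"unknown predictor {predictor!r}")
    slopes, excluded = [], []
    for i, (tr, be) in enumerate(zip(cohort_trials, cohort_beliefs)):
        slope = _subject_switch_slope(tr, be, predictor)
        if slope is None:
            excluded.append(i)
        else:
            slopes.append(slope)
    slopes = np.asarray(slopes)
    if len(slopes) < 2:
        raise ValueError("fewer than 2 usable subjects")
    t, p = stats.ttest_1samp(slopes, 0.0)
    return {
        "slopes": slopes,
        "t": float(t),
        "p": float(p),
        "df": len(slopes) - 1,
        "excluded_subjects": excluded,
    }
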