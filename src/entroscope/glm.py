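"""Trial-wise regression suite, group tests, and permutation inference.

The regression recipes mirror the study's analysis set (GLM1-GLM8): trial
indicators and task regressors predicting univariate activity, model entropy
predicting multivariate representation strength, and pupil-change couplings.
Within-subject fits are ordinary least squares; group inference is a
one-sample t-test on the per-subject betas (the summary-statistics approach,
standing in for a mixed-effects group stage). Whole-volume maps are
corrected by cluster-mass permutation with subject sign-flipping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "build_design",
    "fit_ols",
    "group_ttest",
    "delta_coupling_regression",
    "median_split_contrast",
    "cluster_mass_correction",
    "sample_size_t",
    "GroupResult",
    "GLM_RECIPES",
]

GLM_RECIPES = {
    "GLM1": ["exploit", "explore"],
    "GLM2": ["bias", "entropy", "reward", "switch_next", "last_exploit", "first_exploit"],
    "GLM3": ["exploit", "explore", "entropy", "reward", "switch_next",
             "last_exploit", "first_exploit"],
    "GLM4": ["bias", "entropy"],
    "GLM5": ["bias", "p_exploited"],
    "GLM6": ["bias", "delta_pupil", "delta_entropy"],
    "GLM7": ["bias", "delta_entropy"],
    "GLM8": ["bias", "signal", "delta_entropy", "global_mean"],
}


@dataclass
class GroupResult:
    betas: np.ndarray
    t: float
    df: int
    p: float
    direction: str = "two-sided"
    mean: float = 0.0
    ci95: tuple[float, float] = (np.nan, np.nan)


def _delta_within_run(x: np.ndarray, run: np.ndarray) -> np.ndarray:
    """Forward change x_{t+1} - x_t aligned to trial t; NaN on the last trial
    of each run. Used by the change-coupling regressions (GLM6 family), where
    the predictor is the outcome-evoked change from the current trial to the
    next."""
    d = np.full(len(x), np.nan)
    d[:-1] = x[1:] - x[:-1]
    d[:-1][run[:-1] != run[1:]] = np.nan
    if len(x):
        d[-1] = np.nan
    return d


def _backward_delta_within_run(x: np.ndarray, run: np.ndarray) -> np.ndarray:
    """Backward change x_t - x_{t-1}; NaN on the first trial of each run.
    Used where the regressor is the change arriving AT trial t (entropy-change
    regressors of GLM7/GLM8)."""
    d = np.full(len(x), np.nan)
    d[1:] = x[1:] - x[:-1]
    d[1:][run[1:] != run[:-1]] = np.nan
    return d


def build_design(
    recipe: str,
    trials: pd.DataFrame,
    beliefs: pd.DataFrame | None = None,
    pupil_baselines: np.ndarray | None = None,
    extra_series: dict[str, np.ndarray] | None = None,
    per_run_bias: bool = True,
) -> pd.DataFrame:
    """Assemble the named regression recipe as a DataFrame of columns.

    Regressors are built from the labelled trial table and belief series:
    phase indicators, entropy, reward, next-trial choice switching, phase
    transitions, within-run deltas of entropy and pupil baseline, plus any
    caller-supplied series (``signal``, ``global_mean``). ``bias`` expands to
    one indicator column per run when ``per_run_bias`` (runs concatenated);
    otherwise a single column of ones.
    """
    if recipe not in GLM_RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; known: {sorted(GLM_RECIPES)}")
    extra_series = extra_series or {}
    run = trials["run"].to_numpy()
    n = len(trials)
    cols: dict[str, np.ndarray] = {}

    def add(name: str, values: np.ndarray) -> None:
        if name in cols:
            raise ValueError(f"duplicated regressor {name!r}")
        cols[name] = np.asarray(values, dtype=float)

    for name in GLM_RECIPES[recipe]:
        if name == "bias":
            if per_run_bias:
                for r in np.unique(run):
                    add(f"bias_run{int(r)}", (run == r).astype(float))
            else:
                add("bias", np.ones(n))
        elif name == "exploit":
            add("exploit", (trials["phase"].to_numpy() == "exploit").astype(float))
        elif name == "explore":
            add("explore", (trials["phase"].to_numpy() == "explore").astype(float))
        elif name == "entropy":
            add("entropy", beliefs["entropy"].to_numpy())
        elif name == "reward":
            add("reward", trials["outcome"].to_numpy().astype(float))
        elif name == "switch_next":
            chosen = trials["chosen"].to_numpy()
            sw = np.zeros(n)
            sw[:-1] = (chosen[1:] != chosen[:-1]).astype(float)
            sw[:-1][run[:-1] != run[1:]] = 0.0
            add("switch_next", sw)
        elif name == "last_exploit":
            ph = trials["phase"].to_numpy() == "exploit"
            last = np.zeros(n)
            last[:-1] = ph[:-1] & ~ph[1:] & (run[:-1] == run[1:])
            add("last_exploit", last)
        elif name == "first_exploit":
            ph = trials["phase"].to_numpy() == "exploit"
            first = np.zeros(n)
            first[1:] = ph[1:] & ~ph[:-1] & (run[1:] == run[:-1])
            add("first_exploit", first)
        elif name == "p_exploited":
            ph = beliefs[[f"pH{i}" for i in range(1, 5)]].to_numpy()
            add("p_exploited", ph[np.arange(n), beliefs["chosen_h"].to_numpy().astype(int)])
        elif name == "delta_entropy":
            # GLM6 predicts forward changes (current -> next); GLM7/GLM8 use
            # the entropy change arriving at the current trial's outcome
            delta_fn = _delta_within_run if recipe == "GLM6" else _backward_delta_within_run
            add("delta_entropy", delta_fn(beliefs["entropy"].to_numpy(), run))
        elif name == "delta_pupil":
            if pupil_baselines is None:
                raise ValueError("recipe needs pupil baselines")
            add("delta_pupil", _delta_within_run(np.asarray(pupil_baselines, float), run))
        elif name in ("signal", "global_mean"):
            if name not in extra_series:
                raise ValueError(f"recipe needs extra series {name!r}")
            add(name, extra_series[name])
        else:  # pragma: no cover
            raise ValueError(f"unhandled regressor {name!r}")

    X = pd.DataFrame(cols)
    finite = X.notna().all(axis=1).to_numpy()
    Xf = X.loc[finite]
    rank = np.linalg.matrix_rank(Xf.to_numpy())
    if rank < Xf.shape[1]:
        corr = Xf.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"design is rank deficient; most collinear pair: {worst}")
    X.attrs["recipe"] = recipe
    return X


def fit_ols(design: pd.DataFrame, y: np.ndarray, subset: np.ndarray | None = None) -> pd.DataFrame:
    """OLS with classical standard errors; rows with NaN are dropped.

    Returns a table (regressor, beta, se, t) indexed by design column.
    """
    import statsmodels.api as sm

    X = design.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
    if subset is not None:
        keep &= np.asarray(subset, dtype=bool)
    X, y = X[keep], y[keep]
    if len(y) <= X.shape[1]:
        raise ValueError(f"need more observations ({len(y)}) than regressors ({X.shape[1]})")
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {"regressor": list(design.columns), "beta": fit.params, "se": fit.bse, "t": fit.tvalues}
    )


def group_ttest(betas: np.ndarray, direction: str = "two-sided") -> GroupResult:
    """One-sample t-test of per-subject betas against zero."""
    b = np.asarray(betas, dtype=float)
    b = b[np.isfinite(b)]
    if len(b) < 2:
        raise ValueError("need at least 2 subjects")
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[direction]
    res = stats.ttest_1samp(b, 0.0, alternative=alternative)
    sem = b.std(ddof=1) / np.sqrt(len(b))
    tcrit = stats.t.ppf(0.975, len(b) - 1)
    flagged_zero_var = b.std(ddof=1) == 0
    t = float(res.statistic) if not flagged_zero_var else 0.0
    p = float(res.pvalue) if not flagged_zero_var else 1.0
    return GroupResult(
        betas=b, t=t, df=len(b) - 1, p=p, direction=direction,
        mean=float(b.mean()), ci95=(float(b.mean() - tcrit * sem), float(b.mean() + tcrit * sem)),
    )


def _subject_delta_beta(rs, pupil, dent, run, use, lag=0, min_trials=10):
    """Per-subject beta of dRS(t->t+1) on dPupil(t->t+1), entropy-change
    co-regressor and intercept; returns None when too few usable trials."""
    drs = _delta_within_run(rs, run)
    dpup = _delta_within_run(pupil, run)
    if lag > 0:
        dpup = np.r_[np.full(lag, np.nan), dpup[:-lag]]
    elif lag < 0:
        dpup = np.r_[dpup[-lag:], np.full(-lag, np.nan)]
    X = np.column_stack([np.ones(len(rs)), dpup, dent])
    keep = use & np.isfinite(X).all(axis=1) & np.isfinite(drs)
    if keep.sum() < min_trials:
        return None
    beta, *_ = np.linalg.lstsq(X[keep], drs[keep], rcond=None)
    return float(beta[1])


def delta_coupling_regression(
    cohort: list[dict],
    lag: int = 0,
    min_trials: int = 10,
) -> dict:
    """Does the outcome-evoked pupil change predict the change in
    representation strength, on unrewarded core-exploit trials?

    ``cohort`` is a list of per-subject dicts with keys ``rs`` (trial-wise
    representation strength), ``pupil_baseline``, ``entropy``, ``run``,
    ``outcome``, ``core_exploit`` and optionally ``valid`` (pupil retention
    mask). Per subject and reward split, dRS(t->t+1) is regressed on
    dPupil(t->t+1) with dEntropy as co-regressor; group t-tests per split and
    a paired t-test on the split difference follow. ``lag`` shifts the pupil
    delta series by whole trials for the temporal-specificity control.
    """
    rows = {"unrewarded": [], "rewarded": []}
    diffs = []
    excluded = []
    for i, sub in enumerate(cohort):
        run = np.asarray(sub["run"])
        dent = _delta_within_run(np.asarray(sub["entropy"], float), run)
        core = np.asarray(sub["core_exploit"], bool)
        valid = np.asarray(sub.get("valid", np.ones(len(run), bool)), bool)
        betas = {}
        for split, rewarded in (("unrewarded", 0), ("rewarded", 1)):
            use = core & valid & (np.asarray(sub["outcome"]) == rewarded)
            betas[split] = _subject_delta_beta(
                np.asarray(sub["rs"], float), np.asarray(sub["pupil_baseline"], float),
                dent, run, use, lag=lag, min_trials=min_trials,
            )
        if betas["unrewarded"] is None or betas["rewarded"] is None:
            excluded.append(i)
            continue
        rows["unrewarded"].append(betas["unrewarded"])
        rows["rewarded"].append(betas["rewarded"])
        diffs.append(betas["rewarded"] - betas["unrewarded"])
    out = {
        "unrewarded": group_ttest(np.array(rows["unrewarded"])),
        "rewarded": group_ttest(np.array(rows["rewarded"])),
        "difference": group_ttest(np.array(diffs)),
        "excluded_subjects": excluded,
        "lag": lag,
    }
    return out


def median_split_contrast(cohort: list[dict], min_trials: int = 4) -> GroupResult:
    """Mean dRS on high-dPupil trials minus low-dPupil trials, per subject,
    on unrewarded core-exploit trials; group t across subjects.

    Trials at exactly the median pupil change go to the lower half.
    """
    diffs = []
    for sub in cohort:
        run = np.asarray(sub["run"])
        drs = _delta_within_run(np.asarray(sub["rs"], float), run)
        dpup = _delta_within_run(np.asarray(sub["pupil_baseline"], float), run)
        core = np.asarray(sub["core_exploit"], bool)
        valid = np.asarray(sub.get("valid", np.ones(len(run), bool)), bool)
        use = core & valid & (np.asarray(sub["outcome"]) == 0)
        use &= np.isfinite(drs) & np.isfinite(dpup)
        if use.sum() < min_trials:
            continue
        d, r = dpup[use], drs[use]
        if d.min() == d.max():
            raise ValueError("all pupil changes identical; median split undefined")
        med = np.median(d)
        high = d > med
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        diffs.append(float(r[high].mean() - r[~high].mean()))
    return group_ttest(np.array(diffs))


def cluster_mass_correction(
    subject_volumes: np.ndarray,
    voxel_p_threshold: float = 0.001,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    direction: str = "positive",
) -> dict:
    """Cluster-mass family-wise correction of a one-sample group t map.

    ``subject_volumes`` is (n_subjects, nx, ny, nz) per-subject betas. The
    group t map is thresholded one-tailed per direction at the voxelwise
    p-threshold; cluster mass is the summed |t| within each suprathreshold
    cluster; the null is the maximum cluster mass over random subject
    sign-flips. Returns clusters with corrected p-values, the group t map and
    the null distribution.
    """
    if rng is None:
        rng = np.random.default_rng()
    vols = np.asarray(subject_volumes, dtype=float)
    n_sub = vols.shape[0]
    if n_sub < 8:
        raise ValueError("sign-flip permutation needs >= 8 subjects")
    shape = vols.shape[1:]
    flat = vols.reshape(n_sub, -1)
    sumsq = (flat**2).sum(axis=0)
    tcrit = stats.t.ppf(1 - voxel_p_threshold, n_sub - 1)
    sign = 1.0 if direction == "positive" else -1.0

    def tmap_from(signs: np.ndarray) -> np.ndarray:
        m = signs @ flat / n_sub
        var = (sumsq - n_sub * m**2) / (n_sub - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = m / np.sqrt(var / n_sub)
        return np.nan_to_num(t)

    def max_mass(tflat: np.ndarray) -> tuple[float, np.ndarray, int]:
        supra = (sign * tflat > tcrit).reshape(shape)
        lab, n_lab = ndimage.label(supra)
        if n_lab == 0:
            return 0.0, lab, 0
        masses = ndimage.sum_labels(np.abs(tflat).reshape(shape), lab, np.arange(1, n_lab + 1))
        return float(np.max(masses)), lab, n_lab

    t_obs = tmap_from(np.ones(n_sub))
    _, labels, n_lab = max_mass(t_obs)
    obs_masses = (
        ndimage.sum_labels(np.abs(t_obs).reshape(shape), labels, np.arange(1, n_lab + 1))
        if n_lab else np.array([])
    )

    null = np.empty(n_perm)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    for i in range(n_perm):
        null[i], _, _ = max_mass(tmap_from(signs[i]))

    clusters = []
    for j, mass in enumerate(obs_masses, start=1):
        p_corr = float((null >= mass).mean())
        clusters.append(
            {"label": j, "mass": float(mass), "size": int((labels == j).sum()),
             "p_corrected": p_corr, "survives": p_corr < alpha}
        )
    return {"clusters": clusters, "t_map": t_obs.reshape(shape),
            "cluster_labels": labels, "null_max_mass": null, "alpha": alpha}


def two_sample_power(n_per_group: int, d: float, alpha: float = 0.05,
                     tails: str = "one") -> float:
    """Exact power of an independent two-sample t-test (equal n per group)
    for standardized effect d, via the noncentral t distribution."""
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    if tails == "one":
        tcrit = stats.t.ppf(1 - alpha, df)
        return float(1 - stats.nct.cdf(tcrit, df, ncp))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float((1 - stats.nct.cdf(tcrit, df, ncp)) + stats.nct.cdf(-tcrit, df, ncp))


def sample_size_t(d: float, alpha: float = 0.05, tails: str = "one",
                  power: float = 0.8, n_max: int = 100_000) -> int:
    """Smallest per-group n at which the two-sample t-test reaches the target
    power for effect size d (exact noncentral-t computation, rounded up)."""
    if d <= 0:
        raise ValueError("d must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0.5 < power < 1:
        raise ValueError("power must lie in (0.5, 1)")
    for n in range(2, n_max + 1):
        if two_sample_power(n, d, alpha, tails) >= power:
            return n
    raise ValueError(f"power {power} unattainable for d={d} within n<={n_max}")
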