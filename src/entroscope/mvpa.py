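"""Multivariate representation-strength pipeline.

The decoding scheme follows the cross-run design of the task: each of the
eight options is available in exactly two of the four runs, so the runs are
split into two pairs, each pair covering all eight options. A multinomial
logistic classifier is trained on one pair and tested on the other, and
vice versa, giving every trial a probability for each of the eight options
exactly once.

Before classification, patterns are reduced to the top twenty spatial
principal components of the voxel-voxel covariance (computed over all
trials, training and test together — a deliberate, label-agnostic choice that
:func:`shuffle_bias_check` guards), and the training set is class-balanced
by deterministic oversampling.

The per-trial readout is representation strength: the log of the ratio
between the odds of classifying the trial as the chosen option and the odds
of classifying it as one of the available-but-unchosen options.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import PatternMatrix

__all__ = [
    "pair_runs_split",
    "reduce_dimensions",
    "balance_training_set",
    "train_and_classify",
    "representation_strength",
    "decode_patterns",
    "repstrength_series",
    "residualize_voxelwise",
    "searchlight_map",
    "shuffle_bias_check",
    "DimReduced",
]

N_OPTIONS = 8
CLIP_EPS = 1e-6


def pair_runs_split(availability: dict[int, tuple[int, ...]] | list[tuple[int, ...]]):
    """Split four runs into two pairs, each covering all eight options.

    Returns ``[((train_runs), (test_runs)), ((test_runs), (train_runs))]`` —
    the two fold directions of the chosen pairing, so every trial appears in
    a test set exactly once.
    """
    if isinstance(availability, dict):
        runs = sorted(availability)
        avail = {r: set(availability[r]) for r in runs}
    else:
        runs = list(range(len(availability)))
        avail = {r: set(a) for r, a in enumerate(availability)}
    if len(runs) != 4:
        raise ValueError("expected exactly 4 runs")
    all_options = set(range(N_OPTIONS))
    for (a, b) in itertools.combinations(runs, 2):
        rest = tuple(r for r in runs if r not in (a, b))
        if avail[a] | avail[b] == all_options and avail[rest[0]] | avail[rest[1]] == all_options:
            pair1, pair2 = (a, b), rest
            return [(pair1, pair2), (pair2, pair1)]
    covered = set()
    for r in runs:
        covered |= avail[r]
    raise ValueError(
        "no run pairing covers all options; "
        f"missing entirely: {sorted(all_options - covered)}"
    )


@dataclass
class DimReduced:
    components: np.ndarray  # (k, n_voxels), orthonormal rows
    loadings: np.ndarray    # (n_trials, k)
    eigenvalues: np.ndarray


def reduce_dimensions(activity: np.ndarray, k: int = 20) -> DimReduced:
    """Top-k spatial PCs of the voxel-voxel covariance; loadings by least squares.

    The covariance is taken across all trials. k is capped at the rank of the
    matrix (eigenvalues numerically zero are dropped). Because the retained
    components are orthonormal, the least-squares loadings equal the
    projection of each (mean-centred) trial pattern onto the components.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(activity, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 trials")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / (len(X) - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    tol = max(w[0], 0) * len(w) * np.finfo(float).eps
    rank = int((w > tol).sum())
    k = min(k, max(rank, 1))
    comps = v[:, :k].T
    loadings, *_ = np.linalg.lstsq(comps.T, Xc.T, rcond=None)
    return DimReduced(components=comps, loadings=loadings.T, eigenvalues=w[:k])


def balance_training_set(indices: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Oversample by deterministic cycling until all classes match the max count."""
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0) or len(classes) == 0:
        raise ValueError("empty class in training data")
    target = counts.max()
    out = []
    for c in classes:
        cls_idx = indices[labels == c]
        reps = int(np.ceil(target / len(cls_idx)))
        out.append(np.tile(cls_idx, reps)[:target])
    return np.concatenate(out)


def train_and_classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    C: float = 1.0,
    max_iter: int = 2000,
) -> np.ndarray:
    """Multinomial logistic regression (weak L2); returns (n_test, 8) probabilities.

    Classes absent from the training set get probability 0 (they cannot be
    absent under a valid run pairing, but partial fixtures may omit options).
    """
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=C, max_iter=max_iter, solver="lbfgs")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(train_X, train_y)
    if getattr(clf, "n_iter_", np.array([0])).max() >= max_iter:
        raise RuntimeError(
            f"multinomial logistic regression did not converge in {max_iter} "
            f"iterations (n_train={len(train_X)}, k={train_X.shape[1]})"
        )
    proba = clf.predict_proba(test_X)
    out = np.zeros((len(test_X), N_OPTIONS))
    out[:, clf.classes_.astype(int)] = proba
    return out


def representation_strength(
    probabilities: np.ndarray,
    chosen: int,
    available: tuple[int, ...],
    aggregate: str = "mean",
    eps: float = CLIP_EPS,
) -> float:
    """Log odds ratio of the chosen option against available-but-unchosen ones.

    RS = ln[ odds(p_chosen) / odds(p_unchosen) ] with p_unchosen the mean
    (default) or sum of the probabilities of the available-but-unchosen
    options; probabilities are clipped to [eps, 1-eps] before the odds.
    """
    if chosen not in available:
        raise ValueError(f"chosen option {chosen} not in available set {available}")
    p = np.clip(np.asarray(probabilities, dtype=float), eps, 1.0 - eps)
    p_c = p[chosen]
    unchosen = [o for o in available if o != chosen]
    if aggregate == "mean":
        p_u = p[unchosen].mean()
    elif aggregate == "sum":
        p_u = min(p[unchosen].sum(), 1.0 - eps)
    else:
        raise ValueError("aggregate must be 'mean' or 'sum'")
    return float(np.log((p_c / (1 - p_c)) / (p_u / (1 - p_u))))


def decode_patterns(patterns: PatternMatrix, availability, k: int = 20,
                    C: float = 1.0) -> np.ndarray:
    """Cross-run-pair decoding; returns (n_trials, 8) test probabilities.

    PCA runs once on the full dataset; each fold trains on the balanced
    loadings of its training pair and fills in the probabilities of its test
    pair, so every trial is scored exactly once.
    """
    folds = pair_runs_split(availability)
    red = reduce_dimensions(patterns.activity, k=k)
    proba = np.full((len(patterns.activity), N_OPTIONS), np.nan)
    runs = patterns.runs
    for train_runs, test_runs in folds:
        train_idx = np.where(np.isin(runs, train_runs))[0]
        test_idx = np.where(np.isin(runs, test_runs))[0]
        bal = balance_training_set(train_idx, patterns.labels[train_idx])
        proba[test_idx] = train_and_classify(
            red.loadings[bal], patterns.labels[bal], red.loadings[test_idx], C=C
        )
    return proba


def repstrength_series(patterns: PatternMatrix, availability, k: int = 20,
                       C: float = 1.0, aggregate: str = "mean") -> np.ndarray:
    """Trial-wise representation strength for one region."""
    proba = decode_patterns(patterns, availability, k=k, C=C)
    avail = availability if isinstance(availability, dict) else dict(enumerate(availability))
    return np.array(
        [
            representation_strength(proba[i], int(patterns.labels[i]),
                                    tuple(avail[int(patterns.runs[i])]), aggregate)
            for i in range(len(proba))
        ]
    )


def residualize_voxelwise(patterns: PatternMatrix, nuisance: np.ndarray) -> PatternMatrix:
    """Replace each voxel's trial series by its OLS residual against the
    nuisance regressors (an intercept is appended if absent)."""
    Z = np.asarray(nuisance, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if not np.any(np.ptp(Z, axis=0) == 0):
        Z = np.column_stack([np.ones(len(Z)), Z])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("nuisance matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(Z, patterns.activity, rcond=None)
    resid = patterns.activity - Z @ beta
    return PatternMatrix(resid, patterns.labels.copy(), patterns.runs.copy(), patterns.coords)


def searchlight_map(
    patterns: PatternMatrix,
    mask: np.ndarray,
    statistic,
    radius_voxels: float = 7.0,
    min_voxels: int = 10,
    k: int = 20,
) -> np.ndarray:
    """Run ``statistic(sub_patterns)`` in a sphere around every in-mask voxel.

    ``patterns.coords`` must give integer 3D coordinates; ``mask`` is a 3D
    boolean volume. Returns a volume of statistics (NaN outside the mask or
    where the sphere holds fewer than ``min_voxels`` voxels). ``statistic``
    receives a PatternMatrix restricted to the sphere's voxels.
    """
    if patterns.coords is None:
        raise ValueError("patterns carry no voxel coordinates")
    coords = patterns.coords
    out = np.full(mask.shape, np.nan)
    in_mask = np.array([mask[tuple(c)] for c in coords])
    mask_coords = coords[in_mask]
    mask_cols = np.where(in_mask)[0]
    for ci, center in zip(mask_cols, mask_coords):
        d2 = ((mask_coords - center) ** 2).sum(axis=1)
        sphere = mask_cols[d2 <= radius_voxels**2]
        if len(sphere) < min_voxels:
            continue
        sub = PatternMatrix(patterns.activity[:, sphere], patterns.labels,
                            patterns.runs, coords[sphere])
        out[tuple(center)] = statistic(sub)
    return out


def shuffle_bias_check(
    patterns: PatternMatrix,
    statistic,
    rng: np.random.Generator,
    n_perm: int = 1000,
    observed: float | None = None,
) -> dict:
    """Null distribution of a pipeline statistic under voxel-identity shuffling.

    Each permutation independently permutes the voxel order within every
    trial (preserving each trial's multiset of values, destroying spatial
    structure) and reruns the entire pipeline — including the PCA on all
    trials — via ``statistic``. Guards against bias from performing the
    dimensionality reduction on training and test data together.
    """
    if n_perm < 10:
        warnings.warn("n_perm < 10 gives a very coarse null", stacklevel=2)
    if observed is None:
        observed = statistic(patterns)
    n_trials, n_vox = patterns.activity.shape
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = np.take_along_axis(
            patterns.activity,
            rng.permuted(np.tile(np.arange(n_vox), (n_trials, 1)), axis=1),
            axis=1,
        )
        null[i] = statistic(
            PatternMatrix(shuffled, patterns.labels, patterns.runs, patterns.coords)
        )
    rank = float((np.abs(null) >= abs(observed)).mean())
    return {"null": null, "observed": float(observed), "p_two_sided": rank}
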