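"""Synthetic neural, univariate and pupillometric data generators.

These generators plant the statistical structure that the downstream
analyses are designed to detect, so every stage of the pipeline can be
validated by effect recovery without any real recordings:

state-coding regions
    trial patterns are belief-weighted mixtures of fixed option prototypes
    (the weighting of each option is the model's probability that it is the
    high-reward option), so decoder selectivity for the chosen option drops
    as model entropy rises;
action-coding regions
    trial patterns encode only the chosen option (plus optional bleed onto a
    designated neighbouring option), so they decode well but carry no
    entropy signal;
pupil traces
    per-trial baseline pupil level rises after reward omissions by an amount
    proportional to a latent neuromodulatory pulse tied to the trial's
    entropy increase, and the elevation is sustained until the choice
    switches;
univariate signals
    per-trial scalars coupled to the trial-to-trial change in entropy.

The pupil -> representation coupling is planted through a shared latent
pulse: the same pulse that raises the next trial's pupil baseline also
flattens the belief weights used to mix the next trial's state-region
pattern. The pulse carries trial-specific gain beyond the entropy change
itself, so the coupling is recoverable with entropy change as a co-regressor.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "NeuralGenConfig",
    "PupilGenConfig",
    "entropy_pulses",
    "generate_state_region_patterns",
    "generate_action_region_patterns",
    "generate_pupil_trace",
    "generate_univariate_signal",
    "generate_cohort_dataset",
    "accumulated_flattening",
    "accumulated_pulse_state",
    "PatternMatrix",
]

N_OPTIONS = 8


@dataclass
class PatternMatrix:
    """Trials x voxels activity with per-trial labels."""

    activity: np.ndarray          # (n_trials, n_voxels)
    labels: np.ndarray            # chosen option id per trial
    runs: np.ndarray              # run id per trial
    coords: np.ndarray | None = None  # optional (n_voxels, 3) voxel coordinates

    def __post_init__(self) -> None:
        if len(self.activity) != len(self.labels) or len(self.labels) != len(self.runs):
            raise ValueError("activity, labels and runs must have equal length")


@dataclass
class NeuralGenConfig:
    n_voxels: int = 120
    region_kind: str = "state_mixture"  # or "action_code"
    gain: float = 1.0
    noise_sd: float = 1.0
    neighbor_bleed: float = 0.0
    orthogonalize: bool = False
    volume_shape: tuple[int, int, int] | None = None

    def validate(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.region_kind not in ("state_mixture", "action_code"):
            raise ValueError(f"unknown region_kind {self.region_kind!r}")
        if not (0 <= self.neighbor_bleed < 1):
            raise ValueError("neighbor_bleed must lie in [0, 1)")


@dataclass
class PupilGenConfig:
    sample_rate: float = 100.0       # Hz; 1000 Hz mirrors eyetracker hardware
    trial_duration_s: float = 2.0    # synthetic trial length
    feedback_offset_s: float = 0.05  # feedback this long before trial end
    baseline_mean: float = 1000.0    # arbitrary pupil-area units
    coupling_a: float = 50.0         # baseline rise per unit pulse
    extra_flattening_c: float = 0.6  # belief flattening per unit pulse; 0 = uncoupled
    pulse_gain_sd: float = 0.5       # lognormal sd of the pulse's private gain
    blink_rate: float = 0.05         # blinks per second
    blink_duration_s: float = 0.1
    noise_sd: float = 5.0

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be >= 0")


def option_prototypes(n_voxels: int, rng: np.random.Generator,
                      orthogonalize: bool = False) -> np.ndarray:
    """Fixed (8, n_voxels) standard-normal prototypes, one per option."""
    protos = rng.standard_normal((N_OPTIONS, n_voxels))
    if orthogonalize:
        q, _ = np.linalg.qr(protos.T)
        protos = q.T[:N_OPTIONS] * np.sqrt(n_voxels)
    return protos


def entropy_pulses(trials: pd.DataFrame, beliefs: pd.DataFrame,
                   rng: np.random.Generator, gain_sd: float = 0.5) -> np.ndarray:
    """Latent neuromodulatory pulse per trial.

    z_t = u_t * max(entropy_t - entropy_{t-1}, 0) on unrewarded trials, else 0,
    with a private lognormal gain u_t (median 1). Entropy differences are
    taken within run; the first trial of a run has no pulse.
    """
    ent = beliefs["entropy"].to_numpy()
    run = trials["run"].to_numpy()
    outcome = trials["outcome"].to_numpy()
    dent = np.zeros(len(ent))
    dent[1:] = ent[1:] - ent[:-1]
    dent[np.r_[True, run[1:] != run[:-1]]] = 0.0
    gains = np.exp(rng.normal(0.0, gain_sd, size=len(ent))) if gain_sd > 0 else np.ones(len(ent))
    return np.where(outcome == 0, gains * np.clip(dent, 0.0, None), 0.0)


def accumulated_pulse_state(trials: pd.DataFrame, pulses: np.ndarray, c: float,
                            cap: float = np.inf) -> np.ndarray:
    """Persistent pulse-driven state: S_{t+1} = min(cap, S_t + c * z_t).

    The state resets to zero whenever the choice switches (a new belief is
    formed) or a new run starts. Both the pupil baseline elevation and the
    extra representation flattening integrate the latent pulses this way, so
    their trial-to-trial changes move together only when a new pulse arrives
    — that is, only on unrewarded trials — which makes the planted
    pupil -> representation coupling specific to reward omission and to lag
    zero, as in the sustained post-omission pupil elevation it emulates.
    """
    run = trials["run"].to_numpy()
    chosen = trials["chosen"].to_numpy()
    S = np.zeros(len(trials))
    for t in range(1, len(trials)):
        if run[t] != run[t - 1] or chosen[t] != chosen[t - 1]:
            S[t] = 0.0
        else:
            S[t] = min(cap, S[t - 1] + c * pulses[t - 1])
    return S


def accumulated_flattening(trials: pd.DataFrame, pulses: np.ndarray, c: float,
                           cap: float = 0.95) -> np.ndarray:
    """Flattening state in [0, cap]; see :func:`accumulated_pulse_state`."""
    return accumulated_pulse_state(trials, pulses, c, cap=cap)


def generate_state_region_patterns(
    trials: pd.DataFrame,
    beliefs: pd.DataFrame,
    config: NeuralGenConfig,
    rng: np.random.Generator,
    pulses: np.ndarray | None = None,
    flattening_c: float = 0.0,
) -> PatternMatrix:
    """Belief-weighted mixture patterns (a probabilistic state code).

    Trial t's pattern is gain * sum_i w_i * proto_{option_i} + noise where
    w_i are the trial's posterior option marginals p(H_i) over the run's four
    available options. When ``flattening_c`` > 0 and pulses are supplied,
    the weights are additionally mixed toward uniform by the accumulated
    flattening state (see :func:`accumulated_flattening`), planting the
    pupil -> representation link.
    """
    config.validate()
    if config.region_kind != "state_mixture":
        raise ValueError("config.region_kind must be 'state_mixture'")
    if len(trials) != len(beliefs):
        raise ValueError("trials and beliefs misaligned")
    protos = option_prototypes(config.n_voxels, rng, config.orthogonalize)

    run = trials["run"].to_numpy()
    chosen = trials["chosen"].to_numpy()
    marg = beliefs[[f"pH{i}" for i in range(1, 5)]].to_numpy().copy()

    if flattening_c > 0 and pulses is not None:
        flat = accumulated_flattening(trials, pulses, flattening_c)
        marg = (1.0 - flat[:, None]) * marg + flat[:, None] * 0.25

    # per-trial available option ids: recover from beliefs' chosen_h mapping
    avail_per_run = _available_sets(trials, beliefs)
    n_trials = len(trials)
    acts = np.empty((n_trials, config.n_voxels))
    for r, avail in avail_per_run.items():
        sel = run == r
        acts[sel] = marg[sel] @ protos[list(avail)]
    acts *= config.gain
    acts += rng.normal(0.0, config.noise_sd, size=acts.shape)
    coords = _grid_coords(config)
    return PatternMatrix(acts, chosen.copy(), run.copy(), coords)


def _available_sets(trials: pd.DataFrame, beliefs: pd.DataFrame) -> dict[int, tuple[int, ...]]:
    """Reconstruct each run's ordered available-option tuple.

    Uses the (chosen, chosen_h) pairs in the belief series; falls back to the
    sorted set of chosen options when a position was never sampled.
    """
    out: dict[int, tuple[int, ...]] = {}
    run = trials["run"].to_numpy()
    chosen = trials["chosen"].to_numpy()
    chosen_h = beliefs["chosen_h"].to_numpy()
    for r in np.unique(run):
        sel = run == r
        mapping: dict[int, int] = {}
        for h, c in zip(chosen_h[sel], chosen[sel]):
            mapping[int(h)] = int(c)
        if len(mapping) < 4:
            # unsampled positions: fill with unseen options in sorted order
            seen = set(mapping.values())
            rest = sorted(set(chosen[sel]) - seen)
            pool = iter(rest)
            for h in range(4):
                if h not in mapping:
                    mapping[h] = next(pool, -1)
        out[int(r)] = tuple(mapping[h] for h in range(4))
    return out


def generate_action_region_patterns(
    trials: pd.DataFrame,
    config: NeuralGenConfig,
    rng: np.random.Generator,
) -> PatternMatrix:
    """Pure action-code patterns: chosen-option prototype plus optional bleed
    onto the next option id (mod 8); weights never depend on beliefs."""
    config.validate()
    if config.region_kind != "action_code":
        raise ValueError("config.region_kind must be 'action_code'")
    protos = option_prototypes(config.n_voxels, rng, config.orthogonalize)
    chosen = trials["chosen"].to_numpy()
    neighbor = (chosen + 1) % N_OPTIONS
    acts = config.gain * (protos[chosen] + config.neighbor_bleed * protos[neighbor])
    acts = acts + rng.normal(0.0, config.noise_sd, size=acts.shape)
    coords = _grid_coords(config)
    return PatternMatrix(acts, chosen.copy(), trials["run"].to_numpy().copy(), coords)


def _grid_coords(config: NeuralGenConfig) -> np.ndarray | None:
    if config.volume_shape is None:
        return None
    shape = config.volume_shape
    if int(np.prod(shape)) < config.n_voxels:
        raise ValueError("volume_shape too small for n_voxels")
    idx = np.arange(config.n_voxels)
    return np.stack(np.unravel_index(idx, shape), axis=1)


def generate_pupil_trace(
    trials: pd.DataFrame,
    beliefs: pd.DataFrame,
    config: PupilGenConfig,
    rng: np.random.Generator,
    pulses: np.ndarray | None = None,
) -> dict:
    """Continuous pupil trace for one subject's trial table.

    Each trial occupies a fixed-duration segment at a per-trial baseline
    level; each latent pulse z_t (zero on rewarded trials) raises the next
    trial's baseline by a * z_t, and the elevation is sustained until the
    choice switches or the run ends (see :func:`accumulated_pulse_state`).
    Feedback lands
    ``feedback_offset_s`` before the segment end. Blinks are Poisson gaps of
    missing samples; Gaussian measurement noise is added everywhere.

    Returns a dict with ``trace`` (DataFrame: time_ms, value, is_missing, run),
    ``feedback_ms``, ``baseline_level`` (the planted per-trial levels) and
    ``pulses``.
    """
    config.validate()
    if pulses is None:
        pulses = entropy_pulses(trials, beliefs, rng, config.pulse_gain_sd)
    run = trials["run"].to_numpy()
    n_trials = len(trials)
    levels = config.baseline_mean + accumulated_pulse_state(trials, pulses, config.coupling_a)

    spt = int(round(config.sample_rate * config.trial_duration_s))  # samples per trial
    n_samples = spt * n_trials
    value = np.repeat(levels, spt)
    value = value + rng.normal(0.0, config.noise_sd, size=n_samples)
    time_ms = np.arange(n_samples) / config.sample_rate * 1000.0
    missing = np.zeros(n_samples, dtype=bool)
    if config.blink_rate > 0:
        total_s = n_samples / config.sample_rate
        n_blinks = rng.poisson(config.blink_rate * total_s)
        blen = max(1, int(round(config.blink_duration_s * config.sample_rate)))
        for start in rng.integers(0, max(1, n_samples - blen), size=n_blinks):
            missing[start : start + blen] = True
    value = np.where(missing, np.nan, value)
    feedback_ms = ((np.arange(n_trials) + 1) * config.trial_duration_s
                   - config.feedback_offset_s) * 1000.0
    trace = pd.DataFrame(
        {
            "time_ms": time_ms,
            "value": value,
            "is_missing": missing,
            "run": np.repeat(run, spt),
        }
    )
    return {
        "trace": trace,
        "feedback_ms": feedback_ms,
        "baseline_level": levels,
        "pulses": pulses,
    }


def generate_univariate_signal(
    beliefs: pd.DataFrame,
    coupling_b: float,
    noise_sd: float,
    rng: np.random.Generator,
    run: np.ndarray | None = None,
) -> np.ndarray:
    """Per-trial scalar signal_t = b * (entropy_t - entropy_{t-1}) + noise.

    The entropy difference is zeroed at run starts when ``run`` is given.
    """
    ent = beliefs["entropy"].to_numpy()
    dent = np.zeros(len(ent))
    dent[1:] = ent[1:] - ent[:-1]
    if run is not None:
        dent[np.r_[True, run[1:] != run[:-1]]] = 0.0
    return coupling_b * dent + rng.normal(0.0, noise_sd, size=len(ent))


def generate_cohort_dataset(
    out_dir: str,
    n_subjects: int = 19,
    task_config=None,
    neural_configs: dict[str, NeuralGenConfig] | None = None,
    pupil_config: PupilGenConfig | None = None,
    master_seed: int = 0,
    policy: str = "softmax",
) -> str:
    """Write a full self-describing synthetic cohort to ``out_dir``.

    Per subject: trial table and belief series as TSV, one HDF5 pattern store
    per region, and a pupil trace TSV. A JSON manifest records every file,
    its shape, and all seeds/configs. The directory is written atomically
    (temp dir + rename), so a crash cannot leave a half-written manifest.
    """
    import h5py

    from . import observer, task_env
    from .behavior import label_phases

    task_config = task_config or task_env.TaskConfig()
    neural_configs = neural_configs or {
        "state": NeuralGenConfig(region_kind="state_mixture"),
        "action": NeuralGenConfig(region_kind="action_code"),
    }
    pupil_config = pupil_config or PupilGenConfig()

    parent = os.path.dirname(os.path.abspath(out_dir)) or "."
    os.makedirs(parent, exist_ok=True)
    tmp = tempfile.mkdtemp(prefix=".cohort-", dir=parent)
    manifest: dict = {
        "master_seed": master_seed,
        "n_subjects": n_subjects,
        "policy": policy,
        "configs": {
            "task": {k: v for k, v in asdict(task_config).items()},
            "neural": {name: asdict(c) for name, c in neural_configs.items()},
            "pupil": asdict(pupil_config),
        },
        "subjects": [],
    }
    for s in range(n_subjects):
        rng = task_env.subject_rng(master_seed, s)
        trials = task_env.simulate_subject(task_config, policy, rng)
        beliefs = observer.run_observer(trials, available_ids=task_config.available_ids)
        labeled = label_phases(trials)
        pulses = entropy_pulses(trials, beliefs, rng, pupil_config.pulse_gain_sd)

        sdir = os.path.join(tmp, f"sub-{s:02d}")
        os.makedirs(sdir)
        entry = {"subject": s, "files": {}}
        tpath = os.path.join(sdir, "trials.tsv")
        labeled.to_csv(tpath, sep="\t", index=False)
        entry["files"]["trials"] = {"path": os.path.relpath(tpath, tmp), "shape": list(labeled.shape)}
        bpath = os.path.join(sdir, "beliefs.tsv")
        beliefs.to_csv(bpath, sep="\t", index=False)
        entry["files"]["beliefs"] = {"path": os.path.relpath(bpath, tmp), "shape": list(beliefs.shape)}

        for name, cfg in neural_configs.items():
            if cfg.region_kind == "state_mixture":
                pm = generate_state_region_patterns(
                    trials, beliefs, cfg, rng,
                    pulses=pulses, flattening_c=pupil_config.extra_flattening_c,
                )
            else:
                pm = generate_action_region_patterns(trials, cfg, rng)
            ppath = os.path.join(sdir, f"patterns_{name}.h5")
            with h5py.File(ppath, "w") as f:
                f.create_dataset("activity", data=pm.activity)
                f.create_dataset("labels", data=pm.labels)
                f.create_dataset("runs", data=pm.runs)
            entry["files"][f"patterns_{name}"] = {
                "path": os.path.relpath(ppath, tmp), "shape": list(pm.activity.shape),
            }

        pupil = generate_pupil_trace(trials, beliefs, pupil_config, rng, pulses=pulses)
        pupath = os.path.join(sdir, "pupil.tsv")
        pupil["trace"].to_csv(pupath, sep="\t", index=False)
        np.savetxt(os.path.join(sdir, "feedback_ms.tsv"), pupil["feedback_ms"], fmt="%.3f")
        entry["files"]["pupil"] = {"path": os.path.relpath(pupath, tmp),
                                   "shape": list(pupil["trace"].shape)}
        entry["files"]["feedback_ms"] = {"path": os.path.relpath(os.path.join(sdir, "feedback_ms.tsv"), tmp),
                                         "shape": [len(pupil["feedback_ms"])]}
        manifest["subjects"].append(entry)

    with open(os.path.join(tmp, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=1, default=str)
    if os.path.exists(out_dir):
        raise FileExistsError(f"{out_dir} already exists")
    os.rename(tmp, out_dir)
    return out_dir
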