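# entroscope

Belief-entropy modelling and neural/pupillometric readout for restless
bandit tasks.

When an agent exploits one arm of a probabilistic bandit, its *overt*
behaviour is constant while its *latent* belief about the environment keeps
moving: rewards sharpen the belief, omissions spread it, and some mechanism
must deliberately inject uncertainty so the model stays flexible when the
world changes. `entroscope` is a simulation-and-analysis toolbox for
studying exactly that loop. It provides:

- a **restless 4-armed bandit** (8 options, 4 available per run; one option
  pays at 70% or 90%, the rest at 20%; the high option jumps every
  ~N(20, 5) trials) and agents that play it;
- a **Bayesian ideal observer** with a grid posterior over
  (which option is high) x (its payout rate p in {0.30, ..., 1.00}) and a
  uniform leak, yielding trial-wise option beliefs p(H_i), their entropy
  `ENT_t = -Σ_i p(H_i) log p(H_i)`, relative uncertainty and expected
  values;
- **explore/exploit segmentation** (a block starts at the first rewarded
  choice of the true high option and ends before the next choice switch;
  *core-exploit* trials sit ≥ 5 trials from both switches), softmax policy
  fits and switch-prediction logistic regressions;
- **synthetic data generators** that plant the structure the analyses are
  meant to detect: state-coding voxel patterns (belief-weighted mixtures of
  option prototypes), action-coding patterns (chosen-option code only),
  pupil traces whose baseline rises after reward omissions, and univariate
  signals coupled to entropy change;
- the **multivariate representation-strength pipeline**: cross-run-pair
  train/test splits, top-20 spatial PCA, class-balanced 8-way multinomial
  logistic decoding, and the trial-wise log odds ratio
  `RS_t = ln[ odds(p_chosen) / odds(p̄_unchosen) ]`, with searchlight
  mapping, voxelwise nuisance residualisation and a voxel-shuffle bias
  permutation guard;
- **pupil preprocessing** (blink interpolation, per-run % normalisation,
  20 ms pre-feedback baselines, lead-in/lost-trial exclusions);
- a **regression suite** (GLM1–GLM8 analogs) with one-sample group tests on
  per-subject betas, reward-split change-coupling regressions, median-split
  contrasts, lag controls, cluster-mass permutation correction with subject
  sign-flipping, and exact noncentral-t power/sample-size calculations.

Because every generator is seeded and every planted effect has a configured
size, the whole chain — simulate → infer → decode → regress — is testable by
effect recovery with no external data.

## Worked example

`examples/03_representation_strength.py` simulates an 8-subject cohort,
decodes representation strength from a state-coding and an action-coding
region, and regresses it on model entropy over core-exploit trials:

```
state_mixture  entropy->RS: mean beta -5.39, t(7)=-11.38, p=9.1e-06, 95% CI [-6.50, -4.27]
action_code    entropy->RS: mean beta +0.18, t(7)=+0.65, p=0.54, 95% CI [-0.49, +0.86]
```

In the state-coding region, higher certainty (lower entropy) means a
stronger representation of the chosen option — the group beta on entropy is
strongly negative. The action-coding region decodes the chosen option just
as well but its confidence is untouched by entropy: the double dissociation
that distinguishes a probabilistic state representation from a motor code.

The other examples cover the observer on a hand-traceable sequence (`01`),
behavioural segmentation and policy fits (`02`), the omission-specific,
lag-0-specific pupil → representation coupling (`04`), cluster-mass
correction on a planted volume (`05`), and the power calculations (`06`).
Each prints a short interpretation with its numbers.

A thin CLI runs the same stages on a cohort directory:

```bash
entroscope simulate --out cohort/ --seed 7 --n-subjects 19
entroscope observe --cohort cohort/ && entroscope label --cohort cohort/
entroscope synth --cohort cohort/ && entroscope pupil --cohort cohort/
entroscope mvpa --cohort cohort/ --region state
entroscope glm --cohort cohort/ --region state
entroscope report --cohort cohort/
entroscope power --d 0.89            # -> 17
```

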