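"""Decode representation strength and test the entropy double dissociation.

State-coding regions mix option prototypes by the model's beliefs, so the
decoder's selectivity for the chosen option (the log-odds representation
strength) falls as entropy rises. Action-coding regions encode only the
chosen option and carry no entropy signal. A small synthetic cohort shows
the dissociation in the group regression of representation strength on
entropy over core-exploit trials.
"""

import numpy as np

from entroscope import behavior, glm, mvpa, observer, synthetic, task_env

cfg = task_env.TaskConfig()
N_SUBJECTS, N_VOXELS = 8, 120

betas = {"state_mixture": [], "action_code": []}
for s in range(N_SUBJECTS):
    rng = task_env.subject_rng(11, s)
    trials = task_env.simulate_subject(cfg, "softmax", rng)
    beliefs = observer.run_observer(trials, available_ids=cfg.available_ids)
    labeled = behavior.label_phases(trials)
    design = glm.build_design("GLM4", labeled, beliefs)
    core = labeled["core_exploit"].to_numpy(bool)
    for kind in betas:
        ncfg = synthetic.NeuralGenConfig(n_voxels=N_VOXELS, region_kind=kind, noise_sd=1.0)
        if kind == "state_mixture":
            pm = synthetic.generate_state_region_patterns(trials, beliefs, ncfg, rng)
        else:
            pm = synthetic.generate_action_region_patterns(trials, ncfg, rng)
        rs = mvpa.repstrength_series(pm, cfg.available_ids)
        fit = glm.fit_ols(design, rs, subset=core)
        betas[kind].append(float(fit.set_index("regressor").loc["entropy", "beta"]))

for kind, b in betas.items():
    res = glm.group_ttest(np.array(b))
    print(f"{kind:14s} entropy->RS: mean beta {res.mean:+.2f}, "
          f"t({res.df})={res.t:+.2f}, p={res.p:.2g}, 95% CI "
          f"[{res.ci95[0]:+.2f}, {res.ci95[1]:+.2f}]")
print()
print("The state-coding region shows a reliably negative entropy effect "
      "(certainty strengthens the chosen option's representation); the "
      "action-coding region's confidence is untouched by model entropy.")
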