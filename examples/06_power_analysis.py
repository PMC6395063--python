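"""Minimum sample sizes from the exact noncentral-t power function.

For an independent two-sample t-test with equal groups, one-tailed
alpha = 0.05 and 80% power, the smallest per-group n for each standardized
effect size d.
"""

from entroscope import glm

for d, label in [(0.89, "univariate model-updating effect"),
                 (1.58, "representation-strength effect"),
                 (1.77, "comparison decoding effect")]:
    n = glm.sample_size_t(d, alpha=0.05, tails="one", power=0.8)
    power = glm.two_sample_power(n, d)
    print(f"d = {d:.2f} ({label}): minimum n = {n:2d} per group "
          f"(achieved power {power:.3f})")
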