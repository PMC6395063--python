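"""Cluster-mass permutation correction on a volume with a planted effect.

Nineteen subjects' statistic volumes are pure noise except for a 4x4x4
block with a standardized effect of 1.5. The group t map is thresholded
voxelwise at p = 0.001, cluster masses are compared against the max-mass
null from random subject sign-flips, and only the planted cluster survives.
"""

import numpy as np

from entroscope import glm

rng = np.random.default_rng(61)
vols = rng.standard_normal((19, 12, 12, 12))
vols[:, 4:8, 4:8, 4:8] += 1.5

res = glm.cluster_mass_correction(vols, voxel_p_threshold=0.001, n_perm=500, rng=rng)
print(f"suprathreshold clusters: {len(res['clusters'])}")
for c in res["clusters"]:
    flag = "SURVIVES" if c["survives"] else "n.s."
    print(f"  cluster {c['label']}: {c['size']} voxels, mass {c['mass']:.1f}, "
          f"corrected p = {c['p_corrected']:.3f}  [{flag}]")
print()
print("The 64-voxel planted block is detected at corrected p < 0.05; "
      "incidental noise clusters, if any, are not.")
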