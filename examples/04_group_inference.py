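"""Second-level inference on synthetic accuracy maps.

Twelve subjects share an above-chance block whose height also tracks a
behavioral score; voxel-FWE finds the block, cluster-FWE finds the
correlation, and the conjunction combines both.
"""

import numpy as np

from mvpakit import VolumeGeometry
from mvpakit.group import GroupConfig, run_group_analysis

geom = VolumeGeometry(shape=(12, 14, 12))
rng = np.random.default_rng(0)
scores = np.sort(rng.uniform(0.3, 0.95, 12))
block = np.s_[4:8, 5:9, 4:8]
maps = []
for s in scores:
    vol = 0.25 + 0.02 * rng.standard_normal(geom.shape)
    vol[block] += 0.05 + 0.25 * s  # decodable, and more so for higher scores
    maps.append(np.where(geom.mask, vol, np.nan))

res = run_group_analysis(maps, scores, chance=0.25, mask=geom.mask,
                         config=GroupConfig(n_perm=500, seed=1))
print(f"voxel-FWE t threshold:      {res.voxel_threshold:.2f} "
      f"(df {res.df_t})")
print(f"accuracy-significant voxels:    {int(res.accuracy_sig.sum())}")
print(f"correlation-significant voxels: {int(res.correlation_sig.sum())}")
print(f"conjunction fraction of mask:   {res.conjunction_fraction:.4f}")
print("cluster table:")
print(res.cluster_table.to_string(index=False))
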