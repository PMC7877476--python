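"""Render one synthetic subject and decode category at selected searchlights.

The expert subject's expertise-coupled regions carry strong class patterns,
the visual-like region a fixed-gain pattern, and the null region none; the
leave-one-run-out SVM accuracy at each region's center reflects that.
"""

import numpy as np

import mvpakit as m
from mvpakit.decoding import DecodingConfig, cv_accuracy
from mvpakit.searchlight import SphereSpec, extract_features

geom = m.VolumeGeometry(shape=(12, 16, 12))
regions = m.default_regions(geom)
schedule = m.make_schedule(seed=0)
bank = m.build_pattern_bank(geom, regions, seed=1)
expert = m.sample_cohort(2, (0, 0, 2), seed=2)[0]
print(f"subject: {expert.subject_id} ({expert.group}, "
      f"expertise {expert.expertise:.2f})")

betas = m.render_beta_series(expert, schedule, bank, regions, geom,
                             noise_sd=1.0, seed=3)
spec = SphereSpec(radius=2)
cfg = DecodingConfig(costs=(0.1, 1.0, 10.0))
for reg in regions:
    center = reg.voxels.mean(axis=0).round().astype(int)
    X = extract_features(betas, center, spec)
    res = cv_accuracy(X, betas.categories, betas.run_labels, cfg)
    print(f"{reg.name:14s} center {tuple(int(c) for c in center)}: "
          f"accuracy {res.accuracy:.3f} (chance {res.chance:.2f}), "
          f"costs {sorted(set(res.selected_costs))}")
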