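"""Run the whole pipeline (simulate -> decode -> group) at desk scale.

The same thing is available from the shell:
    mvpakit all --config config.yaml
"""

import numpy as np

from mvpakit import PipelineConfig, run_pipeline

config = PipelineConfig(
    seed=7, outdir="pipeline_out", n_subjects=6, group_sizes=(2, 2, 2),
    grid=(12, 16, 12), radius=2.0, costs=(0.1,), levels=("category",),
    n_perm=300)
manifest = run_pipeline(config)

res = manifest["group_results"]["category"]
scores = manifest["behavior"]
print(f"behavioral scores: "
      f"{ {s: round(v, 2) for s, v in scores.items()} }")
amaps = manifest["accuracy_maps"]["category"]
mean_acc = {s: round(float(np.nanmean(a.values)), 3)
            for s, a in amaps.items()}
print(f"mean in-mask accuracy per subject: {mean_acc}")
print(f"accuracy-significant voxels: {int(res.accuracy_sig.sum())}")
# at this demo size (6 subjects) the accuracy test has power but the
# brain-behavior correlation rarely survives cluster FWE; 12+ subjects are
# needed for the conjunction (see the acceptance report for a 12-subject run)
print(f"correlation-significant voxels: {int(res.correlation_sig.sum())}")
print(f"conjunction fraction: {res.conjunction_fraction:.4f}")
print(f"artifacts in: {manifest['artifacts']['outdir']}")
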