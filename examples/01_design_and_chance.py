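"""Build the stimulus schedule and derive its analytic quantities.

72 code snippets (4 categories x 18; eleven subcategories, ten of size 6 and
one of size 12) are shown 3 times each across 6 runs of 36 trials, category
counts balanced within run.
"""

from mvpakit import make_schedule, run_duration_seconds
from mvpakit.behavior import behavioral_chance
from mvpakit.decoding import chance_level
from mvpakit.searchlight import sphere_offsets

schedule = make_schedule(seed=0)
schedule.validate()

print(f"trials per subject:        {schedule.n_trials}")
print(f"run duration:              {run_duration_seconds(schedule):.0f} s")
print(f"category counts per run:   "
      f"{schedule.entries.groupby(['run', 'category']).size().unique()}")
print(f"decoding chance, category:    {chance_level([18] * 4):.4f}")
print(f"decoding chance, subcategory: {chance_level([6] * 10 + [12]):.4f}")
print(f"behavioral chance, subcategory task: "
      f"{behavioral_chance('subcategory'):.4f}")
print(f"searchlight voxels at radius 4: {len(sphere_offsets(4))}")
print(f"searchlight voxels at radius 2: {len(sphere_offsets(2))}")
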