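"""Score spatial-discrimination and reversal records and allocate groups.

The pass criterion is 10/12 consecutive correct go/no-go decisions --
chance performance achieves that with probability 79/4096, below the 0.05
design threshold.  Learning speed counts trials from the first opening of
the negative-location box to the pass, bounded 12-36 (36 = completed but
failed), and splits fast/slow at the 17-trial median.
"""

from collections import defaultdict

import numpy as np

import pignet as pn
from pignet.cognition import (
    allocate_groups,
    criterion_tail_probability,
    profiles_from_frame,
)

p = criterion_tail_probability(12, 10, 0.5)
print(f"chance probability of meeting 10/12: {p:.4f} (= 79/4096)")

study = pn.generate_study(n_pens=14, seed=1)
profiles = profiles_from_frame(study.trials)

speeds = [pr.trials_to_pass for pr in profiles if pr.sdt_passed]
print(f"{len(profiles)} pigs tested; {len(speeds)} passed the SDT")
print(f"trials to pass: median {np.median(speeds):.0f}, "
      f"range {min(speeds)}-{max(speeds)}")
fast = sum(1 for pr in profiles if pr.learning_category == "fast")
print(f"fast learners (<= 17 trials): {fast}")
rev = [pr for pr in profiles if pr.reversal_completed]
print(f"reversal: {sum(pr.reversal_passed for pr in rev)}/{len(rev)} passed")

# allocation operates on the pre-regrouping litters of four test pigs:
# the two highest point scorers (SDT pass, above-average speed, reversal
# pass) move to a "high test performance" pen, the other two to "low"
litters = defaultdict(list)
for i, pr in enumerate(profiles):
    litters[f"litter{i // 4}"].append(pr)
groups = allocate_groups(litters)
n_high = sum(1 for g in groups.values() if g == "high")
print(f"regrouping allocation: {n_high} high / {len(groups) - n_high} low")
example = litters["litter0"]
for pr in example:
    print(f"  {pr.pig}: {pr.performance_points} points -> {groups[pr.pig]}")
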