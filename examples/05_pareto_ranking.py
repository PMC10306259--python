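"""Compare the three multiobjective reward schemes on one score matrix.

WS rewards a weighted average that emphasizes the batch's weakest objective;
PRCD and PRTD first sort molecules into Pareto fronts, then rank within each
front by crowding distance (objective-space diversity) or mean Tanimoto
distance (structural diversity). Rewards are in [0, 1] with desired
molecules mapped above 0.5.
"""

import numpy as np

from denovogen.environment import Identity, Objective, get_scorer, score_batch
from denovogen.moo_rank import compute_rewards, non_dominated_sort

molecules = ["CCN", "CCCN", "CCO", "c1ccccc1CN", "c1ccccc1CCO", "CC(C)CN"]
objectives = [
    Objective(get_scorer("contains_nitrogen"), Identity(), 0.5),
    Objective(get_scorer("sa_score_proxy"), Identity(), 0.5),
]
table = score_batch(molecules, objectives)

fronts = non_dominated_sort(table.modified)
print("Pareto fronts (indices, best first):", fronts)
for scheme in ("WS", "PRCD", "PRTD"):
    rewards = compute_rewards(table, scheme)
    print(f"{scheme:5s} rewards:",
          np.array2string(rewards, precision=3))
print("\nmolecules:", molecules)
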