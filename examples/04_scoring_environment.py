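"""Score a batch of molecules with a two-objective environment.

Objective 1: molecular weight through a smooth-hump desirability (plateau
250-400 Da). Objective 2: a binary contains-nitrogen scorer. A molecule is
"desired" only if every modified score meets its threshold; the reward
column comes from the dynamic weighted-sum ranking of the batch.
"""

from denovogen.fixtures import make_env_toy

env = make_env_toy()
batch = [
    "c1ccc(cc1)C(=O)Nc1ccc(CCOC2CCCCC2)cc1",   # ~323 Da, has N -> desired
    "CC(=O)Nc1ccc(O)cc1",                      # 151 Da: too light
    "c1ccc(cc1)C(=O)Oc1ccc(CCOC2CCCCC2)cc1",   # right weight, no N
    "definitely_not_a_molecule",               # invalid
]
table = env.score(batch)
print(table.to_frame().to_string(index=False, float_format="%.3f"))
print("\ndesired = all modified scores >= their thresholds; invalid "
      "molecules score 0 everywhere and earn reward 0.")
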