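"""Integer-equitable mate allocation: the 29-females worked example.

Nine of eighteen adult males carry the mate-acquisition trait.  The 29
receptive females (each mating once) are shared as equitably as possible
among the nine carriers while keeping each male's mate count an integer:
29 = 9 * 3 + 2, so two carriers get 4 mates and seven get 3.  Which two
get the extra mate is arbitrary — and provably irrelevant to the
selection differential, as the second half of the script demonstrates.
"""

import numpy as np

from selcascade import allocate_mates, selection_differential

trait = np.array([1] * 9 + [0] * 9)
outcome = allocate_mates(29, trait)
print("per-male mate counts:", outcome.mates.tolist())
print("total matings:", outcome.n_females, "(= number of females: each mates once)")

s_ref = selection_differential(trait, outcome.mates)
print(f"s_sex = {s_ref:.6f}  (closed form 1 - k/n = {1 - 9 / 18:.6f})")

for seed in range(4):
    rng = np.random.default_rng(seed)
    mates = allocate_mates(29, trait, rng=rng).mates
    s = selection_differential(trait, mates)
    print(f"seed {seed}: extras at {np.flatnonzero(mates == 4).tolist()}, "
          f"s_sex = {s:.6f}")
print("-> the remainder placement never moves the differential")
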