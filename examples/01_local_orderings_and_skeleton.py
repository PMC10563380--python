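"""Local dose sets, toxicity orderings and the CRM skeleton.

Builds the 5 x 3 combination grid used in the dose-optimization
benchmark, enumerates the toxicity orderings of a few neighbourhoods
and prints the indifference-interval skeleton the local CRM uses.
"""

import numpy as np

from locrm import DoseGrid, enumerate_orderings, generate_skeleton, local_set

grid = DoseGrid(rawA=(0.08, 0.16, 0.24, 0.32, 0.40), rawB=(0.08, 0.16, 0.24))
print(f"grid: {grid.J} levels of drug A x {grid.K} levels of drug B")
print("standardized doses A:", np.round(grid.stdA, 2))
print("standardized doses B:", np.round(grid.stdB, 2))

for current in [(3, 2), (1, 1), (5, 1)]:
    ls = local_set(grid, current)
    orderings = enumerate_orderings(ls)
    print(f"\ncurrent dose {current}: |A| = {len(ls.A)}, |B| = {len(ls.B)}, "
          f"{len(orderings)} toxicity ordering(s)")
    for o in orderings:
        print("  ", " < ".join(str(d) for d in sorted(ls.A, key=o.rank)))

# Skeleton for a 5-dose local set: prior toxicity guesses, anchored at the
# target rate (0.30) in the prior-MTD position, spread by the indifference
# halfwidth (0.05).
sk = generate_skeleton(target=0.30, n_doses=5, prior_mtd=4, halfwidth=0.05)
print("\nskeleton (target 0.30, halfwidth 0.05):", np.round(sk.probs, 4))
print("the 4th value is the target exactly; neighbours differ by one "
      "indifference interval under p = pi^exp(a)")
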