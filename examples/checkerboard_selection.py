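"""Map the gentamicin x salicylic-acid checkerboard and pick selection wells.

Simulates overnight ODs for a WT-only culture and a mutant library that
contains 10% of a x5-copy-number clone, then reports the wells that are
lethal to WT but permissive for the mutants (the selection conditions).
"""

import numpy as np

from orievolve import build_ori_reference
from orievolve.population import ClonePopulation, PhenotypeMap
from orievolve.reference import WILD_TYPE, MutantGenotype
from orievolve.simulate.selection import (
    CheckerboardGrowthParams, SelectionModel, build_checkerboard,
    select_conditions, simulate_checkerboard,
)

ori = build_ori_reference(orf_length=966, flank=150, seed=2, wt_copy_number=9.5)
pos = ori.orf_start + 10
alt = "A" if ori.amplicon[pos] != "A" else "G"
mutant = MutantGenotype((ori.substitution(pos, alt),))
library = ClonePopulation(ori, {WILD_TYPE: 900, mutant: 100})
phen = PhenotypeMap(ori, {WILD_TYPE: 9.5, mutant: 47.5})
wt_only = ClonePopulation.wild_type_only(ori, 1000)
wt_phen = PhenotypeMap(ori, {WILD_TYPE: 9.5})

grid = build_checkerboard()  # rows A-H: 3000 -> 23.4 mg/L; cols: 2.44 nM -> 5 uM
od_wt, od_mut = simulate_checkerboard(
    wt_only, library, wt_phen, phen, SelectionModel(), grid,
    CheckerboardGrowthParams(), seed=2,
)
print("WT OD600 surface (rows A-H = decreasing gentamicin):")
for r in range(8):
    print("  " + " ".join(f"{od_wt[r, c]:.2f}" for c in range(12)))

selected = select_conditions(grid, od_wt, od_mut, od_threshold=0.2)
print(f"\n{len(selected)} WT-lethal, mutant-permissive wells (the purple set):")
for cond in selected[:8]:
    print(f"  {cond.well}: {cond.gentamicin:7.1f} mg/L gentamicin, "
          f"{cond.salicylic_acid * 1e9:9.2f} nM salicylic acid")
best = max(selected, key=lambda c: (c.gentamicin, c.salicylic_acid))
print(f"strongest selection condition: {best.well} "
      f"({best.gentamicin:.0f} mg/L + {best.salicylic_acid * 1e6:.2f} uM)")
# These wells are where survival requires the higher copy number, so growing
# the library there enriches copy-up mutants.
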