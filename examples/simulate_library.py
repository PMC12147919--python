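"""Simulate an epPCR mutant library and plant copy-number phenotypes.

Builds a random rep-gene amplicon, mutagenizes 5,000 clones, plants three
causal residues at a x5 copy multiplier and removes replication-dead
(premature-stop) clones.
"""

import numpy as np

from orievolve import build_ori_reference, mutagenize_library
from orievolve.simulate.eppcr import (
    EppcrModel, assign_phenotypes, stop_gain_probability,
)

ori = build_ori_reference(orf_length=966, flank=150, seed=1, wt_copy_number=9.5)
model = EppcrModel(mean_mutations=2.0)
library = mutagenize_library(ori, 5_000, model, seed=1)

loads = np.array([len(g) for g, c in library.clones.items() for _ in range(c)])
print(f"amplicon: {len(ori)} nt, ORF {ori.orf_start}..{ori.orf_end} "
      f"({ori.n_residues} residues)")
print(f"library: {library.total} clones, {library.n_genotypes} distinct genotypes")
print(f"mean substitutions per clone: {loads.mean():.3f} (target 2.0)")

causal = {50: 5.0, 120: 5.0, 250: 5.0}
viable, phenotypes = assign_phenotypes(library, causal, seed=1)
removed = library.total - viable.total
print(f"premature-stop clones removed: {removed} "
      f"({removed / library.total:.1%}; analytic single-hit stop-gain "
      f"probability {stop_gain_probability(ori, model):.4f})")
carriers = sum(
    c for g, c in viable.clones.items()
    if phenotypes.copy_number[g] > ori.wt_copy_number
)
print(f"clones carrying a causal (x5 copy) mutation: {carriers} "
      f"({carriers / viable.total:.2%} of the viable library)")
# The removed fraction reflects epPCR stop-gains; the small causal-carrier
# fraction is what selection must amplify for the screen to see it.
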