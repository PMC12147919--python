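"""Clone populations: genotype -> abundance maps over one reference."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import WILD_TYPE, MutantGenotype, OriReference


@dataclass
class ClonePopulation:
    """A mutant library (or selected culture) as genotype counts.

    ``clones`` maps each :class:`MutantGenotype` to a non-negative integer
    abundance; ``total`` is kept equal to the sum of counts.  A population
    with ``total == 0`` is *extinct* (all clones killed by selection).
    """

    ori: OriReference
    clones: dict = field(default_factory=dict)

    def __post_init__(self):
        for genotype, count in self.clones.items():
            if count < 0:
                raise ValueError("clone counts must be non-negative")
            for sub in genotype.substitutions:
                if self.ori.amplicon[sub.position] != sub.ref_base:
                    raise ValueError(
                        f"substitution {sub} inconsistent with reference"
                    )

    @property
    def total(self) -> int:
        return int(sum(self.clones.values()))

    @property
    def extinct(self) -> bool:
        return self.total == 0

    @property
    def n_genotypes(self) -> int:
        return len(self.clones)

    def genotypes(self) -> list:
        return list(self.clones.keys())

    def counts(self) -> np.ndarray:
        return np.array(list(self.clones.values()), dtype=np.int64)

    def frequencies(self) -> dict:
        total = self.total
        if total == 0:
            return {}
        return {g: c / total for g, c in self.clones.items()}

    def frequency_of(self, genotype: MutantGenotype) -> float:
        total = self.total
        return self.clones.get(genotype, 0) / total if total else 0.0

    def allele_frequency(self, position: int, alt_base: str) -> float:
        """Population frequency of clones carrying a specific substitution."""
        total = self.total
        if total == 0:
            return 0.0
        carrier = 0
        for genotype, count in self.clones.items():
            for sub in genotype.substitutions:
                if sub.position == position and sub.alt_base == alt_base:
                    carrier += count
                    break
        return carrier / total

    @classmethod
    def wild_type_only(cls, ori: OriReference, total: int = 1) -> "ClonePopulation":
        return cls(ori=ori, clones={WILD_TYPE: int(total)})


@dataclass
class PhenotypeMap:
    """Genotype -> plasmid copies per cell for every viable clone.

    Non-viable genotypes (premature stop codons in the rep ORF) are recorded
    separately; they never appear in the population they annotate.
    """

    ori: OriReference
    copy_number: dict = field(default_factory=dict)
    non_viable: set = field(default_factory=set)

    def __post_init__(self):
        for genotype, copies in self.copy_number.items():
            if copies < 0:
                raise ValueError("copy numbers must be non-negative")
        wt_copies = self.copy_number.get(WILD_TYPE)
        if wt_copies is not None and wt_copies != self.ori.wt_copy_number:
            raise ValueError("WT genotype must map to ori.wt_copy_number")

    def copies(self, genotype: MutantGenotype) -> float:
        return self.copy_number[genotype]

    def copies_for(self, population: ClonePopulation) -> np.ndarray:
        return np.array(
            [self.copy_number[g] for g in population.clones], dtype=float
        )
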