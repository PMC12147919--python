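"""Error-prone PCR library simulation with planted copy-number phenotypes.

The mutagenesis model is deliberately simple: each library clone carries a
Poisson number of substitutions (truncated at ``max_mutations``), positions
uniform over the ORF, and alternate bases drawn from a 4x4 substitution
spectrum.  The default spectrum is transition-biased (65% transitions, the
two transversions splitting the rest evenly), reflecting the behaviour of
Mn2+ / unbalanced-dNTP Taq mutagenesis; the realized per-molecule rate of an
actual 12-cycle epPCR is a calibration choice, defaulting to a mean of 2
substitutions per amplicon molecule (the middle of the usual 1-3 target).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .._rng import stream_rng
from ..population import ClonePopulation, PhenotypeMap
from ..reference import (
    WILD_TYPE,
    MutantGenotype,
    OriReference,
    Substitution,
    decode,
    translate,
)

#: transition partner of each base code (A<->G, C<->T), codes ACGT=0123
_TRANSITION = np.array([2, 3, 0, 1])

_ALL_CODONS = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


def transition_biased_spectrum(transition_fraction: float = 0.65) -> np.ndarray:
    """4x4 substitution table: rows = ref base, columns = alt base.

    Each row sums to 1 over the three non-diagonal entries; the transition
    gets ``transition_fraction`` and the two transversions split the rest.
    """
    if not 0 <= transition_fraction <= 1:
        raise ValueError("transition_fraction must lie in [0, 1]")
    spectrum = np.zeros((4, 4))
    tv = (1.0 - transition_fraction) / 2.0
    for ref in range(4):
        for alt in range(4):
            if alt == ref:
                continue
            spectrum[ref, alt] = (
                transition_fraction if alt == _TRANSITION[ref] else tv
            )
    return spectrum


@dataclass
class EppcrModel:
    """Mutation-load and spectrum model for one epPCR reaction."""

    mean_mutations: float = 2.0
    spectrum: np.ndarray = field(default_factory=transition_biased_spectrum)
    max_mutations: int = 10

    def __post_init__(self):
        if self.mean_mutations < 0:
            raise ValueError("mean_mutations must be non-negative")
        spectrum = np.asarray(self.spectrum, dtype=float)
        if spectrum.shape != (4, 4):
            raise ValueError("spectrum must be 4x4")
        if np.any(np.diag(spectrum) != 0):
            raise ValueError("spectrum diagonal must be zero")
        if np.any(spectrum < 0) or not np.allclose(spectrum.sum(axis=1), 1.0):
            raise ValueError("each spectrum row must sum to 1")
        self.spectrum = spectrum


def mutagenize_library(
    ori: OriReference,
    n_clones: int,
    model: EppcrModel | None = None,
    seed=0,
) -> ClonePopulation:
    """Draw an epPCR mutant library of ``n_clones`` molecules.

    Substitution count per clone ~ truncated Poisson(mean_mutations);
    positions uniform over the ORF (the flanks come from the vector and are
    never mutagenized); alt base from the spectrum row of the ref base.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    model = model or EppcrModel()
    rng = stream_rng(seed, "library")

    orf_lo, orf_hi = ori.orf_start, ori.orf_end
    codes = ori.codes
    cum_spectrum = np.cumsum(model.spectrum, axis=1)

    n_muts = np.minimum(
        rng.poisson(model.mean_mutations, size=n_clones), model.max_mutations
    )
    clones: Counter = Counter()
    for k in n_muts:
        if k == 0:
            clones[WILD_TYPE] += 1
            continue
        positions = rng.integers(orf_lo, orf_hi, size=k)
        while len(np.unique(positions)) < k:  # enforce unique positions
            positions = rng.integers(orf_lo, orf_hi, size=k)
        refs = codes[positions]
        # inverse-CDF draw; >= keeps the zero-probability diagonal unreachable
        alts = (rng.random(k)[:, None] >= cum_spectrum[refs]).sum(axis=1)
        genotype = MutantGenotype(
            tuple(
                Substitution(int(p), decode([r]), decode([a]))
                for p, r, a in zip(positions, refs, alts)
            )
        )
        clones[genotype] += 1
    return ClonePopulation(ori=ori, clones=dict(clones))


def assign_phenotypes(
    population: ClonePopulation,
    causal_spec: dict,
    seed=0,
) -> tuple:
    """Plant copy-number phenotypes and remove replication-dead clones.

    ``causal_spec`` maps 1-based residue indices to copy-number multipliers.
    A clone whose protein differs from WT at a causal residue gets
    ``wt_copy_number * multiplier`` (max over the causal residues it hits);
    everything else stays at the WT copy number.  Clones whose ORF acquires a
    premature stop codon are removed: a replication-dead plasmid cannot be
    maintained under marker selection.  The assignment is deterministic; the
    seed parameter is accepted for interface symmetry with the other
    simulators.

    Returns ``(viable_population, phenotype_map)``.
    """
    del seed  # deterministic
    ori = population.ori
    n_res = ori.n_residues
    for residue, multiplier in causal_spec.items():
        if not (1 <= residue <= n_res):
            raise ValueError(f"causal residue {residue} outside ORF (1..{n_res})")
        if multiplier <= 0:
            raise ValueError("copy multipliers must be positive")

    wt_protein = ori.protein
    codon_aa = {c: translate(c) for c in _ALL_CODONS}
    surviving: dict = {}
    copy_number: dict = {}
    non_viable: set = set()
    n_res = ori.n_residues
    for genotype, count in population.clones.items():
        # only mutated codons can change the protein (the WT ORF has no
        # internal stops), so translate just those
        by_codon: dict = {}
        for sub in genotype.substitutions:
            idx = ori.codon_index(sub.position)
            if idx is None:
                continue
            by_codon.setdefault(idx, []).append(sub)
        premature_stop = False
        changed_residues = []
        for idx, subs in by_codon.items():
            codon = list(ori.codon(idx))
            start = ori.orf_start + 3 * (idx - 1)
            for sub in subs:
                codon[sub.position - start] = sub.alt_base
            aa = codon_aa["".join(codon)]
            if aa == "*" and idx < n_res:
                premature_stop = True
                break
            if aa != wt_protein[idx - 1]:
                changed_residues.append(idx)
        if premature_stop:
            non_viable.add(genotype)
            continue
        multipliers = [
            causal_spec[r] for r in changed_residues if r in causal_spec
        ]
        copies = ori.wt_copy_number * (max(multipliers) if multipliers else 1.0)
        surviving[genotype] = count
        copy_number[genotype] = copies

    viable = ClonePopulation(ori=ori, clones=surviving)
    phenotypes = PhenotypeMap(
        ori=ori, copy_number=copy_number, non_viable=non_viable
    )
    return viable, phenotypes


def stop_gain_probability(ori: OriReference, model: EppcrModel) -> float:
    """Analytic P(a single ORF substitution creates a premature stop).

    Enumerates, for every ORF position and alternate base, whether the
    substitution turns its codon into a stop before the terminal codon, and
    weights by the uniform-position x spectrum mutation measure.  Used as an
    independent check on the simulated non-viable fraction.
    """
    orf = ori.orf_seq
    n = len(orf)
    p = 0.0
    for pos in range(n - 3):  # exclude the terminal stop codon
        codon_start = (pos // 3) * 3
        codon = list(orf[codon_start : codon_start + 3])
        ref = orf[pos]
        ref_code = "ACGT".index(ref)
        for alt_code, alt in enumerate("ACGT"):
            if alt == ref:
                continue
            codon[pos - codon_start] = alt
            if "".join(codon) in ("TAA", "TAG", "TGA"):
                p += model.spectrum[ref_code, alt_code] / n
            codon[pos - codon_start] = ref
    return p
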