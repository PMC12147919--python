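"""Amplicon reference frame: the repA-style ORF plus sequencing flanks.

Everything downstream (mutagenesis, read simulation, pileups, enrichment)
shares one coordinate system: 0-based half-open positions on the amplicon,
where the amplicon is the ORF plus fixed-length flanks on either side.
Reports convert to 1-based positions and 1-based residue indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from Bio.Seq import Seq

from ._rng import stream_rng

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)

START_CODON = "ATG"
STOP_CODONS = ("TAA", "TAG", "TGA")

#: the 61 sense codons of the standard genetic code
SENSE_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    """uint8 codes 0..3 -> ACGT string."""
    return _CODE_TO_BASE[np.asarray(codes, dtype=np.intp)].tobytes().decode()


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a nucleotide string with the standard code ('*' = stop)."""
    return str(Seq(seq).translate())


@dataclass(frozen=True, order=True)
class Substitution:
    """A single-nucleotide substitution in amplicon coordinates."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base must differ from alt_base")
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError("bases must be one of ACGT")
        if self.position < 0:
            raise ValueError("position must be non-negative")

    def __str__(self) -> str:  # pos is reported 1-based, e.g. "151:A>G"
        return f"{self.position + 1}:{self.ref_base}>{self.alt_base}"

    @classmethod
    def parse(cls, text: str) -> "Substitution":
        pos, change = text.split(":")
        ref, alt = change.split(">")
        return cls(int(pos) - 1, ref, alt)


@dataclass(frozen=True)
class MutantGenotype:
    """An immutable, position-sorted set of substitutions (empty = WT)."""

    substitutions: tuple = ()

    def __post_init__(self):
        subs = tuple(sorted(self.substitutions, key=lambda s: s.position))
        positions = [s.position for s in subs]
        if len(set(positions)) != len(positions):
            raise ValueError("substitution positions must be unique")
        object.__setattr__(self, "substitutions", subs)

    @property
    def is_wild_type(self) -> bool:
        return not self.substitutions

    def __len__(self) -> int:
        return len(self.substitutions)

    def __str__(self) -> str:
        return ";".join(str(s) for s in self.substitutions) or "WT"

    @classmethod
    def parse(cls, text: str) -> "MutantGenotype":
        if text in ("", "WT"):
            return cls()
        return cls(tuple(Substitution.parse(t) for t in text.split(";")))


WILD_TYPE = MutantGenotype()


@dataclass(frozen=True)
class OriReference:
    """The sequenced amplicon: rep ORF + flanks, with its WT copy number.

    Parameters
    ----------
    name
        Reference/ORI label (e.g. ``"pVS1"``).
    amplicon
        ACGT string covering the full amplicon.
    orf_start, orf_end
        0-based half-open ORF coordinates within ``amplicon``.
    wt_copy_number
        Plasmid copies per cell of the unmutated origin.
    """

    name: str
    amplicon: str
    orf_start: int
    orf_end: int
    wt_copy_number: float = 1.0

    def __post_init__(self):
        if not (0 <= self.orf_start < self.orf_end <= len(self.amplicon)):
            raise ValueError("ORF coordinates out of range")
        if (self.orf_end - self.orf_start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.wt_copy_number <= 0:
            raise ValueError("wt_copy_number must be positive")
        encode(self.amplicon)  # validates the alphabet

    def __len__(self) -> int:
        return len(self.amplicon)

    @cached_property
    def codes(self) -> np.ndarray:
        arr = encode(self.amplicon)
        arr.setflags(write=False)
        return arr

    @property
    def orf_seq(self) -> str:
        return self.amplicon[self.orf_start : self.orf_end]

    @property
    def n_residues(self) -> int:
        """Number of codons in the ORF (including the stop codon)."""
        return (self.orf_end - self.orf_start) // 3

    @cached_property
    def protein(self) -> str:
        return translate(self.orf_seq)

    def codon_index(self, position: int):
        """1-based codon index of an amplicon position, None outside the ORF."""
        if not (self.orf_start <= position < self.orf_end):
            return None
        return (position - self.orf_start) // 3 + 1

    def codon(self, index: int) -> str:
        """Codon string for a 1-based codon index."""
        if not (1 <= index <= self.n_residues):
            raise ValueError(f"codon index {index} outside 1..{self.n_residues}")
        start = self.orf_start + 3 * (index - 1)
        return self.amplicon[start : start + 3]

    def apply(self, genotype: MutantGenotype) -> str:
        """Amplicon sequence carrying the genotype's substitutions."""
        seq = list(self.amplicon)
        for sub in genotype.substitutions:
            if seq[sub.position] != sub.ref_base:
                raise ValueError(
                    f"substitution {sub} inconsistent with reference base "
                    f"{seq[sub.position]!r}"
                )
            seq[sub.position] = sub.alt_base
        return "".join(seq)

    def substitution(self, position: int, alt_base: str) -> Substitution:
        return Substitution(position, self.amplicon[position], alt_base)


def build_ori_reference(
    orf_length: int,
    flank: int = 150,
    seed=0,
    wt_copy_number: float = 9.5,
    name: str = "synthetic-ori",
) -> OriReference:
    """Generate a random amplicon with a well-formed ORF.

    The ORF begins with ATG, has no internal stop codons (internal codons are
    drawn uniformly from the 61 sense codons) and ends with a random stop
    codon; flanks are uniform random bases.  Deterministic per seed.
    """
    if orf_length % 3 != 0:
        raise ValueError(f"orf_length must be divisible by 3, got {orf_length}")
    if orf_length < 9:
        raise ValueError("orf_length must be at least 9 (start + codon + stop)")
    if flank < 0:
        raise ValueError("flank must be non-negative")
    rng = stream_rng(seed, "reference")
    n_internal = orf_length // 3 - 2
    internal = rng.choice(len(SENSE_CODONS), size=n_internal)
    orf = (
        START_CODON
        + "".join(SENSE_CODONS[i] for i in internal)
        + STOP_CODONS[rng.integers(len(STOP_CODONS))]
    )
    left = decode(rng.integers(0, 4, size=flank)) if flank else ""
    right = decode(rng.integers(0, 4, size=flank)) if flank else ""
    return OriReference(
        name=name,
        amplicon=left + orf + right,
        orf_start=flank,
        orf_end=flank + orf_length,
        wt_copy_number=wt_copy_number,
    )
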