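"""Paired-end amplicon read simulation (tagmentation-style fragments).

Fragments are drawn per template molecule: clone chosen proportional to
abundance, start uniform over the amplicon, length truncated-normal around
``fragment_mean``.  R1 is the first ``read_length`` bases of the fragment and
R2 the reverse complement of its last ``read_length`` bases (fragments
shorter than the read length yield shorter reads).  Sequencing errors are
i.i.d. per base with a uniformly chosen wrong base; qualities are a constant
Phred score.  Everything is vectorized and bit-reproducible per seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .._rng import stream_rng
from ..population import ClonePopulation
from ..reference import OriReference, decode


@dataclass
class ReadSimParams:
    n_pairs: int = 200_000
    read_length: int = 300
    fragment_mean: float = 600.0
    fragment_sd: float = 60.0
    error_rate: float = 0.003
    base_quality: int = 35  # constant Phred score assigned to every base

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.fragment_mean < 1:
            raise ValueError("fragment_mean must be >= 1")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if not 0 <= self.base_quality <= 60:
            raise ValueError("base_quality must lie in [0, 60]")


@dataclass
class ReadBatch:
    """A column-padded batch of reads as 2-bit base codes.

    ``codes`` is (n_reads, max_len) uint8 with values 0..3; columns at or
    beyond ``lengths[i]`` are padding.  ``quality`` matches ``codes`` in
    shape and holds Phred scores.
    """

    codes: np.ndarray
    lengths: np.ndarray
    quality: np.ndarray
    names: list | None = None

    def __post_init__(self):
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.quality = np.ascontiguousarray(self.quality, dtype=np.uint8)
        if self.codes.shape != self.quality.shape:
            raise ValueError("codes and quality must have the same shape")
        if len(self.lengths) != self.codes.shape[0]:
            raise ValueError("lengths must have one entry per read")

    def __len__(self) -> int:
        return self.codes.shape[0]

    def sequence(self, i: int) -> str:
        return decode(self.codes[i, : self.lengths[i]])

    def quality_string(self, i: int) -> str:
        return (self.quality[i, : self.lengths[i]] + 33).tobytes().decode()

    def name(self, i: int) -> str:
        return self.names[i] if self.names else f"read_{i}"

    @classmethod
    def from_strings(cls, seqs, quals=None, names=None) -> "ReadBatch":
        from ..reference import encode

        n = len(seqs)
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        width = int(lengths.max()) if n else 0
        codes = np.zeros((n, width), dtype=np.uint8)
        quality = np.full((n, width), 40, dtype=np.uint8)
        for i, seq in enumerate(seqs):
            codes[i, : lengths[i]] = encode(seq)
            if quals is not None:
                q = quals[i]
                if len(q) != lengths[i]:
                    raise ValueError(
                        f"record {i}: quality length {len(q)} != "
                        f"sequence length {lengths[i]}"
                    )
                quality[i, : lengths[i]] = (
                    np.frombuffer(q.encode(), dtype=np.uint8) - 33
                )
        return cls(codes=codes, lengths=lengths, quality=quality,
                   names=list(names) if names is not None else None)


@dataclass
class PairedReads:
    """R1/R2 batches of equal cardinality."""

    r1: ReadBatch
    r2: ReadBatch

    def __post_init__(self):
        if len(self.r1) != len(self.r2):
            raise ValueError("R1 and R2 must contain the same number of reads")

    def __len__(self) -> int:
        return len(self.r1)

    def write(self, path_r1, path_r2, compress: bool | None = None) -> None:
        write_fastq(self.r1, path_r1, compress=compress)
        write_fastq(self.r2, path_r2, compress=compress)


def write_fastq(batch: ReadBatch, path, compress: bool | None = None) -> None:
    """Write a batch as Phred+33 FASTQ (gzip if the path ends in .gz)."""
    path = Path(path)
    if compress is None:
        compress = path.suffix == ".gz"
    opener = gzip.open if compress else open
    with opener(path, "wt") as handle:
        for i in range(len(batch)):
            handle.write(
                f"@{batch.name(i)}\n{batch.sequence(i)}\n+\n"
                f"{batch.quality_string(i)}\n"
            )


def simulate_reads(
    population: ClonePopulation,
    params: ReadSimParams | None = None,
    seed=0,
    rng_index: int = 0,
) -> PairedReads:
    """Sequence a population in silico: exactly ``params.n_pairs`` read pairs.

    ``rng_index`` separates the seed streams of multiple sequencing runs of
    the same master seed (e.g. unselected vs selected libraries).
    """
    if population.total == 0:
        raise ValueError("cannot sequence an empty population")
    params = params or ReadSimParams()
    rng = stream_rng(seed, "reads", rng_index)
    ori = population.ori
    ref_len = len(ori)
    n = params.n_pairs
    rl = min(params.read_length, ref_len)

    # genotype sequence matrix (distinct genotypes only)
    genotypes = population.genotypes()
    genomes = np.tile(ori.codes, (len(genotypes), 1))
    sub_rows, sub_pos, sub_alt = [], [], []
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for gi, genotype in enumerate(genotypes):
        for sub in genotype.substitutions:
            sub_rows.append(gi)
            sub_pos.append(sub.position)
            sub_alt.append(base_code[sub.alt_base])
    if sub_rows:
        genomes[np.array(sub_rows), np.array(sub_pos)] = np.array(
            sub_alt, dtype=np.uint8
        )

    p = population.counts() / population.total
    clone_of_pair = rng.choice(len(genotypes), size=n, p=p)

    frag_len = np.rint(
        rng.normal(params.fragment_mean, params.fragment_sd, size=n)
    ).astype(np.int32)
    np.clip(frag_len, 1, ref_len, out=frag_len)
    start = np.floor(rng.random(n) * (ref_len - frag_len + 1)).astype(np.int32)
    end = start + frag_len
    read_len = np.minimum(rl, frag_len)

    cols = np.arange(rl, dtype=np.int32)
    uniform = bool((read_len == rl).all())  # true unless a fragment < read_length
    valid = None if uniform else cols[None, :] < read_len[:, None]

    def build(codes_pos, complement):
        pos = codes_pos if uniform else np.clip(codes_pos, 0, ref_len - 1)
        out = genomes[clone_of_pair[:, None], pos]
        if complement:
            out = 3 - out
        if not uniform:
            out[~valid] = 0
        return out

    r1_codes = build(start[:, None] + cols[None, :], complement=False)
    r2_codes = build(end[:, None] - 1 - cols[None, :], complement=True)

    if params.error_rate > 0:
        for codes in (r1_codes, r2_codes):
            _inject_errors(codes, valid, params.error_rate, rng)

    def batch(codes):
        return ReadBatch(
            codes=codes,
            lengths=read_len.astype(np.int64),
            quality=np.full((n, rl), params.base_quality, dtype=np.uint8),
        )

    return PairedReads(r1=batch(r1_codes), r2=batch(r2_codes))


def _inject_errors(codes, valid, error_rate, rng, block: int = 65536) -> None:
    """I.i.d. substitution errors with a uniform wrong base, in place.

    Row blocks keep the Bernoulli mask's memory footprint bounded.
    """
    n, width = codes.shape
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        mask = rng.random((hi - lo, width), dtype=np.float32) < error_rate
        if valid is not None:
            mask &= valid[lo:hi]
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            continue
        shift = 1 + np.floor(3 * rng.random(rows.size)).astype(np.uint8)
        codes[lo + rows, cols] = (codes[lo + rows, cols] + shift) % 4
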