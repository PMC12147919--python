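"""Reads -> per-position base counts against the amplicon reference.

The mapper is gapless and substitution-only: a 20-mer seed (slid by half a
seed length when it misses) places the read on either strand of the
reference, the full read is then compared base-by-base, and the placement is
accepted when it is the unique minimal-mismatch placement with a mismatch
fraction at or below the threshold.  When every seed window misses (e.g. all
of them straddle sequencing errors) the mapper falls back to an exhaustive
scan over all offsets and strands, so its accept/reject behaviour matches a
brute-force aligner exactly.

The pileup counts one observation per mapped base, with quality masking
instead of read trimming, and collapses overlapping mate pairs to a single
observation per template position: agreeing bases count once, disagreements
are masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference import OriReference, decode, encode
from .simulate.reads import PairedReads, ReadBatch

BASE_COLUMNS = ("A", "C", "G", "T", "masked", "other")
_MASKED = 4
_OTHER = 5


@dataclass
class MappingResult:
    """Placement of one read on the reference."""

    accepted: bool
    offset: int = -1  # 0-based reference start of the aligned segment
    strand: str = "."  # '+' or '-'
    mismatches: int = -1
    aligned_length: int = 0
    reason: str | None = None  # set when not accepted


@dataclass
class PositionCounts:
    """Per-position A/C/G/T/masked/other counts over the full amplicon."""

    sample_id: str
    ori_name: str
    counts: np.ndarray  # (length, 6) int64, columns per BASE_COLUMNS
    n_reads_mapped: int = 0
    n_reads_unmapped: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(BASE_COLUMNS):
            raise ValueError("counts must be (length, 6)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        """Total observations per position (bases + masked + other)."""
        return self.counts.sum(axis=1)

    @property
    def base_depth(self) -> np.ndarray:
        """Usable depth: A+C+G+T only (masked/other excluded)."""
        return self.counts[:, :4].sum(axis=1)

    @property
    def no_reads(self) -> bool:
        """Warning flag: nothing mapped, the matrix is all zero."""
        return self.n_reads_mapped == 0

    def base_count(self, position: int, base: str) -> int:
        return int(self.counts[position, BASE_COLUMNS.index(base)])

    def to_frame(self, ori: OriReference | None = None):
        import pandas as pd

        frame = pd.DataFrame(self.counts, columns=list(BASE_COLUMNS))
        frame.insert(0, "pos_1based", np.arange(1, len(self) + 1))
        if ori is not None:
            frame.insert(1, "ref", list(ori.amplicon))
        frame["depth"] = self.depth
        return frame


class ReferenceIndex:
    """Exact k-mer lookup over both strands of the amplicon.

    Keys are 2-bit packed k-mers.  A key present at more than one
    (window, strand) is flagged ambiguous and never used for placement.
    """

    def __init__(self, ori: OriReference, k: int = 20):
        if k < 1 or k > 31:
            raise ValueError("seed length must lie in 1..31")
        if len(ori) < k:
            raise ValueError("reference shorter than the seed length")
        self.ori = ori
        self.k = k
        codes = ori.codes.astype(np.int64)
        self.ref_codes = ori.codes
        fwd = _pack_kmers(codes, k)
        rev = _pack_kmers((3 - codes)[::-1], k)  # reverse-complement strand
        n_windows = len(fwd)
        keys = np.concatenate([fwd, rev])
        # for forward hits the value is the reference window start q;
        # for reverse hits, q of the *reference* window whose revcomp matches:
        # rc window i starts at ref position (L - k - i)
        starts = np.concatenate(
            [np.arange(n_windows), len(codes) - k - np.arange(n_windows)]
        )
        strands = np.concatenate(
            [np.zeros(n_windows, np.int8), np.ones(n_windows, np.int8)]
        )
        order = np.argsort(keys, kind="stable")
        keys, starts, strands = keys[order], starts[order], strands[order]
        unique, first, counts = np.unique(
            keys, return_index=True, return_counts=True
        )
        self._keys = unique
        self._starts = starts[first]
        self._strands = strands[first]
        self._ambiguous = counts > 1

    def lookup(self, packed: np.ndarray):
        """Vectorized lookup: (found, ambiguous, window_start, strand)."""
        idx = np.searchsorted(self._keys, packed)
        idx_c = np.minimum(idx, len(self._keys) - 1)
        found = self._keys[idx_c] == packed
        ambiguous = found & self._ambiguous[idx_c]
        return found, ambiguous, self._starts[idx_c], self._strands[idx_c]


def _pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit pack every length-k window of a code vector."""
    codes = np.asarray(codes, dtype=np.int64)
    n = len(codes) - k + 1
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)[:n]
    return windows @ powers


def _count_mismatches(ref_codes, read_codes, offset, strand) -> int:
    """Mismatches of a gapless placement (read fully inside the reference)."""
    n = len(read_codes)
    segment = ref_codes[offset : offset + n]
    if strand == 0:
        return int(np.count_nonzero(segment != read_codes))
    return int(np.count_nonzero(segment != (3 - read_codes)[::-1]))


def exhaustive_placements(ref_codes, read_codes):
    """Mismatch counts for every (offset, strand); the rescue/oracle scan."""
    n = len(read_codes)
    n_off = len(ref_codes) - n + 1
    if n_off <= 0:
        return np.empty((0, 2), dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(ref_codes, n)[:n_off]
    fwd = (windows != read_codes).sum(axis=1)
    rev = (windows != (3 - read_codes)[::-1]).sum(axis=1)
    return np.stack([fwd, rev], axis=1)


def map_read(
    read,
    ori_or_index,
    k_seed: int = 20,
    max_mismatch_frac: float = 0.10,
) -> MappingResult:
    """Place one read (string or code array) on the reference.

    Accept iff the minimal-mismatch placement is unique and its mismatch
    fraction is at most ``max_mismatch_frac``.
    """
    index = (
        ori_or_index
        if isinstance(ori_or_index, ReferenceIndex)
        else ReferenceIndex(ori_or_index, k=k_seed)
    )
    if index.k != k_seed:
        index = ReferenceIndex(index.ori, k=k_seed)
    read_codes = encode(read) if isinstance(read, str) else np.asarray(read)
    read_codes = read_codes.astype(np.int64)
    n = len(read_codes)
    if n < k_seed:
        raise ValueError(f"read length {n} shorter than seed length {k_seed}")
    ref_codes = index.ref_codes.astype(np.int64)
    max_mm = int(np.floor(max_mismatch_frac * n))

    candidates = set()
    step = max(1, k_seed // 2)
    for attempt in range(4):  # initial window + up to 3 slides
        s = attempt * step
        if s + k_seed > n:
            break
        packed = _pack_kmers(read_codes[s : s + k_seed], k_seed)
        found, ambiguous, q, strand = index.lookup(packed)
        if not found[0] or ambiguous[0]:
            continue
        if strand[0] == 0:
            offset = int(q[0]) - s
        else:
            offset = int(q[0]) + s + k_seed - n
        if 0 <= offset <= len(ref_codes) - n:
            candidates.add((offset, int(strand[0])))
    if candidates:
        scored = [
            (c, _count_mismatches(ref_codes, read_codes, *c)) for c in candidates
        ]
        best = min(mm for _, mm in scored)
        best_placements = [c for c, mm in scored if mm == best]
        if best <= max_mm:
            if len(best_placements) > 1:
                return MappingResult(False, reason="ambiguous")
            (offset, strand) = best_placements[0]
            return MappingResult(
                True, offset, "+-"[strand], best, aligned_length=n
            )
        # fall through to the rescue scan: a better placement may exist
        # elsewhere even though the seeded one failed the threshold

    table = exhaustive_placements(ref_codes, read_codes)
    if table.size == 0:
        return MappingResult(False, reason="read_longer_than_reference")
    best = int(table.min())
    if best > max_mm:
        return MappingResult(False, mismatches=best, reason="too_many_mismatches")
    hits = np.argwhere(table == best)
    if len(hits) > 1:
        return MappingResult(False, reason="ambiguous")
    offset, strand = (int(hits[0][0]), int(hits[0][1]))
    return MappingResult(True, offset, "+-"[strand], best, aligned_length=n)


def map_batch(
    batch: ReadBatch,
    index: ReferenceIndex,
    max_mismatch_frac: float = 0.10,
):
    """Vectorized mapping of a batch; same accept rule as :func:`map_read`.

    Returns ``(accepted, offset, strand, refspace_codes, refspace_qual)``
    where the refspace arrays give, for each read, the base codes / qualities
    aligned to reference positions ``offset + j`` (reverse-strand reads are
    flipped and complemented).
    """
    k = index.k
    ref_len = len(index.ref_codes)
    n, width = batch.codes.shape
    lengths = batch.lengths
    uniform = bool((lengths == width).all())

    offset = np.full(n, -1, dtype=np.int64)
    strand = np.zeros(n, dtype=np.int8)
    placed = np.zeros(n, dtype=bool)

    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    step = max(1, k // 2)
    # the documented protocol tries 4 windows; the batch path keeps sliding
    # across the whole read as a cheap rescue ladder before the exhaustive
    # scan (the accept rule is unchanged, so outcomes match map_read)
    max_attempts = max(4, (width - k) // step + 1)
    for attempt in range(max_attempts):
        s = attempt * step
        todo = ~placed & (lengths >= s + k)
        if not todo.any():
            break
        rows = np.flatnonzero(todo)
        packed = batch.codes[rows, s : s + k].astype(np.int64) @ powers
        found, ambiguous, q, st = index.lookup(packed)
        ok = found & ~ambiguous
        rows = rows[ok]
        if rows.size == 0:
            continue
        q, st = q[ok], st[ok]
        off = np.where(st == 0, q - s, q + s + k - lengths[rows])
        in_range = (off >= 0) & (off + lengths[rows] <= ref_len)
        rows, off, st = rows[in_range], off[in_range], st[in_range]
        offset[rows] = off
        strand[rows] = st
        placed[rows] = True

    # rescue path: exhaustive scan for the stragglers (rare)
    accepted = np.zeros(n, dtype=bool)
    mism = np.full(n, -1, dtype=np.int64)
    for i in np.flatnonzero(~placed):
        if lengths[i] < k:
            continue
        result = map_read(
            batch.codes[i, : lengths[i]], index, k_seed=k,
            max_mismatch_frac=max_mismatch_frac,
        )
        if result.accepted:
            offset[i] = result.offset
            strand[i] = 0 if result.strand == "+" else 1
            placed[i] = True
            accepted[i] = True
            mism[i] = result.mismatches

    # build refspace codes for all placed reads and verify mismatch fraction
    cols = np.arange(width, dtype=np.int32)
    rev = (strand == 1)[:, None]
    if uniform:
        # every read spans the full width: per-row reversal is a plain flip
        refspace = np.where(rev, (3 - batch.codes)[:, ::-1], batch.codes)
        refspace_qual = np.where(rev, batch.quality[:, ::-1], batch.quality)
        valid = None
    else:
        valid = cols[None, :] < lengths[:, None]
        src = np.where(rev, lengths[:, None] - 1 - cols[None, :], cols[None, :])
        src = np.clip(src, 0, width - 1)
        take = np.take_along_axis(batch.codes, src.astype(np.intp), axis=1)
        refspace = np.where(rev, 3 - take, take).astype(np.uint8)
        refspace_qual = np.take_along_axis(
            batch.quality, src.astype(np.intp), axis=1
        )

    seeded = placed & ~accepted
    rows = np.flatnonzero(seeded)
    if rows.size:
        pos = offset[rows, None].astype(np.int32) + cols[None, :]
        if not uniform:
            np.clip(pos, 0, ref_len - 1, out=pos)
        ref_bases = index.ref_codes[pos]
        diff = ref_bases != refspace[rows]
        if valid is not None:
            diff &= valid[rows]
        mm = diff.sum(axis=1)
        max_mm = np.floor(max_mismatch_frac * lengths[rows]).astype(np.int64)
        ok = mm <= max_mm
        accepted[rows] = ok
        mism[rows] = mm
        # seeded placements that fail the threshold get one exhaustive retry,
        # mirroring map_read's fall-through
        for i in rows[~ok]:
            result = map_read(
                batch.codes[i, : lengths[i]], index, k_seed=k,
                max_mismatch_frac=max_mismatch_frac,
            )
            if result.accepted:
                offset[i] = result.offset
                new_strand = 0 if result.strand == "+" else 1
                if new_strand != strand[i]:
                    strand[i] = new_strand
                    L = lengths[i]
                    flipped = (3 - batch.codes[i, :L][::-1]).astype(np.uint8)
                    refspace[i, :L] = flipped
                    refspace_qual[i, :L] = batch.quality[i, :L][::-1]
                accepted[i] = True
                mism[i] = result.mismatches

    return accepted, offset, strand, refspace, refspace_qual


def pileup_counts(
    reads,
    ori: OriReference,
    min_base_quality: int = 20,
    k_seed: int = 20,
    max_mismatch_frac: float = 0.10,
    sample_id: str = "sample",
    chunk_pairs: int = 50_000,
) -> PositionCounts:
    """Pileup of paired reads (a :class:`PairedReads` or FASTQ path pair).

    Bases below ``min_base_quality`` are masked, not trimmed.  Where mates
    overlap on the template there is one observation per position: agreeing
    unmasked bases count once; a disagreement, or an overlap in which either
    base is quality-masked, counts as masked (this keeps base counters
    monotone non-increasing in the quality threshold).
    """
    if isinstance(reads, (tuple, list)):
        from .io import read_fastq

        reads = PairedReads(r1=read_fastq(reads[0]), r2=read_fastq(reads[1]))
    index = ReferenceIndex(ori, k=k_seed)
    ref_len = len(ori)
    totals = np.zeros(6 * ref_len, dtype=np.int64)
    n_mapped = 0
    n_unmapped = 0

    n = len(reads)
    for lo in range(0, n, chunk_pairs):
        hi = min(lo + chunk_pairs, n)
        mapped = []
        for batch in (reads.r1, reads.r2):
            sub = ReadBatch(
                codes=batch.codes[lo:hi],
                lengths=batch.lengths[lo:hi],
                quality=batch.quality[lo:hi],
            )
            acc, off, _strand, refspace, refqual = map_batch(
                sub, index, max_mismatch_frac=max_mismatch_frac
            )
            eff = refspace.astype(np.int16)
            eff[refqual < min_base_quality] = _MASKED
            mapped.append((acc, off, sub.lengths, eff))
            n_mapped += int(acc.sum())
            n_unmapped += int((~acc).sum())

        (acc1, off1, len1, eff1), (acc2, off2, len2, eff2) = mapped
        if bool((len1 == eff1.shape[1]).all() and (len2 == eff2.shape[1]).all()):
            _accumulate_chunk_sparse(
                totals, index.ref_codes, acc1, off1, eff1, acc2, off2, eff2
            )
        else:
            _accumulate_chunk(totals, ref_len, *mapped[0], *mapped[1])

    counts = totals.reshape(6, ref_len).T
    return PositionCounts(
        sample_id=sample_id,
        ori_name=ori.name,
        counts=counts,
        n_reads_mapped=n_mapped,
        n_reads_unmapped=n_unmapped,
    )


def _accumulate_chunk_sparse(
    totals, ref_codes, acc1, off1, eff1, acc2, off2, eff2
) -> None:
    """Sparse accumulation for uniform-length chunks.

    Reads overwhelmingly match the reference, so instead of tallying every
    base the pileup counts per-position coverage from read intervals and
    handles only *deviant* bases (mismatches and quality masks) explicitly.
    Equivalent to the dense tally; exercised against it in the tests.
    """
    ref_len = len(ref_codes)
    width = eff1.shape[1]
    cols = np.arange(width, dtype=np.int32)
    positions = np.arange(ref_len, dtype=np.int64)
    ref_keys = ref_codes.astype(np.int64) * ref_len + positions

    deviants = []
    for acc, off, eff in ((acc1, off1, eff1), (acc2, off2, eff2)):
        rows = np.flatnonzero(acc)
        if rows.size == 0:
            deviants.append((np.empty(0, np.int64), np.empty(0, np.int64)))
            continue
        off_r = off[rows].astype(np.int32)
        pos = off_r[:, None] + cols[None, :]
        eff_r = eff[rows]
        dev = eff_r != ref_codes[pos]
        di, dj = np.nonzero(dev)
        dpos = pos[di, dj].astype(np.int64)
        deff = eff_r[di, dj].astype(np.int64)
        if dpos.size:
            totals += np.bincount(deff * ref_len + dpos, minlength=6 * ref_len)
        cov = np.cumsum(
            np.bincount(off_r, minlength=ref_len + 1)[: ref_len + 1]
            - np.bincount(off_r + width, minlength=ref_len + 1)[: ref_len + 1]
        )[:ref_len]
        dev_at = np.bincount(dpos, minlength=ref_len)[:ref_len]
        totals[ref_keys] += cov - dev_at
        deviants.append((rows[di].astype(np.int64), dpos))

    # mate-overlap corrections: one observation per template position
    both = acc1 & acc2
    if not both.any():
        return
    n = len(acc1)
    prow = np.flatnonzero(both)
    a = np.maximum(off1[prow], off2[prow]).astype(np.int64)
    b = np.minimum(off1[prow] + width, off2[prow] + width).astype(np.int64)
    keep = b > a
    prow, a, b = prow[keep], a[keep], b[keep]
    if prow.size == 0:
        return
    ov_lo = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    ov_hi = np.full(n, -1, dtype=np.int64)
    ov_lo[prow] = a
    ov_hi[prow] = b
    # generic correction assumes ref/ref agreement everywhere in the overlap
    ovcov = np.cumsum(
        np.bincount(a, minlength=ref_len + 1)[: ref_len + 1]
        - np.bincount(b, minlength=ref_len + 1)[: ref_len + 1]
    )[:ref_len]
    totals[ref_keys] -= ovcov
    # special-case overlap positions where either mate deviates from ref
    keys = []
    for gi, dpos in deviants:
        m = (dpos >= ov_lo[gi]) & (dpos < ov_hi[gi])
        keys.append(gi[m] * ref_len + dpos[m])
    special = np.unique(np.concatenate(keys))
    if special.size == 0:
        return
    gi = special // ref_len
    p = special % ref_len
    b1 = eff1[gi, p - off1[gi]].astype(np.int64)
    b2 = eff2[gi, p - off2[gi]].astype(np.int64)
    corr = np.zeros(6 * ref_len, dtype=np.int64)
    # undo the generic ref/ref subtraction at these positions
    np.add.at(corr, ref_codes[p].astype(np.int64) * ref_len + p, 1)
    same = b1 == b2
    np.add.at(corr, b1[same] * ref_len + p[same], -1)
    diff = ~same  # disagreement or one masked member: the pair gives masked
    np.add.at(corr, b1[diff] * ref_len + p[diff], -1)
    np.add.at(corr, b2[diff] * ref_len + p[diff], -1)
    np.add.at(corr, _MASKED * ref_len + p[diff], 1)
    totals += corr


def _accumulate_chunk(
    totals, ref_len, acc1, off1, len1, eff1, acc2, off2, len2, eff2
) -> None:
    """Add one chunk of mapped pairs to the flattened (6, L) count vector."""
    width = eff1.shape[1]
    cols = np.arange(width, dtype=np.int32)

    for acc, off, lens, eff in ((acc1, off1, len1, eff1), (acc2, off2, len2, eff2)):
        rows = np.flatnonzero(acc)
        if rows.size == 0:
            continue
        pos = off[rows, None].astype(np.int32) + cols[None, :]
        if bool((lens[rows] == width).all()):
            key = eff[rows].astype(np.int32) * ref_len + pos
            totals += np.bincount(key.ravel(), minlength=6 * ref_len)
        else:
            key = eff[rows] * ref_len + np.clip(pos, 0, ref_len - 1)
            mask = cols[None, :] < lens[rows, None]
            totals += np.bincount(key[mask].ravel(), minlength=6 * ref_len)

    # mate-overlap corrections
    both = acc1 & acc2
    rows = np.flatnonzero(both)
    if rows.size == 0:
        return
    a = np.maximum(off1[rows], off2[rows])
    b = np.minimum(off1[rows] + len1[rows], off2[rows] + len2[rows])
    ov = b - a
    keep = ov > 0
    rows, a, ov = rows[keep], a[keep], ov[keep]
    if rows.size == 0:
        return
    # flatten all overlap positions
    rep_rows = np.repeat(rows, ov)
    starts = np.repeat(a, ov)
    within = np.arange(ov.sum()) - np.repeat(np.cumsum(ov) - ov, ov)
    pos = starts + within
    b1 = eff1[rep_rows, pos - off1[rep_rows]]
    b2 = eff2[rep_rows, pos - off2[rep_rows]]

    minus = np.zeros(6 * ref_len, dtype=np.int64)
    plus = np.zeros(6 * ref_len, dtype=np.int64)

    same = b1 == b2
    np.add.at(minus, b1[same] * ref_len + pos[same], 1)

    diff = ~same  # disagreement or one masked member: the pair gives masked
    np.add.at(minus, b1[diff] * ref_len + pos[diff], 1)
    np.add.at(minus, b2[diff] * ref_len + pos[diff], 1)
    np.add.at(plus, _MASKED * ref_len + pos[diff], 1)

    totals += plus - minus


def pileup_from_sam(
    sam_path,
    ori: OriReference,
    min_base_quality: int = 20,
    sample_id: str | None = None,
) -> PositionCounts:
    """CIGAR-aware pileup of an externally aligned SAM file.

    Counts M/=/X bases (quality-masked below the threshold), skips
    insertions and soft clips, tallies deletion/ref-skip spanned positions
    under ``other``, and ignores secondary/supplementary/duplicate/unmapped
    records.  Records with malformed CIGARs are skipped and counted.
    """
    import pysam

    sam_path = Path(sam_path)
    ref_len = len(ori)
    counts = np.zeros((ref_len, 6), dtype=np.int64)
    n_mapped = 0
    n_unmapped = 0
    n_skipped = 0

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        named = {r: l for r, l in zip(sam.references or (), sam.lengths or ())}
        if named:
            length = named.get(ori.name)
            if length is None:
                raise ValueError(
                    f"SAM header references {sorted(named)} do not include "
                    f"reference {ori.name!r}"
                )
            if length != ref_len:
                raise ValueError(
                    f"SAM header length {length} != amplicon length {ref_len}"
                )
        for record in sam.fetch(until_eof=True):
            if (
                record.is_unmapped
                or record.is_secondary
                or record.is_supplementary
                or record.is_duplicate
            ):
                if record.is_unmapped:
                    n_unmapped += 1
                continue
            if record.reference_name != ori.name:
                raise ValueError(
                    f"record {record.query_name!r} aligned to "
                    f"{record.reference_name!r}, expected {ori.name!r}"
                )
            cigar = record.cigartuples
            seq = record.query_sequence
            if not cigar or seq is None:
                n_skipped += 1
                continue
            quals = record.query_qualities
            # validate the whole CIGAR before touching the count matrix, so
            # a malformed record never leaves a partial tally behind
            ref_span = 0
            query_span = 0
            malformed = False
            for op, length in cigar:
                if op in (0, 2, 3, 7, 8):
                    ref_span += length
                if op in (0, 1, 4, 7, 8):
                    query_span += length
                if op not in (0, 1, 2, 3, 4, 5, 6, 7, 8):
                    malformed = True
            if (
                malformed
                or record.reference_start + ref_span > ref_len
                or query_span != len(seq)
            ):
                n_skipped += 1
                continue
            upper = seq.upper()
            n_pos = {i for i, b in enumerate(upper) if b not in "ACGT"}
            codes = encode(
                "".join(b if b in "ACGT" else "A" for b in upper)
            )
            rpos = record.reference_start
            qpos = 0
            for op, length in cigar:
                if op in (0, 7, 8):  # M / = / X
                    for j in range(length):
                        q = quals[qpos + j] if quals is not None else 40
                        if q < min_base_quality or (qpos + j) in n_pos:
                            counts[rpos + j, _MASKED] += 1
                        else:
                            counts[rpos + j, codes[qpos + j]] += 1
                    rpos += length
                    qpos += length
                elif op in (1, 4):  # I / S: read bases with no reference home
                    qpos += length
                elif op in (2, 3):  # D / N: spanned reference positions
                    counts[rpos : rpos + length, _OTHER] += 1
                    rpos += length
                # H / P consume nothing
            n_mapped += 1

    result = PositionCounts(
        sample_id=sample_id or sam_path.stem,
        ori_name=ori.name,
        counts=counts,
        n_reads_mapped=n_mapped,
        n_reads_unmapped=n_unmapped,
    )
    result.n_records_skipped = n_skipped
    return result
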