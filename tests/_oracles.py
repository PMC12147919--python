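"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (exhaustive scans, per-read tallies,
direct enumeration) and shares no code with the library paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

MASKED = 4


def align_exhaustive(ref_codes, read_codes, max_mismatch_frac=0.10):
    """Try every (offset, strand); accept the unique minimal-mismatch hit.

    Returns ``(offset, strand, mismatches)`` or ``None``.
    """
    ref = np.asarray(ref_codes, dtype=int)
    read = np.asarray(read_codes, dtype=int)
    n = len(read)
    best = None
    hits = []
    for strand in (0, 1):
        probe = read if strand == 0 else (3 - read)[::-1]
        for off in range(len(ref) - n + 1):
            mm = int(np.count_nonzero(ref[off : off + n] != probe))
            if best is None or mm < best:
                best = mm
                hits = [(off, strand)]
            elif mm == best:
                hits.append((off, strand))
    if best is None or best > math.floor(max_mismatch_frac * n) or len(hits) != 1:
        return None
    return hits[0][0], hits[0][1], best


def pileup_naive(pairs, ref_codes, min_base_quality=20, k_seed=20):
    """Per-pair manual tally with the count-once-in-overlap policy.

    ``pairs`` is a sequence of ((codes1, qual1), (codes2, qual2)) tuples;
    either mate may be None.  Reads shorter than the seed are unmappable.
    """
    ref = np.asarray(ref_codes, dtype=int)
    counts = np.zeros((len(ref), 6), dtype=np.int64)
    for mates in pairs:
        observations: dict = {}
        for mate in mates:
            if mate is None:
                continue
            codes, quals = mate
            codes = np.asarray(codes, dtype=int)
            quals = np.asarray(quals, dtype=int)
            if len(codes) < k_seed:
                continue
            placement = align_exhaustive(ref, codes)
            if placement is None:
                continue
            off, strand, _ = placement
            if strand == 1:
                codes = (3 - codes)[::-1]
                quals = quals[::-1]
            for j in range(len(codes)):
                eff = int(codes[j]) if quals[j] >= min_base_quality else MASKED
                observations.setdefault(off + j, []).append(eff)
        for position, bases in observations.items():
            if len(bases) == 1:
                counts[position, bases[0]] += 1
            elif bases[0] == bases[1]:
                counts[position, bases[0]] += 1
            else:  # disagreement, or one member quality-masked
                counts[position, MASKED] += 1
    return counts


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def log_comb(n_, k_):
        return (
            math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)
        )

    def log_prob(x):
        return (
            log_comb(row1, x)
            + log_comb(row2, col1 - x)
            - log_comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    observed = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= observed + 1e-12:
            total += math.exp(lp)
    return min(1.0, total)


def bh_step_up(p_values):
    """Benjamini-Hochberg step-up q values, by the textbook recipe."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        q[idx] = running_min
    return q


def expected_selected_frequency(freqs, weights, generations):
    """Closed-form post-selection frequencies: f_i w_i^G / sum_j f_j w_j^G."""
    freqs = np.asarray(freqs, dtype=float)
    weights = np.asarray(weights, dtype=float)
    scaled = freqs * weights**generations
    return scaled / scaled.sum()


def pileup_from_sam_naive(records, ref_len, min_base_quality=20):
    """Independent CIGAR walker over (flag, pos, cigar, seq, qual) tuples.

    ``records`` use 0-based positions and pre-parsed cigar op lists
    [(op_char, length), ...].  Returns the (L, 6) count matrix.
    """
    base_to_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((ref_len, 6), dtype=np.int64)
    for flag, pos, cigar, seq, qual in records:
        if flag & (0x4 | 0x100 | 0x400 | 0x800):
            continue
        rpos, qpos = pos, 0
        for op, length in cigar:
            if op in "M=X":
                for j in range(length):
                    q = qual[qpos + j] if qual is not None else 40
                    base = seq[qpos + j]
                    if q < min_base_quality or base not in base_to_code:
                        counts[rpos + j, MASKED] += 1
                    else:
                        counts[rpos + j, base_to_code[base]] += 1
                rpos += length
                qpos += length
            elif op == "I":
                qpos += length
            elif op in "DN":
                for j in range(length):
                    counts[rpos + j, 5] += 1
                rpos += length
            elif op == "S":
                qpos += length
            # H and P consume nothing
    return counts
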