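"""Selected-vs-unselected allele-frequency fold-change enrichment.

The screen's statistic: for every (position, alternate base) allele,

    FC = ((alt_sel + c) / (depth_sel + 2c)) / ((alt_unsel + c) / (depth_unsel + 2c))

with a Haldane-Anscombe pseudocount ``c = 0.5`` on counts, keeping the fold
change finite and exactly reciprocal under swapping the two samples.
Significance is a per-allele two-sided Fisher exact test on raw counts with
Benjamini-Hochberg correction; nucleotide alleles are annotated with their
codon consequence, aggregated per residue (max over nonsynonymous alleles),
and ranked to call the top-k candidate residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .reference import BASES, OriReference, translate
from .variant_counts import PositionCounts


def allele_frequencies(
    counts: PositionCounts,
    ori: OriReference,
    min_depth: int = 100,
) -> pd.DataFrame:
    """Three alt-allele rows per position, with frequencies and depth flags.

    Frequency is ``alt_count / (A+C+G+T)``; masked and other observations do
    not enter the denominator.  Positions with usable depth below
    ``min_depth`` are flagged ``low_depth``.  An all-zero pileup yields a
    valid table whose every row is flagged.
    """
    if len(counts) != len(ori):
        raise ValueError("counts length does not match the reference")
    length = len(ori)
    ref_codes = ori.codes.astype(np.int64)
    acgt = counts.counts[:, :4]
    depth = acgt.sum(axis=1)

    positions = np.repeat(np.arange(length), 3)
    alt_codes = np.concatenate(
        [np.delete(np.arange(4), r) for r in ref_codes]
    ).astype(np.int64)
    alt_count = acgt[positions, alt_codes]
    pos_depth = depth[positions]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(pos_depth > 0, alt_count / np.maximum(pos_depth, 1), 0.0)

    frame = pd.DataFrame(
        {
            "position": positions,
            "ref": [BASES[c] for c in ref_codes[positions]],
            "alt": [BASES[c] for c in alt_codes],
            "alt_count": alt_count,
            "depth": pos_depth,
            "frequency": freq,
            "low_depth": pos_depth < min_depth,
        }
    )
    frame.attrs["sample_id"] = counts.sample_id
    frame.attrs["ori_name"] = counts.ori_name
    frame.attrs["all_zero"] = bool(depth.sum() == 0)
    return frame


def fold_changes(
    sel: pd.DataFrame,
    unsel: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-allele enrichment records from two allele-frequency tables.

    Alleles present in only one table are omitted (the omission count is
    recorded in ``frame.attrs['n_omitted']``); low-depth flags are carried
    forward as ``low_depth`` = flagged in either sample.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    merged = sel.merge(
        unsel,
        on=["position", "ref", "alt"],
        how="inner",
        suffixes=("_sel", "_unsel"),
    )
    n_omitted = (len(sel) - len(merged)) + (len(unsel) - len(merged))
    c = pseudocount
    f_sel = (merged["alt_count_sel"] + c) / (merged["depth_sel"] + 2 * c)
    f_unsel = (merged["alt_count_unsel"] + c) / (merged["depth_unsel"] + 2 * c)
    records = pd.DataFrame(
        {
            "position": merged["position"],
            "ref": merged["ref"],
            "alt": merged["alt"],
            "alt_sel": merged["alt_count_sel"],
            "depth_sel": merged["depth_sel"],
            "alt_unsel": merged["alt_count_unsel"],
            "depth_unsel": merged["depth_unsel"],
            "f_sel": merged["frequency_sel"],
            "f_unsel": merged["frequency_unsel"],
            "fold_change": f_sel / f_unsel,
            "low_depth": merged["low_depth_sel"] | merged["low_depth_unsel"],
        }
    )
    records.attrs["n_omitted"] = int(n_omitted)
    records.attrs["pseudocount"] = c
    return records


def fisher_exact_batch(a, b, c, d) -> np.ndarray:
    """Vectorized two-sided Fisher exact p for many 2x2 tables at once.

    Two-sided p is the classic sum of hypergeometric probabilities at most
    the observed table's probability (log-space comparison with a 1e-12
    tolerance for floating ties).  Tables with a zero margin get p = 1.
    The per-table support is enumerated with log-gamma arithmetic, which is
    what makes thousands of allele tests cheap.
    """
    from scipy.special import gammaln

    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    n1, n2 = a + b, c + d
    t = a + c
    total = n1 + n2
    ok = (n1 > 0) & (n2 > 0) & (t > 0) & (b + d > 0)
    p = np.ones(len(a))
    if not ok.any():
        return p

    def log_comb(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    idx = np.flatnonzero(ok)
    lo = np.maximum(0, t[idx] - n2[idx])
    hi = np.minimum(t[idx], n1[idx])
    sizes = hi - lo + 1
    tab = np.repeat(np.arange(len(idx)), sizes)
    offset = np.arange(sizes.sum()) - np.repeat(np.cumsum(sizes) - sizes, sizes)
    x = lo[tab] + offset
    i = idx[tab]
    log_pmf = (
        log_comb(n1[i], x)
        + log_comb(n2[i], t[i] - x)
        - log_comb(total[i], t[i])
    )
    log_obs = (
        log_comb(n1[idx], a[idx])
        + log_comb(n2[idx], c[idx])
        - log_comb(total[idx], t[idx])
    )
    include = log_pmf <= log_obs[tab] + 1e-12
    sums = np.bincount(
        tab[include], weights=np.exp(log_pmf[include]), minlength=len(idx)
    )
    p[idx] = np.minimum(sums, 1.0)
    return p


def enrichment_test(records: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Fisher exact p per allele, Benjamini-Hochberg q across all.

    The 2x2 table is [[alt_sel, depth_sel - alt_sel],
    [alt_unsel, depth_unsel - alt_unsel]]; degenerate tables (a zero margin)
    get p = 1 by convention.
    """
    records = records.copy()
    if not len(records):
        records["p_value"] = np.ones(0)
        records["q_value"] = np.ones(0)
        return records
    p_values = fisher_exact_batch(
        records["alt_sel"].to_numpy(),
        (records["depth_sel"] - records["alt_sel"]).to_numpy(),
        records["alt_unsel"].to_numpy(),
        (records["depth_unsel"] - records["alt_unsel"]).to_numpy(),
    )
    records["p_value"] = p_values
    records["q_value"] = multipletests(p_values, method="fdr_bh")[1]
    return records


def annotate_codons(records: pd.DataFrame, ori: OriReference) -> pd.DataFrame:
    """Attach codon index, amino-acid change and a nonsynonymous flag.

    Flank (non-ORF) positions keep NA annotations and ``nonsynonymous`` =
    NA.  The mutated codon is the reference codon with the single alternate
    base substituted (pileup alleles are single-SNP by construction).
    """
    records = records.copy()
    codon_index = pd.array([None] * len(records), dtype="Int64")
    aa_ref = pd.array([None] * len(records), dtype="string")
    aa_alt = pd.array([None] * len(records), dtype="string")
    nonsyn = pd.array([None] * len(records), dtype="boolean")

    positions = records["position"].to_numpy()
    alts = records["alt"].to_numpy()
    for i, (pos, alt) in enumerate(zip(positions, alts)):
        idx = ori.codon_index(int(pos))
        if idx is None:
            continue
        codon = ori.codon(idx)
        within = (int(pos) - ori.orf_start) % 3
        mutated = codon[:within] + alt + codon[within + 1 :]
        ref_aa = translate(codon)
        alt_aa = translate(mutated)
        codon_index[i] = idx
        aa_ref[i] = ref_aa
        aa_alt[i] = alt_aa
        nonsyn[i] = ref_aa != alt_aa
    records["codon_index"] = codon_index
    records["aa_ref"] = aa_ref
    records["aa_alt"] = aa_alt
    records["nonsynonymous"] = nonsyn
    return records


def aggregate_residues(records: pd.DataFrame) -> pd.DataFrame:
    """One row per residue: max fold change over its nonsynonymous alleles.

    Synonymous, flank and low-depth alleles are excluded; a residue with no
    qualifying allele is absent from the output.  Also reports the best
    allele and the minimum q among contributing alleles.
    """
    usable = records[
        (records["nonsynonymous"] == True)  # noqa: E712 (nullable boolean)
        & ~records["low_depth"].astype(bool)
    ]
    if usable.empty:
        frame = pd.DataFrame(
            columns=[
                "residue_index", "fold_change", "best_position", "best_alt",
                "aa_change", "min_q",
            ]
        )
        return frame

    rows = []
    for residue, group in usable.groupby("codon_index"):
        best = group.loc[group["fold_change"].idxmax()]
        rows.append(
            {
                "residue_index": int(residue),
                "fold_change": float(best["fold_change"]),
                "best_position": int(best["position"]),
                "best_alt": best["alt"],
                "aa_change": f"{best['aa_ref']}{residue}{best['aa_alt']}",
                "min_q": float(group["q_value"].min())
                if "q_value" in group
                else np.nan,
            }
        )
    frame = pd.DataFrame(rows).sort_values("residue_index", ignore_index=True)
    return frame


@dataclass
class CandidateSet:
    """Top-k residues by fold change (ties broken by ascending residue)."""

    residues: pd.DataFrame
    k_requested: int
    threshold: float  # realized fold change of the last admitted residue
    shortfall: int  # how many residues short of k the table fell

    @property
    def residue_indices(self) -> set:
        if self.residues.empty:
            return set()
        return set(self.residues["residue_index"].astype(int))


def top_residues(residues: pd.DataFrame, k: int = 20) -> CandidateSet:
    """Select the k highest-fold-change residues."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = residues.sort_values(
        ["fold_change", "residue_index"], ascending=[False, True],
        ignore_index=True,
    )
    top = ranked.head(k).copy()
    threshold = float(top["fold_change"].iloc[-1]) if len(top) else np.nan
    return CandidateSet(
        residues=top,
        k_requested=k,
        threshold=threshold,
        shortfall=max(0, k - len(top)),
    )


@dataclass
class RecoveryMetrics:
    precision: float  # NaN when no candidates were called
    recall: float
    n_candidates: int
    n_truth: int

    @property
    def precision_defined(self) -> bool:
        return not np.isnan(self.precision)


def recovery_metrics(candidates: CandidateSet, truth) -> RecoveryMetrics:
    """Precision/recall of called residues against the planted causal set."""
    truth = set(int(t) for t in truth)
    if not truth:
        raise ValueError("truth set must be non-empty")
    called = candidates.residue_indices
    hits = len(called & truth)
    precision = hits / len(called) if called else float("nan")
    recall = hits / len(truth)
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        n_candidates=len(called),
        n_truth=len(truth),
    )
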