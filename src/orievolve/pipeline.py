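"""End-to-end screen orchestration: library -> selection -> reads -> candidates.

One call reproduces the whole in-silico experiment: build the amplicon,
mutagenize a library, plant causal copy-number residues, choose a WT-lethal
checkerboard condition, select, sequence both populations, pile up, compute
enrichment and call top residues against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream_rng
from . import enrichment as enr
from .population import ClonePopulation, PhenotypeMap
from .reference import OriReference, build_ori_reference
from .simulate.eppcr import EppcrModel, assign_phenotypes, mutagenize_library
from .simulate.reads import ReadSimParams, simulate_reads
from .simulate.selection import (
    CheckerboardGrowthParams,
    SelectionCondition,
    SelectionModel,
    apply_selection,
    build_checkerboard,
    select_conditions,
    simulate_checkerboard,
)
from .variant_counts import pileup_counts


@dataclass
class ScreenConfig:
    """Study conditions of one in-silico directed-evolution screen.

    Defaults mirror the wet protocol's scales: a 966 nt rep ORF with 150 nt
    flanks, a 10,000-clone working library (the pooled library is larger,
    but the analysis operates on this scale), epPCR load of ~2 substitutions
    per molecule, five causal residues at a x5 copy multiplier, selection
    over 10 generations in a 96-condition checkerboard, 200,000 2x300 bp
    read pairs per population at 0.3% base error, and a selected culture of
    10^6 cells (bulk cultures impose no meaningful clone bottleneck).
    """

    orf_length: int = 966
    flank: int = 150
    wt_copy_number: float = 9.5
    n_clones: int = 10_000
    eppcr: EppcrModel = field(default_factory=EppcrModel)
    n_causal: int = 5
    causal_multiplier: float = 5.0
    causal_residues: tuple | None = None  # explicit 1-based residues, or None
    selection: SelectionModel = field(default_factory=SelectionModel)
    condition: SelectionCondition | None = None  # None = auto from checkerboard
    od_threshold: float = 0.2
    culture_size: int = 1_000_000
    reads: ReadSimParams = field(default_factory=ReadSimParams)
    min_base_quality: int = 20
    min_depth: int = 100
    k_top: int = 20


@dataclass
class ScreenResult:
    ori: OriReference
    library: ClonePopulation
    phenotypes: PhenotypeMap
    causal_residues: tuple
    condition: SelectionCondition
    selected_conditions: list
    selected: ClonePopulation
    records: pd.DataFrame
    residues: pd.DataFrame
    candidates: enr.CandidateSet
    recovery: enr.RecoveryMetrics | None


def choose_causal_residues(ori: OriReference, n_causal: int, seed) -> tuple:
    """Pick causal residues uniformly among internal codons (not start/stop)."""
    rng = stream_rng(seed, "phenotype")
    internal = np.arange(2, ori.n_residues)  # 1-based; excludes Met1 and stop
    picked = rng.choice(internal, size=n_causal, replace=False)
    return tuple(sorted(int(r) for r in picked))


def run_screen(config: ScreenConfig | None = None, seed=0) -> ScreenResult:
    """Run the full screen under one master seed."""
    config = config or ScreenConfig()
    ori = build_ori_reference(
        config.orf_length,
        config.flank,
        seed=seed,
        wt_copy_number=config.wt_copy_number,
    )

    library = mutagenize_library(ori, config.n_clones, config.eppcr, seed=seed)
    if config.causal_residues is not None:
        causal = tuple(config.causal_residues)
    elif config.n_causal > 0:
        causal = choose_causal_residues(ori, config.n_causal, seed)
    else:
        causal = ()
    causal_spec = {r: config.causal_multiplier for r in causal}
    library, phenotypes = assign_phenotypes(library, causal_spec, seed=seed)

    # checkerboard: find WT-lethal, mutant-permissive wells (skipped when a
    # condition is pinned explicitly, e.g. the no-selection control)
    if config.condition is None:
        grid = build_checkerboard()
        wt_pop = ClonePopulation.wild_type_only(ori, total=config.n_clones)
        wt_phen = PhenotypeMap(
            ori=ori, copy_number={g: ori.wt_copy_number for g in wt_pop.clones}
        )
        od_wt, od_mut = simulate_checkerboard(
            wt_pop, library, wt_phen, phenotypes, config.selection, grid,
            CheckerboardGrowthParams(), seed=seed,
        )
        selected_conditions = select_conditions(
            grid, od_wt, od_mut, config.od_threshold
        )
    else:
        selected_conditions = []
    if config.condition is not None:
        condition = config.condition
    elif selected_conditions:
        # the strongest WT-lethal condition: highest gentamicin, then highest
        # inducer (mirrors picking harsh wells off the checkerboard)
        condition = max(
            selected_conditions,
            key=lambda cond: (cond.gentamicin, cond.salicylic_acid),
        )
    else:
        raise RuntimeError(
            "no WT-lethal mutant-permissive condition found; "
            "pass config.condition explicitly"
        )

    selected = apply_selection(
        library, phenotypes, condition, config.selection,
        seed=seed, output_total=config.culture_size,
    )
    if selected.extinct:
        raise RuntimeError("selection extinguished the library")

    reads_unsel = simulate_reads(library, config.reads, seed=seed, rng_index=0)
    reads_sel = simulate_reads(selected, config.reads, seed=seed, rng_index=1)
    counts_unsel = pileup_counts(
        reads_unsel, ori, config.min_base_quality, sample_id="unselected"
    )
    counts_sel = pileup_counts(
        reads_sel, ori, config.min_base_quality, sample_id="selected"
    )

    table_sel = enr.allele_frequencies(counts_sel, ori, config.min_depth)
    table_unsel = enr.allele_frequencies(counts_unsel, ori, config.min_depth)
    records = enr.fold_changes(table_sel, table_unsel)
    records = enr.enrichment_test(records)
    records = enr.annotate_codons(records, ori)
    residues = enr.aggregate_residues(records)
    candidates = enr.top_residues(residues, config.k_top)
    recovery = (
        enr.recovery_metrics(candidates, causal) if causal else None
    )

    return ScreenResult(
        ori=ori,
        library=library,
        phenotypes=phenotypes,
        causal_residues=causal,
        condition=condition,
        selected_conditions=selected_conditions,
        selected=selected,
        records=records,
        residues=residues,
        candidates=candidates,
        recovery=recovery,
    )


def null_config(n_pairs: int = 60_000, n_clones: int = 10_000) -> ScreenConfig:
    """A no-selection control: no causal residues, gentamicin = 0.

    Used for calibration checks: with zero gentamicin every clone's growth
    weight is 1, so the 'selected' culture is just a resample of the library
    and every allele's expected fold change is 1.
    """
    return ScreenConfig(
        n_clones=n_clones,
        n_causal=0,
        condition=SelectionCondition(gentamicin=0.0, salicylic_acid=5e-6),
        reads=ReadSimParams(n_pairs=n_pairs),
    )
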