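"""Growth-coupled selection: inducible-resistance survival model + checkerboard.

The selection plasmid carries a salicylic-acid-inducible gentamicin
resistance gene, so resistance dose scales with plasmid copy number times
promoter induction.  The quantitative survival model here is an invented
parametric stand-in (the real copy-number -> tolerance relation was never
measured): Hill induction

    I(s) = I_min + (I_max - I_min) * s^h / (K_s^h + s^h)

resistance dose ``R = copies * I(s)``, and a log-logistic per-generation
growth weight

    w(g, R) = 1 / (1 + (g / (alpha * R))^beta)

with ``w = 1`` at zero gentamicin and expected post-selection abundance
proportional to ``count * w^G`` over ``G`` generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._rng import stream_rng
from ..population import ClonePopulation, PhenotypeMap

#: 8 checkerboard rows labelled like a microtitre plate
ROW_LABELS = "ABCDEFGH"


@dataclass(frozen=True)
class SelectionCondition:
    """One well of the selection grid."""

    gentamicin: float  # mg/L
    salicylic_acid: float  # molar
    row: int | None = None  # 0-based grid row (A=0)
    col: int | None = None  # 0-based grid column (well 1 = 0)

    def __post_init__(self):
        if self.gentamicin < 0 or self.salicylic_acid < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def well(self) -> str | None:
        if self.row is None or self.col is None:
            return None
        return f"{ROW_LABELS[self.row]}{self.col + 1}"


@dataclass
class SelectionModel:
    """Hill induction x log-logistic kill, applied over ``generations``."""

    i_min: float = 0.02
    i_max: float = 1.0
    k_s: float = 0.25e-6  # molar; half-max induction
    hill: float = 1.0
    alpha: float = 20.0  # mg/L of gentamicin tolerated per unit resistance dose
    beta: float = 2.0  # kill-curve steepness
    generations: int = 10

    def __post_init__(self):
        if self.i_min < 0 or self.i_max < self.i_min:
            raise ValueError("need 0 <= i_min <= i_max")
        if self.k_s <= 0 or self.hill <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("k_s, hill, alpha, beta must be positive")
        if self.generations < 1:
            raise ValueError("generations must be a positive integer")

    def induction(self, salicylic_acid: float) -> float:
        s = float(salicylic_acid)
        if s == 0:
            return self.i_min
        sh = s**self.hill
        return self.i_min + (self.i_max - self.i_min) * sh / (
            self.k_s**self.hill + sh
        )

    def weight(self, gentamicin, copies, salicylic_acid) -> np.ndarray:
        """Per-generation growth weight w in (0, 1]; w(0, .) = 1."""
        copies = np.asarray(copies, dtype=float)
        g = float(gentamicin)
        if g == 0:
            return np.ones_like(copies)
        dose = self.alpha * copies * self.induction(salicylic_acid)
        # overflow in ratio**beta is deliberate: the weight underflows to 0
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(dose > 0, g / np.where(dose > 0, dose, 1.0), np.inf)
            return 1.0 / (1.0 + ratio**self.beta)

    def log_selection_factor(self, condition, copies) -> np.ndarray:
        """G * log w, computed stably for many genotypes at once."""
        w = self.weight(condition.gentamicin, copies, condition.salicylic_acid)
        with np.errstate(divide="ignore"):
            return self.generations * np.log(w)


def expected_frequencies(
    population: ClonePopulation,
    phenotypes: PhenotypeMap,
    condition: SelectionCondition,
    model: SelectionModel,
) -> dict:
    """Deterministic post-selection genotype frequencies (no resampling).

    Returns an empty dict if every clone's selection factor underflows to
    zero weight (extinct population).
    """
    genotypes = population.genotypes()
    if not genotypes:
        return {}
    counts = population.counts().astype(float)
    copies = phenotypes.copies_for(population)
    log_factor = model.log_selection_factor(condition, copies)
    finite = np.isfinite(log_factor)
    if not finite.any():
        return {}
    shifted = np.where(finite, log_factor - log_factor[finite].max(), -np.inf)
    weight = counts * np.exp(shifted)
    total = weight.sum()
    if total == 0:
        return {}
    freqs = weight / total
    return {g: float(f) for g, f in zip(genotypes, freqs)}


def apply_selection(
    population: ClonePopulation,
    phenotypes: PhenotypeMap,
    condition: SelectionCondition,
    model: SelectionModel | None = None,
    seed=0,
    output_total: int | None = None,
) -> ClonePopulation:
    """Grow the population under one selection condition.

    Expected post-selection abundance is ``count * w^G``; the realized
    culture is a multinomial resample of ``output_total`` cells (default:
    the input total).  An extinct population (all weights underflow) is
    returned as an empty :class:`ClonePopulation`, not an exception.
    """
    for genotype in population.clones:
        if genotype not in phenotypes.copy_number:
            raise ValueError(f"genotype {genotype} has no phenotype")
    model = model or SelectionModel()
    rng = stream_rng(seed, "selection")
    output_total = population.total if output_total is None else int(output_total)

    freqs = expected_frequencies(population, phenotypes, condition, model)
    if not freqs:
        return ClonePopulation(ori=population.ori, clones={})
    genotypes = list(freqs.keys())
    p = np.array(list(freqs.values()))
    p = p / p.sum()
    draws = rng.multinomial(output_total, p)
    clones = {g: int(c) for g, c in zip(genotypes, draws) if c > 0}
    return ClonePopulation(ori=population.ori, clones=clones)


# ---------------------------------------------------------------------------
# checkerboard grid


@dataclass
class CheckerboardGrid:
    """8x12 two-axis serial dilution: gentamicin by row, salicylic acid by column.

    Row A holds ``gent_start`` mg/L, halving down to row H; column 12 holds
    ``sa_max`` molar, halving leftwards to column 1.
    """

    gent_start: float = 3000.0  # mg/L in row A
    sa_max: float = 5e-6  # molar in column 12
    gent_factor: float = 2.0
    sa_factor: float = 2.0
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self):
        if self.gent_start <= 0 or self.sa_max <= 0:
            raise ValueError("starting concentrations must be positive")

    def gentamicin(self, row: int) -> float:
        return self.gent_start / self.gent_factor**row

    def salicylic_acid(self, col: int) -> float:
        return self.sa_max / self.sa_factor ** (self.n_cols - 1 - col)

    def condition(self, row: int, col: int) -> SelectionCondition:
        return SelectionCondition(
            gentamicin=self.gentamicin(row),
            salicylic_acid=self.salicylic_acid(col),
            row=row,
            col=col,
        )

    def conditions(self) -> list:
        return [
            self.condition(r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
        ]


def build_checkerboard(
    gent_start: float = 3000.0, sa_max: float = 5e-6
) -> CheckerboardGrid:
    """The default 96-condition grid (3,000 -> 23.4 mg/L; 5 uM -> 2.44 nM)."""
    return CheckerboardGrid(gent_start=gent_start, sa_max=sa_max)


@dataclass
class CheckerboardGrowthParams:
    """Overnight outgrowth model for well ODs.

    Each well grows for a fixed window equivalent to ``doublings`` doublings
    of an unchallenged clone; a clone with growth weight w achieves
    ``2**(doublings * w)``-fold expansion, summed over the population and
    capped at ``od_max`` (saturation).
    """

    inoculum_od: float = 0.002
    od_max: float = 1.0
    doublings: float = 24.0
    noise_sd: float = 0.0


def simulate_checkerboard(
    pop_wt: ClonePopulation,
    pop_mut: ClonePopulation,
    phenotypes_wt: PhenotypeMap,
    phenotypes_mut: PhenotypeMap,
    model: SelectionModel,
    grid: CheckerboardGrid | None = None,
    growth: CheckerboardGrowthParams | None = None,
    seed=0,
) -> tuple:
    """Simulate overnight ODs of the WT and mutant populations over the grid.

    Returns ``(od_wt, od_mut)`` as (n_rows, n_cols) arrays.
    """
    grid = grid or build_checkerboard()
    growth = growth or CheckerboardGrowthParams()
    rng = stream_rng(seed, "checkerboard")

    def well_od(population, phenotypes, condition):
        if population.total == 0:
            return 0.0
        freqs = population.counts() / population.total
        copies = phenotypes.copies_for(population)
        w = model.weight(condition.gentamicin, copies, condition.salicylic_acid)
        expansion = float(np.sum(freqs * 2.0 ** (growth.doublings * w)))
        return min(growth.od_max, growth.inoculum_od * expansion)

    shape = (grid.n_rows, grid.n_cols)
    od_wt = np.zeros(shape)
    od_mut = np.zeros(shape)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            condition = grid.condition(r, c)
            od_wt[r, c] = well_od(pop_wt, phenotypes_wt, condition)
            od_mut[r, c] = well_od(pop_mut, phenotypes_mut, condition)
    if growth.noise_sd > 0:
        od_wt = np.clip(od_wt + rng.normal(0, growth.noise_sd, shape), 0, None)
        od_mut = np.clip(od_mut + rng.normal(0, growth.noise_sd, shape), 0, None)
    return od_wt, od_mut


def select_conditions(
    grid: CheckerboardGrid,
    od_wt: np.ndarray,
    od_mut: np.ndarray,
    od_threshold: float = 0.2,
) -> list:
    """WT-lethal, mutant-permissive wells: od_wt < threshold <= od_mut."""
    if od_threshold <= 0:
        raise ValueError("od_threshold must be positive")
    od_wt = np.asarray(od_wt)
    od_mut = np.asarray(od_mut)
    if od_wt.shape != od_mut.shape:
        raise ValueError("OD matrices must have the same shape")
    selected = []
    for r in range(od_wt.shape[0]):
        for c in range(od_wt.shape[1]):
            if od_wt[r, c] < od_threshold <= od_mut[r, c]:
                selected.append(grid.condition(r, c))
    return selected
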