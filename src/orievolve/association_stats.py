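"""Cross-variable statistics for strain panels.

The per-mutant characterization produces, for each strain, a plasmid copy
number, a growth rate and a mean reporter output, plus the screen's
enrichment fold change.  This module holds the tests relating them:
polynomial regressions with adjusted R^2 and an overall F-test, Tukey HSD
group comparisons with compact letter displays, Fisher exact tests on
transformation counts, Welch t tests on colony counts, Pearson correlations
with BH correction, and the interface-membership enrichment test.
All functions are pure and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class RegressionResult:
    """Polynomial OLS fit summary."""

    coefficients: tuple  # ascending powers: intercept, x, x^2, ...
    r_squared: float
    adjusted_r_squared: float
    f_statistic: float
    p_value: float
    n: int
    degree: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return sum(c * x**p for p, c in enumerate(self.coefficients))


def regress(x, y, degree: int = 1) -> RegressionResult:
    """OLS on a polynomial basis with adjusted R^2 and the overall F-test p.

    adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) for p non-intercept
    terms; the p value is for the two-sided overall F test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    design = np.vander(x, degree + 1, increasing=True)
    if np.linalg.matrix_rank(design) < degree + 1:
        raise ValueError("degenerate design: collinear or constant predictor")
    model = sm.OLS(y, design).fit()
    return RegressionResult(
        coefficients=tuple(float(c) for c in model.params),
        r_squared=float(model.rsquared),
        adjusted_r_squared=float(model.rsquared_adj),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=n,
        degree=degree,
    )


@dataclass
class TukeyResult:
    """Pairwise studentized-range p values and the compact letter display."""

    groups: tuple
    p_values: pd.DataFrame  # symmetric matrix, index/columns = groups
    letters: dict  # group -> letter string, e.g. "ab"
    alpha: float


def tukey_hsd(groups: dict, alpha: float = 0.05) -> TukeyResult:
    """Tukey honestly-significant-difference test over labelled groups.

    Groups sharing any display letter are not significantly different at the
    family level ``alpha``.  Letters are assigned with the insert-and-absorb
    algorithm over groups ordered by decreasing mean.
    """
    labels = list(groups.keys())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for label in labels:
        values = np.asarray(list(groups[label]), dtype=float)
        if len(values) < 2:
            raise ValueError(f"group {label!r} needs >= 2 replicates")
        samples.append(values)
    result = stats.tukey_hsd(*samples)
    k = len(labels)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                p[i, j] = result.pvalue[i, j]
    p_frame = pd.DataFrame(p, index=labels, columns=labels)
    significant = {
        (labels[i], labels[j])
        for i in range(k)
        for j in range(i + 1, k)
        if p[i, j] < alpha
    }
    letters = compact_letter_display(
        labels,
        {label: float(np.mean(sample)) for label, sample in zip(labels, samples)},
        significant,
    )
    return TukeyResult(
        groups=tuple(labels), p_values=p_frame, letters=letters, alpha=alpha
    )


def compact_letter_display(labels, means: dict, significant: set) -> dict:
    """Insert-and-absorb letter assignment.

    Starts from one letter covering everything; each significantly different
    pair splits every letter containing both; letters that become subsets of
    another are absorbed.  Result: two groups share a letter iff no
    significant difference separates them within that letter set.
    """
    ordered = sorted(labels, key=lambda g: -means[g])
    letter_sets = [set(ordered)]
    for a, b in sorted(significant, key=lambda pair: (str(pair[0]), str(pair[1]))):
        split = []
        for current in letter_sets:
            if a in current and b in current:
                split.append(current - {a})
                split.append(current - {b})
            else:
                split.append(current)
        # absorb: drop empties, duplicates and strict subsets of another set
        letter_sets = []
        for candidate in split:
            if not candidate or candidate in letter_sets:
                continue
            if any(candidate < other for other in split if other != candidate):
                continue
            letter_sets.append(candidate)
    # order letters by the best (highest-mean) group they contain
    letter_sets.sort(
        key=lambda s: min(ordered.index(g) for g in s) if s else len(ordered)
    )
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment = {label: "" for label in labels}
    for letter, members in zip(alphabet, letter_sets):
        for label in members:
            assignment[label] += letter
    return assignment


def fisher_2x2(a: int, b: int, c: int, d: int):
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    Returns ``(p, odds_ratio)``; a table with an all-zero margin gets p = 1
    by convention.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        odds = np.nan if min(b, c) == 0 or min(a, d) == 0 else (a * d) / (b * c)
        return 1.0, float(odds) if np.isfinite(odds) else float("nan")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), float(odds)


def welch_t(x, y):
    """Welch's unequal-variance two-sided t test; returns ``(t, p)``."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def welch_satterthwaite_df(x, y) -> float:
    """Welch-Satterthwaite effective degrees of freedom."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    return float(
        (vx + vy) ** 2
        / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    )


def pearson_bh(pairs: dict) -> pd.DataFrame:
    """Pearson r with t-approximation p per variable pair, BH across pairs.

    ``pairs`` maps a label to ``(x, y)`` paired observations.  A pair with a
    zero-variance member is reported with NaN r and p (undefined) and is
    excluded from the BH family.
    """
    rows = []
    for label, (x, y) in pairs.items():
        x = np.asarray(list(x), dtype=float)
        y = np.asarray(list(y), dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise ValueError(f"pair {label!r}: need >= 3 paired observations")
        if x.std() == 0 or y.std() == 0:
            rows.append({"pair": label, "r": np.nan, "p_value": np.nan, "n": len(x)})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"pair": label, "r": float(r), "p_value": float(p), "n": len(x)})
    frame = pd.DataFrame(rows)
    frame["q_value"] = np.nan
    defined = frame["p_value"].notna()
    if defined.any():
        frame.loc[defined, "q_value"] = multipletests(
            frame.loc[defined, "p_value"], method="fdr_bh"
        )[1]
    return frame


def interface_enrichment(candidates, interface, n_residues: int):
    """Are candidate residues over-represented on an interface?

    2x2 membership table (candidate x interface) -> two-sided Fisher exact.
    Returns ``(p, odds_ratio)``.
    """
    candidates = set(int(r) for r in candidates)
    interface = set(int(r) for r in interface)
    if not interface:
        raise ValueError("interface set must be non-empty")
    universe = set(range(1, n_residues + 1))
    if not candidates <= universe or not interface <= universe:
        raise ValueError("residue sets must lie within 1..n_residues")
    a = len(candidates & interface)
    b = len(candidates - interface)
    c = len(interface - candidates)
    d = n_residues - a - b - c
    p, odds = fisher_2x2(a, b, c, d)
    return p, odds
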