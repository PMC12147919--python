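"""Digital-PCR Poisson quantification of plasmid copy number.

With n partitions of which k light up, the mean template load per partition
is ``lambda = -ln(1 - k/n)``; plasmid copies per cell is the ratio of the
plasmid-borne target channel (e.g. KanR) to a single-copy chromosomal
reference channel (e.g. rpoB).  Partition volume cancels in the ratio, so
equal reaction volumes are the only assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class SaturatedPlateError(ValueError):
    """Every partition positive: lambda is unbounded, not estimable."""


class NoReferenceSignalError(ValueError):
    """Zero positives in the reference channel: the ratio is undefined."""


@dataclass(frozen=True)
class PartitionCount:
    """One dPCR channel of one reaction."""

    sample_id: str
    channel: str
    n_total: int
    n_positive: int

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")


def poisson_lambda(n_positive: int, n_total: int) -> float:
    """Mean copies per partition from a positive-partition count."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_positive < 0 or n_positive > n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    if n_positive == n_total:
        raise SaturatedPlateError(
            f"all {n_total} partitions positive; dilute and re-run"
        )
    return float(-np.log1p(-n_positive / n_total))


def _lambda_variance(n_positive: int, n_total: int) -> float:
    """Delta-method variance of the lambda estimate.

    lambda-hat = -ln(1 - p-hat) with Var(p-hat) = p(1-p)/n gives
    Var(lambda-hat) ~= p / (n (1 - p)).
    """
    p = n_positive / n_total
    if n_positive == 0:
        return 0.0
    return p / (n_total * (1.0 - p))


@dataclass
class CopyNumberEstimate:
    """Target:reference lambda ratio with a 95% delta-method CI."""

    sample_id: str
    lambda_target: float
    lambda_reference: float
    ratio: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if not self.ci_low <= self.ratio <= self.ci_high:
            raise ValueError("CI must bracket the ratio")


def copy_ratio(
    target: PartitionCount, reference: PartitionCount
) -> CopyNumberEstimate:
    """Copies per cell = lambda(target) / lambda(reference).

    The 95% CI comes from the delta method on the two binomial positive
    counts, applied on the log-ratio scale (the two channels are
    independent reactions).
    """
    lam_t = poisson_lambda(target.n_positive, target.n_total)
    lam_r = poisson_lambda(reference.n_positive, reference.n_total)
    if reference.n_positive < 1 or lam_r == 0:
        raise NoReferenceSignalError(
            "reference channel has no positive partitions"
        )
    ratio = lam_t / lam_r
    var_log = (
        _lambda_variance(target.n_positive, target.n_total) / lam_t**2
        if lam_t > 0
        else 0.0
    ) + _lambda_variance(reference.n_positive, reference.n_total) / lam_r**2
    z = stats.norm.ppf(0.975)
    half = z * np.sqrt(var_log)
    if ratio == 0:
        raise ValueError("target channel has no signal; ratio is zero")
    return CopyNumberEstimate(
        sample_id=target.sample_id,
        lambda_target=lam_t,
        lambda_reference=lam_r,
        ratio=ratio,
        ci_low=float(ratio * np.exp(-half)),
        ci_high=float(ratio * np.exp(half)),
    )


@dataclass
class ReplicateSummary:
    """Average of per-replicate copy-number ratios (not pooled lambdas)."""

    mean_ratio: float
    se: float  # NaN for a single replicate
    ratios: tuple

    @property
    def se_defined(self) -> bool:
        return not np.isnan(self.se)


def average_replicates(estimates) -> ReplicateSummary:
    """Arithmetic mean of biological-replicate ratios, with its SE."""
    ratios = [
        e.ratio if isinstance(e, CopyNumberEstimate) else float(e)
        for e in estimates
    ]
    if not ratios:
        raise ValueError("need at least one replicate")
    arr = np.asarray(ratios, dtype=float)
    se = (
        float(arr.std(ddof=1) / np.sqrt(len(arr)))
        if len(arr) > 1
        else float("nan")
    )
    return ReplicateSummary(
        mean_ratio=float(arr.mean()), se=se, ratios=tuple(ratios)
    )
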