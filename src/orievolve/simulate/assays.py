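"""Downstream-assay simulators: digital-PCR plates and OD600 growth curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._rng import stream_rng
from ..copy_number import PartitionCount
from ..growth_kinetics import GrowthCurve


def simulate_dpcr(
    lam: float,
    n_partitions: int = 8500,
    seed=0,
    sample_id: str = "sample",
    channel: str = "target",
    rng_index: int = 0,
) -> PartitionCount:
    """One dPCR channel: positives ~ Binomial(n, 1 - exp(-lambda)).

    ``lam`` is the mean template copies per partition; partitioning is
    Poisson, so a partition is positive unless it received zero copies.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    rng = stream_rng(seed, "dpcr", rng_index)
    p_positive = 1.0 - np.exp(-lam)
    n_positive = int(rng.binomial(n_partitions, p_positive))
    return PartitionCount(
        sample_id=sample_id,
        channel=channel,
        n_total=n_partitions,
        n_positive=n_positive,
    )


@dataclass
class GrowthSimParams:
    """Logistic OD600 curve parameters, sampled every 6 min for 24 h."""

    k: float = 1.0  # carrying-capacity OD
    n0: float = 0.01  # inoculum OD
    r: float = 0.5  # intrinsic rate, per hour
    noise_sd: float = 0.005  # additive OD noise
    interval_min: float = 6.0
    duration_h: float = 24.0

    def __post_init__(self):
        if not self.k > self.n0 > 0:
            raise ValueError("need K > N0 > 0")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def times(self) -> np.ndarray:
        step = self.interval_min / 60.0
        n_points = int(round(self.duration_h / step)) + 1
        return np.arange(n_points) * step


def logistic_od(t, k, n0, r) -> np.ndarray:
    """Three-parameter logistic N(t) = K / (1 + ((K-N0)/N0) e^{-rt})."""
    t = np.asarray(t, dtype=float)
    return k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))


def simulate_growth(
    params: GrowthSimParams | None = None,
    seed=0,
    sample_id: str = "well",
    rng_index: int = 0,
) -> GrowthCurve:
    """A noisy logistic OD600 time series (241 points at the defaults)."""
    params = params or GrowthSimParams()
    rng = stream_rng(seed, "growth", rng_index)
    times = params.times()
    od = logistic_od(times, params.k, params.n0, params.r)
    if params.noise_sd > 0:
        od = od + rng.normal(0.0, params.noise_sd, size=times.shape)
    od = np.clip(od, 0.0, None)  # an OD reading cannot be negative
    return GrowthCurve(sample_id=sample_id, times=times, od=od)
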