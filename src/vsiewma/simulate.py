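"""Monte-Carlo validation of the Markov-chain metrics and synthetic streams.

The simulator replays the chart's stochastic operation exactly as specified
-- continuous EWMA recursion (no state discretization), first sample drawn
after the long interval, subsequent intervals chosen by the zone of the
current point -- so agreement with the Markov-chain numbers bounds both the
chain's discretization error and any bookkeeping mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import MU0, TRANSFORM_POWER, WEIBULL_SHAPE, ChartDesign
from .errors import DomainError
from .estimation import EstimationContext


def generate_exponential(n: int, eta: float, seed=None) -> np.ndarray:
    """``n`` i.i.d. exponential waiting times with scale (mean) ``eta``."""
    if n < 1:
        raise DomainError("n must be >= 1")
    if not (eta > 0.0 and math.isfinite(eta)):
        raise DomainError("eta must be positive")
    return np.random.default_rng(seed).exponential(scale=eta, size=n)


@dataclass(frozen=True)
class SimulationSpec:
    """Replication plan for the run-length simulator."""

    reps: int = 10_000
    seed: int | None = None
    max_samples_per_run: int = 50_000

    def __post_init__(self):
        if self.reps < 1:
            raise DomainError("reps must be >= 1")
        if self.max_samples_per_run < 1:
            raise DomainError("max_samples_per_run must be >= 1")


@dataclass(frozen=True)
class McResult:
    """Simulated time-to-signal summary.

    ``truncation_rate`` is the fraction of replications still unabsorbed at
    the sample cap; such runs contribute their censored time, so a
    non-negligible rate (> 1e-4) flags the estimate as unreliable (low).
    """

    estimate: float
    se: float
    mean_samples: float
    se_samples: float
    reps: int
    seed: int | None
    truncation_rate: float

    @property
    def reliable(self) -> bool:
        return self.truncation_rate < 1e-4


def mc_ats(design: ChartDesign, delta: float, m: float = math.inf,
           spec: SimulationSpec = SimulationSpec()) -> McResult:
    """Simulate the time to signal of the chart.

    Each replication: draw the Phase I estimation ratio
    ``gamma ~ Gamma(m, 1/m)`` (1 for known parameter), then run the chart on
    the normalized scale -- transformed observations are unit-Weibull draws
    times ``(delta / gamma)**(1/3.6)`` -- starting from the in-control mean
    with the long interval first, until the statistic leaves the action band.
    Time to signal sums the intervals up to and including the one preceding
    the signalling sample.
    """
    if not (delta > 0.0):
        raise DomainError("delta must be positive")
    ctx = EstimationContext(m)
    rng = np.random.default_rng(spec.seed)
    lim = design.limits
    n = spec.reps

    gammas = np.ones(n) if ctx.known else rng.gamma(m, 1.0 / m, size=n)
    scale = (delta / gammas) ** TRANSFORM_POWER

    z = np.full(n, MU0)
    interval = np.full(n, design.h1)
    clock = np.zeros(n)
    samples = np.zeros(n)
    times = np.empty(n)
    counts = np.empty(n)
    idx = np.arange(n)          # positions in the output arrays
    truncated = 0

    lam = design.lam
    for _ in range(spec.max_samples_per_run):
        if idx.size == 0:
            break
        clock += interval
        samples += 1.0
        y = rng.weibull(WEIBULL_SHAPE, size=idx.size) * scale
        z = lam * y + (1.0 - lam) * z
        out = (z < lim.lcl) | (z > lim.ucl)
        if out.any():
            done = idx[out]
            times[done] = clock[out]
            counts[done] = samples[out]
            keep = ~out
            idx, z, clock, samples, scale = (
                idx[keep], z[keep], clock[keep], samples[keep], scale[keep])
        warn = (z < lim.lwl) | (z > lim.uwl)
        interval = np.where(warn, design.h2, design.h1)
    if idx.size:
        truncated = idx.size
        times[idx] = clock
        counts[idx] = samples

    est = float(times.mean())
    carl = float(counts.mean())
    return McResult(
        estimate=est,
        se=float(times.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
        mean_samples=carl,
        se_samples=float(counts.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
        reps=n,
        seed=spec.seed,
        truncation_rate=truncated / n,
    )
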