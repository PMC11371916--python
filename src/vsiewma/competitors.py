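"""Comparison charts sharing the same Markov engine.

Four competitors to the variable-interval EWMA chart on transformed
exponential data:

* ``SHEWHART_EXP`` -- fixed-interval Shewhart chart on the transformed
  observation, i.e. the ``lam = 1`` special case with symmetric ``K sigma``
  limits; its run length is geometric with a closed-form ARL ``1/p``.
* ``VSISHEWHART_EXP`` -- the same chart with the two-interval sampling
  scheme.
* ``FSIEWMA_EXP`` -- the EWMA chart with a fixed sampling interval, with its
  own ``(lam, K)`` optimized under the single in-control constraint.
* ``VSIEWMA_NOR`` -- a variable-interval EWMA chart designed as if the
  transformed observation were exactly normal with the matched Weibull
  moments; evaluating such a design under the true Weibull law quantifies
  the cost of the normality shortcut.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .core import ChartDesign, TRANSFORM_POWER
from .design import (
    GridSpec,
    K_BRACKET,
    _ConstraintEvaluator,
    _grid,
    _solve_k,
)
from .errors import DomainError, InfeasibleDesignError
from .estimation import (
    DEFAULT_QUADRATURE,
    EstimationContext,
    QuadratureSpec,
    unconditional_metric,
)
from .markov import weibull_cdf


class ChartFamily(Enum):
    VSIEWMA_EXP = "VSIEWMA-exp"
    FSIEWMA_EXP = "FSIEWMA-exp"
    VSISHEWHART_EXP = "VSIShewhart-exp"
    SHEWHART_EXP = "Shewhart-exp"
    VSIEWMA_NOR = "VSIEWMA-nor"


@dataclass(frozen=True)
class ChartVariant:
    """A chart family together with a concrete design.

    ``reference_distribution`` records the law assumed when the design was
    calibrated; evaluation may use either law (the normal-assumption chart is
    typically evaluated under the true Weibull law).
    """

    family: ChartFamily
    design: ChartDesign
    reference_distribution: str = "weibull"

    def __post_init__(self):
        if self.family in (ChartFamily.SHEWHART_EXP,
                           ChartFamily.VSISHEWHART_EXP):
            if self.design.lam != 1.0:
                raise DomainError(f"{self.family.value} requires lam = 1")
        if self.family in (ChartFamily.SHEWHART_EXP, ChartFamily.FSIEWMA_EXP):
            if not self.design.is_fsi:
                raise DomainError(f"{self.family.value} requires h1 == h2")
        if (self.reference_distribution == "normal"
                and self.family is not ChartFamily.VSIEWMA_NOR):
            raise DomainError(
                "only the normal-assumption chart is designed under the "
                "normal reference distribution"
            )

    def aats(self, delta: float, m: float = math.inf, N: int = 100,
             distribution: str = "weibull") -> float:
        """Average time to signal of this variant at shift ``delta``."""
        return unconditional_metric(self.design, delta, m, N,
                                    metric="ats", distribution=distribution)


def fsi_ewma_ats(lam: float, K: float, m: float, delta: float,
                 N: int = 100, h0: float = 1.0) -> float:
    """AATS of a fixed-interval EWMA chart: ``h0`` times the unconditional
    ARL (the warning width is irrelevant when both intervals coincide)."""
    design = ChartDesign(lam=lam, K=K, W=0.0, h1=h0, h2=h0, h0=h0)
    return h0 * unconditional_metric(design, delta, m, N, metric="arl")


def optimize_fsi_design(
    delta: float,
    m: float = math.inf,
    tau: float = 370.4,
    h0: float = 1.0,
    lam_grid: tuple[float, ...] | None = None,
    N: int = 100,
    quad: QuadratureSpec = DEFAULT_QUADRATURE,
) -> tuple[ChartDesign, float]:
    """Best fixed-interval EWMA design: scan ``lam``, calibrate ``K`` from
    ``AATS0 = tau`` (equivalently unconditional ARL0 = ``tau/h0``), minimize
    AATS1.  Returns the design and its AATS1."""
    if delta == 1.0:
        raise DomainError("delta = 1 has no out-of-control objective")
    lam_grid = lam_grid or _grid(0.03, 1.0, 0.01)
    best = None
    for lam in lam_grid:
        ev = _ConstraintEvaluator(lam, m, tau, h0, N, quad)
        f = lambda K: ev.cats0(K, 0.0, h0, h0) - tau
        lo, hi = K_BRACKET
        if f(lo) * f(hi) > 0.0:
            continue
        K = brentq(f, lo, hi, xtol=1e-9)
        a1 = fsi_ewma_ats(lam, K, m, delta, N, h0)
        if best is None or a1 < best[1] - 1e-9:
            best = (ChartDesign(lam=lam, K=K, W=0.0, h1=h0, h2=h0,
                                h0=h0, tau=tau), a1)
    if best is None:
        raise InfeasibleDesignError("no feasible fixed-interval design")
    return best


def shewhart_arl(K: float, delta: float = 1.0, gamma: float = 1.0) -> float:
    """Closed-form ARL of the ``lam = 1`` chart: geometric with success
    probability ``p = 1 - [F((g/d)^(1/3.6) ucl) - F((g/d)^(1/3.6) lcl)]``."""
    lim = ChartDesign(lam=1.0, K=K, W=0.0).limits
    c = (gamma / delta) ** TRANSFORM_POWER
    p = 1.0 - float(weibull_cdf(c * lim.ucl) - weibull_cdf(c * lim.lcl))
    return 1.0 / p


def shewhart_ats(K: float, delta: float, m: float = math.inf,
                 h0: float = 1.0,
                 quad: QuadratureSpec = DEFAULT_QUADRATURE) -> float:
    """Unconditional ATS of the fixed-interval Shewhart chart."""
    ctx = EstimationContext(m)
    if ctx.known:
        return h0 * shewhart_arl(K, delta)
    g, w = quad.nodes_weights(m)
    return h0 * float(w @ np.array([shewhart_arl(K, delta, gi) for gi in g]))


def shewhart_designs(
    m: float = math.inf,
    tau: float = 370.4,
    h0: float = 1.0,
    h1: float = 2.0,
    h2: float = 0.1,
    N: int = 100,
    quad: QuadratureSpec = DEFAULT_QUADRATURE,
) -> tuple[float, tuple[float, float]]:
    """Calibrated Shewhart widths: ``K`` for the fixed-interval chart (from
    ``AATS0 = tau``) and ``(K, W)`` for the variable-interval chart (both
    in-control constraints, via the shared Markov machinery at ``lam = 1``).
    """
    ctx = EstimationContext(m)
    if ctx.known:
        K_fsi = brentq(lambda K: shewhart_arl(K) - tau / h0,
                       *K_BRACKET, xtol=1e-12)
    else:
        K_fsi = brentq(lambda K: shewhart_ats(K, 1.0, m, h0, quad) - tau,
                       *K_BRACKET, xtol=1e-12)
    ev = _ConstraintEvaluator(1.0, m, tau, h0, N, quad)
    K_vsi = _solve_k(ev, h1, h2, k_init=K_fsi)
    W_vsi = ev.solve_w(K_vsi, h1, h2)
    return K_fsi, (K_vsi, W_vsi)


def normal_chart_design(
    lam: float,
    h1: float,
    h2: float,
    tau: float = 370.4,
    h0: float = 1.0,
    N: int = 100,
    m: float = math.inf,
    quad: QuadratureSpec = DEFAULT_QUADRATURE,
) -> ChartDesign:
    """Design calibrated under the normality assumption.

    Transition probabilities use the normal CDF with the transformed
    observation's matched mean and standard deviation; the same state-space
    discretization applies.  The returned design meets the in-control
    constraints under the normal law, not under the true Weibull law.
    """
    ev = _ConstraintEvaluator(lam, m, tau, h0, N, quad, distribution="normal")
    K = _solve_k(ev, h1, h2)
    W = ev.solve_w(K, h1, h2)
    return ChartDesign(lam=lam, K=K, W=W, h1=h1, h2=h2, h0=h0, tau=tau)
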