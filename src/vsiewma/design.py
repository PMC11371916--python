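"""Constrained design of the VSI EWMA chart by exhaustive grid search.

The design problem: choose ``(lam, K, W, h1, h2)`` minimizing the
out-of-control average time to signal ``AATS1`` at a given shift ``delta``
and Phase I size ``m``, subject to the in-control calibration

    ``AATS0 = tau``        (average time to signal)
    ``AASI0 = h0``         (average sampling interval per epoch)

``lam``, ``h1`` and ``h2`` range over fixed grids; at each grid point the two
remaining parameters ``(K, W)`` are pinned by the constraints.

Numerical shape of the inner solve: the expected-visit vector of the
in-control chain depends on ``(lam, K)`` only, while both constraint
functions are inner products of that vector with interval weights determined
by ``W``.  ``W`` is therefore eliminated inside the ``K`` root-find -- for
each trial ``K`` the average-interval constraint is solved exactly in ``W``
using the interval-overlap CASI (continuous in ``W``; see
:func:`vsiewma.markov.interval_fraction_casi`), and the time constraint
becomes a one-dimensional root-find in ``K``.  Visit vectors are cached per
``K`` so neighbouring grid points share most of the linear algebra.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import ChartDesign
from .errors import (
    DomainError,
    InfeasibleDesignError,
    OptimizationError,
)
from .estimation import DEFAULT_QUADRATURE, EstimationContext, QuadratureSpec
from .markov import build_transition_model, expected_visits

logger = logging.getLogger(__name__)

#: Search bracket for the action-limit width.
K_BRACKET = (1.2, 5.0)

#: Ties in the objective closer than this are broken by grid preference.
TIE_TOL = 1e-6


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step))
    return tuple(round(start + i * step, 10) for i in range(n + 1))


@dataclass(frozen=True)
class GridSpec:
    """Grids for the free design parameters plus the calibration targets.

    Defaults follow the standard sweep: ``lam`` from 0.03 to 1 in steps of
    0.01, ``h1`` from ``h0 + 0.1`` to 2.5 in steps of 0.1, ``h2`` from 0.1
    to 0.9 in steps of 0.1, ``tau = 370.4`` and ``h0 = 1``.
    """

    tau: float = 370.4
    h0: float = 1.0
    lam_grid: tuple[float, ...] = field(default_factory=lambda: _grid(0.03, 1.0, 0.01))
    h1_grid: tuple[float, ...] = None
    h2_grid: tuple[float, ...] = field(default_factory=lambda: _grid(0.1, 0.9, 0.1))

    def __post_init__(self):
        if self.h1_grid is None:
            object.__setattr__(self, "h1_grid", _grid(self.h0 + 0.1, 2.5, 0.1))

    @classmethod
    def coarse(cls, **kw) -> "GridSpec":
        """Reduced grid (``lam`` step 0.05) for quick searches."""
        return cls(lam_grid=_grid(0.05, 1.0, 0.05), **kw)

    def pairs(self):
        """Valid interval pairs, ``h2 < h0 < h1``."""
        return [(h1, h2) for h2 in self.h2_grid for h1 in self.h1_grid
                if h2 < self.h0 < h1]


class _ConstraintEvaluator:
    """In-control constraint functions for one ``(lam, m, N)`` slice.

    Caches the expected-visit vectors (one per gamma quadrature node, or one
    for known parameter) keyed by ``K``, and evaluates both constraints as
    inner products with interval weights derived from ``(K, W)``.
    """

    def __init__(self, lam, m, tau, h0, N, quad=DEFAULT_QUADRATURE,
                 distribution="weibull"):
        self.lam, self.m, self.tau, self.h0, self.N = lam, m, tau, h0, N
        self.distribution = distribution
        ctx = EstimationContext(m)
        if ctx.known:
            self.gammas, self.weights = np.array([1.0]), np.array([1.0])
        else:
            self.gammas, self.weights = quad.nodes_weights(m)
        self._cache: dict[float, list[np.ndarray]] = {}
        self._idx = np.abs(np.arange(2 * N + 1) - N)

    def visits(self, K: float) -> list[np.ndarray]:
        got = self._cache.get(K)
        if got is None:
            design = ChartDesign(lam=self.lam, K=K, W=K, h0=self.h0, tau=self.tau)
            got = [
                expected_visits(build_transition_model(
                    design, 1.0, g, self.N, distribution=self.distribution))
                for g in self.gammas
            ]
            self._cache[K] = got
        return got

    # state geometry in action-limit units: state r = |j - N| spans
    # [(r - 1/2) s, (r + 1/2) s] with s = 2K / (2N + 1)
    def _midpoint_weights(self, K, W, h1, h2):
        s = 2.0 * K / (2 * self.N + 1)
        return np.where(self._idx * s <= W, h1, h2)

    def _overlap_weights(self, K, W, h1, h2):
        s = 2.0 * K / (2 * self.N + 1)
        lo, hi = (self._idx - 0.5) * s, (self._idx + 0.5) * s
        frac = np.clip((np.minimum(hi, W) - np.maximum(lo, -W)) / s, 0.0, 1.0)
        return h2 + (h1 - h2) * frac

    def cats0(self, K, W, h1, h2) -> float:
        h = self._midpoint_weights(K, W, h1, h2)
        return float(sum(w * (v @ h)
                         for w, v in zip(self.weights, self.visits(K))))

    def aasi0_continuous(self, K, W, h1, h2) -> float:
        h = self._overlap_weights(K, W, h1, h2)
        return float(sum(w * (v @ h) / v.sum()
                         for w, v in zip(self.weights, self.visits(K))))

    def aasi0_midpoint(self, K, W, h1, h2) -> float:
        h = self._midpoint_weights(K, W, h1, h2)
        return float(sum(w * (v @ h) / v.sum()
                         for w, v in zip(self.weights, self.visits(K))))

    def solve_w(self, K, h1, h2) -> float:
        """Warning width making the continuous average interval equal h0."""
        f = lambda W: self.aasi0_continuous(K, W, h1, h2) - self.h0
        lo, hi = 0.0, K
        if f(lo) > 0.0 or f(hi) < 0.0:
            raise InfeasibleDesignError(
                f"average interval {self.h0} unattainable with "
                f"(h1, h2) = ({h1}, {h2}) at lam={self.lam}, K={K:.4f}"
            )
        return brentq(f, lo, hi, xtol=1e-12)

    def time_residual(self, K, h1, h2) -> float:
        """AATS0 - tau with the W-constraint eliminated at this K."""
        return self.cats0(K, self.solve_w(K, h1, h2), h1, h2) - self.tau


def _solve_k(ev: _ConstraintEvaluator, h1, h2, k_init=None):
    """Root of the time constraint in K, warm-started when possible."""
    f = lambda K: ev.time_residual(K, h1, h2)
    lo, hi = K_BRACKET
    if k_init is not None:
        a, b = max(lo, k_init - 0.05), min(hi, k_init + 0.05)
        fa, fb = f(a), f(b)
        while fa * fb > 0.0 and (a > lo or b < hi):
            a, b = max(lo, a - 0.1), min(hi, b + 0.1)
            fa, fb = f(a), f(b)
        if fa * fb <= 0.0:
            return brentq(f, a, b, xtol=1e-9)
    fa, fb = f(lo), f(hi)
    if fa * fb > 0.0:
        raise InfeasibleDesignError(
            f"no K in {K_BRACKET} meets AATS0={ev.tau} at lam={ev.lam}, "
            f"(h1, h2)=({h1}, {h2})"
        )
    return brentq(f, lo, hi, xtol=1e-9)


def solve_constraints(
    lam: float,
    h1: float,
    h2: float,
    m: float = math.inf,
    tau: float = 370.4,
    h0: float = 1.0,
    N: int = 100,
    quad: QuadratureSpec = DEFAULT_QUADRATURE,
    distribution: str = "weibull",
) -> tuple[float, float]:
    """Solve the two in-control constraints for ``(K, W)`` at a grid point.

    For a degenerate fixed-interval point (``h1 == h2 == h0``) the interval
    constraint is vacuous: ``K`` is solved from ``AATS0 = tau`` alone and the
    returned ``W`` is ``nan`` (indeterminate).

    Raises
    ------
    InfeasibleDesignError
        If no ``(K, W)`` in the bracket meets the constraints.
    """
    if h1 == h2:
        if h1 != h0:
            raise InfeasibleDesignError(
                "fixed-interval point must have h1 == h2 == h0"
            )
        ev = _ConstraintEvaluator(lam, m, tau, h0, N, quad, distribution)
        f = lambda K: ev.cats0(K, 0.0, h0, h0) - tau
        lo, hi = K_BRACKET
        if f(lo) * f(hi) > 0.0:
            raise InfeasibleDesignError(
                f"no K in {K_BRACKET} meets AATS0={tau} at lam={lam} (FSI)"
            )
        return brentq(f, lo, hi, xtol=1e-9), math.nan
    ev = _ConstraintEvaluator(lam, m, tau, h0, N, quad, distribution)
    K = _solve_k(ev, h1, h2)
    return K, ev.solve_w(K, h1, h2)


@dataclass(frozen=True)
class GridSearchResult:
    """Outcome of the exhaustive design search."""

    best: ChartDesign
    best_aats1: float
    delta: float
    m: float
    trace: pd.DataFrame

    def summary(self) -> str:
        d = self.best
        return (
            f"optimal design for delta={self.delta:g}, m={self.m:g}: "
            f"lam={d.lam:.2f}, K={d.K:.4f}, W={d.W:.4f}, "
            f"(h1, h2)=({d.h1:.1f}, {d.h2:.1f}), AATS1={self.best_aats1:.2f}"
        )


def _prefer(cand, best):
    """Tie-break: smaller AATS1, then smaller lam, then smaller h1, then
    larger h2."""
    if cand[0] < best[0] - TIE_TOL:
        return True
    if cand[0] > best[0] + TIE_TOL:
        return False
    clam, ch1, ch2 = cand[1], cand[2], cand[3]
    blam, bh1, bh2 = best[1], best[2], best[3]
    return (clam, ch1, -ch2) < (blam, bh1, -bh2)


def optimize_design(
    delta: float,
    m: float = math.inf,
    grid: GridSpec | None = None,
    N: int = 100,
    quad: QuadratureSpec = DEFAULT_QUADRATURE,
) -> GridSearchResult:
    """Exhaustive scan of the design grid with the inner constraint solve.

    Infeasible grid points are skipped (and logged at DEBUG level); the scan
    is fully deterministic, including tie-breaking.
    """
    if delta == 1.0:
        raise DomainError(
            "delta = 1 is the in-control state; the out-of-control objective "
            "is undefined there"
        )
    if delta <= 0.0:
        raise DomainError("delta must be positive")
    grid = grid or GridSpec()
    ctx = EstimationContext(m)
    rows, best = [], None

    for lam in grid.lam_grid:
        ev = _ConstraintEvaluator(lam, m, grid.tau, grid.h0, N, quad)
        oov_cache: dict[float, list[np.ndarray]] = {}

        def aats1_at(K, W, h1, h2):
            vs = oov_cache.get(K)
            if vs is None:
                design = ChartDesign(lam=lam, K=K, W=K,
                                     h0=grid.h0, tau=grid.tau)
                vs = [expected_visits(
                    build_transition_model(design, delta, g, N))
                    for g in ev.gammas]
                oov_cache[K] = vs
            h = ev._midpoint_weights(K, W, h1, h2)
            return float(sum(w * (v @ h) for w, v in zip(ev.weights, vs)))

        k_warm = None
        for h1, h2 in grid.pairs():
            try:
                K = _solve_k(ev, h1, h2, k_init=k_warm)
                W = ev.solve_w(K, h1, h2)
            except InfeasibleDesignError as exc:
                logger.debug("skipping infeasible grid point: %s", exc)
                continue
            k_warm = K
            a1 = aats1_at(K, W, h1, h2)
            rows.append((lam, h1, h2, K, W, a1))
            cand = (a1, lam, h1, h2, K, W)
            if best is None or _prefer(cand, best):
                best = cand

    if best is None:
        raise OptimizationError("every grid point was infeasible")
    a1, lam, h1, h2, K, W = best
    design = ChartDesign(lam=lam, K=K, W=W, h1=h1, h2=h2,
                         h0=grid.h0, tau=grid.tau)
    trace = pd.DataFrame(rows, columns=["lam", "h1", "h2", "K", "W", "aats1"])
    return GridSearchResult(best=design, best_aats1=a1, delta=delta, m=m,
                            trace=trace)
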