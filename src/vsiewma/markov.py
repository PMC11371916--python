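"""Markov-chain run-length analysis of the VSI EWMA chart.

The in-control band ``[lcl, ucl]`` is discretized into ``2N + 1`` equal
subintervals; the EWMA statistic restricted to the band is approximated by a
finite Markov chain whose single absorbing state is "signal".  The transient
transition probabilities follow from the EWMA recursion
``Z_i = lam * Y_i + (1 - lam) * Z_{i-1}`` and the Weibull law of the
transformed observation: the probability of moving from the midpoint ``m_k``
into subinterval ``[l_j, u_j)`` is a difference of Weibull CDF values at
``(gamma / delta)**(1/3.6) * (bound - (1 - lam) * m_k) / lam``.

Absorption time of the chain, weighted by the per-state sampling interval,
gives the conditional average time to signal (CATS); the unweighted version is
the conditional average run length (CARL); their ratio is the conditional
average sampling interval (CASI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.stats import norm as _norm

from .core import (
    MU0,
    SIGMA0,
    TRANSFORM_POWER,
    WEIBULL_SHAPE,
    ChartDesign,
    NormalizedLimits,
)
from .errors import ConditioningError, DomainError, ResolutionError

#: Smallest supported half-resolution; the chain then has 51 states.
MIN_HALF_RESOLUTION = 25

#: Zone labels: central region, warning region, action region.
CR, WR, AR = "CR", "WR", "AR"


def weibull_cdf(x):
    """CDF of the unit-scale Weibull with shape 3.6, zero for ``x <= 0``.

    Closed form ``1 - exp(-x**3.6)`` via ``expm1``; this sits inside the
    transition-matrix builder and the design optimizer's root-finding loops,
    where it is evaluated on ~40k-point grids thousands of times.
    """
    x = np.asarray(x, dtype=float)
    return -np.expm1(-np.maximum(x, 0.0) ** WEIBULL_SHAPE)


def zone_of(z: float, limits: NormalizedLimits) -> str:
    """Classify a chart statistic: CR inside the warning band (inclusive),
    WR between warning and action limits, AR beyond the action limits."""
    if limits.lwl <= z <= limits.uwl:
        return CR
    if limits.lcl <= z <= limits.ucl:
        return WR
    return AR


@dataclass(frozen=True)
class TransitionModel:
    """Discretized chart chain for one ``(design, delta, gamma)`` triple.

    ``Q`` is the ``(2N+1) x (2N+1)`` transient submatrix; the absorbing
    remainder of each row is ``1 - Q.sum(axis=1)``.  ``b`` is the one-hot
    initial vector at the state containing the start value (the in-control
    mean).  ``h`` holds the sampling interval attached to each state by the
    zone of its midpoint; ``cr_overlap`` holds the fraction of each
    subinterval lying inside the central region, which interpolates ``h``
    continuously in ``W`` for the constraint solver.
    """

    design: ChartDesign
    delta: float
    gamma: float
    N: int
    lower: np.ndarray
    upper: np.ndarray
    mid: np.ndarray
    Q: np.ndarray
    b: np.ndarray
    h: np.ndarray
    cr_overlap: np.ndarray
    distribution: str = "weibull"

    @property
    def n_states(self) -> int:
        return 2 * self.N + 1

    @property
    def width(self) -> float:
        return float(self.upper[0] - self.lower[0])

    def dump(self, path) -> None:
        """Write Q, b and h to a plain-text file for inspection."""
        with open(path, "w") as fh:
            fh.write(f"# transition model: {self.n_states} states, "
                     f"delta={self.delta}, gamma={self.gamma}\n")
            fh.write("# b: " + " ".join(f"{v:.0f}" for v in self.b) + "\n")
            fh.write("# h: " + " ".join(f"{v:g}" for v in self.h) + "\n")
            np.savetxt(fh, self.Q, fmt="%.12e")


def _increment_cdf(x, scale_ratio: float, distribution: str):
    """CDF of the (normalized) transformed observation at ``x``.

    ``scale_ratio = (gamma / delta)**(1/3.6)`` rescales the argument so the
    chain can be built once on the eta-free axis.  ``distribution`` selects
    the true Weibull law or the normal approximation with the matched first
    two moments (used by the normality-assuming competitor chart).
    """
    if distribution == "weibull":
        return weibull_cdf(scale_ratio * np.asarray(x, dtype=float))
    if distribution == "normal":
        return _norm.cdf(scale_ratio * np.asarray(x, dtype=float),
                         loc=MU0, scale=SIGMA0)
    raise DomainError(f"unknown reference distribution {distribution!r}")


def build_transition_model(
    design: ChartDesign,
    delta: float = 1.0,
    gamma: float = 1.0,
    N: int = 100,
    z0: float | None = None,
    distribution: str = "weibull",
) -> TransitionModel:
    """Discretize the in-control band and assemble the transient matrix.

    Parameters
    ----------
    design : ChartDesign
        Chart parameters; the normalized limits define the band.
    delta : float
        Shift ratio ``eta1 / eta0`` of the process being monitored.
    gamma : float
        Estimation ratio ``eta_hat0 / eta0``; 1 for known parameter.
    N : int
        Half-resolution; the chain has ``2N + 1`` transient states
        (at least ``2 * MIN_HALF_RESOLUTION + 1``).
    z0 : float, optional
        Start value on the normalized axis; defaults to the in-control mean
        ``mu0`` (zero-state convention), which lands in the central state.
    distribution : {"weibull", "normal"}
        Law of the transformed observation used for the increments.
    """
    if N < MIN_HALF_RESOLUTION:
        raise ResolutionError(
            f"N={N} below floor {MIN_HALF_RESOLUTION}; the discretization "
            "needs at least 51 states"
        )
    if not (delta > 0.0 and gamma > 0.0):
        raise DomainError("delta and gamma must be positive")

    lim = design.limits
    n = 2 * N + 1
    edges = lim.lcl + (lim.ucl - lim.lcl) * np.arange(n + 1) / n
    lower, upper = edges[:-1], edges[1:]
    mid = 0.5 * (lower + upper)

    ratio = (gamma / delta) ** TRANSFORM_POWER
    shrink = (1.0 - design.lam) * mid[:, None]
    Q = (_increment_cdf((upper[None, :] - shrink) / design.lam, ratio, distribution)
         - _increment_cdf((lower[None, :] - shrink) / design.lam, ratio, distribution))
    np.maximum(Q, 0.0, out=Q)

    # interval per state: long in the central region, short in the warning
    # region; midpoints exactly on a warning limit count as central.
    in_cr = (mid >= lim.lwl) & (mid <= lim.uwl)
    h = np.where(in_cr, design.h1, design.h2)
    cr_overlap = (
        np.clip(np.minimum(upper, lim.uwl) - np.maximum(lower, lim.lwl),
                0.0, None)
        / (upper - lower)
    )

    start = MU0 if z0 is None else z0
    if not (lim.lcl <= start <= lim.ucl):
        raise DomainError("start value z0 lies outside the control band")
    j = min(int(np.searchsorted(edges, start, side="right")) - 1, n - 1)
    b = np.zeros(n)
    b[j] = 1.0

    return TransitionModel(
        design=design, delta=delta, gamma=gamma, N=N,
        lower=lower, upper=upper, mid=mid, Q=Q, b=b, h=h,
        cr_overlap=cr_overlap, distribution=distribution,
    )


@dataclass(frozen=True)
class PerformanceSummary:
    """Conditional run-length metrics for one ``(delta, gamma)`` pair.

    ``cats`` is the expected time to signal, ``carl`` the expected number of
    samples, ``casi = cats / carl`` the expected interval per sampling epoch
    (the visit-fraction definition: ``casi = p1 * h1 + p2 * h2`` with ``p1``
    and ``p2`` the expected fractions of pre-signal epochs spent in the
    central and warning regions).  ``s`` flags the regime: 0 in-control
    (``delta == 1``), 1 out-of-control.
    """

    cats: float
    carl: float
    casi: float
    s: int
    delta: float
    gamma: float

    def __str__(self):
        tag = "in-control" if self.s == 0 else "out-of-control"
        return (f"{tag} (delta={self.delta:g}, gamma={self.gamma:g}): "
                f"CATS={self.cats:.4f}, CARL={self.carl:.4f}, "
                f"CASI={self.casi:.6f}")


def _fundamental_solve(model: TransitionModel) -> tuple[np.ndarray, np.ndarray]:
    """Expected-visit row vector ``e = b' (I - Q)^-1`` and its LU context.

    One factorization serves both right-hand sides (``h`` and ``1``) and the
    optimizer's repeated interval reweighting.
    """
    A = np.eye(model.n_states) - model.Q
    try:
        lu = lu_factor(A)
    except Exception as exc:  # pragma: no cover - scipy raises LinAlgError
        raise ConditioningError("I - Q could not be factorized") from exc
    diag = np.abs(lu[0].diagonal())
    if diag.min() <= 1e-14 * max(diag.max(), 1.0):
        raise ConditioningError(
            "I - Q is numerically singular; the chart signals too rarely at "
            "this resolution for a stable absorption-time solve"
        )
    visits = lu_solve(lu, model.b, trans=1)
    return visits, lu


def expected_visits(model: TransitionModel) -> np.ndarray:
    """Expected number of pre-signal visits to each state from the start."""
    visits, _ = _fundamental_solve(model)
    return visits


def conditional_ats(model: TransitionModel) -> PerformanceSummary:
    """CATS, CARL and CASI by absorption analysis of the transient chain."""
    visits = expected_visits(model)
    carl = float(visits.sum())
    cats = float(visits @ model.h)
    if carl <= 0.0 or not math.isfinite(carl):
        raise ConditioningError("absorption-time solve produced a "
                                f"non-finite run length ({carl!r})")
    return PerformanceSummary(
        cats=cats, carl=carl, casi=cats / carl,
        s=0 if model.delta == 1.0 else 1,
        delta=model.delta, gamma=model.gamma,
    )


def interval_fraction_casi(
    visits: np.ndarray, cr_overlap: np.ndarray, h1: float, h2: float
) -> float:
    """CASI with states weighted by their fractional overlap with the CR.

    The midpoint zone assignment makes CASI piecewise constant in ``W`` (a
    state flips from long to short interval only when a warning limit crosses
    its midpoint).  Weighting each state's interval by the fraction of its
    subinterval inside the central region yields the same continuum limit but
    varies continuously in ``W``, which makes the average-interval design
    constraint root-solvable.  Used only by the constraint solver.
    """
    h_eff = h2 + (h1 - h2) * cr_overlap
    return float(visits @ h_eff / visits.sum())
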