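"""Distributional groundwork for EWMA monitoring of exponential inter-event times.

An exponential waiting time :math:`X \\sim \\mathrm{Exp}(\\eta)` raised to the
power :math:`1/3.6` is approximately symmetric: :math:`Y = X^{1/3.6}` follows a
Weibull distribution with shape 3.6 and scale :math:`\\eta^{1/3.6}`, whose
skewness is nearly zero.  Monitoring the transformed observations therefore
permits a classical two-sided EWMA chart with symmetric control limits.

This module holds the transform, the Weibull moments that center and scale the
chart, and the control/warning-limit formulas in both normalized
(:math:`\\hat\\eta_0`-free) and absolute form.  Everything downstream (the
Markov chain, the design optimizer, the monitoring runtime) works on the
normalized scale and multiplies by :math:`\\hat\\eta_0^{1/3.6}` only at the
data boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma_fn

from .errors import DomainError, InvalidDesignError

#: Weibull shape of the transformed observation.  The 1/3.6 power is the
#: classical symmetrizing transform for exponential data and is treated as a
#: fixed constant of the method, not a tunable parameter.
WEIBULL_SHAPE: float = 3.6

#: Exponent applied to raw waiting times.
TRANSFORM_POWER: float = 1.0 / WEIBULL_SHAPE

#: In-control mean of the transformed observation at unit scale,
#: :math:`\mu_0 = \Gamma(1 + 1/3.6)`.
MU0: float = float(_gamma_fn(1.0 + TRANSFORM_POWER))

#: In-control standard deviation of the transformed observation at unit scale,
#: :math:`\sigma_0 = \sqrt{\Gamma(1 + 2/3.6) - \Gamma^2(1 + 1/3.6)}`.
SIGMA0: float = float(
    math.sqrt(_gamma_fn(1.0 + 2.0 * TRANSFORM_POWER) - MU0**2)
)


def transform_observation(x):
    """Symmetrizing power transform ``y = x ** (1/3.6)``.

    Parameters
    ----------
    x : float or array_like
        Positive waiting time(s).

    Returns
    -------
    float or ndarray
        The transformed observation(s); strictly increasing in ``x``.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0.0) or not np.all(np.isfinite(arr)):
        raise DomainError("observations must be positive finite reals")
    out = arr**TRANSFORM_POWER
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def weibull_mean_sd(eta_hat: float) -> tuple[float, float]:
    """Mean and standard deviation of the transformed observation.

    For ``X ~ Exp(eta_hat)``, ``Y = X**(1/3.6)`` is Weibull with scale
    ``eta_hat**(1/3.6)`` and shape 3.6, so both moments scale with
    ``eta_hat**(1/3.6)``.
    """
    if not (eta_hat > 0.0 and math.isfinite(eta_hat)):
        raise DomainError(f"eta_hat must be positive, got {eta_hat!r}")
    s = eta_hat**TRANSFORM_POWER
    return s * MU0, s * SIGMA0


@dataclass(frozen=True)
class ProcessModel:
    """Exponential process with an in-control scale and a shift ratio.

    Attributes
    ----------
    eta0 : float
        In-control exponential scale (mean waiting time).
    delta : float
        Shift magnitude ``eta1 / eta0``; 1 is in-control, below 1 a downward
        shift (events arriving faster), above 1 an upward shift.
    """

    eta0: float
    delta: float = 1.0

    def __post_init__(self):
        if not (self.eta0 > 0.0 and math.isfinite(self.eta0)):
            raise DomainError(f"eta0 must be positive, got {self.eta0!r}")
        if not (self.delta > 0.0 and math.isfinite(self.delta)):
            raise DomainError(f"delta must be positive, got {self.delta!r}")

    @property
    def eta1(self) -> float:
        """Out-of-control scale ``delta * eta0``."""
        return self.delta * self.eta0

    @property
    def in_control(self) -> bool:
        return self.delta == 1.0


@dataclass(frozen=True)
class NormalizedLimits:
    """Asymptotic control and warning limits on the unit-scale (eta-free) axis.

    The absolute limits are these values times ``eta_hat**(1/3.6)``.  The
    action band is ``[lcl, ucl]``, the central region ``[lwl, uwl]``; both are
    symmetric about ``mu0``.
    """

    lcl: float
    ucl: float
    lwl: float
    uwl: float
    mu0: float = MU0
    sigma0: float = SIGMA0

    @property
    def half_width(self) -> float:
        return 0.5 * (self.ucl - self.lcl)

    def scaled(self, eta_hat: float) -> "NormalizedLimits":
        """Absolute limits for an estimated in-control scale."""
        s = eta_hat**TRANSFORM_POWER
        return NormalizedLimits(
            lcl=s * self.lcl, ucl=s * self.ucl,
            lwl=s * self.lwl, uwl=s * self.uwl,
            mu0=s * self.mu0, sigma0=s * self.sigma0,
        )


def ewma_sd_factor(lam: float) -> float:
    """Asymptotic EWMA standard-deviation factor ``sqrt(lam / (2 - lam))``."""
    return math.sqrt(lam / (2.0 - lam))


def normalized_limits(lam: float, K: float, W: float) -> NormalizedLimits:
    """Asymptotic normalized limits for smoothing ``lam`` and widths ``K, W``.

    ``lcl/ucl = mu0 -/+ K * sqrt(lam/(2-lam)) * sigma0`` and likewise for the
    warning pair with ``W``.  Requires ``0 < lam <= 1`` and ``0 <= W < K``
    (``W == K`` collapses the warning band and is accepted for the degenerate
    fixed-interval case).
    """
    _validate_lam(lam)
    if not (K > 0.0 and math.isfinite(K)):
        raise InvalidDesignError(f"K must be positive, got {K!r}")
    if not (0.0 <= W <= K):
        raise InvalidDesignError(f"need 0 <= W <= K, got W={W!r}, K={K!r}")
    hw = ewma_sd_factor(lam) * SIGMA0
    return NormalizedLimits(
        lcl=MU0 - K * hw, ucl=MU0 + K * hw,
        lwl=MU0 - W * hw, uwl=MU0 + W * hw,
    )


def time_varying_limits(i, lam: float, K: float, W: float, eta_hat: float = 1.0):
    """Exact early-sample limits with the ``1 - (1-lam)**(2i)`` variance factor.

    These widen monotonically with the sample index ``i`` and converge to the
    asymptotic limits; they are intended for retrospective plotting.  Returns
    ``(LCL_i, UCL_i, LWL_i, UWL_i)`` as floats or arrays matching ``i``.
    """
    _validate_lam(lam)
    idx = np.asarray(i)
    if np.any(idx < 1) or not np.issubdtype(idx.dtype, np.number):
        raise DomainError("sample index i must be >= 1")
    if not (eta_hat > 0.0):
        raise DomainError("eta_hat must be positive")
    mu, sigma = weibull_mean_sd(eta_hat)
    f = ewma_sd_factor(lam) * np.sqrt(1.0 - (1.0 - lam) ** (2.0 * idx))
    return (mu - K * f * sigma, mu + K * f * sigma,
            mu - W * f * sigma, mu + W * f * sigma)


def _validate_lam(lam: float) -> None:
    if not (0.0 < lam <= 1.0):
        raise InvalidDesignError(f"lam must lie in (0, 1], got {lam!r}")


@dataclass(frozen=True)
class ChartDesign:
    """Complete VSI EWMA chart design.

    Attributes
    ----------
    lam : float
        EWMA smoothing parameter in (0, 1]; 1 recovers a Shewhart chart.
    K, W : float
        Action- and warning-limit half-widths in asymptotic EWMA standard
        deviations, ``0 <= W <= K``.
    h1, h2 : float
        Long and short sampling intervals (time units).  A fixed-interval
        chart has ``h1 == h2``.
    h0 : float
        Nominal in-control average sampling interval the design is
        calibrated to.
    tau : float
        Target in-control average time to signal.
    """

    lam: float
    K: float
    W: float
    h1: float = 1.0
    h2: float = 1.0
    h0: float = 1.0
    tau: float = 370.4
    limits: NormalizedLimits = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        _validate_lam(self.lam)
        if self.h1 < self.h2 or self.h2 <= 0.0:
            raise InvalidDesignError(
                f"need 0 < h2 <= h1, got h1={self.h1!r}, h2={self.h2!r}"
            )
        if self.h1 != self.h2 and not (self.h2 < self.h0 < self.h1):
            raise InvalidDesignError(
                "variable-interval design requires h2 < h0 < h1"
            )
        if self.tau <= 0.0 or self.h0 <= 0.0:
            raise InvalidDesignError("tau and h0 must be positive")
        object.__setattr__(
            self, "limits", normalized_limits(self.lam, self.K, self.W)
        )

    @property
    def is_fsi(self) -> bool:
        """True for the degenerate fixed-sampling-interval design."""
        return self.h1 == self.h2

    def as_fsi(self) -> "ChartDesign":
        """Companion design with both intervals pinned at ``h0``."""
        return ChartDesign(lam=self.lam, K=self.K, W=self.W,
                           h1=self.h0, h2=self.h0, h0=self.h0, tau=self.tau)
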