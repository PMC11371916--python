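"""Operational chart execution: Phase I estimation and Phase II monitoring.

Phase I estimates the in-control scale as the mean of the retrospective
waiting times.  Phase II transforms each incoming waiting time, updates the
EWMA statistic, classifies it against the absolute limits (normalized limits
scaled by ``eta_hat**(1/3.6)``), raises an alarm in the action region, and
picks the next sampling interval from the current zone: the long interval
after a central point, the short interval after a warning point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    MU0,
    TRANSFORM_POWER,
    ChartDesign,
    time_varying_limits,
    transform_observation,
)
from .errors import DataError, DomainError, InsufficientDataError
from .markov import AR, CR, WR, zone_of


def estimate_eta0(phase1) -> float:
    """Phase I estimate of the in-control scale: the sample mean."""
    arr = np.asarray(phase1, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("Phase I sample is empty")
    if np.any(arr <= 0.0) or not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~(arr > 0.0) | ~np.isfinite(arr))[0])
        raise DataError(f"nonpositive or non-finite waiting time at index {bad}")
    return float(arr.mean())


@dataclass(frozen=True)
class MonitoringRecord:
    """One plotted point of a monitoring session."""

    i: int
    x: float
    y: float
    z: float
    zone: str
    interval_used: float
    clock: float


@dataclass
class MonitoringSession:
    """Result of running the chart over an observation stream."""

    eta_hat: float
    design: ChartDesign
    z0: float
    mode: str
    records: list[MonitoringRecord] = field(default_factory=list)

    @property
    def alarms(self) -> list[int]:
        """Sample indices classified in the action region."""
        return [r.i for r in self.records if r.zone == AR]

    @property
    def scale_factor(self) -> float:
        return self.eta_hat**TRANSFORM_POWER

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def alarm_summary(self) -> dict:
        return {
            "eta_hat": self.eta_hat,
            "n_samples": len(self.records),
            "n_alarms": len(self.alarms),
            "alarm_indices": self.alarms,
            "total_time": self.records[-1].clock if self.records else 0.0,
        }

    def summary(self) -> str:
        d = self.design
        lim = d.limits.scaled(self.eta_hat)
        lines = [
            "VSI EWMA monitoring session",
            f"  eta_hat = {self.eta_hat:.6f}   z0 = {self.z0:.6f}",
            f"  design: lam={d.lam:g} K={d.K:.4f} W={d.W:.4f} "
            f"(h1, h2)=({d.h1:g}, {d.h2:g})",
            f"  limits: LCL={lim.lcl:.4f} LWL={lim.lwl:.4f} "
            f"UWL={lim.uwl:.4f} UCL={lim.ucl:.4f}",
            f"  samples: {len(self.records)}   alarms: {len(self.alarms)} "
            f"{self.alarms if self.alarms else ''}",
        ]
        return "\n".join(lines)

    def save(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.alarm_summary(), fh, indent=2)


def run_chart(
    observations,
    design: ChartDesign,
    eta_hat: float,
    z0: float | None = None,
    mode: str = "continue",
    time_varying: bool = False,
) -> MonitoringSession:
    """Run the chart over a waiting-time stream.

    Parameters
    ----------
    observations : sequence of float
        Positive waiting times, in arrival order.
    design : ChartDesign
        Calibrated chart parameters.
    eta_hat : float
        Phase I scale estimate fixing the absolute limits.
    z0 : float, optional
        Start value on the absolute (data) scale; defaults to the in-control
        mean of the transformed observation.
    mode : {"continue", "halt"}
        ``"halt"`` stops at the first alarm (prospective use);
        ``"continue"`` keeps scoring every point (retrospective charts).
    time_varying : bool
        Classify early points against the exact time-varying limits instead
        of their asymptotic values (diagnostic displays).
    """
    if mode not in ("continue", "halt"):
        raise DomainError(f"mode must be 'continue' or 'halt', got {mode!r}")
    if not (eta_hat > 0.0 and math.isfinite(eta_hat)):
        raise DomainError("eta_hat must be positive")
    sf = eta_hat**TRANSFORM_POWER
    z_abs = MU0 * sf if z0 is None else float(z0)
    session = MonitoringSession(eta_hat=eta_hat, design=design,
                                z0=z_abs, mode=mode)
    clock = 0.0
    interval = design.h1          # first draw always waits the long interval
    for i, x in enumerate(observations, start=1):
        if not (x > 0.0 and math.isfinite(x)):
            raise DataError(f"nonpositive waiting time at sample {i}: {x!r}")
        y = transform_observation(float(x))
        z_abs = design.lam * y + (1.0 - design.lam) * z_abs
        if time_varying:
            lcl, ucl, lwl, uwl = time_varying_limits(
                i, design.lam, design.K, design.W, eta_hat)
            if lwl <= z_abs <= uwl:
                zone = CR
            elif lcl <= z_abs <= ucl:
                zone = WR
            else:
                zone = AR
        else:
            zone = zone_of(z_abs / sf, design.limits)
        clock += interval
        session.records.append(MonitoringRecord(
            i=i, x=float(x), y=y, z=z_abs, zone=zone,
            interval_used=interval, clock=clock))
        if zone == AR:
            if mode == "halt":
                break
            interval = design.h2  # treat like a warning point and carry on
        else:
            interval = design.h1 if zone == CR else design.h2
    return session


def read_observations(path, phase: str | None = None) -> np.ndarray:
    """Read a waiting-time CSV: one observation per row, header row, optional
    ``phase`` column ("I"/"II") for combined files."""
    df = pd.read_csv(path)
    if phase is not None:
        if "phase" not in df.columns:
            raise DataError("no 'phase' column in combined input file")
        df = df[df["phase"] == phase]
    value_col = next(
        (c for c in df.columns if c.lower() in
         ("days", "value", "x", "observation", "tbe")),
        None,
    )
    if value_col is None:
        numeric = df.select_dtypes("number").columns
        drop = [c for c in numeric if c.lower() in ("index", "i")]
        candidates = [c for c in numeric if c not in drop]
        if not candidates:
            raise DataError("no numeric observation column found")
        value_col = candidates[0]
    return df[value_col].to_numpy(dtype=float)
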