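"""Minimal chart rendering for monitoring sessions."""

from __future__ import annotations

import numpy as np

from .core import time_varying_limits
from .markov import AR, WR


def plot_session(session, ax=None, time_varying: bool = False):
    """Plot the EWMA trajectory with action and warning limits.

    Returns the matplotlib axes.  Alarm points are highlighted; warning-zone
    points use an open marker.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    df = session.to_frame()
    d = session.design
    ax.plot(df["i"], df["z"], "-", color="0.4", lw=1)
    for zone, style in ((AR, dict(marker="s", color="crimson")),
                        (WR, dict(marker="o", mfc="white", color="darkorange"))):
        sub = df[df["zone"] == zone]
        ax.plot(sub["i"], sub["z"], ls="", **style)
    rest = df[~df["zone"].isin((AR, WR))]
    ax.plot(rest["i"], rest["z"], "o", color="steelblue", ms=4)

    idx = np.arange(1, len(df) + 1)
    if time_varying:
        lcl, ucl, lwl, uwl = time_varying_limits(
            idx, d.lam, d.K, d.W, session.eta_hat)
    else:
        lim = d.limits.scaled(session.eta_hat)
        lcl, ucl, lwl, uwl = (np.full(len(idx), v) for v in
                              (lim.lcl, lim.ucl, lim.lwl, lim.uwl))
    ax.plot(idx, lcl, "k-", idx, ucl, "k-", lw=1.2)
    ax.plot(idx, lwl, "k--", idx, uwl, "k--", lw=0.8)
    ax.set_xlabel("sample")
    ax.set_ylabel("EWMA of transformed waiting time")
    return ax
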