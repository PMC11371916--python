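"""Bundled example data.

The urinary-tract-infection (UTI) surveillance set records the days between
discharges of male patients with hospital-acquired UTIs: 54 retrospective
(Phase I) and 20 prospective (Phase II) waiting times.  The Phase I sample is
consistent with an exponential law and serves to estimate the in-control
scale; the Phase II stream is monitored for a change in the infection rate.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

def load_uti() -> pd.DataFrame:
    """UTI waiting times with columns ``phase`` ("I"/"II"), ``index``,
    ``days``."""
    path = resources.files("vsiewma").joinpath("data/uti_tbe.csv")
    with path.open() as fh:
        return pd.read_csv(fh)


def uti_phases() -> tuple[pd.Series, pd.Series]:
    """Phase I and Phase II waiting-time series."""
    df = load_uti()
    return (df.loc[df["phase"] == "I", "days"].reset_index(drop=True),
            df.loc[df["phase"] == "II", "days"].reset_index(drop=True))
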