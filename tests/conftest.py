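"""Shared fixtures.

The printed reference design (lam=0.09, K=2.6426, W=0.6519, h=(2.0, 0.1))
is the published optimum for detecting a halving of the event rate with a
known in-control scale; several tests evaluate the chain at exactly these
parameters.
"""

import math

import pytest

from vsiewma import ChartDesign, build_transition_model, conditional_ats


@pytest.fixture(scope="session")
def ref_design():
    """Published known-parameter design optimized for delta = 0.5."""
    return ChartDesign(lam=0.09, K=2.6426, W=0.6519, h1=2.0, h2=0.1)


@pytest.fixture(scope="session")
def ref_model_ic(ref_design):
    """In-control chain (delta = 1, known parameter) at N = 100."""
    return build_transition_model(ref_design, delta=1.0, N=100)


@pytest.fixture(scope="session")
def ref_perf_ic(ref_model_ic):
    return conditional_ats(ref_model_ic)
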