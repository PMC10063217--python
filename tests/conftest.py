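"""Shared fixtures.

The reference steady-beat simulation (the headline parameter set
(S, rho, M, kappa_c) = (18, 36.4, 900, 1.5) at N = 40) is expensive, so it
is computed once per session and shared by the waveform, conservation and
regime tests.  Coarser companion runs use reduced resolution; the methods
note documents the problem sizes.
"""

from __future__ import annotations

import numpy as np
import pytest

from archswim.params import DimensionlessParameters
from archswim.assembly import run_to_steady_beat, _Discretization


REF = dict(S=18.0, rho=36.4, M=900.0, kappa_c=1.5)


@pytest.fixture(scope="session")
def ref_params() -> DimensionlessParameters:
    return DimensionlessParameters(**REF, N=40, max_time=150.0,
                                   reporting_cadence=50.0)


@pytest.fixture(scope="session")
def ref_run(ref_params):
    """Reference steady beat: (record, status, period)."""
    return run_to_steady_beat(ref_params)


@pytest.fixture(scope="session")
def coarse_params() -> DimensionlessParameters:
    """Reduced-resolution settings for cheap dynamic tests."""
    return DimensionlessParameters(**REF, N=16, head_Q=8, head_refinement=2,
                                   max_time=120.0, reporting_cadence=25.0)


@pytest.fixture(scope="session")
def coarse_run(coarse_params):
    return run_to_steady_beat(coarse_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
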