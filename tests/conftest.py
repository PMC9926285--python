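"""Shared fixtures.

The regulon sweeps are by far the most expensive computations in the
suite, so they are run once per session and shared between the regulon
unit tests and the acceptance tests.
"""

from dataclasses import replace

import pytest

from phostat.regulon import (
    DEFAULT_SOUT_GRID,
    bistable_window,
    default_params,
    sweep,
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def no_spl2_params(params):
    """Spl2 inhibition disabled (K_S -> inf): low-affinity always active."""
    return replace(params, K_S=float("inf"))


@pytest.fixture(scope="session")
def default_sweeps(params):
    return {
        "down": sweep(params, DEFAULT_SOUT_GRID, "down_from_rich"),
        "up": sweep(params, DEFAULT_SOUT_GRID, "up_from_starved"),
    }


@pytest.fixture(scope="session")
def no_spl2_sweeps(no_spl2_params):
    return {
        "down": sweep(no_spl2_params, DEFAULT_SOUT_GRID, "down_from_rich"),
        "up": sweep(no_spl2_params, DEFAULT_SOUT_GRID, "up_from_starved"),
    }


@pytest.fixture(scope="session")
def default_bistable(params):
    return bistable_window(params, DEFAULT_SOUT_GRID)


@pytest.fixture(scope="session")
def no_spl2_bistable(no_spl2_params):
    return bistable_window(no_spl2_params, DEFAULT_SOUT_GRID)
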