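"""Shared fixtures.

Expensive simulation products (equilibria, reference points, effort sweeps)
are session-scoped and built lazily so their cost is paid once and only by
the tests that need them.  Fixture numerics trade a little tolerance for
speed (tol 1e-4/yr, t_max 300 yr); properties asserted on them are either
exact identities or hold with wide margins.
"""

from __future__ import annotations

import numpy as np
import pytest

from mnyield.refpoints import estimate_all_fmsy, sweep_effort
from mnyield.synthetic import (
    CommunitySpec,
    make_generic_community,
    make_nutrient_loading_fixture,
)

# numerics used by all heavy fixtures
FAST_EQ = {"tol": 1e-4, "t_max": 300.0}

EFFORT_GRID = np.arange(0.0, 4.0001, 0.05)


@pytest.fixture(scope="session")
def bundle3():
    """Small 3-species interacting community."""
    return make_generic_community(
        CommunitySpec(n_species=3, w_inf_range=(50.0, 2.0e4), seed=1)
    )


@pytest.fixture(scope="session")
def model3(bundle3):
    return bundle3.model(n_bins=60)


@pytest.fixture(scope="session")
def state3(model3):
    state, report = model3.project_to_equilibrium(**FAST_EQ)
    assert report.converged
    return state


@pytest.fixture(scope="session")
def refpoints3(model3):
    """Golden-section reference points for the 3-species fixture."""
    return estimate_all_fmsy(model3, max_rounds=3, **FAST_EQ)


@pytest.fixture(scope="session")
def bundle1():
    """Single-species community (usable by every downstream stage)."""
    return make_generic_community(
        CommunitySpec(n_species=1, w_inf_range=(100.0, 1.0e3), seed=2)
    )


@pytest.fixture(scope="session")
def model1(bundle1):
    return bundle1.model(n_bins=50)


@pytest.fixture(scope="session")
def bundle15():
    """The generic 15-species community with default trait spacing."""
    return make_generic_community(CommunitySpec(n_species=15, seed=0))


@pytest.fixture(scope="session")
def model15(bundle15):
    return bundle15.model(n_bins=80)


@pytest.fixture(scope="session")
def refpoints15(model15):
    return estimate_all_fmsy(
        model15, max_rounds=1, damping=1.0, rel_tol=0.02, **FAST_EQ
    )


@pytest.fixture(scope="session")
def loading_community():
    """The forage+piscivore loading community with its sweep, shared by both
    loading directions (the catches do not depend on the nutrient profiles)."""
    resilient = make_nutrient_loading_fixture("resilient", seed=0)
    vulnerable = make_nutrient_loading_fixture("vulnerable", seed=0)
    model = resilient.bundle.model(n_bins=80)
    # default (tight) equilibrium numerics: the directional signal rides on
    # the shape of the curve near the community optimum
    refpoints = estimate_all_fmsy(model, max_rounds=3)
    curve = sweep_effort(
        model, refpoints, EFFORT_GRID, resilient.bundle.profiles
    )
    return {
        "resilient": resilient,
        "vulnerable": vulnerable,
        "model": model,
        "refpoints": refpoints,
        "curve": curve,
    }
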