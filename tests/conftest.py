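"""Shared fixtures: models and cached 0D pre-paced states.

Pacing a model to quasi-steady state (100 beats at 1 Hz) is the common
prerequisite of most cellular and all tissue tests, so paced traces are
cached per (model, scaling) for the whole session.
"""

from __future__ import annotations

import numpy as np
import pytest

from atrialsim import (ConductanceScaling, courtemanche_model, grandi_model,
                       surrogate_model)
from atrialsim.protocols0d import PacingProtocol, measure_biomarkers, pace


@pytest.fixture(scope="session")
def crn():
    return courtemanche_model()


@pytest.fixture(scope="session")
def gpv():
    return grandi_model()


@pytest.fixture(scope="session")
def surrogate():
    return surrogate_model(200.0)


@pytest.fixture(scope="session")
def protocol():
    return PacingProtocol()


@pytest.fixture(scope="session")
def paced_cache(protocol):
    """pace-to-steady-state results shared across the session."""
    cache: dict = {}

    def _get(model, scaling=None, **proto_kwargs):
        key = (model.name, repr(scaling) if scaling else "id",
               tuple(sorted(proto_kwargs.items())))
        if key not in cache:
            prot = protocol if not proto_kwargs else \
                PacingProtocol(**proto_kwargs)
            cache[key] = pace(model, scaling, prot)
        return cache[key]

    return _get


@pytest.fixture(scope="session")
def crn_steady(crn, paced_cache):
    """Baseline Courtemanche trace after 100 beats at 1 Hz."""
    return paced_cache(crn)


@pytest.fixture(scope="session")
def gpv_steady(gpv, paced_cache):
    """Baseline Grandi trace after 100 beats at 1 Hz."""
    return paced_cache(gpv)


@pytest.fixture(scope="session")
def crn_biomarkers(crn_steady):
    return measure_biomarkers(crn_steady)


@pytest.fixture(scope="session")
def gpv_biomarkers(gpv_steady):
    return measure_biomarkers(gpv_steady)


@pytest.fixture(scope="session")
def cv_calibration(crn, crn_steady):
    """Diffusion coefficient calibrated to the 45-50 cm/s band on the
    200 x 15 Courtemanche strip (shared: several tests reuse D)."""
    from atrialsim.tissue import calibrate_cv

    return calibrate_cv(crn, None, (45.0, 50.0),
                        initial_state=crn_steady.final_state)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def ito_half():
    return ConductanceScaling({"Ito": 0.5})
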