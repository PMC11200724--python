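"""Shared fixtures.

Scenario runs are expensive (a limit cycle of the coupled model), so each
scenario is run once per session with the packaged calibrated
configuration and shared across simulator, metrics and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardioloop.constitutive import (ActiveMaterialParams,
                                     PassiveMaterialParams)
from cardioloop.geometry import LVGeometryConfig, build_idealized_lv


@pytest.fixture(scope="session")
def ventricle_passive():
    return PassiveMaterialParams.ventricle()


@pytest.fixture(scope="session")
def ventricle_active():
    return ActiveMaterialParams.ventricle()


@pytest.fixture(scope="session")
def mesh():
    return build_idealized_lv(LVGeometryConfig(seed=7))


@pytest.fixture(scope="session")
def default_config():
    from cardioloop.config import default_config

    return default_config()


def _run(name, config):
    from cardioloop.simulator import HeartModel, ScenarioConfig

    model = HeartModel(config, ScenarioConfig.preset(name))
    return model.run_to_limit_cycle()


@pytest.fixture(scope="session")
def baseline_result(default_config):
    return _run("baseline", default_config)


@pytest.fixture(scope="session")
def stiff_result(default_config):
    return _run("stiff_aa", default_config)


@pytest.fixture(scope="session")
def inotropy_result(default_config):
    return _run("stiff_aa_inotropy", default_config)


@pytest.fixture(scope="session")
def baseline_bundle(baseline_result):
    from cardioloop.metrics import bundle_from_result

    return bundle_from_result(baseline_result)


@pytest.fixture(scope="session")
def stiff_bundle(stiff_result):
    from cardioloop.metrics import bundle_from_result

    return bundle_from_result(stiff_result)


@pytest.fixture(scope="session")
def inotropy_bundle(inotropy_result):
    from cardioloop.metrics import bundle_from_result

    return bundle_from_result(inotropy_result)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240612)
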