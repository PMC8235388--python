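"""Shared fixtures: worlds are generated once per session where possible."""

import numpy as np
import pytest

from nutrisk import cge_core as cg
from nutrisk import sam_calibration as sc
from nutrisk import synthetic_world as sw


@pytest.fixture(scope="session")
def default_spec():
    return sw.WorldSpec(seed=3)


@pytest.fixture(scope="session")
def default_sam(default_spec):
    return sw.generate_sam(default_spec)


@pytest.fixture(scope="session")
def default_params(default_spec, default_sam):
    return sc.calibrate(default_sam, sc.Elasticities.from_spec(default_spec))


@pytest.fixture(scope="session")
def toy_spec():
    return sw.toy_trade_world(seed=1)


@pytest.fixture(scope="session")
def toy_params(toy_spec):
    sam = sw.generate_sam(toy_spec)
    return sc.calibrate(sam, sc.Elasticities.from_spec(toy_spec))


@pytest.fixture(scope="session")
def toy_benchmark(toy_params):
    return cg.solve(cg.build_system(toy_params, cg.ShockVector.ones(3)))


@pytest.fixture(scope="session")
def symmetric_spec():
    return sw.WorldSpec(regions=("east", "west"), heterogeneity=0.0, seed=11)


@pytest.fixture(scope="session")
def symmetric_params(symmetric_spec):
    sam = sw.generate_sam(symmetric_spec)
    return sc.calibrate(sam, sc.Elasticities.from_spec(symmetric_spec))
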