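import dataclasses

import pytest

import cabpbpk as cp
from cabpbpk.params import load_default_formulations


@pytest.fixture(scope="session")
def default_config():
    """Packaged cabozantinib defaults: (drug, physiology, ehc, regimen)."""
    return cp.load_default_config()


@pytest.fixture(scope="session")
def drug(default_config):
    return default_config[0]


@pytest.fixture(scope="session")
def physiology(default_config):
    return default_config[1]


@pytest.fixture(scope="session")
def ehc_params(default_config):
    return default_config[2]


@pytest.fixture(scope="session")
def regimen(default_config):
    return default_config[3]


@pytest.fixture(scope="session")
def formulations():
    return load_default_formulations()


@pytest.fixture(scope="session")
def fast_options():
    """Loose-but-accurate solver settings for multi-scenario tests."""
    return cp.SimulationOptions(rtol=1e-7, atol=1e-10)


@pytest.fixture(scope="session")
def base_system(drug, physiology, ehc_params, fast_options):
    return cp.PBPKSystem(drug, physiology, ehc_params, fast_options)


@pytest.fixture(scope="session")
def tablet_140_result(base_system, regimen):
    """Shared default simulation: 140 mg tablet, 96 h."""
    return base_system.simulate(regimen, 96.0)


def make_regimen(regimen, formulations, dose, kind, **kw):
    return dataclasses.replace(regimen, dose=dose,
                               formulation=formulations[kind], **kw)
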