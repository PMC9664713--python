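import dataclasses

import pytest

from adhereval import SimulationConfig, build_panel, simulate_cohort

#: every measurement-error mechanism switched off: each channel then reads
#: the underlying intake stream exactly
NOISE_FREE = dict(
    sr_zero_report_prob=0.0,
    sr_underreport_factor=1.0,
    pr_unknown_leftover_prob=0.0,
    pr_surplus_prob=0.0,
    rtmm_outage_day_prob=0.0,
    rtmm_pocket_dose_prob=0.0,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=20260924)


@pytest.fixture(scope="session")
def noise_free_config():
    return SimulationConfig(seed=11, **NOISE_FREE)


@pytest.fixture(scope="session")
def cohort(default_config):
    return simulate_cohort(default_config)


@pytest.fixture(scope="session")
def panel(cohort):
    return build_panel(cohort)


def config_with(base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    return dataclasses.replace(base or SimulationConfig(), **overrides)
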