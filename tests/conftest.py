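"""Shared fixtures: one small synthetic cohort reused across module tests."""

import pytest

from metharray import preprocess as pp
from metharray import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.SimulationConfig(
        seed=11,
        n_probes=4000,
        n_samples_per_group={"d0_PTC": 4, "LT_PTC": 4, "SE": 3, "control": 4},
        planted_dmrs=(syn.PlantedDMR("2", 100_000, 110_000, 6, -3.0, group="LT_PTC"),),
        planted_cnvs=(syn.PlantedCNV("SE", "12", 1, 600_000, 3),),
    )


@pytest.fixture(scope="session")
def small_manifest(small_config):
    return syn.generate_manifest(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_manifest):
    raw, truth = syn.generate_cohort(small_config, small_manifest)
    return raw, truth


@pytest.fixture(scope="session")
def small_meth(small_cohort, small_manifest):
    raw, _ = small_cohort
    meth, report = pp.preprocess_pipeline(raw, small_manifest)
    return meth, report
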