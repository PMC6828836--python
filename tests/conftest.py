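import numpy as np
import pytest

from peathaze import (
    DispersionParams,
    Grid,
    PipelineConfig,
    SyntheticScenario,
    generate_scenario,
    run_all,
)


@pytest.fixture(scope="session")
def tiny_scenario():
    """One fire year, 30 deep + 30 shallow hotspots, 12 villages."""
    return SyntheticScenario(
        seed=11,
        years=(2015,),
        hotspot_counts_per_year={2015: (30, 30)},
        region_extent=(60.0, 40.0),
        n_villages=12,
        total_population=60_000,
        station_location=(25.0, 30.0),
        station_annual_means={2015: 65.0},
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_scenario):
    return generate_scenario(tiny_scenario)


@pytest.fixture(scope="session")
def small_result():
    """A full, fast end-to-end run shared across tests."""
    return run_all(PipelineConfig.small(seed=1))


@pytest.fixture
def plume_grid():
    return Grid.centered(30.0)


@pytest.fixture
def calm_params():
    """Small puff count / fine sampling for kernel-level checks."""
    return DispersionParams(n_puffs=4, dt_sample_h=0.5)


@pytest.fixture(autouse=True)
def _quiet_af_warnings():
    """AF > 1 warnings are expected on extreme synthetic exposures."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*attributable fraction exceeds 1.*"
        )
        yield
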