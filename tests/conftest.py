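import numpy as np
import pytest

from phagerange import (
    ExperimentConfig,
    WellCoordinate,
    WellSeries,
    analyze,
    preset_panel,
    simulate_plate,
)


def make_series(readings, interval_h=0.5, well="A1"):
    readings = np.asarray(readings, dtype=float)
    times = np.arange(readings.size) * interval_h
    return WellSeries(WellCoordinate.parse(well), times, readings)


@pytest.fixture
def config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def salmonella_panel():
    return preset_panel("salmonella")


@pytest.fixture(scope="session")
def clean_plate(salmonella_panel):
    """Noise-free simulated plate with its ground truth."""
    layout, cfg = salmonella_panel
    series, truth = simulate_plate(layout, cfg, noise_sd=0.0, seed=11)
    return layout, cfg, series, truth


@pytest.fixture(scope="session")
def clean_analysis(clean_plate):
    layout, cfg, series, _truth = clean_plate
    return analyze(series, layout, cfg)
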