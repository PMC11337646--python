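from datetime import date

import numpy as np
import pytest

from canopycalib import PlotState, render_scene, synthetic_weather


@pytest.fixture(scope="session")
def weather():
    return synthetic_weather(date(2021, 5, 15), 200, seed=11)


@pytest.fixture(scope="session")
def mixed_scene():
    """Half-grown canopy: a genuine soil/plant mixture."""
    state = PlotState("plot-a", date(2021, 8, 15), mean_height=0.6,
                      green_fraction=0.5, senescence=0.0)
    return render_scene(state, gsd=1 / 64, seed=21)


@pytest.fixture(scope="session")
def bare_scene():
    state = PlotState("plot-b", date(2021, 5, 20), mean_height=0.0,
                      green_fraction=0.0, senescence=0.0)
    return render_scene(state, gsd=1 / 64, seed=22)


@pytest.fixture(scope="session")
def full_canopy_scene():
    """Closed canopy, zero sensor noise: every raster is spatially constant."""
    state = PlotState("plot-c", date(2021, 9, 10), mean_height=0.8,
                      green_fraction=1.0, senescence=0.0)
    return render_scene(state, gsd=1 / 64, seed=23,
                        height_noise_sd=0.0, reflectance_noise_cv=0.0)
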