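import numpy as np
import pandas as pd
import pytest

from tundratrack.raster import Raster
from tundratrack import synthetic as syn


@pytest.fixture(scope="session")
def small_landscape():
    """A 20 x 20 km landscape at 100-m cells, shared across tests."""
    return syn.make_landscape(42, extent_m=(20_000.0, 20_000.0),
                              cell_size=100.0)


@pytest.fixture(scope="session")
def terrain_stack(small_landscape):
    from tundratrack.terrain import build_terrain_stack
    return build_terrain_stack(small_landscape)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def flat_raster():
    return Raster(np.full((12, 10), 7.0), origin_x=0.0, origin_y=1200.0,
                  cell_size=100.0)


def make_track(points_km, start="2019-06-15 12:00", freq="D",
               individual_id="h1", argos_class="3"):
    """Telemetry frame from a list of (x_km, y_km) positions."""
    pts = np.asarray(points_km, dtype=float) * 1000.0
    ts = pd.date_range(start, periods=len(pts), freq=freq)
    return pd.DataFrame({
        "individual_id": individual_id,
        "timestamp": ts,
        "x": pts[:, 0],
        "y": pts[:, 1],
        "argos_class": argos_class,
        "error_radius": syn.ARGOS_ERROR_RADII[str(argos_class)],
        "interpolated": False,
    })


@pytest.fixture()
def track_factory():
    return make_track
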