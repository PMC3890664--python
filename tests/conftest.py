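import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from intdelim.datatypes import ClimateStack, OccurrenceSet, ToleranceConfig


@pytest.fixture
def two_sided():
    return ToleranceConfig(content=0.95, confidence=0.95, side="two-sided")


@pytest.fixture
def one_sided():
    return ToleranceConfig(content=0.95, confidence=0.95, side="one-sided")


@pytest.fixture
def small_stack():
    """3x3 two-layer stack with one nodata corner cell."""
    layer1 = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, -9999.0]])
    layer2 = np.array([[10.0, 20.0, 30.0], [40.0, 50.0, 60.0], [70.0, 80.0, -9999.0]])
    return ClimateStack(
        names=["layer1", "layer2"],
        values=np.stack([layer1, layer2]),
        xllcorner=0.0,
        yllcorner=0.0,
        cellsize=1.0,
        nodata=-9999.0,
    )


@pytest.fixture
def occ_on_grid():
    """Occurrences at cell centers of the small stack (one per valid cell)."""
    coords = [(c + 0.5, 2.5 - r) for r in range(3) for c in range(3) if not (r == 2 and c == 2)]
    return OccurrenceSet(taxon="sp", records=np.array(coords))
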