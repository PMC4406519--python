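import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diabrisk import DoseResponseDataset, RiskPoint, load_hba1c_npdr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hba1c_npdr() -> DoseResponseDataset:
    """The packaged 16-point HbA1c vs NPDR dose-response table."""
    return load_hba1c_npdr()


def make_dataset(x, y, factor="f", complication="c") -> DoseResponseDataset:
    pts = tuple(RiskPoint(float(a), float(b)) for a, b in zip(x, y))
    return DoseResponseDataset(factor, complication, pts)


@pytest.fixture
def line_dataset() -> DoseResponseDataset:
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    return make_dataset(x, 2.0 + 3.0 * x)
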