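import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from balscan.demography import DemographyConfig, PopulationConfig
from balscan.panel import HaplotypePanel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(matrix, positions=None, populations=None, **kwargs) -> HaplotypePanel:
    matrix = np.asarray(matrix, dtype=np.int8)
    n, m = matrix.shape
    if positions is None:
        positions = np.arange(1, m + 1)
    if populations is None:
        populations = np.array(["P"] * n, dtype=object)
    return HaplotypePanel(
        matrix=matrix,
        positions=np.asarray(positions),
        populations=np.asarray(populations, dtype=object),
        **kwargs,
    )


def random_panel(rng, n=12, m=40, region_length=None) -> HaplotypePanel:
    """A random polymorphic panel (columns neither lost nor fixed)."""
    while True:
        matrix = (rng.random((n, m)) < rng.uniform(0.1, 0.9, size=m)).astype(np.int8)
        counts = matrix.sum(axis=0)
        keep = (counts > 0) & (counts < n)
        if keep.sum() >= 2:
            matrix = matrix[:, keep]
            break
    positions = np.sort(rng.choice(np.arange(1, 10 * matrix.shape[1]),
                                   size=matrix.shape[1], replace=False))
    return make_panel(matrix, positions=positions, region_length=region_length)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def single_pop_dem():
    """Constant-size single population used across simulator tests."""
    def _make(n=1000, mu=0.0, r=0.0):
        return DemographyConfig(
            populations=[PopulationConfig("P", n)],
            mutation_rate=mu,
            recombination_rate=r,
            name="single",
        )
    return _make


@pytest.fixture
def scan_dem():
    """The frozen single-population study conditions for scan calibration."""
    return DemographyConfig(
        populations=[PopulationConfig("P", 150)],
        mutation_rate=1.5e-6,
        recombination_rate=5e-7,
        name="scan_single",
    )
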