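import numpy as np
import pytest

from chemocal import SpectrumSet, SyntheticDesign, WavenumberGrid, simulate_study


@pytest.fixture
def tiny_set() -> SpectrumSet:
    """3 samples x 5 wavenumbers with reference contents."""
    grid = WavenumberGrid(np.array([500.0, 1000.0, 1500.0, 2000.0, 2500.0]))
    matrix = np.array([
        [0.10, 0.20, 0.30, 0.20, 0.10],
        [0.15, 0.30, 0.45, 0.30, 0.15],
        [0.20, 0.40, 0.60, 0.40, 0.20],
    ])
    return SpectrumSet(grid=grid, matrix=matrix,
                       sample_ids=["s1", "s2", "s3"],
                       reference=np.array([4.0, 8.0, 12.0]))


@pytest.fixture(scope="session")
def tablet_study() -> SpectrumSet:
    """One seeded default tablet campaign (210 spectra, HPLC-like refs)."""
    return simulate_study(SyntheticDesign.tablet(seed=42))


@pytest.fixture(scope="session")
def granule_study() -> SpectrumSet:
    return simulate_study(SyntheticDesign.granule(seed=42))


def strata(sset: SpectrumSet) -> list[float]:
    return sset.metadata["nominal_mg"].tolist()
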