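import numpy as np
import pandas as pd
import pytest

from ploidyscope import MarkerManifest, NoiseModel, ThresholdsConfig, make_manifest


@pytest.fixture(scope="session")
def manifest():
    """Mid-size manifest: 4400 autosomal + 300 X + 120 Y markers."""
    return make_manifest(4400, 300, 120, seed=11)


@pytest.fixture(scope="session")
def small_manifest():
    """Tiny manifest for brute-force/oracle comparisons (<= 100 markers)."""
    return make_manifest(60, 8, 6, seed=13)


@pytest.fixture(scope="session")
def tiny_manifest():
    """One marker per chromosome (24 markers), hand-constructed."""
    chroms = [str(c) for c in range(1, 23)] + ["X", "Y"]
    return MarkerManifest(
        pd.DataFrame(
            {
                "marker_id": [f"t{c}" for c in chroms],
                "chrom": chroms,
                "pos": [100] * 24,
                "pop_b_freq": [0.5] * 24,
            }
        )
    )


@pytest.fixture(scope="session")
def noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdsConfig()
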