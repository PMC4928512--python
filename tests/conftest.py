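import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from metabnet.atlas import RegionAtlas
from metabnet.series import SubjectSeries

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_label_table() -> pd.DataFrame:
    """Five regions, two cerebellar (codes 4 and 5)."""
    return pd.DataFrame(
        {
            "code": [1, 2, 3, 4, 5],
            "name": ["Frontal_L", "Frontal_R", "Occipital_L", "Cerebelum_1_L", "Vermis_1"],
            "cerebellar": [0, 0, 0, 1, 1],
        }
    )


@pytest.fixture
def toy_atlas(toy_label_table) -> RegionAtlas:
    """A 6x6x4 label volume: regions fill distinct slabs, 0 elsewhere."""
    vol = np.zeros((6, 6, 4), dtype=int)
    vol[0:2, :, :] = 1
    vol[2:4, 0:3, :] = 2
    vol[2:4, 3:6, :] = 3
    vol[4:6, 0:3, :] = 4
    vol[4:6, 3:6, :] = 5
    return RegionAtlas(label_table=toy_label_table, label_volume=vol)


@pytest.fixture
def small_series_pair() -> tuple[SubjectSeries, SubjectSeries]:
    """Two 10-subject, 6-region groups drawn from one correlated normal."""
    rng = np.random.default_rng(42)
    cov = 0.4 + 0.6 * np.eye(6)
    root = np.linalg.cholesky(cov)
    a = SubjectSeries.from_array(rng.standard_normal((10, 6)) @ root.T, group_label="a")
    b = SubjectSeries.from_array(rng.standard_normal((10, 6)) @ root.T, group_label="b")
    return a, b
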