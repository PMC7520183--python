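import numpy as np
import pandas as pd
import pytest

from dietspec import io as dio
from dietspec.simulate import SimulationConfig, simulate_study


@pytest.fixture()
def tiny_counts(tmp_path):
    """A 3-sample x 4-taxon count table on disk."""
    path = tmp_path / "counts.csv"
    path.write_text(
        "sample_id,Clupea pallasii,Gadus macrocephalus,Parophrys vetulus,Sebastes caurinus\n"
        "s1,10,30,60,0\n"
        "s2,5,0,0,0\n"
        "s3,1,1,1,1\n")
    return path


@pytest.fixture(scope="session")
def annotation():
    return dio.load_annotation_fixture()


def small_template():
    """A 12-group layout: 2 sites x 2 sexes x 3 months, N between 6 and 12."""
    rows = []
    sizes = {"Female": (6, 12, 8), "Male": (5, 9, 11)}
    for loc in ("AA", "BB"):
        for sex in ("Female", "Male"):
            for month, n in zip((5, 7, 9), sizes[sex]):
                rows.append({"location": loc, "year": 2020, "month": month,
                             "sex": sex, "n": n})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_study():
    cfg = SimulationConfig(template=small_template())
    return simulate_study(cfg, seed=11)


@pytest.fixture(scope="session")
def full_study():
    """Default-condition study: the printed 111-group layout."""
    return simulate_study(SimulationConfig(), seed=3)
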