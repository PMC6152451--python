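import numpy as np
import pandas as pd
import pytest

from countylex.core_io import LanguageDictionary, WordCountTable


@pytest.fixture
def small_counts() -> WordCountTable:
    """Two counties x three words, with hand-checkable sums.

    county 01001: good=3, bad=1, the=6  (total 10)
    county 01003: good=2, bad=4, the=4  (total 10)
    """
    frame = pd.DataFrame(
        {
            "fips": ["01001"] * 3 + ["01003"] * 3,
            "word": ["good", "bad", "the"] * 2,
            "count": [3, 1, 6, 2, 4, 4],
        }
    )
    return WordCountTable.from_long_frame(frame)


@pytest.fixture
def good_dict() -> LanguageDictionary:
    return LanguageDictionary(
        id="positive", label="Positive words", valence="protective",
        words=frozenset({"good", "great"}),
    )


@pytest.fixture
def county_csv(tmp_path):
    """Well-formed 3-row county table with one mortality cause."""
    path = tmp_path / "counties.csv"
    pd.DataFrame(
        {
            "cnty": ["1001", "01003", "02013"],
            "name": ["Autauga", "Baldwin", "Aleutians"],
            "state": ["AL", "AL", "AK"],
            "population": [54571, 182265, 3141],
            "lat": [32.53, 30.72, 55.0],
            "lon": [-86.64, -87.72, -161.0],
            "income": [53_255, 50_147, 61_000],
            "education": [0.21, 0.26, 0.12],
            "I25.1_deaths": [60, 170, np.nan],
            "I25.1_years": [2.0, 2.0, np.nan],
            "I25.1_rate": [55.0, 46.6, np.nan],
        }
    ).to_csv(path, index=False)
    return path
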