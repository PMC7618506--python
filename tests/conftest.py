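import numpy as np
import pandas as pd
import pytest

from pharmatrace import synthetic_data
from pharmatrace.tables_io import CountTable, SampleSheet


def make_count_table(matrix, marker="16S", prefix="ASV"):
    arr = np.asarray(matrix, dtype="int64")
    return CountTable(
        pd.DataFrame(
            arr,
            index=[f"{prefix}{i + 1}" for i in range(arr.shape[0])],
            columns=[f"s{j + 1}" for j in range(arr.shape[1])],
        ),
        marker,
    )


def make_sheet(sample_ids, countries, manufacturing=None, sample_type="tablet",
               groups=None):
    n = len(sample_ids)
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_type": [sample_type] * n,
                "country": list(countries),
                "manufacturing": list(manufacturing or ["direct_compression"] * n),
                "water_source": ["none"] * n,
                "group_label": list(groups or ["G"] * n),
            },
            index=list(sample_ids),
        )
    )


@pytest.fixture(scope="session")
def study():
    """One full synthetic study under the default two-site design."""
    table, sheet, truth = synthetic_data.simulate_counts(seed=11)
    return table, sheet, truth


@pytest.fixture(scope="session")
def spectra_study():
    spectra, truth = synthetic_data.simulate_spectra(seed=11)
    return spectra, truth
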