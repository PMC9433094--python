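import numpy as np
import pandas as pd
import pytest

from crossomix.core_io import SampleDesign
from crossomix.synthetic import default_design


@pytest.fixture(scope="session")
def study_design() -> SampleDesign:
    """2 cell lines x 3 treatments x 2 times x 3 replicates (36 samples)."""
    return default_design()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def two_group_design() -> SampleDesign:
    rows = []
    for grp, cl in (("A", "L1"), ("B", "L2")):
        for rep in range(1, 5):
            rows.append(
                {
                    "sample_id": f"{grp}{rep}",
                    "cell_line": cl,
                    "treatment": "ctrl",
                    "time": "6h",
                    "replicate": rep,
                }
            )
    return SampleDesign(pd.DataFrame(rows))
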