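import numpy as np
import pandas as pd
import pytest

from comecol import CohortDesign, FeatureTable


@pytest.fixture
def toy_table() -> FeatureTable:
    """4 samples x 5 taxa with lineages spanning 2 families."""
    data = pd.DataFrame(
        [
            [5, 0, 3, 2, 1],
            [1, 3, 0, 4, 2],
            [0, 2, 6, 0, 3],
            [2, 2, 2, 2, 2],
        ],
        index=["s1", "s2", "s3", "s4"],
        columns=["tA", "tB", "tC", "tD", "tE"],
        dtype=float,
    )
    lineages = {
        "tA": ("Bacteria", "F1", "GA", "spA"),
        "tB": ("Bacteria", "F1", "GA", "spB"),
        "tC": ("Bacteria", "F1", "GB", "spC"),
        "tD": ("Bacteria", "F2", "GC", "spD"),
        "tE": ("Bacteria", "F2", "GD", "spE"),
    }
    return FeatureTable(data=data, feature_kind="taxon", lineages=lineages)


@pytest.fixture
def toy_design() -> CohortDesign:
    return CohortDesign(
        assignments={"s1": "ctl", "s2": "ctl", "s3": "dis", "s4": "dis"},
        cohort_order=["ctl", "dis"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
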