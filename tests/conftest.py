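import numpy as np
import pandas as pd
import pytest

from pathmarker.diffexpr import CountMatrix
from pathmarker.synthetic_data import simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study used by several integration tests."""
    return simulate_study(
        5,
        n_genes=600,
        n_tumor=40,
        n_normal=20,
        n_network_genes=300,
        n_pathways=12,
        n_marker_genes=8,
    )


@pytest.fixture
def toy_counts():
    """4 tumor + 4 normal samples, 3 genes, equal libraries."""
    counts = pd.DataFrame(
        {
            "T1": [10, 20, 30],
            "T2": [12, 18, 30],
            "T3": [11, 19, 30],
            "T4": [9, 21, 30],
            "N1": [10, 20, 30],
            "N2": [10, 20, 30],
            "N3": [10, 20, 30],
            "N4": [10, 20, 30],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    labels = pd.Series(
        ["tumor"] * 4 + ["normal"] * 4, index=counts.columns
    )
    return CountMatrix(counts=counts, labels=labels)


MINIMAL_KGML = """<?xml version="1.0"?>
<pathway name="path:hsa00001" title="toy">
  <entry id="1" name="hsa:10" type="gene"/>
  <entry id="2" name="hsa:20" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
</pathway>
"""


@pytest.fixture
def minimal_kgml():
    return MINIMAL_KGML
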