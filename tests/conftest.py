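import numpy as np
import pandas as pd
import pytest

from tftea.io import ClinicalTable, CountMatrix, TFTargetCollection


@pytest.fixture
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(11)
    genes = [f"g{i:03d}" for i in range(50)]
    samples = ["s1", "s2", "s3", "s4"]
    mu = rng.lognormal(4.0, 1.0, 50)
    counts = rng.negative_binomial(5, 5 / (5 + mu[:, None]), size=(50, 4))
    return CountMatrix(genes, samples, counts)


@pytest.fixture
def toy_collection() -> TFTargetCollection:
    return TFTargetCollection(
        sets={"TFA": {"g1", "g2", "g3"}, "TFB": {"g4", "g5"}},
        provenance="toy")


@pytest.fixture
def toy_clinical() -> ClinicalTable:
    return ClinicalTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(1, 7)],
        "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 1, 1, 1, 0, 0],
        "stage": ["I", "II", "II", "III", "III", "IV"],
        "purity": [0.8, 0.7, 0.9, 0.6, 0.75, 0.85]}))
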