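import numpy as np
import pandas as pd
import pytest

from clinomics.data_io import ClinicalTable, LabelSpec, OmicMatrix, Partition


@pytest.fixture
def tiny_matrix() -> OmicMatrix:
    """3 features x 4 samples, no missing values."""
    vals = np.array([[1.0, 2.0, 3.0, 4.0],
                     [4.0, 4.0, 4.0, 4.0],
                     [0.0, -1.0, 5.0, 2.0]])
    return OmicMatrix("expr", ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], vals)


@pytest.fixture
def clinical_small() -> ClinicalTable:
    samples = [f"s{i}" for i in range(1, 11)]
    ct = ClinicalTable(samples)
    ct.add_label("status", pd.Series(["pos"] * 5 + ["neg"] * 5, index=samples),
                 LabelSpec("status", "categorical"))
    ct.add_label("age", pd.Series([40, 61, 70, 55, 48, 62, 66, 59, 51, 45],
                                  index=samples, dtype=float),
                 LabelSpec("age", "numeric"))
    ct.add_label("grade", pd.Series(["I", "II", "III", "I", "II",
                                     "III", "I", "II", "III", "I"], index=samples),
                 LabelSpec("grade", "ordinal", levels=["I", "II", "III"]))
    ct.add_label("OS", pd.DataFrame({"time": np.arange(1.0, 11.0),
                                     "event": [1, 0, 1, 1, 0, 1, 1, 0, 1, 1]},
                                    index=samples),
                 LabelSpec("OS", "survival"))
    return ct


@pytest.fixture
def halves_partition() -> Partition:
    ids = [f"s{i}" for i in range(1, 11)]
    return Partition.from_labels("samples", ids, [1] * 5 + [2] * 5)


def planted_blobs(n_per: int, n_features: int, separation_sd: float,
                  k: int = 2, seed: int = 0) -> tuple[OmicMatrix, np.ndarray]:
    """k Gaussian sample blobs shifted along every feature by separation_sd."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(k), n_per)
    X = rng.standard_normal((n_features, k * n_per))
    shift = separation_sd / np.sqrt(n_features)  # total between-mean distance in SD units
    for c in range(k):
        X[:, labels == c] += c * shift
    ids = [f"s{j}" for j in range(k * n_per)]
    m = OmicMatrix("sim", [f"f{i}" for i in range(n_features)], ids, X)
    return m, labels + 1
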