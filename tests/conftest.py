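from __future__ import annotations

import numpy as np
import pytest

from lincscan.datasets import SyntheticSpec, generate_corpus
from lincscan.feature_extraction import FeatureConfig, build_feature_table
from lincscan.svm_model import LabeledDataset


SMALL_SPEC = SyntheticSpec(
    n_coding=30,
    n_noncoding=30,
    length_range=(300, 600),
    orf_length_range=(180, 450),
    transcripts_per_chrom=20,
    seed=42,
)


@pytest.fixture(scope="session")
def small_corpus():
    """A small but fully-featured synthetic corpus shared across tests."""
    return generate_corpus(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_feature_table(small_corpus):
    return build_feature_table(
        small_corpus.transcripts,
        small_corpus.genome,
        small_corpus.track,
        FeatureConfig(),
    )


@pytest.fixture(scope="session")
def small_dataset(small_corpus, small_feature_table) -> LabeledDataset:
    y = np.array(
        [
            1 if small_corpus.truth[tid] == "noncoding" else 0
            for tid in small_feature_table.ids
        ]
    )
    return LabeledDataset(
        ids=list(small_feature_table.ids),
        names=small_feature_table.names,
        X=small_feature_table.X,
        y=y,
    )


@pytest.fixture()
def blob_dataset() -> LabeledDataset:
    """Well-separated 2-D Gaussian blobs for quick SVM behavior tests."""
    rng = np.random.default_rng(0)
    n = 40
    x_pos = rng.normal(loc=(2.0, 2.0), scale=0.3, size=(n, 2))
    x_neg = rng.normal(loc=(-2.0, -2.0), scale=0.3, size=(n, 2))
    return LabeledDataset(
        ids=[f"p{i}" for i in range(n)] + [f"n{i}" for i in range(n)],
        names=("f1", "f2"),
        X=np.vstack([x_pos, x_neg]),
        y=np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)]),
    )
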