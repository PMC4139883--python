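import numpy as np
import pytest

from vkcotc import (
    LabeledDataset,
    ProteinRecord,
    SyntheticSpec,
    build_count_table,
    confidence_levels,
    default_benchmark_like_spec,
    generate,
)


@pytest.fixture(scope="session")
def benchmark_like():
    """Default 217-sequence, 6-class synthetic dataset with its truth."""
    return generate(default_benchmark_like_spec())


@pytest.fixture(scope="session")
def benchmark_ranking(benchmark_like):
    dataset, _ = benchmark_like
    return confidence_levels(build_count_table(dataset))


@pytest.fixture(scope="session")
def small_spec():
    """Reduced 3-class spec for fast end-to-end runs."""
    base = default_benchmark_like_spec()
    return SyntheticSpec(
        n_classes=3,
        seqs_per_class=10,
        length_range=(150, 300),
        planted=base.planted[:3],
        insertions_per_seq=8,
        seed=base.seed + 1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    dataset, _ = generate(small_spec)
    return dataset


@pytest.fixture()
def toy_dataset():
    """Two tiny classes with hand-countable tripeptide content."""
    records = [
        ProteinRecord("a1", "", "AAAA"),
        ProteinRecord("b1", "", "ACDAC"),
    ]
    return LabeledDataset(records=records, labels=["K1", "K2"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
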