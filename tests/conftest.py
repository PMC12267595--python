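import numpy as np
import pytest

from il2kit import descriptors, io, models
from il2kit.synth import SyntheticConfig, generate

REFERENCE_SEED = 11


def dummy_dataset(n_pos: int, n_neg: int) -> io.PeptideDataset:
    """Unique placeholder peptides for pure count/split arithmetic checks."""
    aa = io.AMINO_ACIDS

    def encode(i: int) -> str:
        s = []
        for _ in range(10):
            s.append(aa[i % 20])
            i //= 20
        return "".join(s)

    records = [
        io.PeptideRecord(f"pos{i}", encode(i), "positive") for i in range(n_pos)
    ] + [
        io.PeptideRecord(f"neg{i}", encode(n_pos + i), "negative")
        for i in range(n_neg)
    ]
    return io.PeptideDataset(records)


@pytest.fixture(scope="session")
def synth_default() -> io.PeptideDataset:
    """The reference synthetic conditions: 400/400, planted ALEGSLQ at 0.6."""
    return generate(SyntheticConfig(seed=REFERENCE_SEED))


@pytest.fixture(scope="session")
def synth_split(synth_default) -> io.SplitResult:
    return io.split_dataset(synth_default, ratio=0.2, seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def dpc_len_features(synth_split):
    train = descriptors.compute_feature_set(synth_split.train, "DPC_LEN")
    test = descriptors.compute_feature_set(synth_split.test, "DPC_LEN")
    return train, test


@pytest.fixture(scope="session")
def et_predictor(synth_split, dpc_len_features) -> models.TrainedPredictor:
    """Grid-searched extra-trees classifier on the reference training split."""
    train_fm, _ = dpc_len_features
    spec = models.ModelSpec("ET", seed=REFERENCE_SEED)
    return models.train(train_fm, synth_split.train.labels(), spec)


@pytest.fixture(scope="session")
def quick_et_spec() -> models.ModelSpec:
    """Single-point grid for tests that need a fitted model, not a search."""
    return models.ModelSpec(
        "ET", grid={"n_estimators": [250]}, seed=REFERENCE_SEED
    )


@pytest.fixture
def tiny_labeled() -> io.PeptideDataset:
    records = [
        io.PeptideRecord("p1", "ALEGSLQK", "positive"),
        io.PeptideRecord("p2", "KALEGSLQ", "positive"),
        io.PeptideRecord("p3", "GGALEGWW", "positive"),
        io.PeptideRecord("n1", "CCDDTTCC", "negative"),
        io.PeptideRecord("n2", "DTDTDTDT", "negative"),
        io.PeptideRecord("n3", "WCDCDCDC", "negative"),
    ]
    return io.PeptideDataset(records)
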