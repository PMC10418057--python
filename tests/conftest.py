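import numpy as np
import pytest

from epistitch.classifier import TrainingExample, split_by_wildtype, train_model
from epistitch.synth import classifier_fixture


@pytest.fixture(scope="session")
def planted_examples():
    """Balanced planted-epitope training examples (n=2,000, seed 7)."""
    return classifier_fixture(2000, seed=7)


@pytest.fixture(scope="session")
def planted_split(planted_examples):
    return split_by_wildtype(planted_examples, test_fraction=0.05, seed=7)


@pytest.fixture(scope="session")
def planted_model(planted_split):
    train_set, _ = planted_split
    return train_model(train_set, k=15, seed=42)


@pytest.fixture(scope="session")
def shuffled_model(planted_examples):
    """Same examples with labels shuffled: the permutation null."""
    rng = np.random.default_rng(7)
    labels = np.array([ex.label for ex in planted_examples])
    rng.shuffle(labels)
    shuffled = [
        TrainingExample(ex.seq, int(lab), ex.wildtype_id, ex.n_reactive_samples, ex.bead_count)
        for ex, lab in zip(planted_examples, labels)
    ]
    return train_model(shuffled, k=15, seed=42)


@pytest.fixture(scope="session")
def separable_model():
    """Tiny model trained on trivially separable composition classes."""
    rng = np.random.default_rng(0)
    pos_letters, neg_letters = "KRED", "ILVF"
    pos = ["".join(rng.choice(list(pos_letters), 15)) for _ in range(30)]
    neg = ["".join(rng.choice(list(neg_letters), 15)) for _ in range(30)]
    examples = [TrainingExample(s, 1, f"wp{i}", 3) for i, s in enumerate(pos)]
    examples += [TrainingExample(s, 0, f"wn{i}", 0, 50) for i, s in enumerate(neg)]
    return train_model(examples, k=15, seed=42)
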