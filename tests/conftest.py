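import random

import numpy as np
import pytest

from rnam5c import Dataset, GeneratorModel, RnaWindow, generate
from rnam5c.windows import NEGATIVE, POSITIVE

from oracles import random_window


@pytest.fixture
def rng():
    return random.Random(20240)


@pytest.fixture
def random_windows(rng):
    """Factory: n random 41-nt cytosine-centered windows."""

    def make(n, length=41):
        return [random_window(rng, length) for _ in range(n)]

    return make


@pytest.fixture
def small_dataset(random_windows):
    """10 positives + 10 negatives, random sequences."""
    seqs = random_windows(20)
    windows = [RnaWindow(f"p{i}", s, POSITIVE) for i, s in enumerate(seqs[:10])]
    windows += [RnaWindow(f"n{i}", s, NEGATIVE) for i, s in enumerate(seqs[10:])]
    return Dataset(windows)


@pytest.fixture
def planted_dataset():
    """Synthetic benchmark with a clear planted signal (fast to classify)."""
    model = GeneratorModel(delta=0.2, seed=77)
    return generate(model, 150, 150)


def make_disjoint_dataset(n_each=5):
    """Positives all one fixed sequence, negatives all another; the
    per-position propensity difference is then exactly +/-1."""
    pos_seq = ("ACGU" * 11)[:41]
    neg_seq = ("UGCA" * 11)[:41]
    windows = [RnaWindow(f"p{i}", pos_seq, POSITIVE) for i in range(n_each)]
    windows += [RnaWindow(f"n{i}", neg_seq, NEGATIVE) for i in range(n_each)]
    return Dataset(windows), pos_seq, neg_seq
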