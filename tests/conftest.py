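import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from kernelselect import ExpressionDataset


@pytest.fixture
def tiny_dataset():
    """6 samples × 3 genes; gene 1 is strongly class-separated."""
    rng = np.random.default_rng(42)
    values = rng.standard_normal((6, 3))
    labels = np.array([1, 1, 1, -1, -1, -1])
    values[:3, 1] += 4.0
    values[3:, 1] -= 4.0
    return ExpressionDataset(values=values, labels=labels)


def random_dataset(rng, n=8, m=6):
    labels = np.array([1] * (n // 2) + [-1] * (n - n // 2))
    return ExpressionDataset(values=rng.standard_normal((n, m)), labels=labels)
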