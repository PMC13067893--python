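import numpy as np
import pytest

from dxeval import AnalysisConfig, ConfusionMatrix


@pytest.fixture
def example_cm() -> ConfusionMatrix:
    """The worked-example confusion matrix (TP=58, FP=15, FN=14, TN=26)."""
    return ConfusionMatrix(tp=58, fp=15, fn=14, tn=26)


@pytest.fixture
def cfg() -> AnalysisConfig:
    """Default analysis settings: population prevalence 0.1, z = 1.96."""
    return AnalysisConfig(prevalence=0.1)


def random_instance(rng: np.random.Generator, max_group: int = 20, tie_prone: bool = False):
    """Random scores/labels with both classes present; ties when requested."""
    m = int(rng.integers(2, max_group + 1))
    n = int(rng.integers(2, max_group + 1))
    if tie_prone:
        scores = rng.integers(0, 6, size=m + n).astype(float)
    else:
        scores = np.concatenate([rng.normal(1.0, 1.0, m), rng.normal(0.0, 1.0, n)])
    labels = np.concatenate([np.ones(m, dtype=int), np.zeros(n, dtype=int)])
    return scores, labels


def random_confusion_matrix(rng: np.random.Generator, max_cell: int = 30) -> ConfusionMatrix:
    """Random matrix with non-empty margins."""
    while True:
        tp, fp, fn, tn = (int(v) for v in rng.integers(0, max_cell + 1, size=4))
        if tp + fn > 0 and tn + fp > 0:
            return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
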