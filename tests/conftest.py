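import numpy as np
import pytest

from rocsurface import LabeledScores, compute_curve


@pytest.fixture
def six_feature_data():
    """Worked example: six features, three positives, three negatives.

    Sweeping the six cutoffs by hand gives
    fpr = [0, 0, 1/3, 2/3, 2/3, 1], tpr = [1/3, 2/3, 2/3, 2/3, 1, 1],
    fdr = [0, 0, 1/3, 1/2, 2/5, 1/2].
    """
    return LabeledScores(
        [0.9, 0.8, 0.7, 0.6, 0.5, 0.4], [1, 1, 0, 0, 1, 0]
    )


@pytest.fixture
def six_feature_curve(six_feature_data):
    return compute_curve(six_feature_data)


def random_labeled_scores(rng, n_max=60, ties=True):
    """A random valid LabeledScores instance for property tests."""
    n = int(rng.integers(2, n_max + 1))
    if ties and rng.random() < 0.5:
        scores = rng.integers(0, max(2, n // 3), size=n).astype(float)
    else:
        scores = rng.normal(size=n)
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = True
    if labels.all():
        labels[int(rng.integers(n))] = False
    return LabeledScores(scores, labels)
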