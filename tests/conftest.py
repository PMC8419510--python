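import itertools

import numpy as np
import pytest

from who_select.synthetic_data import SyntheticSpec, generate
from who_select.wrapper_selection import (
    FeatureMatrix,
    FitnessConfig,
    LabelVector,
    SelectionMask,
    SubsetFitnessEvaluator,
)


@pytest.fixture
def small_dataset():
    """120 x 8 planted dataset (3 informative, 2 redundant, 3 noise)."""
    spec = SyntheticSpec(
        n_samples=120,
        n_informative=3,
        n_redundant=2,
        n_noise=3,
        effect_size=1.5,
        seed=3,
    )
    X, y, gt = generate(spec)
    return FeatureMatrix.from_array(X), LabelVector(y), gt


@pytest.fixture
def planted_dataset():
    """300 x 50 planted dataset matching the headline synthetic regime."""
    spec = SyntheticSpec(n_samples=300, seed=11)
    X, y, gt = generate(spec)
    return FeatureMatrix.from_array(X), LabelVector(y), gt


def exhaustive_minimum(matrix, labels, fc):
    """Brute-force minimum fitness over every nonempty mask."""
    d = matrix.n_features
    ev = SubsetFitnessEvaluator(matrix, labels, fc)
    best = np.inf
    best_mask = None
    for r in range(1, d + 1):
        for combo in itertools.combinations(range(d), r):
            mask = SelectionMask.from_indices(combo, d)
            value = ev.fitness(mask)
            if value < best:
                best, best_mask = value, mask
    return best, best_mask
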