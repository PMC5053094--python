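import itertools

import numpy as np
import pytest

from securelink import fellegi_sunter as fs
from securelink import synthdata

#: Published three-field unit-weight table (family name, first name, date of
#: birth) used to replay the worked compound-weight examples.
PUBLISHED_AGREE = (8.4, 5.7, 10.3)
PUBLISHED_DISAGREE = (-2.8, -3.5, -3.1)


@pytest.fixture
def published_weights() -> fs.UnitWeightTable:
    return fs.UnitWeightTable.from_values(PUBLISHED_AGREE, PUBLISHED_DISAGREE)


@pytest.fixture
def clean_files():
    """Two small producer files with 70% overlap and no identifier errors."""
    pop = synthdata.generate_population(120, seed=11)
    return synthdata.make_producer_files(pop, synthdata.ErrorConfig(overlap=0.7), seed=11)


def simulate_pattern_counts(m, u, p, n_pairs, seed):
    """Multinomial agreement-pattern counts from known (m, u, p).

    Independent oracle for EM tests: the generating distribution is written
    out directly as the two-class mixture, without using the estimator.
    """
    k = len(m)
    patterns = list(itertools.product((0, 1), repeat=k))

    def class_prob(pattern, probs):
        out = 1.0
        for bit, pr in zip(pattern, probs):
            out *= pr if bit else 1 - pr
        return out

    mix = np.array([p * class_prob(t, m) + (1 - p) * class_prob(t, u)
                    for t in patterns])
    counts = np.random.default_rng(seed).multinomial(n_pairs, mix)
    return {t: int(c) for t, c in zip(patterns, counts) if c > 0}
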