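"""Shared fixtures: cost models and seeded random string pairs."""

import string

import numpy as np
import pytest

from gedmatch.cost_models import (
    keyboard_cost_model,
    sample_similarity_table,
    sample_substitution_costs,
    shape_cost_model,
    table_cost_model,
    unit_cost_model,
)

ALPHABET_DNA = "acgt"
ALPHABET_AZ = string.ascii_lowercase


def random_pairs(seed, n, alphabet=ALPHABET_AZ, max_len=12, min_len=0):
    """n seeded (X, Y) pairs with independent uniform lengths in [min_len, max_len]."""
    rng = np.random.default_rng(seed)

    def word():
        length = int(rng.integers(min_len, max_len + 1))
        return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))

    return [(word(), word()) for _ in range(n)]


def model_for(name, pattern):
    """Build a shipped cost model; shape adapts its indel cost to the pattern."""
    if name == "unit":
        return unit_cost_model()
    if name == "shape":
        return shape_cost_model(
            sample_similarity_table(), C=1.0, pattern_length=max(1, len(pattern))
        )
    if name == "keyboard":
        return keyboard_cost_model()
    if name == "table":
        return table_cost_model(
            sample_substitution_costs(), deletion_cost=0.76, insertion_cost=0.76
        )
    raise ValueError(name)


#: metrics for which the pruning register is exact (every substitution cost
#: is at most the indel cost at the tested pattern lengths)
SOUND_METRICS = ("unit", "shape")
#: shipped metrics where some substitution exceeds the indel cost, so the
#: register engines are only guaranteed to be one-sided (no false matches)
ONE_SIDED_METRICS = ("keyboard", "table")
ALL_METRICS = SOUND_METRICS + ONE_SIDED_METRICS


@pytest.fixture(scope="session")
def unit_model():
    return unit_cost_model()


@pytest.fixture(scope="session")
def keyboard_model():
    return keyboard_cost_model()
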