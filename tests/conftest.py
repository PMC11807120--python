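"""Shared fixtures.

The two expensive study setups — the conditioning experiment and the fully
trained search system — are session-scoped so every test (and the acceptance
suite) shares one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from rxntree.data import prepare_records
from rxntree.grammar import GrammarConfig, default_templates, generate_reaction_dataset
from rxntree.workflows import (
    ConditioningResult,
    SearchSystem,
    build_search_system,
    conditioning_experiment,
)

SEED = 0


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def ambiguous_records():
    """The ambiguity-3 conditioning dataset (no closure)."""
    return prepare_records(generate_reaction_dataset(GrammarConfig(seed=SEED)))


@pytest.fixture(scope="session")
def search_system() -> SearchSystem:
    """Closure grammar + memorizing transformer + GCN + QSAR reward + MCTS."""
    return build_search_system(seed=SEED)


@pytest.fixture(scope="session")
def conditioning() -> ConditioningResult:
    """Conditional vs unconditional twins on the ambiguous grammar."""
    return conditioning_experiment(seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
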