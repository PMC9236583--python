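"""Shared fixtures: tiny hand-built models and the synthetic small fixture."""

from __future__ import annotations

import numpy as np
import pytest

import domarch as dm
from domarch.model import NULL, Alphabet, CountTables, FirstOrderModel


def make_model(bigram_counts: dict, tokens: tuple[str, ...], k: float | str = 0.0) -> FirstOrderModel:
    """Model from a literal {(prev, next): count} dict."""
    counts = CountTables()
    for pair, c in bigram_counts.items():
        counts.bigram[pair] = c
    return FirstOrderModel.from_counts(counts, Alphabet(tokens), k)


def random_trained_model(rng: np.random.Generator, n_d: int | None = None, k: float | None = None) -> FirstOrderModel:
    """A model with random sparse bigram counts and random pseudocount."""
    if n_d is None:
        n_d = int(rng.integers(2, 8))
    tokens = tuple(f"T{i}" for i in range(n_d))
    counts = CountTables()
    universe = list(tokens) + [NULL]
    for prev in universe:
        for nxt in universe:
            if prev == NULL and nxt == NULL:
                continue
            if rng.random() < 0.6:
                counts.bigram[(prev, nxt)] = int(rng.integers(1, 50))
    if k is None:
        k = float(rng.uniform(0.01, 2.0))
    return FirstOrderModel.from_counts(counts, Alphabet(tokens), k)


def random_architecture(rng: np.random.Generator, model: FirstOrderModel, max_len: int = 8) -> tuple[str, ...]:
    n = int(rng.integers(1, max_len + 1))
    return tuple(model.alphabet.tokens[int(i)] for i in rng.integers(0, model.n_d, n))


def brute_force_log_prob(model: FirstOrderModel, da) -> float:
    """Independent full-product oracle: sum of per-factor log conditionals."""
    import math

    padded = (NULL, *da, NULL)
    total = 0.0
    for prev, nxt in zip(padded, padded[1:]):
        p = model.conditional_probability(prev, nxt)
        if p == 0.0:
            return -math.inf
        total += math.log(p)
    return total


@pytest.fixture(scope="session")
def small_fixture():
    return dm.make_paperlike_fixture("small")


@pytest.fixture(scope="session")
def small_trained(small_fixture):
    _, corpus = small_fixture
    tc = dm.build_corpus(corpus)
    return dm.build_model(tc.counts, tc.alphabet)


@pytest.fixture(scope="session")
def medium_fixture():
    return dm.make_paperlike_fixture("medium")


@pytest.fixture(scope="session")
def medium_trained(medium_fixture):
    _, corpus = medium_fixture
    tc = dm.build_corpus(corpus)
    return dm.build_model(tc.counts, tc.alphabet)
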