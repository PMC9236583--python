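"""Synthetic training corpora drawn from a known first-order ground truth.

Real training corpora are genome-scale domain-annotation sets (on the order
of a thousand superfamilies and several thousand unique architectures per
metazoan lineage).  This module stands in for them with corpora sampled
from a randomly generated — but fully known — first-order model, so the
whole pipeline (train -> simulate -> evaluate) is testable offline and
parameter recovery can be measured against ground truth.

The generator controls the features that matter to the simulator: alphabet
size, the fraction of forbidden domain adjacencies (genuine bigram matrices
are very sparse), and the termination probability, which sets the expected
architecture length (genuine means are ~3.6-6.2 domains with right-skewed
distributions and medians of 3-4).  What it deliberately does not emulate:
gene-duplication redundancy (corpora are unique-DA sets by construction,
matching how training data are deduplicated) and any selection beyond
first-order adjacency preferences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Alphabet, Architecture, FirstOrderModel


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth model shape.

    ``termination_strength`` is the mean p(NULL | token); expected DA length
    is roughly its reciprocal.  ``transition_sparsity`` is the fraction of
    token->token bigrams forced to zero before renormalization.
    """

    alphabet_size: int = 20
    transition_sparsity: float = 0.3
    termination_strength: float = 0.25
    corpus_size: int = 200
    seed: int = 20220627
    # genuine superfamily usage is strongly heavy-tailed (a handful of
    # superfamilies dominate all n-gram counts); token weights follow a
    # Zipf-like law with this exponent
    usage_exponent: float = 0.9
    # genuine corpora contain repeat-forming superfamilies (zinc fingers,
    # EGF, cadherin repeats ...) with self-adjacency far above baseline; a
    # fraction of tokens gets a sticky self-transition drawn up to this
    # probability, so tandem arrays have genuine-like length spread
    tandem_prone_fraction: float = 0.2
    max_self_stickiness: float = 0.8

    def __post_init__(self) -> None:
        if self.alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        if not 0 <= self.transition_sparsity < 1:
            raise ValueError("transition_sparsity must be in [0, 1)")
        if not 0.01 <= self.termination_strength <= 1:
            raise ValueError(
                "termination_strength below 0.01 admits near-infinite expected lengths"
            )


def _token_names(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"SF{i:0{width}d}" for i in range(n))


def sample_ground_truth(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> FirstOrderModel:
    """Draw a normalized conditional table over alphabet + NULL.

    Tokens receive Zipf-like popularity weights (``usage_exponent``); each
    context row distributes its non-termination mass over continuations in
    proportion to popularity times lognormal noise, with
    ``transition_sparsity`` of the token->token cells zeroed.  Tandem-prone
    tokens get a sticky self-transition drawn up to
    ``max_self_stickiness``.  p(NULL | token) is jittered around
    ``termination_strength``, which sets the expected architecture length.
    The NULL row is strictly positive over the alphabet, so every token can
    start an architecture and every architecture can terminate: the chain
    is irreducible on the table's support.
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    n = spec.alphabet_size
    alphabet = Alphabet(_token_names(n))
    table = np.zeros((n + 1, n + 1))

    rank = rng.permutation(n) + 1
    popularity = rank ** (-spec.usage_exponent)

    # NULL start row: strictly positive over the alphabet
    start = popularity * np.exp(rng.normal(0.0, 0.3, n))
    table[n, :n] = start / start.sum()

    prone = rng.random(n) < spec.tandem_prone_fraction
    for i in range(n):
        term = np.clip(spec.termination_strength * np.exp(rng.normal(0.0, 0.3)), 0.02, 0.9)
        if n == 1:
            table[i, 0], table[i, n] = 1.0 - term, term
            continue
        w = popularity * np.exp(rng.normal(0.0, 0.5, n))
        if spec.transition_sparsity > 0:
            # self-transitions are handled by the prone/non-prone rule below;
            # sparsity hits non-self cells, always sparing one continuation
            candidates = rng.permutation(n)
            candidates = candidates[candidates != i]
            n_zero = min(int(round(spec.transition_sparsity * n)), n - 2)
            w[candidates[:n_zero]] = 0.0
        if prone[i]:
            stick = min(rng.uniform(0.2, spec.max_self_stickiness), 0.95 - term)
            w[i] = 0.0
            others = w / w.sum() * (1.0 - term - stick)
            table[i, :n] = others
            table[i, i] = stick
        else:
            # repeat propensity is a class property: outside the
            # tandem-prone class self-adjacency is strongly suppressed,
            # though not forbidden (only sparsity introduces exact zeros)
            w[i] *= 0.005
            table[i, :n] = w / w.sum() * (1.0 - term)
        table[i, n] = term
    return FirstOrderModel.from_probabilities(alphabet, table)


def expected_length(model: FirstOrderModel) -> float:
    """Closed-form expected architecture length under ancestral sampling.

    With Q the token->token sub-matrix of the conditional table, the chain
    started from the NULL row is absorbed at NULL after
    ``pi0 (I - Q)^-1 1`` tokens on average (absorbing-chain fundamental
    matrix).
    """
    n = model.n_d
    p = np.exp(model.log_conditional_table)
    q = p[:n, :n]
    pi0 = p[n, :n]
    visits = np.linalg.solve(np.eye(n) - q.T, pi0)
    return float(visits.sum())


def sample_architecture(model: FirstOrderModel, rng: np.random.Generator) -> Architecture:
    """One ancestral draw: start from the NULL row, emit until NULL."""
    p = np.exp(model.log_conditional_table)
    n = model.n_d
    cum = np.cumsum(p, axis=1)
    tokens = model.alphabet.tokens
    out = []
    row = n
    while True:
        row = int(np.searchsorted(cum[row], rng.random(), side="right"))
        if row >= n:
            break
        out.append(tokens[row])
    return tuple(out)


def sample_corpus(
    model: FirstOrderModel,
    corpus_size: int,
    rng: np.random.Generator,
    max_attempts_factor: int = 200,
) -> tuple[Architecture, ...]:
    """Sample until ``corpus_size`` *unique* architectures are collected.

    Duplicates are re-drawn (the corpus emulates a deduplicated training
    set); if the model's support is too concentrated to yield that many
    distinct architectures within ``max_attempts_factor * corpus_size``
    draws, an error is raised.
    """
    seen: set[Architecture] = set()
    attempts = 0
    cap = max_attempts_factor * corpus_size
    while len(seen) < corpus_size:
        if attempts >= cap:
            raise RuntimeError(
                f"drew {attempts} architectures but found only {len(seen)} unique ones; "
                "the model is too concentrated for the requested corpus size"
            )
        seen.add(sample_architecture(model, rng))
        attempts += 1
    return tuple(sorted(seen))


def sample_corpus_growth(
    model: FirstOrderModel,
    sizes: tuple[int, ...],
    rng: np.random.Generator,
    max_attempts_factor: int = 200,
) -> list[tuple[Architecture, ...]]:
    """Nested unique corpora at increasing ``sizes`` from one draw stream.

    Used by parameter-recovery experiments: each corpus extends the previous
    one, so estimation error shrinks with data rather than re-rolling it.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be increasing")
    seen: set[Architecture] = set()
    out = []
    attempts = 0
    for target in sizes:
        cap = max_attempts_factor * target
        while len(seen) < target:
            if attempts >= cap:
                raise RuntimeError("model support too concentrated for the requested corpus size")
            seen.add(sample_architecture(model, rng))
            attempts += 1
        out.append(tuple(sorted(seen)))
    return out


def max_abs_conditional_error(estimate: FirstOrderModel, truth: FirstOrderModel) -> float:
    """Largest absolute deviation between two conditional tables.

    The estimate's alphabet may be a subset of the truth's (tokens never
    sampled into a finite corpus); missing rows/columns count as estimated
    zero, which penalizes un-recovered mass.
    """
    t_truth = np.exp(truth.log_conditional_table)
    est = np.zeros_like(t_truth)
    null_t, null_e = truth.n_d, estimate.n_d
    t_est = np.exp(estimate.log_conditional_table)
    ids = [truth.alphabet.index(t) for t in estimate.alphabet.tokens]
    for i, gi in enumerate(ids):
        for j, gj in enumerate(ids):
            est[gi, gj] = t_est[i, j]
        est[gi, null_t] = t_est[i, null_e]
        est[null_t, gi] = t_est[null_e, i]
    return float(np.max(np.abs(est - t_truth)))


_PRESETS = {
    # alphabet, corpus, sparsity, termination, seed
    "small": GeneratorSpec(20, 0.30, 0.28, 200, 915001),
    "medium": GeneratorSpec(150, 0.40, 0.24, 3000, 915002),
    "paper-scale": GeneratorSpec(1100, 0.60, 0.22, 7000, 915003),
}


def make_paperlike_fixture(preset: str = "small") -> tuple[FirstOrderModel, tuple[Architecture, ...]]:
    """Deterministic (model, corpus) fixtures shaped like genuine corpora.

    ``small`` (20 tokens / 200 DAs) keeps the full battery seconds-scale;
    ``medium`` (150 tokens / 3000 DAs) has mean length in the genuine 3-6
    range with a right-skewed length distribution; ``paper-scale``
    (1100 tokens / 7000 DAs) approaches genuine corpus dimensions and is
    meant for manual experiments, not routine tests.  Fixed internal seeds
    make every preset byte-identical across runs.
    """
    try:
        spec = _PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}") from None
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    model = sample_ground_truth(spec, rng)
    corpus = sample_corpus(model, spec.corpus_size, rng)
    return model, corpus
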