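"""First-order probability model over protein domain architectures.

A domain architecture (DA) is the ordered N- to C-terminal list of domain
superfamily tokens in one protein.  Its probability is approximated by a
first-order Markov product of conditionals, one per adjacent token pair,
with a reserved NULL sentinel marking the two termini::

    p(DA) = p(d1 | NULL) * p(d2 | d1) * ... * p(NULL | dn)

Conditionals are estimated from bigram counts over a deduplicated training
corpus with Add-k smoothing: every bigram count gains a pseudocount ``k``,
which connects the state space (every gain/loss move has positive
probability) and so makes the simulator's Markov chain irreducible.

Conventions fixed here and used throughout the package:

* The continuation set of every alphabet token is ``alphabet + {NULL}``
  (``N_D + 1`` outcomes).  The NULL start context continues into the
  alphabet only (``N_D`` outcomes): an empty architecture has probability
  zero, so smoothed conditionals still sum to one per context.
* Insertion sites are 0-based (``0 .. n``: before the first token through
  after the last); deletion positions are 1-based (``1 .. n``).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Reserved sentinel marking DA termini.  Never a member of an alphabet.
NULL = "<NULL>"

#: An architecture is an ordered, nonempty tuple of superfamily id strings.
Architecture = tuple[str, ...]


class TokenNotInAlphabetError(KeyError):
    """A token outside the model's alphabet (and not the NULL sentinel)."""


class InvalidBigramError(ValueError):
    """The (NULL, NULL) bigram, which corresponds to the empty architecture."""


def as_architecture(tokens: Iterable[str]) -> Architecture:
    """Validate and freeze a token sequence into an :data:`Architecture`.

    Raises ``ValueError`` for empty input or an embedded NULL sentinel.
    """
    arch = tuple(tokens)
    if len(arch) == 0:
        raise ValueError("a domain architecture must contain at least one domain")
    if NULL in arch:
        raise ValueError("the NULL sentinel marks termini only; it cannot appear inside an architecture")
    return arch


@dataclass(frozen=True)
class Alphabet:
    """The set of ``N_D`` domain superfamily tokens seen in training."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(set(self.tokens)))
        if len(ordered) == 0:
            raise ValueError("alphabet must contain at least one token")
        if NULL in ordered:
            raise ValueError("the NULL sentinel cannot be an alphabet member")
        object.__setattr__(self, "tokens", ordered)

    @property
    def size(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def _index(self) -> dict[str, int]:
        # cached token -> integer id map (NULL gets id N_D, appended by users)
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {t: i for i, t in enumerate(self.tokens)}
            self.__dict__["_index_cache"] = idx
        return idx

    def index(self, token: str) -> int:
        """Integer id of ``token``; the NULL sentinel maps to ``N_D``."""
        if token == NULL:
            return len(self.tokens)
        try:
            return self._index[token]
        except KeyError:
            raise TokenNotInAlphabetError(f"token {token!r} is not in the alphabet") from None


@dataclass
class CountTables:
    """n-gram counts over a set of unique architectures.

    Bigrams and trigrams include NULL-boundary pairs/triples; monograms
    count token occurrences with multiplicity across unique architectures.
    """

    monogram: Counter = field(default_factory=Counter)
    bigram: Counter = field(default_factory=Counter)
    trigram: Counter = field(default_factory=Counter)
    n_unique_das: int = 0

    def validate(self) -> None:
        if any(c < 0 for c in self.monogram.values()):
            raise ValueError("negative monogram count")
        if any(c < 0 for c in self.bigram.values()):
            raise ValueError("negative bigram count")
        if self.bigram.get((NULL, NULL), 0) != 0:
            raise ValueError("(NULL, NULL) bigram implies an empty architecture")


class FirstOrderModel:
    """Smoothed first-order (bigram) model over domain architectures.

    Parameters
    ----------
    alphabet:
        The ``N_D`` superfamily tokens.
    counts:
        Bigram counts (boundary pairs included).  May be ``None`` when the
        model is built directly from a probability table
        (:meth:`from_probabilities`).
    k:
        Add-k pseudocount, ``>= 0`` or the string ``"default"`` which
        resolves to ``1 / N_D`` (about 0.0009 at the metazoan training
        scale of ~1100 superfamilies).
    """

    def __init__(
        self,
        alphabet: Alphabet,
        counts: CountTables | None,
        k: float | str = "default",
    ) -> None:
        self.alphabet = alphabet
        self.counts = counts
        self.k = self._resolve_k(k, alphabet.size)
        if counts is not None:
            counts.validate()
            self._log_cond = self._table_from_counts(alphabet, counts, self.k)
        else:
            self._log_cond = None  # set by from_probabilities

    @staticmethod
    def _resolve_k(k: float | str, n_d: int) -> float:
        if isinstance(k, str):
            if k != "default":
                raise ValueError(f"k must be a nonnegative number or 'default', got {k!r}")
            return 1.0 / n_d
        if k < 0:
            raise ValueError("pseudocount k must be nonnegative")
        return float(k)

    @staticmethod
    def _table_from_counts(alphabet: Alphabet, counts: CountTables, k: float) -> np.ndarray:
        n = alphabet.size
        c = np.zeros((n + 1, n + 1))
        for (prev, nxt), cnt in counts.bigram.items():
            c[alphabet.index(prev), alphabet.index(nxt)] = cnt
        c += k
        # NULL context cannot continue into NULL (no empty architecture)
        c[n, n] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            log_cond = np.log(c) - np.log(c.sum(axis=1, keepdims=True))
        log_cond[np.isnan(log_cond)] = -np.inf
        return log_cond

    @classmethod
    def from_counts(
        cls, counts: CountTables, alphabet: Alphabet, k: float | str = "default"
    ) -> "FirstOrderModel":
        return cls(alphabet, counts, k)

    @classmethod
    def from_probabilities(cls, alphabet: Alphabet, table: np.ndarray) -> "FirstOrderModel":
        """Build a model from an explicit conditional-probability matrix.

        ``table[x, y] = p(y | x)`` with token ids per ``alphabet.index`` and
        NULL at id ``N_D``.  Rows must sum to 1; ``table[NULL, NULL]`` must
        be 0.  Used by the synthetic-fixture generator, where the ground
        truth is a probability table rather than counts.
        """
        n = alphabet.size
        table = np.asarray(table, dtype=float)
        if table.shape != (n + 1, n + 1):
            raise ValueError(f"table must be ({n + 1}, {n + 1}), got {table.shape}")
        if table[n, n] != 0.0:
            raise ValueError("p(NULL | NULL) must be zero")
        if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional rows must sum to 1")
        model = cls.__new__(cls)
        model.alphabet = alphabet
        model.counts = None
        model.k = 0.0
        with np.errstate(divide="ignore"):
            model._log_cond = np.log(table)
        return model

    # -- probability calculus -------------------------------------------------

    @property
    def n_d(self) -> int:
        return self.alphabet.size

    @property
    def log_conditional_table(self) -> np.ndarray:
        """Read-only ``(N_D+1, N_D+1)`` matrix of log conditionals."""
        return self._log_cond

    @property
    def is_irreducible(self) -> bool:
        """True when every conditional (bar the NULL->NULL cell) is positive."""
        n = self.n_d
        table = self._log_cond
        mask = np.ones_like(table, dtype=bool)
        mask[n, n] = False
        return bool(np.all(np.isfinite(table[mask])))

    def _pair_ids(self, prev: str, nxt: str) -> tuple[int, int]:
        i, j = self.alphabet.index(prev), self.alphabet.index(nxt)
        if i == self.n_d and j == self.n_d:
            raise InvalidBigramError("the (NULL, NULL) bigram has no probability (empty architecture)")
        return i, j

    def log_conditional(self, prev: str, nxt: str) -> float:
        """``log p(nxt | prev)``; ``-inf`` for a zero conditional (k = 0)."""
        i, j = self._pair_ids(prev, nxt)
        return float(self._log_cond[i, j])

    def conditional_probability(self, prev: str, nxt: str) -> float:
        """Smoothed conditional ``p(nxt | prev)``.

        ``(C(prev, nxt) + k) / (sum_y C(prev, y) + k * |continuations(prev)|)``
        where the continuation set is the alphabet plus NULL for alphabet
        contexts and the alphabet alone for the NULL start context.
        """
        return math.exp(self.log_conditional(prev, nxt))

    def architecture_log_probability(self, da: Sequence[str]) -> float:
        """Log of the first-order DA probability: ``n + 1`` boundary-padded factors."""
        arch = as_architecture(da)
        ids = [self.alphabet.index(t) for t in arch]
        n = self.n_d
        total = self._log_cond[n, ids[0]]
        for a, b in zip(ids, ids[1:]):
            total += self._log_cond[a, b]
        total += self._log_cond[ids[-1], n]
        return float(total)

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        """Serialize alphabet, k, and sparse bigram counts (NULL as JSON null)."""
        if self.counts is None:
            raise ValueError("only count-backed models can be serialized (probability-table models cannot)")

        def enc(t: str):
            return None if t == NULL else t

        payload = {
            "alphabet": list(self.alphabet.tokens),
            "k": self.k,
            "n_unique_das": self.counts.n_unique_das,
            "bigram_counts": [
                [enc(p), enc(q), c] for (p, q), c in sorted(self.counts.bigram.items()) if c
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FirstOrderModel":
        payload = json.loads(text)
        alphabet = Alphabet(tuple(payload["alphabet"]))
        counts = CountTables(n_unique_das=payload.get("n_unique_das", 0))
        for p, q, c in payload["bigram_counts"]:
            counts.bigram[(NULL if p is None else p, NULL if q is None else q)] = c
        return cls(alphabet, counts, payload["k"])


def insertion_ratio(model: FirstOrderModel, da: Sequence[str], site: int, token: str) -> float:
    """Probability ratio p(t)/p(s) for gaining ``token`` at insertion ``site``.

    All first-order factors not touching the insertion point cancel, leaving
    three conditionals: ``p(x|left) * p(right|x) / p(right|left)`` with
    ``left``/``right`` the flanking tokens (NULL at the termini).
    """
    arch = as_architecture(da)
    n = len(arch)
    if not 0 <= site <= n:
        raise ValueError(f"insertion site must be in 0..{n}, got {site}")
    left = arch[site - 1] if site > 0 else NULL
    right = arch[site] if site < n else NULL
    return _three_factor_ratio(model, left, token, right, inverse=False)


def deletion_ratio(model: FirstOrderModel, da: Sequence[str], pos: int) -> float:
    """Probability ratio p(t)/p(s) for losing the domain at 1-based ``pos``.

    Requires ``len(da) >= 2``; the simulator vetoes deletions from
    single-domain architectures before ever computing a ratio.
    """
    arch = as_architecture(da)
    n = len(arch)
    if n < 2:
        raise ValueError("deletion ratio is undefined for single-domain architectures")
    if not 1 <= pos <= n:
        raise ValueError(f"deletion position must be in 1..{n}, got {pos}")
    left = arch[pos - 2] if pos >= 2 else NULL
    right = arch[pos] if pos < n else NULL
    return _three_factor_ratio(model, left, arch[pos - 1], right, inverse=True)


def _three_factor_ratio(model: FirstOrderModel, left: str, mid: str, right: str, inverse: bool) -> float:
    table = model.log_conditional_table
    li, mi, ri = (model.alphabet.index(t) for t in (left, mid, right))
    num = table[li, mi] + table[mi, ri]
    den = table[li, ri]
    if inverse:
        num, den = den, num
    if num == -np.inf:
        return 0.0
    if den == -np.inf:
        return math.inf
    return math.exp(num - den)


def adjacent_state_count(n: int, n_d: int) -> int:
    """Number of architectures one gain or loss away from a length-``n`` one.

    ``n + (n+1) * N_D`` in general; ``2 * N_D`` for ``n = 1``, where the
    single deletion would cause extinction and is forbidden.
    """
    if n < 1:
        raise ValueError("architecture length must be >= 1")
    if n_d < 1:
        raise ValueError("alphabet size must be >= 1")
    if n == 1:
        return 2 * n_d
    return n + (n + 1) * n_d
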