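"""Validation statistics comparing genuine and simulated architecture sets.

Every statistic is computed identically on both sets of unique domain
architectures, paired over the union of observed keys (zero-filled), and
summarized by a Pearson correlation.  The battery covers:

* singleton / bigram / trigram frequencies (does the simulator preserve
  local order constraints?),
* pair co-occurrence and promiscuity measures (does it preserve which
  domains combine at all?),
* tandem-array statistics (does bigram-driven insertion reproduce repeat
  expansion?),
* architecture-probability quantiles (does the sampled distribution match
  the model's?),
* event-position histograms and Gelman–Rubin convergence diagnostics on
  chain traces.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .model import NULL, Architecture, FirstOrderModel, as_architecture
from .simulate import ChainTrace
from .training import count_ngrams


@dataclass
class StatisticComparison:
    """One Table-row comparison: paired vectors and their Pearson r."""

    name: str
    keys: list
    values_a: np.ndarray
    values_b: np.ndarray
    pearson_r: float
    p_value: float


@dataclass
class ComparisonReport:
    """Pearson correlations of the full statistic battery on two DA sets."""

    statistics: dict[str, StatisticComparison] = field(default_factory=dict)

    def correlations(self) -> dict[str, float]:
        return {name: s.pearson_r for name, s in self.statistics.items()}

    def as_dict(self) -> dict:
        return {
            name: {"pearson_r": s.pearson_r, "p_value": s.p_value, "n_keys": len(s.keys)}
            for name, s in self.statistics.items()
        }


def _pair_and_correlate(name: str, counts_a: dict, counts_b: dict, keys: str = "union") -> StatisticComparison:
    if keys == "union":
        universe = sorted(set(counts_a) | set(counts_b))
    elif keys == "intersection":
        universe = sorted(set(counts_a) & set(counts_b))
    else:
        raise ValueError("keys must be 'union' or 'intersection'")
    a = np.array([counts_a.get(k, 0.0) for k in universe], dtype=float)
    b = np.array([counts_b.get(k, 0.0) for k in universe], dtype=float)
    r, p = _pearson(a, b)
    return StatisticComparison(name, universe, a, b, r, p)


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        # constant vectors: identical -> perfect agreement, else undefined
        return (1.0, 0.0) if np.allclose(a, b) else (np.nan, np.nan)
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def _unique(archs: Iterable[Sequence[str]]) -> list[Architecture]:
    uniq = sorted({as_architecture(a) for a in archs})
    if not uniq:
        raise ValueError("architecture set is empty")
    return uniq


# -- n-gram frequencies ------------------------------------------------------


def ngram_frequency_vectors(
    set_a: Iterable[Sequence[str]],
    set_b: Iterable[Sequence[str]],
    order: int,
    keys: str = "union",
) -> StatisticComparison:
    """Paired, within-set-normalized n-gram frequencies (order 1, 2 or 3)."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")

    def freqs(archs):
        tables = count_ngrams(_unique(archs))
        table = {1: tables.monogram, 2: tables.bigram, 3: tables.trigram}[order]
        total = sum(table.values())
        return {k: v / total for k, v in table.items()}

    return _pair_and_correlate(f"{order}-gram frequency", freqs(set_a), freqs(set_b), keys)


# -- co-occurrence and promiscuity ------------------------------------------


def pair_cooccurrence_counts(archs: Iterable[Sequence[str]]) -> Counter:
    """Per unordered token pair {x, y}, x != y: number of unique DAs
    containing both anywhere (not necessarily adjacent)."""
    counts: Counter = Counter()
    for arch in _unique(archs):
        present = sorted(set(arch))
        for i, x in enumerate(present):
            for y in present[i + 1 :]:
                counts[(x, y)] += 1
    return counts


def pair_cooccurrence(
    set_a: Iterable[Sequence[str]], set_b: Iterable[Sequence[str]], keys: str = "union"
) -> StatisticComparison:
    return _pair_and_correlate(
        "pair co-occurrence", pair_cooccurrence_counts(set_a), pair_cooccurrence_counts(set_b), keys
    )


def neighbor_sets(archs: Iterable[Sequence[str]]) -> dict[str, set[str]]:
    """Distinct adjacent partners of each token (both sides, NULL excluded;
    a token adjacent to its own copy is its own neighbor)."""
    partners: dict[str, set[str]] = defaultdict(set)
    for arch in _unique(archs):
        for t in arch:
            partners.setdefault(t, set())
        for a, b in zip(arch, arch[1:]):
            partners[a].add(b)
            partners[b].add(a)
    return dict(partners)


def unique_neighbors(archs: Iterable[Sequence[str]]) -> dict[str, int]:
    return {t: len(p) for t, p in neighbor_sets(archs).items()}


def unique_neighbors_comparison(
    set_a: Iterable[Sequence[str]], set_b: Iterable[Sequence[str]], keys: str = "union"
) -> StatisticComparison:
    return _pair_and_correlate("unique neighbors", unique_neighbors(set_a), unique_neighbors(set_b), keys)


def weighted_bigram_promiscuity(
    archs: Iterable[Sequence[str]], top_n: int = 100
) -> dict[str, float]:
    """Promiscuity score of the ``top_n`` most promiscuous tokens.

    A domain is promiscuous when it combines with many, themselves
    non-promiscuous, partners.  Score(d) = sum over distinct partners p of
    w(p) with w(p) = 1 / (number of distinct partners of p), on unique DAs.
    Ranking by descending score, ties broken lexicographically.
    """
    partners = neighbor_sets(archs)
    degree = {t: len(p) for t, p in partners.items()}
    scores = {
        t: sum(1.0 / degree[p] for p in ps if degree[p] > 0) for t, ps in partners.items()
    }
    ranked = sorted(scores, key=lambda t: (-scores[t], t))[:top_n]
    return {t: scores[t] for t in ranked}


def weighted_bigram_promiscuity_comparison(
    set_a: Iterable[Sequence[str]],
    set_b: Iterable[Sequence[str]],
    top_n: int = 100,
) -> StatisticComparison:
    """Scores of set A's ``top_n`` most promiscuous tokens, paired with the
    same tokens' scores in set B (zero when absent)."""
    scores_a = weighted_bigram_promiscuity(set_a, top_n)
    partners_b = neighbor_sets(set_b)
    degree_b = {t: len(p) for t, p in partners_b.items()}
    scores_b = {
        t: sum(1.0 / degree_b[p] for p in partners_b.get(t, ()) if degree_b[p] > 0)
        for t in scores_a
    }
    keys = sorted(scores_a)
    a = np.array([scores_a[k] for k in keys])
    b = np.array([scores_b.get(k, 0.0) for k in keys])
    r, p = _pearson(a, b)
    return StatisticComparison("weighted bigram promiscuity", keys, a, b, r, p)


# -- tandem arrays -----------------------------------------------------------


def tandem_array_stats(archs: Iterable[Sequence[str]]) -> dict[str, tuple[int, int, float]]:
    """Per superfamily: (total tandem copies, max array length, mean length).

    A tandem array is a maximal run of >= 2 identical adjacent tokens; the
    total aggregates run lengths over all arrays of that superfamily across
    unique DAs.
    """
    totals: Counter = Counter()
    maxima: Counter = Counter()
    n_arrays: Counter = Counter()
    for arch in _unique(archs):
        i = 0
        while i < len(arch):
            j = i
            while j + 1 < len(arch) and arch[j + 1] == arch[i]:
                j += 1
            run = j - i + 1
            if run >= 2:
                t = arch[i]
                totals[t] += run
                maxima[t] = max(maxima[t], run)
                n_arrays[t] += 1
            i = j + 1
    return {t: (totals[t], maxima[t], totals[t] / n_arrays[t]) for t in totals}


def tandem_array_comparison(
    set_a: Iterable[Sequence[str]], set_b: Iterable[Sequence[str]], keys: str = "union"
) -> StatisticComparison:
    mean_a = {t: s[2] for t, s in tandem_array_stats(set_a).items()}
    mean_b = {t: s[2] for t, s in tandem_array_stats(set_b).items()}
    return _pair_and_correlate("mean tandem array length", mean_a, mean_b, keys)


# -- architecture-probability quantiles --------------------------------------


def probability_quantile_comparison(
    model: FirstOrderModel,
    set_a: Iterable[Sequence[str]],
    set_b: Iterable[Sequence[str]],
    trim_fraction: float = 0.01,
    n_quantiles: int = 101,
) -> StatisticComparison:
    """Q-Q comparison of per-DA log-probabilities under the trained model.

    Each set is independently stripped of its longest ``trim_fraction`` of
    DAs (ties by lower probability first), to blunt the extreme-length tail;
    matched quantiles (linear / type-7 interpolation) are then correlated.
    """

    def trimmed_logps(archs):
        uniq = _unique(archs)
        logps = np.array([model.architecture_log_probability(a) for a in uniq])
        n_drop = int(np.floor(trim_fraction * len(uniq)))
        if n_drop >= len(uniq):
            raise ValueError("trim fraction removes the entire set")
        if n_drop:
            order = sorted(range(len(uniq)), key=lambda i: (-len(uniq[i]), logps[i]))
            keep = np.ones(len(uniq), dtype=bool)
            keep[order[:n_drop]] = False
            logps = logps[keep]
        return logps

    q = np.linspace(0.0, 1.0, n_quantiles)
    qa = np.quantile(trimmed_logps(set_a), q, method="linear")
    qb = np.quantile(trimmed_logps(set_b), q, method="linear")
    r, p = _pearson(qa, qb)
    return StatisticComparison("DA probability quantiles", list(q), qa, qb, r, p)


# -- event positions ---------------------------------------------------------


def event_position_frequencies(
    traces: Sequence[ChainTrace],
    length_range: range = range(3, 9),
) -> dict[tuple[int, str], np.ndarray]:
    """Accepted-event position histograms, keyed by (pre-move length, kind).

    Gains over 1-based insertion sites ``1 .. length+1``; losses over domain
    positions ``1 .. length``.  Frequencies normalized per (length, kind);
    lengths without accepted events of a kind are omitted.
    """
    if not any(t.events for t in traces):
        raise ValueError("traces retain no events (run with emit_trace=True)")
    bins: dict[tuple[int, str], np.ndarray] = {}
    for n in length_range:
        bins[(n, "gain")] = np.zeros(n + 1)
        bins[(n, "loss")] = np.zeros(n)
    for trace in traces:
        for ev in trace.events or ():
            if not ev.accepted or ev.length not in length_range:
                continue
            if ev.kind == "gain":
                bins[(ev.length, "gain")][ev.site] += 1  # 0-based site -> 1-based bin
            else:
                bins[(ev.length, "loss")][ev.site - 1] += 1
    out = {}
    for key, counts in bins.items():
        total = counts.sum()
        if total:
            out[key] = counts / total
    return out


def terminal_event_excess(
    frequencies: dict[tuple[int, str], np.ndarray]
) -> dict[tuple[int, str], float]:
    """Ratio of summed terminal-bin frequency to its uniform expectation.

    Values above 1 indicate the terminal preference of gains and losses.
    """
    out = {}
    for (n, kind), freq in frequencies.items():
        terminal = freq[0] + freq[-1]
        out[(n, kind)] = terminal / (2.0 / len(freq))
    return out


# -- convergence -------------------------------------------------------------


def gelman_rubin(
    chains: Sequence[Sequence[float]],
    burn_in_fraction: float = 0.5,
    df_correction: bool = False,
) -> tuple[float, bool]:
    """Classic potential scale reduction factor on parallel chain series.

    The first ``burn_in_fraction`` of every chain is discarded; the PSRF
    compares between-chain and within-chain variance of the remainder:
    ``R-hat = sqrt(((n-1)/n W + B/n) / W)``.  Returns (R-hat, converged at
    the conventional 1.1 threshold).  ``df_correction`` applies the
    sampling-variability d/(d-2) factor of the original formulation.
    """
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    lengths = {len(c) for c in chains}
    if len(lengths) != 1:
        raise ValueError("chains must have equal lengths")
    arr = np.asarray(chains, dtype=float)
    start = int(arr.shape[1] * burn_in_fraction)
    arr = arr[:, start:]
    m, n = arr.shape
    if n < 10:
        raise ValueError("need at least 10 retained samples per chain")
    chain_means = arr.mean(axis=1)
    w = arr.var(axis=1, ddof=1).mean()
    b_over_n = chain_means.var(ddof=1)  # = B / n
    if w == 0.0:
        return (1.0, True) if b_over_n == 0.0 else (np.inf, False)
    if b_over_n == 0.0:
        # identical chains: no between-chain disagreement at all
        return 1.0, True
    var_plus = (n - 1) / n * w + b_over_n
    r_hat_sq = var_plus / w + b_over_n / w / m  # sigma_hat+ + B/(mn), over W
    if df_correction:
        grand = arr.mean()
        s2 = arr.var(axis=1, ddof=1)
        var_v = (
            ((n - 1) / n) ** 2 / m * s2.var(ddof=1)
            + ((m + 1) / (m * n)) ** 2 * 2 / (m - 1) * (b_over_n * n) ** 2
            + 2 * (m + 1) * (n - 1) / (m * n**2)
            * n / m
            * (np.cov(s2, chain_means**2)[0, 1] - 2 * grand * np.cov(s2, chain_means)[0, 1])
        )
        v = var_plus + b_over_n / m
        d = 2 * v**2 / var_v if var_v > 0 else np.inf
        if d > 2:
            r_hat_sq *= (d + 3) / (d + 1)
    r_hat = float(np.sqrt(r_hat_sq))
    return r_hat, r_hat < 1.1


# -- full battery ------------------------------------------------------------


def compare_sets(
    genuine: Iterable[Sequence[str]],
    simulated: Iterable[Sequence[str]],
    model: FirstOrderModel | None = None,
    top_n_promiscuous: int = 100,
    trim_fraction: float = 0.01,
) -> ComparisonReport:
    """The full statistic battery on two DA sets.

    The probability-quantile row requires a trained ``model`` and is skipped
    when none is given.
    """
    genuine = _unique(genuine)
    simulated = _unique(simulated)
    report = ComparisonReport()
    rows = [
        ("singleton_frequency", ngram_frequency_vectors(genuine, simulated, 1)),
        ("bigram_frequency", ngram_frequency_vectors(genuine, simulated, 2)),
        ("trigram_frequency", ngram_frequency_vectors(genuine, simulated, 3)),
        ("pair_cooccurrence", pair_cooccurrence(genuine, simulated)),
        ("unique_neighbors", unique_neighbors_comparison(genuine, simulated)),
        (
            "wtd_bigram_promiscuity",
            weighted_bigram_promiscuity_comparison(genuine, simulated, top_n_promiscuous),
        ),
        ("mean_tandem_array_length", tandem_array_comparison(genuine, simulated)),
    ]
    if model is not None:
        rows.append(
            (
                "da_probability_quantiles",
                probability_quantile_comparison(model, genuine, simulated, trim_fraction),
            )
        )
    for key, comparison in rows:
        report.statistics[key] = comparison
    return report
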