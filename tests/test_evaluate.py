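"""Comparison statistics and convergence diagnostics."""

import itertools
import math

import numpy as np
import pytest

from domarch.evaluate import (
    ComparisonReport,
    compare_sets,
    event_position_frequencies,
    gelman_rubin,
    ngram_frequency_vectors,
    pair_cooccurrence,
    pair_cooccurrence_counts,
    probability_quantile_comparison,
    tandem_array_stats,
    terminal_event_excess,
    unique_neighbors,
    weighted_bigram_promiscuity,
)
from domarch.simulate import ChainTrace, ProposalEvent

from conftest import random_trained_model, random_architecture


def random_corpus(seed, n=40):
    rng = np.random.default_rng(seed)
    m = random_trained_model(rng, n_d=5)
    return sorted({random_architecture(rng, m) for _ in range(n)})


class TestNgramFrequencies:
    def test_identical_sets_perfect_correlation(self):
        corpus = random_corpus(0)
        for order in (1, 2, 3):
            assert ngram_frequency_vectors(corpus, corpus, order).pearson_r == pytest.approx(1.0)

    def test_disjoint_singletons_anticorrelated(self):
        assert ngram_frequency_vectors([("A",)], [("B",)], 1).pearson_r == pytest.approx(-1.0)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            ngram_frequency_vectors([("A",)], [("A",)], 4)

    def test_order_invariance_and_symmetry(self):
        a, b = random_corpus(1), random_corpus(2)
        fwd = ngram_frequency_vectors(a, b, 2)
        rev = ngram_frequency_vectors(b, a, 2)
        shuffled = ngram_frequency_vectors(list(reversed(a)), b, 2)
        assert fwd.pearson_r == pytest.approx(rev.pearson_r)
        assert fwd.pearson_r == pytest.approx(shuffled.pearson_r)


class TestPairCooccurrence:
    def test_repeat_counts_once_per_da(self):
        assert pair_cooccurrence_counts([("A", "B", "A")]) == {("A", "B"): 1}

    def test_never_coresident_pair_absent(self):
        counts = pair_cooccurrence_counts([("ZF", "ZF"), ("IG", "K")])
        assert ("IG", "ZF") not in counts

    def test_matches_brute_force_scan(self):
        corpus = random_corpus(3)
        counts = pair_cooccurrence_counts(corpus)
        tokens = sorted({t for a in corpus for t in a})
        for x, y in itertools.combinations(tokens, 2):
            expected = sum(1 for a in corpus if x in a and y in a)
            assert counts.get((x, y), 0) == expected


class TestUniqueNeighbors:
    def test_two_sided_partners(self):
        assert unique_neighbors([("A", "B"), ("B", "C")])["B"] == 2

    def test_self_adjacency_counts_self(self):
        assert unique_neighbors([("A", "A")])["A"] == 1

    def test_matches_brute_force_adjacency(self):
        corpus = random_corpus(4)
        result = unique_neighbors(corpus)
        for token, count in result.items():
            partners = set()
            for a in corpus:
                for i, t in enumerate(a):
                    if t == token:
                        if i > 0:
                            partners.add(a[i - 1])
                        if i < len(a) - 1:
                            partners.add(a[i + 1])
            assert count == len(partners)


class TestWeightedBigramPromiscuity:
    def test_hand_recomputation_on_toy_corpus(self):
        # A-B, A-C, B-C adjacencies: degrees A=2, B=2, C=2 -> each score = 1/2+1/2
        corpus = [("A", "B"), ("A", "C"), ("B", "C")]
        scores = weighted_bigram_promiscuity(corpus)
        assert scores == {"A": 1.0, "B": 1.0, "C": 1.0}
        # hub H touches leaves L1..L3 (degree 1): score(H) = 3, score(Li) = 1/3
        corpus = [("H", "L1"), ("H", "L2"), ("H", "L3")]
        scores = weighted_bigram_promiscuity(corpus)
        assert scores["H"] == pytest.approx(3.0)
        assert scores["L1"] == pytest.approx(1 / 3)

    def test_single_partner_token_minimal(self):
        corpus = [("H", "L1"), ("H", "L2"), ("H", "L3")]
        scores = weighted_bigram_promiscuity(corpus)
        assert min(scores, key=scores.get) in {"L1", "L2", "L3"}

    def test_symmetric_tokens_equal_scores(self):
        corpus = [("X", "M"), ("Y", "M")]
        scores = weighted_bigram_promiscuity(corpus)
        assert scores["X"] == scores["Y"]

    def test_top_n_truncates_by_score(self):
        corpus = [("H", "L1"), ("H", "L2"), ("H", "L3")]
        top = weighted_bigram_promiscuity(corpus, top_n=1)
        assert list(top) == ["H"]


class TestTandemArrays:
    def test_basic_run(self):
        stats = tandem_array_stats([("A", "A", "A", "B")])
        assert stats["A"] == (3, 3, 3.0)

    def test_non_adjacent_copies_excluded(self):
        assert tandem_array_stats([("A", "B", "A")]) == {}

    def test_matches_brute_force_run_lengths(self):
        corpus = random_corpus(5, n=60)
        result = tandem_array_stats(corpus)
        expected = {}
        for a in corpus:
            for token, group in itertools.groupby(a):
                run = len(list(group))
                if run >= 2:
                    tot, mx, cnt = expected.get(token, (0, 0, 0))
                    expected[token] = (tot + run, max(mx, run), cnt + 1)
        assert set(result) == set(expected)
        for t, (tot, mx, cnt) in expected.items():
            assert result[t] == (tot, mx, pytest.approx(tot / cnt))


class TestProbabilityQuantiles:
    def test_identical_sets_on_diagonal(self):
        rng = np.random.default_rng(6)
        m = random_trained_model(rng, n_d=5)
        corpus = sorted({random_architecture(rng, m) for _ in range(50)})
        cmp = probability_quantile_comparison(m, corpus, corpus)
        assert cmp.pearson_r == pytest.approx(1.0)
        np.testing.assert_allclose(cmp.values_a, cmp.values_b)

    def test_trim_robustness_without_extremes(self):
        rng = np.random.default_rng(7)
        m = random_trained_model(rng, n_d=5)
        a = sorted({random_architecture(rng, m, max_len=4) for _ in range(60)})
        b = sorted({random_architecture(rng, m, max_len=4) for _ in range(60)})
        trimmed = probability_quantile_comparison(m, a, b, trim_fraction=0.01)
        untrimmed = probability_quantile_comparison(m, a, b, trim_fraction=0.0)
        assert trimmed.pearson_r == pytest.approx(untrimmed.pearson_r, abs=0.05)

    def test_trim_everything_rejected(self):
        rng = np.random.default_rng(8)
        m = random_trained_model(rng, n_d=3)
        corpus = [("T0",), ("T1",)]
        with pytest.raises(ValueError):
            probability_quantile_comparison(m, corpus, corpus, trim_fraction=1.0)


class TestEventPositions:
    def test_hand_built_trace_exact_bins(self):
        events = [
            ProposalEvent(1, "gain", 0, "A", 1.0, True, length=3),
            ProposalEvent(2, "gain", 3, "A", 1.0, True, length=3),
            ProposalEvent(3, "loss", 2, None, 1.0, True, length=3),
            ProposalEvent(4, "gain", 1, "A", 1.0, False, length=3),  # rejected: ignored
        ]
        trace = ChainTrace(events=events)
        freqs = event_position_frequencies([trace])
        np.testing.assert_allclose(freqs[(3, "gain")], [0.5, 0, 0, 0.5])
        np.testing.assert_allclose(freqs[(3, "loss")], [0, 1.0, 0])

    def test_frequencies_normalized(self, small_trained):
        import domarch as dm

        cfg = dm.SimulationConfig(chain_length=20_000, seed=3, emit_trace=True, trace_accepted_only=True)
        _, trace = dm.run_chain(cfg, small_trained)
        freqs = event_position_frequencies([trace])
        for freq in freqs.values():
            assert freq.sum() == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            event_position_frequencies([ChainTrace()])

    def test_terminal_excess_uniform_is_one(self):
        freqs = {(4, "gain"): np.full(5, 0.2), (4, "loss"): np.array([0.5, 0.0, 0.0, 0.5])}
        excess = terminal_event_excess(freqs)
        assert excess[(4, "gain")] == pytest.approx(1.0)
        assert excess[(4, "loss")] == pytest.approx(2.0)


class TestGelmanRubin:
    def test_identical_chains_unity(self):
        chain = list(np.sin(np.arange(100)) * 3 + 5)
        r_hat, converged = gelman_rubin([chain, chain, chain])
        assert r_hat == pytest.approx(1.0)
        assert converged

    def test_separated_means_diverge(self):
        rng = np.random.default_rng(0)
        a = rng.normal(3, 1, 200)
        b = rng.normal(30, 1, 200)
        r_hat, converged = gelman_rubin([a, b])
        assert r_hat > 5 and not converged

    def test_matches_independent_reference(self):
        """Classic PSRF recomputed from its textbook definition."""
        rng = np.random.default_rng(1)
        chains = rng.normal(0, 1, (4, 400)) + rng.normal(0, 0.3, (4, 1))
        r_hat, _ = gelman_rubin(chains, burn_in_fraction=0.0)

        arr = np.asarray(chains)
        m, n = arr.shape
        means = arr.mean(axis=1)
        w = np.mean([np.var(c, ddof=1) for c in arr])
        b = n * np.var(means, ddof=1)
        v_hat = (n - 1) / n * w + (m + 1) / (m * n) * b
        expected = math.sqrt(v_hat / w)
        assert r_hat == pytest.approx(expected, abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            gelman_rubin([[1.0] * 100])
        with pytest.raises(ValueError):
            gelman_rubin([[1.0] * 100, [1.0] * 50])


class TestCompareSets:
    def test_identity_gives_all_ones(self, small_fixture, small_trained):
        _, corpus = small_fixture
        report = compare_sets(corpus, corpus, small_trained)
        for name, r in report.correlations().items():
            assert r == pytest.approx(1.0), name

    def test_report_covers_all_battery_rows(self, small_fixture, small_trained):
        _, corpus = small_fixture
        report = compare_sets(corpus, corpus, small_trained)
        assert set(report.correlations()) == {
            "singleton_frequency",
            "bigram_frequency",
            "trigram_frequency",
            "pair_cooccurrence",
            "unique_neighbors",
            "wtd_bigram_promiscuity",
            "mean_tandem_array_length",
            "da_probability_quantiles",
        }
        payload = report.as_dict()
        assert all("pearson_r" in row for row in payload.values())
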