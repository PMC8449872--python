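"""Background model construction, motif probabilities, clumpability and
surrogate construction."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifdist import (
    BackgroundError,
    MotifQuery,
    MotifValidationError,
    NonErgodicChainError,
    build_background,
    estimate_from_genome,
    is_clumpable,
    motif_probability,
    non_clumpable_surrogate,
    random_genome,
    stationary_distribution,
    stationary_occurrence_probability,
    FixtureSpec,
)

motif_strings = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestBuildBackground:
    def test_uniform_model_valid(self):
        model = build_background({s: 0.25 for s in "ACGT"})
        assert math.isclose(sum(model.base_freqs.values()), 1.0, abs_tol=1e-12)

    def test_skewed_model_valid(self):
        model = build_background({"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4})
        assert model.base_freqs["A"] == 0.4

    @pytest.mark.parametrize(
        "freqs",
        [
            {"A": 0.5, "C": 0.5, "G": 0.2, "T": 0.2},  # sums to 1.4
            {"A": -0.1, "C": 0.5, "G": 0.3, "T": 0.3},  # negative
            {"A": 0.5, "C": 0.5},  # missing symbols
        ],
    )
    def test_invalid_frequencies_rejected(self, freqs):
        with pytest.raises(BackgroundError):
            build_background(freqs)

    def test_near_one_sum_renormalized(self):
        model = build_background({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.2500001})
        assert abs(math.fsum(model.base_freqs.values()) - 1.0) < 1e-12

    def test_order1_requires_transitions(self):
        with pytest.raises(BackgroundError):
            build_background({s: 0.25 for s in "ACGT"}, order=1)

    def test_order1_rows_renormalized(self):
        trans = {(a, b): 0.25 for a in "ACGT" for b in "ACGT"}
        model = build_background({s: 0.25 for s in "ACGT"}, order=1, transitions=trans)
        assert np.allclose(model.transition_matrix().sum(axis=1), 1.0, atol=1e-12)

    def test_order1_missing_row_rejected(self):
        trans = {("A", b): 0.25 for b in "ACGT"}
        with pytest.raises(BackgroundError):
            build_background({s: 0.25 for s in "ACGT"}, order=1, transitions=trans)


class TestEstimateFromGenome:
    def test_one_of_each(self):
        model, n = estimate_from_genome("ACGT")
        assert n == 4
        assert all(model.base_freqs[s] == 0.25 for s in "ACGT")

    def test_direct_count(self):
        model, n = estimate_from_genome("AAAC")
        assert n == 4
        assert model.base_freqs == {"A": 0.75, "C": 0.25, "G": 0.0, "T": 0.0}

    def test_ambiguity_codes_skipped(self):
        model, n = estimate_from_genome("ACGTNNNRY")
        assert n == 4

    def test_lower_case_folded(self):
        model, n = estimate_from_genome("acgt")
        assert n == 4

    def test_empty_genome_rejected(self):
        with pytest.raises(BackgroundError):
            estimate_from_genome("NNN")

    def test_generated_genome_recovers_frequencies(self):
        target = {"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4}
        genome = random_genome(
            FixtureSpec(genome_length=10_000, base_freqs=target, seed=42)
        )
        model, n = estimate_from_genome(genome)
        assert n == 10_000
        for s in "ACGT":
            assert abs(model.base_freqs[s] - target[s]) < 0.02

    def test_order1_transitions_are_bigram_conditionals(self):
        model, n = estimate_from_genome("AACAAC", order=1)
        # contexts: A->A, A->C, C->A, A->A, A->C
        assert model.transitions[("A", "A")] == pytest.approx(0.5)
        assert model.transitions[("A", "C")] == pytest.approx(0.5)
        assert model.transitions[("C", "A")] == pytest.approx(1.0)


class TestMotifProbability:
    def test_uniform_product(self, equi_model):
        assert motif_probability(equi_model, "ACGTAC") == pytest.approx(
            0.25**6, rel=1e-12
        )

    def test_skewed_product(self, at_rich_model):
        assert motif_probability(at_rich_model, "AC") == pytest.approx(0.04, rel=1e-12)

    def test_anagrams_have_equal_probability(self, equi_model, at_rich_model):
        for model in (equi_model, at_rich_model):
            assert motif_probability(model, "AACCC") == pytest.approx(
                motif_probability(model, "CCCAA"), rel=1e-13
            )

    def test_probabilities_sum_to_one_over_all_words(self, at_rich_model):
        m = 4
        total = math.fsum(
            motif_probability(at_rich_model, "".join(w))
            for w in itertools.product("ACGT", repeat=m)
        )
        assert abs(total - 1.0) < 1e-10

    def test_zero_frequency_symbol_gives_zero(self):
        model = build_background({"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0})
        assert motif_probability(model, "AG") == 0.0

    def test_ambiguity_code_rejected(self, equi_model):
        with pytest.raises(MotifValidationError):
            motif_probability(equi_model, "ACGTN")

    def test_order1_uniform_rows_match_order0(self, equi_model):
        trans = {(a, b): 0.25 for a in "ACGT" for b in "ACGT"}
        markov = build_background(
            {s: 0.25 for s in "ACGT"}, order=1, transitions=trans
        )
        for motif in ("AC", "ACGTAC"):
            assert motif_probability(markov, motif) == pytest.approx(
                motif_probability(equi_model, motif), rel=1e-12
            )

    def test_order1_chain_product(self):
        # two-state-dominant chain: A and T sticky, C/G rare
        trans = {}
        rows = {
            "A": {"A": 0.7, "C": 0.1, "G": 0.1, "T": 0.1},
            "C": {"A": 0.4, "C": 0.2, "G": 0.2, "T": 0.2},
            "G": {"A": 0.4, "C": 0.2, "G": 0.2, "T": 0.2},
            "T": {"A": 0.1, "C": 0.1, "G": 0.1, "T": 0.7},
        }
        for a, row in rows.items():
            for b, p in row.items():
                trans[(a, b)] = p
        model = build_background(
            {s: 0.25 for s in "ACGT"}, order=1, transitions=trans
        )
        pi = stationary_distribution(model)
        idx = model.symbol_index()
        expected = pi[idx["A"]] * 0.7 * 0.1  # A->A->C
        assert motif_probability(model, "AAC") == pytest.approx(expected, rel=1e-12)


class TestStationaryOccurrence:
    def test_order0_equals_window_probability(self, equi_model):
        assert stationary_occurrence_probability(equi_model, "AC") == 1 / 16

    def test_non_ergodic_chain_rejected(self):
        trans = {(a, b): (1.0 if a == b else 0.0) for a in "ACGT" for b in "ACGT"}
        model = build_background(
            {s: 0.25 for s in "ACGT"}, order=1, transitions=trans
        )
        with pytest.raises(NonErgodicChainError):
            stationary_distribution(model)

    def test_matches_long_run_start_frequency(self):
        """Monte-Carlo referee: the stationary occurrence probability of a
        motif under a sticky order-1 chain matches the empirical start
        frequency in a million-step simulated chain within 3 SE."""
        rows = {
            "A": [0.7, 0.1, 0.1, 0.1],
            "C": [0.4, 0.2, 0.2, 0.2],
            "G": [0.4, 0.2, 0.2, 0.2],
            "T": [0.1, 0.1, 0.1, 0.7],
        }
        trans = {
            (a, "ACGT"[j]): rows[a][j] for a in "ACGT" for j in range(4)
        }
        model = build_background(
            {s: 0.25 for s in "ACGT"}, order=1, transitions=trans
        )
        motif = "AAT"
        p = stationary_occurrence_probability(model, motif)

        rng = np.random.default_rng(2024)
        n_steps = 1_000_000
        t = model.transition_matrix()
        cum = np.cumsum(t, axis=1)
        pi = stationary_distribution(model)
        chain = np.empty(n_steps, dtype=np.int8)
        chain[0] = rng.choice(4, p=pi)
        u = rng.random(n_steps)
        for i in range(1, n_steps):
            chain[i] = np.searchsorted(cum[chain[i - 1]], u[i])
        code = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in motif])
        m = len(motif)
        hits = np.ones(n_steps - m + 1, dtype=bool)
        for k in range(m):
            hits &= chain[k : n_steps - m + 1 + k] == code[k]
        n_pos = n_steps - m + 1
        se = math.sqrt(n_pos * p * (1 - p))
        assert abs(hits.sum() - n_pos * p) < 3 * se


class TestClumpability:
    @pytest.mark.parametrize(
        "motif,expected",
        [
            ("AC", False),
            ("ACA", True),   # border "A"
            ("ACCA", True),  # border "A"
            ("CCAA", False),
            ("AAAA", True),
            ("ACGT", False),
        ],
    )
    def test_examples(self, motif, expected):
        assert is_clumpable(motif) is expected

    def test_empty_motif_rejected(self):
        with pytest.raises(MotifValidationError):
            is_clumpable("")

    @settings(derandomize=True, max_examples=300)
    @given(motif_strings)
    def test_agrees_with_brute_force(self, motif):
        brute = any(
            motif[:L] == motif[-L:] for L in range(1, len(motif))
        )
        assert is_clumpable(motif) == brute


class TestSurrogate:
    def test_clumpable_anagram_replaced(self, equi_model):
        surrogate, method = non_clumpable_surrogate("ACCA", equi_model)
        assert method == "anagram"
        assert not is_clumpable(surrogate)
        assert sorted(surrogate) == sorted("ACCA")

    def test_homopolymer_falls_back_to_end_replacement(self, equi_model):
        surrogate, method = non_clumpable_surrogate("AAAA", equi_model)
        assert method == "end_replacement"
        assert not is_clumpable(surrogate)
        # replacement symbol must have equal frequency under the model
        assert motif_probability(equi_model, surrogate) == motif_probability(
            equi_model, "AAAA"
        )

    def test_homopolymer_unique_frequency_fails(self):
        model = build_background({"A": 0.4, "C": 0.1, "G": 0.2, "T": 0.3})
        surrogate, method = non_clumpable_surrogate("AAAA", model)
        assert surrogate is None and method == "failed"

    @settings(derandomize=True, max_examples=200)
    @given(motif=st.text(alphabet="ACGT", min_size=2, max_size=10))
    def test_surrogate_never_clumpable_same_probability(self, equi_model, motif):
        if not is_clumpable(motif):
            return
        surrogate, method = non_clumpable_surrogate(motif, equi_model)
        assert method in ("anagram", "end_replacement")
        assert not is_clumpable(surrogate)
        assert motif_probability(equi_model, surrogate) == pytest.approx(
            motif_probability(equi_model, motif), rel=1e-13
        )

    def test_query_routes_clumpable_through_surrogate(self, equi_model):
        query = MotifQuery.from_sequence("ACCA", equi_model)
        assert query.clumpable
        assert query.surrogate is not None
        assert not is_clumpable(query.analyzed_sequence)
        plain = MotifQuery.from_sequence("acgt", equi_model)
        assert plain.sequence == "ACGT" and not plain.clumpable
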