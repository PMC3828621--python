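"""Entropy and KL divergence: hand-arithmetic oracles and distribution properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from designvar.msa_io import Alignment, CountMatrix, build_site_map, CANONICAL_AA
from designvar.site_statistics import (
    FrequencyProfile,
    LN20,
    kl_divergence,
    mean_entropy,
    per_protein_mean,
    rank_ordered_kl,
    site_entropy,
    site_frequencies,
    split_half_control,
)

from conftest import random_pseudocounted_profiles


def counts_from(d: dict[str, int]) -> CountMatrix:
    row = np.zeros((1, 20), dtype=np.int64)
    for aa, n in d.items():
        row[0, CANONICAL_AA.index(aa)] = n
    return CountMatrix(row, row.sum(axis=1), np.array([1]))


def naive_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Independent 20-term loop oracle for a single site."""
    total = 0.0
    for j in range(20):
        if p[j] > 0:
            total += p[j] * np.log(p[j] / q[j])
    return total


def naive_rank_kl(p: np.ndarray, q: np.ndarray) -> float:
    ps = sorted(p, reverse=True)
    qs = sorted(q, reverse=True)
    total = 0.0
    for a, b in zip(ps, qs):
        if a > 0:
            total += a * np.log(a / b)
    return total


class TestSiteFrequencies:
    def test_pseudocount_hand_arithmetic(self):
        # counts {A:3}: p_A = 3.05/4, every other = 0.05/4
        prof = site_frequencies(counts_from({"A": 3}), pseudocount=True)
        a = CANONICAL_AA.index("A")
        assert prof.freqs[0, a] == pytest.approx(0.7625, abs=1e-12)
        others = np.delete(prof.freqs[0], a)
        assert np.allclose(others, 0.0125, atol=1e-12)

    def test_one_of_each_residue_pseudocounts_to_uniform(self):
        prof = site_frequencies(
            counts_from({aa: 1 for aa in CANONICAL_AA}), pseudocount=True
        )
        assert np.allclose(prof.freqs, 0.05, atol=1e-12)

    def test_plain_normalization(self):
        prof = site_frequencies(counts_from({"L": 10}), pseudocount=False)
        assert prof.freqs[0, CANONICAL_AA.index("L")] == 1.0

    def test_zero_total_site_rejected(self):
        cm = CountMatrix(np.zeros((1, 20), int), np.zeros(1, int), np.array([1]))
        with pytest.raises(ValueError):
            site_frequencies(cm)


class TestSiteEntropy:
    def test_single_residue_column_is_zero(self):
        prof = site_frequencies(counts_from({"G": 5}))
        assert site_entropy(prof).values[0] == 0.0

    def test_uniform_is_ln20(self):
        prof = FrequencyProfile(np.full((1, 20), 0.05), pseudocounted=False)
        assert site_entropy(prof).values[0] == pytest.approx(LN20, abs=1e-9)

    def test_two_equal_residues_give_ln2(self):
        prof = site_frequencies(counts_from({"I": 5, "L": 5}))
        assert site_entropy(prof).values[0] == pytest.approx(np.log(2), abs=1e-12)

    def test_mean_entropy_matches_sitewise_sum(self):
        rng = np.random.default_rng(42)
        p, _ = random_pseudocounted_profiles(rng, 50)
        ev = site_entropy(p)
        by_hand = sum(-sum(x * np.log(x) for x in row if x > 0) for row in p.freqs) / 50
        assert mean_entropy(ev) == pytest.approx(by_hand, abs=1e-12)

    def test_mean_of_empty_vector_rejected(self):
        from designvar.site_statistics import EntropyVector

        with pytest.raises(ValueError):
            mean_entropy(EntropyVector(np.array([])))


class TestKLDivergence:
    def test_identical_profiles_give_zero(self):
        rng = np.random.default_rng(0)
        p, _ = random_pseudocounted_profiles(rng, 10)
        assert np.allclose(kl_divergence(p, p).values, 0.0, atol=1e-15)

    def test_against_naive_loop_oracle(self):
        # natural {I:10, L:7, V:3} vs designed {A:10, V:7, I:3}, 20 seqs each
        q = site_frequencies(counts_from({"I": 10, "L": 7, "V": 3}), pseudocount=True)
        p = site_frequencies(counts_from({"A": 10, "V": 7, "I": 3}), pseudocount=True)
        expected = naive_kl(p.freqs[0], q.freqs[0])
        assert kl_divergence(p, q).values[0] == pytest.approx(expected, abs=1e-12)
        assert expected > 0

    def test_zero_in_reference_rejected(self):
        p = site_frequencies(counts_from({"A": 2}), pseudocount=True)
        q = site_frequencies(counts_from({"A": 2}), pseudocount=False)
        with pytest.raises(ValueError, match="pseudocount"):
            kl_divergence(p, q)

    def test_not_silently_symmetrized(self):
        q = site_frequencies(counts_from({"I": 10, "L": 7, "V": 3}), pseudocount=True)
        p = site_frequencies(counts_from({"A": 18, "V": 2}), pseudocount=True)
        assert kl_divergence(p, q).values[0] != pytest.approx(
            kl_divergence(q, p).values[0]
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_gibbs_inequality_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        p, q = random_pseudocounted_profiles(rng, 5)
        assert (kl_divergence(p, q).values >= 0).all()


class TestRankOrderedKL:
    def test_worked_shape_example_is_zero(self):
        """Same sorted frequencies under different residue identities -> 0."""
        q = site_frequencies(counts_from({"I": 10, "L": 7, "V": 3}), pseudocount=True)
        p = site_frequencies(counts_from({"A": 10, "V": 7, "I": 3}), pseudocount=True)
        assert rank_ordered_kl(p, q).values[0] == 0.0

    def test_against_naive_sorted_oracle(self):
        q = site_frequencies(counts_from({"F": 7, "Y": 3}), pseudocount=True)
        p = site_frequencies(counts_from({"K": 6, "R": 4}), pseudocount=True)
        expected = naive_rank_kl(p.freqs[0], q.freqs[0])
        assert rank_ordered_kl(p, q).values[0] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_invariant_under_independent_relabelings(self, seed):
        rng = np.random.default_rng(seed)
        p, q = random_pseudocounted_profiles(rng, 5)
        base = rank_ordered_kl(p, q).values
        perm_p, perm_q = rng.permutation(20), rng.permutation(20)
        p2 = FrequencyProfile(p.freqs[:, perm_p], pseudocounted=True)
        q2 = FrequencyProfile(q.freqs[:, perm_q], pseudocounted=True)
        assert np.allclose(rank_ordered_kl(p2, q2).values, base, atol=1e-12)
        # standard KL is NOT invariant under such relabelings in general
        assert not np.allclose(
            kl_divergence(p2, q2).values, kl_divergence(p, q).values, atol=1e-9
        )

    def test_oracle_equivalence_many_random_profiles(self):
        rng = np.random.default_rng(7)
        p, q = random_pseudocounted_profiles(rng, 1000)
        kl = kl_divergence(p, q).values
        rkl = rank_ordered_kl(p, q).values
        for i in range(1000):
            assert kl[i] == pytest.approx(naive_kl(p.freqs[i], q.freqs[i]), abs=1e-12)
            assert rkl[i] == pytest.approx(
                naive_rank_kl(p.freqs[i], q.freqs[i]), abs=1e-12
            )


class TestPerProteinMean:
    def test_hand_means(self):
        from designvar.site_statistics import DivergenceVector

        assert per_protein_mean(DivergenceVector(np.zeros(3), "standard")) == 0.0
        assert per_protein_mean(
            DivergenceVector(np.array([0.2, 0.4]), "standard")
        ) == pytest.approx(0.3)
        rng = np.random.default_rng(3)
        vals = rng.random(30)
        assert per_protein_mean(
            DivergenceVector(vals, "standard")
        ) == pytest.approx(sum(vals) / 30, abs=1e-12)


class TestSplitHalfControl:
    def _uniform_alignment(self, n=10, L=8):
        return Alignment(
            [(f"s{i}", "ACDEFGHI"[:L]) for i in range(n)], "s0", "natural"
        )

    def test_identical_sequences_give_zero(self):
        aln = self._uniform_alignment()
        assert split_half_control(aln, seed=3) == pytest.approx(0.0, abs=1e-15)

    def test_deterministic_under_seed(self, default_scenario):
        aln = default_scenario["natural"]
        smap = build_site_map(aln)
        a = split_half_control(aln, smap, seed=5)
        b = split_half_control(aln, smap, seed=5)
        assert a == b
        assert split_half_control(aln, smap, seed=6) != a

    def test_too_few_records_rejected(self):
        aln = Alignment([("a", "AC"), ("b", "AC"), ("c", "AC")], "a")
        with pytest.raises(ValueError):
            split_half_control(aln)

    def test_control_below_wrong_temperature_design_kl(self, default_scenario):
        """Natural-vs-natural divergence sits far below designed-vs-natural."""
        from designvar.msa_io import column_counts

        natural = default_scenario["natural"]
        smap = build_site_map(natural)
        q = site_frequencies(column_counts(natural, smap), pseudocount=True)
        control = split_half_control(natural, smap, seed=1)
        design = default_scenario["designs"][2.4]  # clearly wrong temperature
        p = site_frequencies(column_counts(design, smap), pseudocount=True)
        assert control < per_protein_mean(kl_divergence(p, q))
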