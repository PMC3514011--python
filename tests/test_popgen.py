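"""Diversity indices, Tajima's D and its simulated null, AMOVA."""

import numpy as np
import pytest

from thermoclade import (
    AlignedSeqSet,
    amova,
    diversity_indices,
    pairwise_k2p,
    pairwise_phi_st,
    tajima_null_test,
    tajimas_d,
)
from thermoclade.errors import ConfigurationError, DataError, DegenerateDesignError
from thermoclade.popgen import simulate_null_d

import oracles
from conftest import mutate, related_alignment


class TestDiversityIndices:
    def test_two_sequence_toy(self):
        seqs = AlignedSeqSet([("a", "p", "ACGTACGTAA"), ("b", "p", "ACGTACGTTT")])
        idx = diversity_indices(seqs)
        assert (idx.s, idx.k) == (2, 2)
        assert idx.pi == pytest.approx(0.2)
        assert idx.s_over_n == pytest.approx(1.0)
        assert idx.d is None  # n < 4

    def test_monomorphic_sample(self):
        seqs = AlignedSeqSet([(f"s{i}", "p", "ACGT" * 5) for i in range(6)])
        idx = diversity_indices(seqs)
        assert (idx.s, idx.k, idx.pi, idx.d) == (0, 1, 0.0, None)

    def test_matches_enumeration_oracle(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=80))
        seqs = AlignedSeqSet(
            [(f"s{i}", "p", mutate(base, rng.choice(80, size=i, replace=False), rng))
             for i in range(6)]
        )
        idx = diversity_indices(seqs)
        s, pi, _ = oracles.pi_and_s(seqs.sequences)
        assert idx.s == s
        assert idx.pi == pytest.approx(pi, abs=1e-12)

    def test_requires_two_sequences(self):
        with pytest.raises(DataError):
            diversity_indices(AlignedSeqSet([("a", "p", "ACGT")]))


class TestTajimasD:
    def test_matches_formula_oracle(self, rng):
        for n in (4, 7, 12):
            base = "".join(rng.choice(list("ACGT"), size=60))
            seqs = AlignedSeqSet(
                [(f"s{i}", "p",
                  mutate(base, rng.choice(60, size=rng.integers(0, 4), replace=False), rng))
                 for i in range(n)]
            )
            try:
                d = tajimas_d(seqs)
            except DataError:
                continue  # all mutations hit the same state: S = 0
            s, _, pi_total = oracles.pi_and_s(seqs.sequences)
            assert d == pytest.approx(oracles.tajimas_d(pi_total, s, n), abs=1e-10)

    def test_column_and_label_invariance(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=50))
        seqs = AlignedSeqSet(
            [(f"s{i}", "p", mutate(base, rng.choice(50, size=2, replace=False), rng))
             for i in range(6)]
        )
        d = tajimas_d(seqs)
        perm = rng.permutation(50)
        shuffled_cols = AlignedSeqSet(
            [(r.label, r.population, "".join(r.sequence[j] for j in perm))
             for r in seqs]
        )
        shuffled_rows = AlignedSeqSet(list(reversed(seqs.records)))
        assert tajimas_d(shuffled_cols) == pytest.approx(d, abs=1e-12)
        assert tajimas_d(shuffled_rows) == pytest.approx(d, abs=1e-12)

    def test_sample_size_and_s_preconditions(self):
        small = AlignedSeqSet([("a", "p", "AAAA"), ("b", "p", "AAAT"), ("c", "p", "AATT")])
        with pytest.raises(DataError):
            tajimas_d(small)
        mono = AlignedSeqSet([(f"s{i}", "p", "ACGT") for i in range(5)])
        with pytest.raises(DataError):
            tajimas_d(mono)


class TestTajimaNullTest:
    def _two_clade_mixture(self):
        # balanced mixture of two diverged haplotype clusters: strongly
        # positive D, like an admixed harbour sample
        a = "A" * 30 + "ACGT" * 10
        b = "G" * 30 + "ACGT" * 10
        return AlignedSeqSet(
            [(f"a{i}", "p", a) for i in range(5)]
            + [(f"b{i}", "p", b) for i in range(5)]
        )

    def test_positive_d_lands_in_upper_tail(self):
        res = tajima_null_test(self._two_clade_mixture(), replicates=300, seed=11)
        assert res.d > 1.5
        assert res.p_upper < 0.05
        assert res.p_lower > 0.95

    def test_seed_determinism_and_tie_rule(self):
        seqs = self._two_clade_mixture()
        r1 = tajima_null_test(seqs, replicates=200, seed=3)
        r2 = tajima_null_test(seqs, replicates=200, seed=3)
        assert (r1.p_upper, r1.p_lower) == (r2.p_upper, r2.p_lower)
        assert r1.p_upper + r1.p_lower >= 1.0
        assert 0 < r1.p_upper <= 1 and 0 < r1.p_lower <= 1

    def test_replicate_floor(self):
        with pytest.raises(ConfigurationError):
            tajima_null_test(self._two_clade_mixture(), replicates=50, seed=1)

    def test_null_draw_at_median_gives_half_p(self):
        # the p of the null median against the null itself is ~0.5 by
        # construction of the tail definition
        rng = np.random.default_rng(0)
        sims = np.array([simulate_null_d(10, 5, rng) for _ in range(2000)])
        med = np.median(sims)
        p_upper = (1 + (sims >= med).sum()) / (len(sims) + 1)
        assert p_upper == pytest.approx(0.5, abs=0.03)


def _padded(block_rows):
    pad = "ACGT" * 15
    return AlignedSeqSet([(l, "p", s + pad) for l, s in block_rows])


class TestAMOVA:
    def test_fixed_difference_gives_phi_one(self):
        seqs = _padded(
            [(f"x{i}", "A" * 6) for i in range(3)]
            + [(f"y{i}", "A" * 5 + "G") for i in range(3)]
        )
        pops = {l: l[0] for l in seqs.labels}
        res = amova(pairwise_k2p(seqs), pops, permutations=199, seed=1)
        assert res.phi_st == pytest.approx(1.0)
        assert res.variance_components[2] == pytest.approx(0.0)

    def test_one_level_matches_algebraic_oracle(self, rng):
        seqs = related_alignment(6, 120, rng)
        pops = {l: ("P1" if i < 3 else "P2") for i, l in enumerate(seqs.labels)}
        dist = pairwise_k2p(seqs)
        res = amova(dist, pops, permutations=120, seed=0)
        sigma_a, sigma_w, phi = oracles.amova_one_level(
            (dist.values**2).tolist(), [pops[l] for l in dist.labels]
        )
        assert res.variance_components[1] == pytest.approx(sigma_a, abs=1e-9)
        assert res.variance_components[2] == pytest.approx(sigma_w, abs=1e-9)
        assert res.phi_st == pytest.approx(phi, abs=1e-9)

    def test_two_level_matches_algebraic_oracle(self, rng):
        seqs = related_alignment(12, 150, rng)
        pops = {l: f"P{i // 3}" for i, l in enumerate(seqs.labels)}
        groups = {"P0": "G0", "P1": "G0", "P2": "G1", "P3": "G1"}
        dist = pairwise_k2p(seqs)
        res = amova(dist, pops, groups, permutations=120, seed=0)
        exp = oracles.amova_two_level(
            (dist.values**2).tolist(), [pops[l] for l in dist.labels], groups
        )
        for got, want in zip(res.variance_components, exp[:3]):
            assert got == pytest.approx(want, abs=1e-9)
        assert res.phi_ct == pytest.approx(exp[3], abs=1e-9)
        assert res.phi_sc == pytest.approx(exp[4], abs=1e-9)
        assert res.phi_st == pytest.approx(exp[5], abs=1e-9)

    def test_components_sum_to_total_ss_partition(self, rng):
        # the three SS terms must decompose the total sum of squared
        # deviations exactly; checked through the df-weighted identity
        seqs = related_alignment(12, 150, rng)
        pops = {l: f"P{i // 3}" for i, l in enumerate(seqs.labels)}
        groups = {"P0": "G0", "P1": "G0", "P2": "G1", "P3": "G1"}
        dist = pairwise_k2p(seqs)
        d2 = dist.values**2
        n = dist.n
        ss_total = d2.sum() / (2 * n)
        ss_wp = sum(
            d2[np.ix_(m, m)].sum() / (2 * len(m))
            for m in [[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11]]
        )
        ss_wg = sum(
            d2[np.ix_(m, m)].sum() / (2 * len(m))
            for m in [[0, 1, 2, 3, 4, 5], [6, 7, 8, 9, 10, 11]]
        )
        assert (ss_total - ss_wg) + (ss_wg - ss_wp) + ss_wp == pytest.approx(
            ss_total, abs=1e-9
        )

    def test_random_labels_give_small_phi(self, rng):
        seqs = related_alignment(16, 200, rng)
        pops = {l: f"P{i % 2}" for i, l in enumerate(rng.permutation(seqs.labels))}
        res = amova(pairwise_k2p(seqs), pops, permutations=199, seed=2)
        assert abs(res.phi_st) < 0.2
        assert res.p_st > 0.05

    def test_degenerate_designs_rejected(self, rng):
        seqs = related_alignment(6, 100, rng)
        dist = pairwise_k2p(seqs)
        pops = {l: ("P1" if i < 3 else "P2") for i, l in enumerate(seqs.labels)}
        with pytest.raises(DegenerateDesignError):
            amova(dist, {l: "P1" for l in seqs.labels}, permutations=100)
        with pytest.raises(DegenerateDesignError):
            amova(dist, pops, groups={"P1": "G", "P2": "G"}, permutations=100)
        zero = AlignedSeqSet([(f"s{i}", "p", "ACGT" * 10) for i in range(6)])
        zdist = pairwise_k2p(zero)
        with pytest.raises(DegenerateDesignError):
            amova(zdist, {l: ("P1" if i < 3 else "P2")
                          for i, l in enumerate(zero.labels)},
                  permutations=100)

    def test_seed_reproducibility(self, rng):
        seqs = related_alignment(8, 150, rng)
        pops = {l: f"P{i % 2}" for i, l in enumerate(seqs.labels)}
        dist = pairwise_k2p(seqs)
        r1 = amova(dist, pops, permutations=150, seed=9)
        r2 = amova(dist, pops, permutations=150, seed=9)
        assert r1.p_st == r2.p_st
        assert 1 / 151 <= r1.p_st <= 1.0


class TestPairwisePhiST:
    def test_split_population_phi_near_zero(self, rng):
        seqs = related_alignment(12, 200, rng)
        pops = {l: f"P{i % 2}" for i, l in enumerate(seqs.labels)}
        out = pairwise_phi_st(pairwise_k2p(seqs), pops, permutations=99, seed=4)
        assert len(out) == 1
        assert abs(out[0]["phi_st"]) < 0.25

    def test_monomorphic_distinct_pops_phi_one(self):
        seqs = _padded(
            [(f"x{i}", "AAAA") for i in range(3)]
            + [(f"y{i}", "AAGG") for i in range(3)]
        )
        pops = {l: l[0] for l in seqs.labels}
        out = pairwise_phi_st(pairwise_k2p(seqs), pops, permutations=99, seed=4)
        assert out[0]["phi_st"] == pytest.approx(1.0)

    def test_entries_match_two_population_amova(self, rng):
        seqs = related_alignment(9, 150, rng)
        pops = {l: f"P{i // 3}" for i, l in enumerate(seqs.labels)}
        dist = pairwise_k2p(seqs)
        out = pairwise_phi_st(dist, pops, permutations=99, seed=4)
        assert len(out) == 3
        for rec in out:
            keep = [l for l in dist.labels if pops[l] in (rec["pop_a"], rec["pop_b"])]
            direct = amova(
                dist.submatrix(keep), {l: pops[l] for l in keep},
                permutations=99, seed=0,
            )
            assert rec["phi_st"] == pytest.approx(direct.phi_st, abs=1e-12)
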