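"""Codon counting, GC, MILC, shuffled-null backgrounds, Ψ and filters."""

import numpy as np
import pytest

import cubgrowth as cg
from cubgrowth._genetic_code import codon_index, genetic_code
from cubgrowth.codonstats import (
    BackgroundFrequencies,
    background_from_counts,
    count_codons,
    pooled_counts,
    self_shuffle_background,
    weighted_median,
)
from tests._oracle import (
    ALL_FAMILY_CODONS,
    FAMILIES,
    count_codons_brute,
    gc_brute,
    milc_brute,
    weighted_median_brute,
)
from tests.conftest import random_background, random_gene


def _bg_as_dict(bg):
    return {c: bg.freqs[codon_index(c)] for c in ALL_FAMILY_CODONS}


class TestCountCodons:
    def test_direct_read_off(self):
        assert count_codons("ATGGCTGCC").as_dict() == {"ATG": 1, "GCT": 1, "GCC": 1}
        assert count_codons("ATGGCTGCC").total_codons == 3

    def test_ambiguous_codons_skipped_and_reported(self):
        table = count_codons("GCTNCTGCC")
        assert table.as_dict() == {"GCT": 1, "GCC": 1}
        assert table.skipped == 1

    def test_random_sequences_match_brute_force_recount(self, rng):
        for _ in range(20):
            gene = random_gene(rng, n_codons=300)
            expected, skipped = count_codons_brute(gene.sequence)
            table = count_codons(gene.sequence)
            assert table.as_dict() == expected
            assert table.total_codons == 300 - skipped

    def test_too_short_sequence_errors(self):
        with pytest.raises(ValueError, match="too short"):
            count_codons("AT")


class TestGcContent:
    def test_symmetric_composition(self):
        assert cg.gc_content([cg.GeneRecord("g", "ATGCATGC")]) == 0.5
        assert cg.gc_content([cg.GeneRecord("g", "GGGCCC")]) == 1.0

    def test_weighted_mean(self):
        genes = [
            cg.GeneRecord("a", "AAA", weight=3.0),
            cg.GeneRecord("b", "GGG", weight=1.0),
        ]
        assert cg.gc_content(genes, weighted=True) == pytest.approx(0.25)
        assert cg.gc_content(genes, weighted=True) == pytest.approx(
            gc_brute([("AAA", 3.0), ("GGG", 1.0)])
        )

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError, match="unambiguous"):
            cg.gc_content([cg.GeneRecord("g", "NNNNNN")])

    def test_concatenation_equals_length_weighted_mean(self, rng):
        genes = [random_gene(rng, n_codons=n, gene_id=f"g{n}") for n in (50, 120, 300)]
        concat = cg.GeneRecord("cat", "".join(g.sequence for g in genes))
        per_gene = [cg.gc_content([g]) for g in genes]
        lengths = [len(g.sequence) for g in genes]
        expected = float(np.average(per_gene, weights=lengths))
        assert cg.gc_content([concat]) == pytest.approx(expected, abs=1e-12)


class TestBackgroundFromCounts:
    def test_family_normalization(self):
        counts = np.zeros(64, dtype=np.int64)
        counts[codon_index("GCT")] = 3
        counts[codon_index("GCC")] = 1
        bg = background_from_counts(counts)
        assert bg.freqs[codon_index("GCT")] == pytest.approx(0.75)
        assert bg.freqs[codon_index("GCC")] == pytest.approx(0.25)
        # family with zero total omitted
        assert bg.freqs[codon_index("TTT")] == 0.0

    def test_uniform_counts_give_uniform_frequencies(self):
        counts = np.zeros(64, dtype=np.int64)
        for c in FAMILIES["Ala"]:
            counts[codon_index(c)] = 7
        bg = background_from_counts(counts)
        for c in FAMILIES["Ala"]:
            assert bg.freqs[codon_index(c)] == pytest.approx(0.25)

    def test_pooled_counts_equal_concatenation(self, rng):
        g1, g2 = random_gene(rng, 80, "a"), random_gene(rng, 140, "b")
        pooled = background_from_counts(pooled_counts([g1, g2]))
        concat = background_from_counts(
            count_codons(g1.sequence + g2.sequence)
        )
        np.testing.assert_allclose(pooled.freqs, concat.freqs, atol=1e-15)

    def test_within_family_frequencies_sum_to_one(self, rng):
        bg = random_background(rng)
        code = genetic_code()
        for idx in code.family_codon_idx:
            assert bg.freqs[idx].sum() == pytest.approx(1.0, abs=1e-9)


class TestMilc:
    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            gene = random_gene(rng, n_codons=int(rng.integers(30, 300)))
            bg = random_background(rng)
            ours = cg.milc(count_codons(gene.sequence), bg)
            ref = milc_brute(gene.sequence, _bg_as_dict(bg))
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_equals_minus_c_when_gene_matches_background(self):
        # gene: 2x each Ala codon and 3x each Phe codon; background = own freqs
        seq = "".join(c * 2 for c in FAMILIES["Ala"]) + "".join(
            c * 3 for c in FAMILIES["Phe"]
        )
        bg = background_from_counts(count_codons(seq))
        length = 8 + 6
        c_term = ((4 - 1) + (2 - 1)) / length - 0.5
        assert cg.milc(count_codons(seq), bg) == pytest.approx(-c_term, abs=1e-12)

    def test_single_family_hand_example(self):
        # 4 Ala codons, all GCT, uniform background: M = 8 ln 4, L = 4, C = 0.25
        counts = count_codons("GCTGCTGCTGCT")
        freqs = np.zeros(64)
        bg_counts = np.zeros(64, dtype=np.int64)
        for c in FAMILIES["Ala"]:
            freqs[codon_index(c)] = 0.25
            bg_counts[codon_index(c)] = 100
        bg = BackgroundFrequencies(freqs=freqs, source="sample-wide", counts=bg_counts)
        expected = 2.0 * np.log(4.0) - 0.25
        assert cg.milc(counts, bg) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(2.5226, abs=1e-4)

    def test_invariant_under_codon_permutation(self, rng):
        gene = random_gene(rng, 120)
        bg = random_background(rng)
        codons = [gene.sequence[i : i + 3] for i in range(0, len(gene.sequence), 3)]
        rng.shuffle(codons)
        shuffled = "".join(codons)
        assert cg.milc(count_codons(gene.sequence), bg) == pytest.approx(
            cg.milc(count_codons(shuffled), bg), abs=1e-12
        )

    def test_only_single_codon_families_errors(self, rng):
        bg = random_background(rng)
        with pytest.raises(ValueError, match="no informative codons"):
            cg.milc(count_codons("ATGTGG" * 10), bg)

    def test_zero_background_frequency_uses_pseudocount(self, rng):
        counts = np.zeros(64, dtype=np.int64)
        counts[codon_index("GCT")] = 10  # GCC absent from background
        bg = background_from_counts(counts)
        gene_counts = count_codons("GCC" * 5 + "GCT" * 5)
        with pytest.warns(cg.CubgrowthWarning, match="pseudocount"):
            value = cg.milc(gene_counts, bg)
        assert np.isfinite(value)


class TestSelfShuffleBackground:
    def test_preserves_nucleotide_multiset_and_determinism(self, rng):
        gene = random_gene(rng, 100)
        a = self_shuffle_background(gene, n_shuffles=20, seed=7)
        b = self_shuffle_background(gene, n_shuffles=20, seed=7)
        np.testing.assert_array_equal(a.freqs, b.freqs)
        # pooled counts use exactly n_shuffles * n_codons codons
        assert a.counts.sum() == 20 * 100

    def test_invalid_shuffle_count_errors(self, rng):
        with pytest.raises(ValueError, match="n_shuffles"):
            self_shuffle_background(random_gene(rng, 50), n_shuffles=0)

    def test_converges_to_iid_composition_distribution(self, rng):
        gene = random_gene(rng, 200)
        bg = self_shuffle_background(gene, n_shuffles=10_000, seed=3)
        nt = np.array(list(gene.sequence))
        p = {b: float((nt == b).mean()) for b in "ACGT"}
        code = genetic_code()
        from cubgrowth._genetic_code import CODON_STRINGS

        for idx in code.family_codon_idx:
            raw = np.array(
                [np.prod([p[ch] for ch in CODON_STRINGS[i]]) for i in idx]
            )
            analytic = raw / raw.sum()
            np.testing.assert_allclose(bg.freqs[idx], analytic, atol=0.01)

    def test_short_gene_milc_noisier_than_long_windows(self, rng):
        # the short-gene degradation regime: 60-bp chunks of a gene give far
        # more variable MILC estimates than 600-bp chunks
        ratios = []
        for k in range(10):
            gene = random_gene(rng, 1000, gene_id=f"g{k}")
            bg = background_from_counts(count_codons(gene.sequence))
            var = {}
            for w in (60, 600):
                vals = [
                    cg.milc(count_codons(gene.sequence[s : s + w]), bg)
                    for s in range(0, 3000 - w + 1, w)
                ]
                var[w] = np.var(vals)
            ratios.append(var[60] / var[600])
        assert np.median(ratios) > 1.0
        assert np.mean(ratios) > 1.0


class TestWeightedMedian:
    def test_equal_weights_reduce_to_plain_median(self, rng):
        for n in (3, 4, 7, 10):
            x = rng.normal(size=n)
            assert weighted_median(x) == pytest.approx(float(np.median(x)))

    def test_dominant_weight_wins(self):
        x = np.array([0.1, 5.0, 9.9])
        w = np.array([0.0005, 999.0, 0.0005])
        assert weighted_median(x, w) == 5.0

    def test_straddling_convention(self):
        assert weighted_median(
            np.array([0.2, 0.4, 1.0]), np.array([1.0, 1.0, 2.0])
        ) == pytest.approx(0.7)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            x = rng.normal(size=n)
            w = rng.uniform(0.1, 3.0, size=n)
            assert weighted_median(x, w) == pytest.approx(
                weighted_median_brute(list(x), list(w))
            )


class TestCubHe:
    def test_no_he_genes_errors(self, rng):
        bg = random_background(rng)
        with pytest.raises(ValueError, match="no highly expressed"):
            cg.cub_he([random_gene(rng, 100)], bg)

    def test_few_he_genes_warns(self, rng):
        genes = [random_gene(rng, 100, f"g{i}", he=True) for i in range(3)]
        bg = random_background(rng)
        with pytest.warns(cg.CubgrowthWarning, match="<10"):
            cg.cub_he(genes, bg)

    def test_weighted_median_dominance(self, rng):
        genes = [
            random_gene(rng, 100, f"g{i}", he=True, weight=w)
            for i, w in enumerate([1e-4, 1e-4, 100.0])
        ]
        bg = random_background(rng)
        dominant = cg.milc(count_codons(genes[2].sequence), bg)
        assert cg.cub_he(genes, bg, aggregate="weighted-median") == pytest.approx(
            dominant
        )


class TestIcubMean:
    def test_single_gene_equals_own_icub(self, rng):
        gene = random_gene(rng, 150)
        solo = cg.icub_mean([gene], n_shuffles=50, seed=9)
        bg = self_shuffle_background(gene, n_shuffles=50, seed=9)
        assert solo == pytest.approx(cg.milc(count_codons(gene.sequence), bg))

    def test_duplicated_list_preserves_mean(self, rng):
        gene = random_gene(rng, 150)
        one = cg.icub_mean([gene], n_shuffles=50, seed=4)
        four = cg.icub_mean([gene] * 4, n_shuffles=50, seed=4)
        assert four == pytest.approx(one, abs=0.05)  # fresh shuffles per copy

    def test_agrees_with_per_gene_loop(self, rng):
        genes = [random_gene(rng, 120, f"g{i}") for i in range(20)]
        weights = rng.uniform(0.2, 3.0, size=20)
        for g, w in zip(genes, weights):
            g.weight = float(w)
        ours = cg.icub_mean(genes, n_shuffles=30, seed=11, weighted=True)
        loop_rng = np.random.default_rng(11)
        num = den = 0.0
        for g in genes:
            bg = self_shuffle_background(g, n_shuffles=30, seed=loop_rng)
            num += g.weight * cg.milc(count_codons(g.sequence), bg)
            den += g.weight
        assert ours == pytest.approx(num / den, abs=1e-12)


class TestSampleBackgroundGenes:
    def test_exhaustion_returns_all(self, rng):
        genes = [random_gene(rng, 80, f"g{i}") for i in range(50)]
        assert len(cg.sample_background_genes(genes, k=100, seed=0)) == 50

    def test_deterministic_given_seed(self, rng):
        genes = [random_gene(rng, 80, f"g{i}") for i in range(30)]
        a = cg.sample_background_genes(genes, k=10, seed=5)
        b = cg.sample_background_genes(genes, k=10, seed=5)
        assert [g.id for g in a] == [g.id for g in b]

    def test_he_genes_rejected(self, rng):
        genes = [random_gene(rng, 80, "g0", he=True)]
        with pytest.raises(ValueError, match="exclude HE"):
            cg.sample_background_genes(genes, k=1, seed=0)

    def test_sampling_is_uniform(self, rng):
        from scipy import stats

        genes = [random_gene(rng, 30, f"g{i}") for i in range(8)]
        hits = np.zeros(8)
        for rep in range(10_000):
            for g in cg.sample_background_genes(genes, k=2, seed=rep):
                hits[int(g.id[1:])] += 1
        _, p = stats.chisquare(hits)
        assert p > 1e-3


class TestPsi:
    def test_identical_genes_give_minus_c(self, rng):
        gene = random_gene(rng, 200, he=True)
        genes = [
            cg.GeneRecord(f"g{i}", gene.sequence, is_highly_expressed=True)
            for i in range(5)
        ]
        bg = background_from_counts(count_codons(gene.sequence))
        expected = cg.milc(count_codons(gene.sequence), bg)  # = -C analytically
        assert cg.psi(genes) == pytest.approx(expected, abs=1e-12)

    def test_disjoint_two_codon_family_limit(self):
        n = 10_000
        group_a = [cg.GeneRecord(f"a{i}", "TTT" * n, is_highly_expressed=True) for i in range(2)]
        group_b = [cg.GeneRecord(f"b{i}", "TTC" * n, is_highly_expressed=True) for i in range(2)]
        value = cg.psi(group_a + group_b)
        assert value == pytest.approx(2.0 * np.log(2.0) + 0.5, abs=1e-3)
        assert value == pytest.approx(1.886, abs=1e-3)

    def test_divergent_exceeds_homogeneous(self, rng):
        shared = [random_gene(rng, 200, f"s{i}", he=True) for i in range(6)]
        base = random_gene(rng, 200, "base")
        homogeneous = [
            cg.GeneRecord(f"h{i}", base.sequence, is_highly_expressed=True)
            for i in range(6)
        ]
        assert cg.psi(shared) > cg.psi(homogeneous)

    def test_requires_two_genes(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            cg.psi([random_gene(rng, 100, he=True)])


class TestFilterGenes:
    def test_length_thresholds(self, rng):
        short = random_gene(rng, 79, "short")
        mid = random_gene(rng, 40, "mid")
        long = random_gene(rng, 120, "long")
        assert [g.id for g in cg.filter_genes([short, long], 80)] == ["long"]
        assert [g.id for g in cg.filter_genes([mid, long], 40)] == ["mid", "long"]
        assert cg.filter_genes([long], 80) == [long]

    def test_empty_result_errors_with_threshold(self, rng):
        with pytest.raises(ValueError, match="80-codon"):
            cg.filter_genes([random_gene(rng, 20)], 80)


class TestPropertyInvariants:
    """Randomized invariants (hypothesis, derandomized for CI stability)."""

    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=12),
        st.lists(st.floats(0.05, 4.0), min_size=12, max_size=12),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_weighted_median_matches_brute_force(self, values, weights):
        v = np.array(values)
        w = np.array(weights[: len(values)])
        assert weighted_median(v, w) == pytest.approx(
            weighted_median_brute(list(v), list(w))
        )

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_milc_matches_oracle_on_arbitrary_seeds(self, seed):
        r = np.random.default_rng(seed)
        gene = random_gene(r, n_codons=int(r.integers(30, 120)))
        bg = random_background(r)
        ours = cg.milc(count_codons(gene.sequence), bg)
        ref = milc_brute(gene.sequence, _bg_as_dict(bg))
        assert ours == pytest.approx(ref, abs=1e-9)
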