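import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldne.genotype_io import MISSING, GenotypeMatrix, default_samples
from ldne.ld import (
    DEFAULT_BIN_EDGES_BP,
    HaplotypeFreqs,
    LdScanStats,
    MonomorphicLocusError,
    bin_ld,
    em_haplotype_freqs,
    pairwise_ld,
    r_squared,
    two_locus_loglik,
)

from conftest import random_panel


def genotype_table(g_a, g_b):
    """3x3 table from two genotype vectors (no missing)."""
    t = np.zeros((3, 3), dtype=np.int64)
    np.add.at(t, (np.asarray(g_a), np.asarray(g_b)), 1)
    return t


def haplotype_r2(h_a, h_b):
    """Direct haplotype-count r² from phased 0/1 vectors."""
    pa, pb = h_a.mean(), h_b.mean()
    d = (h_a * h_b).mean() - pa * pb
    return d**2 / (pa * (1 - pa) * pb * (1 - pb))


tables_strategy = st.lists(
    st.integers(0, 4), min_size=9, max_size=9
).filter(lambda c: sum(c) >= 1).map(lambda c: np.array(c).reshape(3, 3))


class TestEmHaplotypeFreqs:
    def test_no_double_het_equals_counting(self, rng):
        """Without double heterozygotes every haplotype is phase-determined,
        so EM must reproduce the closed-form counting answer."""
        for _ in range(20):
            t = rng.integers(0, 5, size=(3, 3))
            t[1, 1] = 0
            if t.sum() == 0:
                continue
            h = em_haplotype_freqs(t)
            n2 = 2 * t.sum()
            k11 = 2 * t[0, 0] + t[0, 1] + t[1, 0]
            k12 = 2 * t[0, 2] + t[0, 1] + t[1, 2]
            k21 = 2 * t[2, 0] + t[2, 1] + t[1, 0]
            k22 = 2 * t[2, 2] + t[2, 1] + t[1, 2]
            assert h.p11 == pytest.approx(k11 / n2, abs=1e-9)
            assert h.p12 == pytest.approx(k12 / n2, abs=1e-9)
            assert h.p21 == pytest.approx(k21 / n2, abs=1e-9)
            assert h.p22 == pytest.approx(k22 / n2, abs=1e-9)

    def test_all_double_het_bimodal_likelihood(self):
        """A table of only double heterozygotes has a phase-symmetric,
        bimodal likelihood whose maxima are the two fully-phased solutions
        (coupling or repulsion); either one beats the D = 0 saddle point and
        both give the same r² = 1, so the multi-start EM must reach it."""
        t = np.zeros((3, 3), dtype=int)
        t[1, 1] = 20
        h = em_haplotype_freqs(t)
        assert abs(h.d) == pytest.approx(0.25, abs=1e-6)
        assert r_squared(h) == pytest.approx(1.0, abs=1e-6)
        saddle = HaplotypeFreqs(0.25, 0.25, 0.25, 0.25)
        assert two_locus_loglik(t, h) > two_locus_loglik(t, saddle)

    def test_loglik_monotone_over_iterations(self, rng):
        for _ in range(25):
            t = rng.integers(0, 6, size=(3, 3))
            if t.sum() == 0:
                continue
            _, trace = em_haplotype_freqs(t, return_trace=True)
            diffs = np.diff(trace)
            assert (diffs >= -1e-9).all(), f"likelihood decreased for table {t}"

    def test_grid_oracle_small_sample(self, rng):
        """EM likelihood must reach the profile-grid maximum (allele
        frequencies at their MLEs, p11 scanned at 1e-3 resolution)."""
        for _ in range(20):
            t = rng.integers(0, 3, size=(3, 3))
            if t.sum() < 1:
                continue
            h = em_haplotype_freqs(t)
            ll_em = two_locus_loglik(t, h)
            assert ll_em >= grid_max_loglik(t) - 1e-6


def grid_max_loglik(table, step=1e-3):
    """Profile grid search: allele frequencies fixed at their observed MLEs
    (the genotype-likelihood marginals force them), p11 scanned over its
    feasible interval."""
    t = np.asarray(table, float)
    n2 = 2 * t.sum()
    pa = (2 * t[0].sum() + t[1].sum()) / n2  # freq of allele A1
    pb = (2 * t[:, 0].sum() + t[:, 1].sum()) / n2
    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    best = -np.inf
    for p11 in np.arange(lo, hi + step / 2, step):
        p11 = min(max(p11, lo), hi)
        h = HaplotypeFreqs(p11, pa - p11, pb - p11, 1 - pa - pb + p11)
        best = max(best, two_locus_loglik(t, h))
    return best


class TestRSquared:
    def test_complete_ld(self):
        assert r_squared(HaplotypeFreqs(0.5, 0.0, 0.0, 0.5)) == pytest.approx(1.0)

    def test_independence(self):
        assert r_squared(HaplotypeFreqs(0.25, 0.25, 0.25, 0.25)) == pytest.approx(0.0)

    def test_monomorphic_signalled(self):
        with pytest.raises(MonomorphicLocusError):
            r_squared(HaplotypeFreqs(0.5, 0.5, 0.0, 0.0))

    def test_equals_squared_indicator_correlation(self, rng):
        """r² is the squared correlation of allelic indicators under the
        haplotype distribution (checked numerically)."""
        for _ in range(20):
            p = rng.dirichlet([1, 1, 1, 1])
            h = HaplotypeFreqs(*p)
            if min(h.pA1, h.pA2, h.pB1, h.pB2) < 1e-3:
                continue
            # indicators over the 4 haplotypes with probabilities p
            x_a = np.array([0, 0, 1, 1])
            x_b = np.array([0, 1, 0, 1])
            mean_a = (p * x_a).sum()
            mean_b = (p * x_b).sum()
            cov = (p * (x_a - mean_a) * (x_b - mean_b)).sum()
            var_a = (p * (x_a - mean_a) ** 2).sum()
            var_b = (p * (x_b - mean_b) ** 2).sum()
            assert r_squared(h) == pytest.approx(cov**2 / (var_a * var_b), abs=1e-12)

    @given(tables_strategy)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_label_and_locus_swap_invariance(self, t):
        def r2_of(table):
            h = em_haplotype_freqs(table)
            try:
                return r_squared(h)
            except MonomorphicLocusError:
                return None

        base = r2_of(t)
        flipped_a = r2_of(t[::-1, :])  # swap allele labels at locus A
        flipped_b = r2_of(t[:, ::-1])
        swapped = r2_of(t.T)  # swap the two loci
        for other in (flipped_a, flipped_b, swapped):
            if base is None:
                assert other is None
            else:
                assert other == pytest.approx(base, abs=1e-7)


class TestPairwiseLd:
    def test_distance_cutoff(self):
        codes = np.array(
            [[0, 0, 0], [1, 1, 1], [2, 2, 2], [1, 0, 2], [0, 2, 1]], dtype=np.int8
        )
        snp_map = pd.DataFrame(
            {
                "chrom": "1",
                "snp_id": ["a", "b", "c"],
                "genetic_pos": 0.0,
                "physical_pos": [1, 5_000_001, 20_000_001],
                "allele_a": "A",
                "allele_b": "C",
            }
        )
        geno = GenotypeMatrix(codes, default_samples(5))
        pairs = list(pairwise_ld(geno, snp_map))
        assert len(pairs) == 1
        assert (pairs[0].snp_i, pairs[0].snp_j) == ("a", "b")
        assert pairs[0].distance_bp == 5_000_000

    def test_duplicated_column_gives_r2_one(self, rng):
        col = rng.integers(0, 3, size=30).astype(np.int8)
        while len(np.unique(col)) < 2:
            col = rng.integers(0, 3, size=30).astype(np.int8)
        codes = np.stack([col, col], axis=1)
        snp_map = pd.DataFrame(
            {
                "chrom": "1",
                "snp_id": ["a", "b"],
                "genetic_pos": 0.0,
                "physical_pos": [100, 200],
                "allele_a": "A",
                "allele_b": "C",
            }
        )
        pairs = list(pairwise_ld(GenotypeMatrix(codes, default_samples(30)), snp_map))
        assert len(pairs) == 1
        assert pairs[0].r2 == pytest.approx(1.0, abs=1e-6)

    def test_pair_count_matches_brute_force(self, rng):
        geno, snp_map = random_panel(rng, n=50, m=20, missing_rate=0.05)
        max_d = 4_000_000
        stats = LdScanStats()
        pairs = list(pairwise_ld(geno, snp_map, max_distance_bp=max_d, stats=stats))

        expected = 0
        chroms = snp_map["chrom"].to_numpy()
        pos = snp_map["physical_pos"].to_numpy()
        for i, j in itertools.combinations(range(len(snp_map)), 2):
            if chroms[i] != chroms[j]:
                continue
            if 0 < abs(pos[i] - pos[j]) <= max_d:
                expected += 1
        assert stats.n_pairs + stats.n_skipped_monomorphic == expected
        assert len(pairs) == stats.n_pairs

    def test_n_used_is_pairwise_complete(self, rng):
        geno, snp_map = random_panel(rng, n=40, m=2, missing_rate=0.3)
        snp_map.loc[:, "chrom"] = "1"
        snp_map.loc[:, "physical_pos"] = [100, 200]
        pairs = list(pairwise_ld(geno, snp_map))
        if pairs:
            both = (geno.codes[:, 0] != MISSING) & (geno.codes[:, 1] != MISSING)
            assert pairs[0].n_used == both.sum()

    def test_phased_collapse_without_double_hets_exact(self, rng):
        """Collapsing phased haplotypes to genotypes and running EM must
        equal the direct haplotype-count r² whenever no double heterozygote
        is present (no phase ambiguity anywhere)."""
        checked = 0
        for _ in range(20_000):
            if checked >= 3:
                break
            h_a = rng.integers(0, 2, size=16)
            h_b = np.where(rng.random(16) < 0.9, h_a, rng.integers(0, 2, size=16))
            g_a = h_a[::2] + h_a[1::2]
            g_b = h_b[::2] + h_b[1::2]
            if np.any((g_a == 1) & (g_b == 1)):
                continue
            if len(np.unique(h_a)) < 2 or len(np.unique(h_b)) < 2:
                continue
            table = genotype_table(g_a, g_b)
            r2_em = r_squared(em_haplotype_freqs(table))
            assert r2_em == pytest.approx(haplotype_r2(h_a, h_b), abs=1e-9)
            checked += 1
        assert checked >= 3


class TestBinLd:
    @staticmethod
    def make_pairs(distances, r2s, chrom="1"):
        from ldne.ld import LdPair

        return [
            LdPair(chrom, f"s{i}", f"t{i}", int(d), float(r), 50)
            for i, (d, r) in enumerate(zip(distances, r2s))
        ]

    def test_single_pair(self):
        bins = bin_ld(self.make_pairs([5_000], [0.4]), scope="genome")
        row = bins[bins.n_pairs > 0].iloc[0]
        assert (row.bin_lo_bp, row.bin_hi_bp) == (0, 10_000)
        assert row.mean_r2 == pytest.approx(0.4)
        assert row.n_pairs == 1

    def test_boundary_belongs_to_lower_bin(self):
        bins = bin_ld(self.make_pairs([10_000], [0.2]), scope="genome")
        row = bins[bins.n_pairs > 0].iloc[0]
        assert (row.bin_lo_bp, row.bin_hi_bp) == (0, 10_000)

    def test_out_of_range_counted_unbinned(self):
        bins = bin_ld(self.make_pairs([20_000_000], [0.2]), scope="genome")
        assert bins["n_pairs"].sum() == 0
        assert bins.attrs["n_unbinned"] == 1

    def test_means_match_brute_force(self, rng):
        d = rng.integers(1, 10_000_000, size=1000)
        r = rng.random(1000)
        bins = bin_ld(self.make_pairs(d, r), scope="genome")
        edges = np.asarray(DEFAULT_BIN_EDGES_BP)
        for _, row in bins.iterrows():
            sel = (d > row.bin_lo_bp) & (d <= row.bin_hi_bp)
            assert row.n_pairs == sel.sum()
            if sel.sum():
                assert row.mean_r2 == pytest.approx(r[sel].mean())
            if sel.sum() >= 2:
                assert row.sd_r2 == pytest.approx(r[sel].std(ddof=1), abs=1e-9)
                assert row.se_r2 == pytest.approx(
                    r[sel].std(ddof=1) / np.sqrt(sel.sum()), abs=1e-9
                )

    def test_genome_mean_is_weighted_chromosome_mean(self, rng):
        pairs = self.make_pairs(
            rng.integers(1, 9_000_000, 300), rng.random(300), chrom="1"
        ) + self.make_pairs(
            rng.integers(1, 9_000_000, 200), rng.random(200), chrom="2"
        )
        genome, chrom = bin_ld(pairs, scope="both")
        for _, row in genome[genome.n_pairs > 0].iterrows():
            sub = chrom[(chrom.bin_lo_bp == row.bin_lo_bp) & (chrom.n_pairs > 0)]
            weighted = (sub.mean_r2 * sub.n_pairs).sum() / sub.n_pairs.sum()
            assert row.mean_r2 == pytest.approx(weighted)
            assert row.n_pairs == sub.n_pairs.sum()

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            bin_ld([], bin_edges_bp=[0, 10, 10])
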