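"""GWAS post-processing: thresholds, region clumping, haplotypes,
phenotype tests and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from panpav.assoc import (bonferroni_threshold, compact_letter_display,
                          define_candidate_regions, gene_haplotypes,
                          haplotype_phenotype_test, hypergeometric_enrichment,
                          iterative_region_scan, reliable_regions, trend_test,
                          variant_filters)
from panpav.genome import GeneModel
from panpav.popscan import GenotypeMatrix


class TestThreshold:
    def test_published_snp_panel_threshold(self):
        p, neglog = bonferroni_threshold(1_890_542)
        assert p == pytest.approx(2.64e-8, rel=5e-3)
        assert neglog == 7.58

    def test_single_test(self):
        assert bonferroni_threshold(1) == (0.05, 1.30)

    def test_pav_panel_threshold_order_of_magnitude(self):
        p, _ = bonferroni_threshold(19_492)
        assert p == pytest.approx(2.57e-6, rel=5e-3)
        assert round(math.log10(p)) == -6

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


def _gm(dosage, positions=None, labels=None, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=np.int8)
    n = dosage.shape[1]
    samples = [f"s{i}" for i in range(n)]
    positions = positions or list(range(100, 100 + 10 * len(dosage), 10))
    variants = pd.DataFrame({"chrom": chrom, "pos": positions,
                             "ref": "A", "alt": "C"})
    return GenotypeMatrix(variants, dosage, samples, labels or {})


class TestVariantFilters:
    def test_maf_cut(self):
        low = [2] + [0] * 49                    # MAF 0.02
        ok = [2] * 10 + [0] * 40                # MAF 0.2
        out = variant_filters(_gm([low, ok]), maf_min=0.05, missing_max=0.1)
        assert len(out.variants) == 1

    def test_missing_rate_snp_vs_pav_defaults(self):
        row = [2] * 5 + [0] * 6 + [-1] * 9      # 45% missing, MAF ~0.45
        g = _gm([row])
        assert len(variant_filters(g, 0.05, 0.1).variants) == 0     # SNP rule
        assert len(variant_filters(g, 0.05, 0.5).variants) == 1     # PAV rule

    def test_fully_called_balanced_variant_always_kept(self):
        row = [2] * 25 + [0] * 25
        assert len(variant_filters(_gm([row]), 0.05, 0.1).variants) == 1


class TestRegions:
    def test_worked_example_two_regions(self):
        res = pd.DataFrame({
            "chrom": "chr1",
            "pos": [1_000_000, 1_150_000, 1_500_000],
            "p": [1e-9, 1e-9, 1e-9],
        })
        regions = define_candidate_regions(res, 1e-8, ext=200_000)
        assert [(r.start, r.end) for r in regions] == \
            [(1_000_000, 1_150_000), (1_500_000, 1_500_000)]

    def test_single_variant_zero_length_region(self):
        res = pd.DataFrame({"chrom": ["chr2"], "pos": [5_000], "p": [1e-10]})
        (r,) = define_candidate_regions(res, 1e-8)
        assert (r.start, r.end) == (5_000, 5_000)
        assert r.peak == (5_000, 1e-10)

    def test_no_significant_variants(self):
        res = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "p": [0.5]})
        assert define_candidate_regions(res, 1e-8) == []

    def test_peak_is_smallest_p_ties_leftmost(self):
        res = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30],
                            "p": [1e-9, 1e-12, 1e-12]})
        (r,) = define_candidate_regions(res, 1e-8, ext=100)
        assert r.peak == (20, 1e-12)

    @pytest.mark.parametrize("n_layouts", [300])
    def test_clustering_equals_iterative_scan(self, rng, n_layouts):
        for _ in range(n_layouts):
            n = int(rng.integers(1, 40))
            pos = np.sort(rng.choice(5_000_000, size=n, replace=False))
            p = np.where(rng.random(n) < 0.5, 1e-9, 0.5)
            res = pd.DataFrame({"chrom": "chr1", "pos": pos, "p": p})
            got = [(r.chrom, r.start, r.end)
                   for r in define_candidate_regions(res, 1e-8)]
            assert got == iterative_region_scan(res, 1e-8)

    def test_regions_disjoint_partition_invariant(self, rng):
        pos = np.sort(rng.choice(3_000_000, size=60, replace=False))
        res = pd.DataFrame({"chrom": "chr1", "pos": pos, "p": 1e-9})
        regions = define_candidate_regions(res, 1e-8)
        members = [m for r in regions for m, _p in r.members]
        assert sorted(members) == sorted(pos.tolist())
        for a, b in zip(regions, regions[1:]):
            assert a.end < b.start

    def test_reliable_requires_multiple_environments(self):
        res1 = pd.DataFrame({"chrom": "chr1", "pos": [100, 200], "p": 1e-9})
        res2 = pd.DataFrame({"chrom": "chr1", "pos": [150], "p": 1e-9})
        res3 = pd.DataFrame({"chrom": "chr2", "pos": [999], "p": 1e-9})
        envs = [define_candidate_regions(r, 1e-8) for r in (res1, res2, res3)]
        rel = reliable_regions(envs)
        assert ("chr1", 100, 200, 2) in rel
        assert not any(r[0] == "chr2" for r in rel)


class TestHaplotypes:
    def _gene(self):
        return GeneModel("g", "chr1", "+", [(1_000, 1_300)])

    def test_two_sites_group_sizes_sum(self):
        dosage = [[0, 0, 2, 2, -1, 0],
                  [0, 2, 0, 2, 0, 1]]
        g = _gm(dosage, positions=[1_100, 1_200])
        haps = gene_haplotypes(g, self._gene(), min_group=1)
        assert len(haps.groups) <= 4
        # s4 missing at site 1, s5 heterozygous at site 2: both excluded
        assert set(haps.assignments) == {"s0", "s1", "s2", "s3"}
        assert sum(len(m) for _h, m in haps.groups) == 4

    def test_groups_equal_bruteforce_string_grouping(self, rng):
        dosage = rng.choice([0, 2, -1], size=(3, 30), p=[0.45, 0.45, 0.1])
        g = _gm(dosage, positions=[1_010, 1_150, 1_290])
        haps = gene_haplotypes(g, self._gene(), min_group=1)
        # oracle: group allele strings directly
        expect = {}
        for j in range(30):
            col = dosage[:, j]
            if (col < 0).any():
                continue
            expect.setdefault(tuple(col), set()).add(f"s{j}")
        got = {frozenset(m) for _h, m in haps.groups}
        assert got == {frozenset(v) for v in expect.values()}

    def test_numbering_by_descending_size(self):
        dosage = [[0] * 8 + [2] * 3]
        g = _gm(dosage, positions=[1_100])
        haps = gene_haplotypes(g, self._gene(), min_group=1)
        assert len(haps.groups[0][1]) == 8
        assert haps.group_name(haps.groups[0][0]) == "Hap1"

    def test_no_sites_is_an_error(self):
        g = _gm([[0, 2]], positions=[900_000])
        with pytest.raises(ValueError):
            gene_haplotypes(g, self._gene())


class TestPhenotypeTest:
    def _haps(self, sizes):
        groups = []
        assignments = {}
        for k, n in enumerate(sizes):
            members = [f"g{k}_{i}" for i in range(n)]
            groups.append((f"H{k}", members))
            assignments.update({m: f"H{k}" for m in members})
        from panpav.assoc import HaplotypeTable
        return HaplotypeTable("g", [("chr1", 1)], assignments, groups)

    def test_two_shifted_groups_distinct_letters(self, rng):
        haps = self._haps([20, 20])
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        phe = pd.Series(vals, index=[m for _h, ms in haps.groups for m in ms])
        rep = haplotype_phenotype_test(haps, phe)
        assert rep.test == "wilcoxon" and rep.p_value < 1e-4
        assert rep.letters["Hap1"] != rep.letters["Hap2"]

    def test_three_groups_one_shifted(self, rng):
        haps = self._haps([25, 25, 25])
        vals = np.concatenate([rng.normal(0, 1, 25), rng.normal(0, 1, 25),
                               rng.normal(3, 1, 25)])
        phe = pd.Series(vals, index=[m for _h, ms in haps.groups for m in ms])
        rep = haplotype_phenotype_test(haps, phe)
        assert rep.test == "kruskal-wallis" and rep.p_value < 1e-4
        assert rep.letters["Hap1"] == rep.letters["Hap2"]
        assert rep.letters["Hap3"] not in rep.letters["Hap1"]

    def test_constant_phenotype_h_zero_p_one(self):
        haps = self._haps([12, 12, 12])
        phe = pd.Series(5.0, index=[m for _h, ms in haps.groups for m in ms])
        rep = haplotype_phenotype_test(haps, phe)
        assert rep.statistic == 0.0 and rep.p_value == 1.0
        assert len(set(rep.letters.values())) == 1

    def test_small_groups_untestable(self):
        haps = self._haps([15, 3])
        phe = pd.Series(np.arange(18, dtype=float),
                        index=[m for _h, ms in haps.groups for m in ms])
        rep = haplotype_phenotype_test(haps, phe)
        assert rep.test == "untestable"

    def test_letter_display_transitive_sharing(self):
        # A ~ B, B ~ C, A != C: B shares a letter with both
        p = np.array([[1.0, 0.5, 0.01],
                      [0.5, 1.0, 0.5],
                      [0.01, 0.5, 1.0]])
        letters = compact_letter_display(["A", "B", "C"], p)
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])


class TestTrendTest:
    def test_causal_variant_ranks_first(self, rng):
        n = 80
        dos = rng.choice([0, 2], size=(10, n)).astype(np.int8)
        g = _gm(dos, positions=list(range(1_000, 11_000, 1_000)))
        y = 2.0 * dos[3] + rng.normal(0, 1, n)
        res = trend_test(g, pd.Series(y, index=g.samples))
        assert res["p"].idxmin() == 3


class TestEnrichment:
    def test_zero_overlap_p_one(self):
        uni = {f"g{i}" for i in range(50)}
        df = hypergeometric_enrichment({"g0", "g1"}, {"T": {"g40", "g41"}}, uni)
        assert df.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_exact_tail_matches_bruteforce_summation(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(50, 62)}
        assert len(gene_set) == 20 and len(gene_set & term) == 8
        df = hypergeometric_enrichment(gene_set, {"T": term}, universe)
        # oracle: direct summation of the hypergeometric tail
        def comb(n, k):
            return math.comb(n, k)
        p_oracle = sum(comb(10, k) * comb(90, 20 - k) for k in range(8, 11)) \
            / comb(100, 20)
        assert df.iloc[0]["p_value"] == pytest.approx(p_oracle, rel=1e-9)

    def test_set_equal_to_universe_gives_p_one(self):
        uni = {f"g{i}" for i in range(30)}
        df = hypergeometric_enrichment(uni, {"T": {f"g{i}" for i in range(5)}},
                                       uni)
        assert df.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_p_monotone_decreasing_in_overlap(self):
        universe = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)}
        prev = 1.1
        for k in range(0, 11):
            gene_set = {f"g{i}" for i in range(k)} \
                | {f"g{i}" for i in range(40, 60 - k)}
            assert len(gene_set) == 20 and len(gene_set & term) == k
            df = hypergeometric_enrichment(gene_set, {"T": term}, universe)
            p = df.iloc[0]["p_value"]
            assert p <= prev + 1e-12
            prev = p

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {"T": set()}, set())
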