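"""Windowed statistics, sweep compositing, LD decay, 4DTv extraction and
the PAV frequency-shift test."""

import numpy as np
import pandas as pd
import pytest

from panpav.genome import GeneModel, revcomp
from panpav.intervals import IntervalSet
from panpav.popscan import (FOURFOLD_PREFIXES, GenotypeMatrix, WindowTrack,
                            extract_4dtv, intersect_sweeps, jaccard, ld_decay,
                            pav_frequency_shift, pi_ratio_track, smooth_track,
                            top_quantile_regions,
                            windowed_fst, windowed_pi)


def gm(positions, dosage, labels=None, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=np.int8)
    n = dosage.shape[1]
    samples = [f"s{i}" for i in range(n)]
    variants = pd.DataFrame({"chrom": chrom, "pos": positions,
                             "ref": "A", "alt": "C"})
    return GenotypeMatrix(variants, dosage, samples,
                          labels or {s: "P" for s in samples})


class TestWindowedPi:
    def test_monomorphic_window_is_zero(self):
        g = gm([5_000], [[2] * 10])
        track = windowed_pi(g, "P", {"chr1": 20_000})
        assert track.values()[0] == 0.0

    def test_single_site_formula(self):
        # c = 5 of n = 10 called alleles in one 20-kb window:
        # h = 2*5*5/(10*9) = 50/90; pi = h / 20000 = 2.78e-5
        g = gm([5_000], [[2, 2, 1, 0, 0]])
        track = windowed_pi(g, "P", {"chr1": 20_000})
        assert track.values()[0] == pytest.approx((50 / 90) / 20_000)
        assert track.values()[0] == pytest.approx(2.78e-5, rel=2e-3)

    def test_window_length_in_denominator(self):
        g = gm([5_000], [[2, 2, 1, 0, 0]])
        v20 = windowed_pi(g, "P", {"chr1": 20_000}, window=20_000).values()[0]
        v40 = windowed_pi(g, "P", {"chr1": 40_000}, window=40_000).values()[0]
        assert v40 == pytest.approx(v20 / 2)

    def test_empty_window_flagged_missing(self):
        g = gm([5_000], [[2, 0]])
        track = windowed_pi(g, "P", {"chr1": 60_000})
        vals = track.values()
        assert np.isnan(vals[-1])       # last window has no sites

    def test_matches_per_site_oracle_on_toy(self, rng):
        pos = np.sort(rng.choice(20_000, size=10, replace=False))
        dos = rng.choice([0, 2, -1], size=(10, 8), p=[0.45, 0.45, 0.1])
        g = gm(pos, dos)
        track = windowed_pi(g, "P", {"chr1": 20_000})
        total = 0.0
        for row in dos:
            called = row[row >= 0]
            n = 2 * len(called)
            c = called.sum()
            if n >= 2:
                total += 2 * c * (n - c) / (n * (n - 1))
        assert track.values()[0] == pytest.approx(total / 20_000)

    def test_unknown_population_label_rejected(self):
        g = gm([100], [[2, 0]])
        with pytest.raises(ValueError):
            windowed_pi(g, "nope", {"chr1": 20_000})


class TestWindowedFst:
    def _two_pop(self, dosA, dosB):
        dosage = np.hstack([dosA, dosB]).astype(np.int8)
        nA = dosA.shape[1]
        labels = {f"s{i}": ("A" if i < nA else "B")
                  for i in range(dosage.shape[1])}
        return gm([5_000] * dosage.shape[0], dosage, labels)

    def test_fixed_difference_gives_one(self):
        g = self._two_pop(np.zeros((1, 10)), np.full((1, 10), 2))
        track = windowed_fst(g, "A", "B", {"chr1": 20_000})
        assert track.values()[0] == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        col = np.array([[2] * 5 + [0] * 5])
        g = self._two_pop(col, col)
        track = windowed_fst(g, "A", "B", {"chr1": 20_000})
        assert track.values()[0] <= 1e-12

    def test_matches_hand_evaluated_components(self):
        # p1 = 0.2, p2 = 0.8, 10 diploids each, all homozygous
        dosA = np.array([[2, 2] + [0] * 8])
        dosB = np.array([[2] * 8 + [0, 0]])
        g = self._two_pop(dosA, dosB)
        track = windowed_fst(g, "A", "B", {"chr1": 20_000})
        # independent scalar evaluation of the variance components
        n1 = n2 = 10.0
        p1, p2 = 0.2, 0.8
        h1 = h2 = 0.0
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = 0.0
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        assert track.values()[0] == pytest.approx(a / (a + b + c))

    def test_relabeling_within_population_invariant(self, rng):
        dosA = rng.choice([0, 2], size=(5, 12)).astype(np.int8)
        dosB = rng.choice([0, 2], size=(5, 12)).astype(np.int8)
        g1 = self._two_pop(dosA, dosB)
        g2 = self._two_pop(dosA[:, ::-1], dosB[:, ::-1])
        t1 = windowed_fst(g1, "A", "B", {"chr1": 20_000}).values()
        t2 = windowed_fst(g2, "A", "B", {"chr1": 20_000}).values()
        assert np.allclose(t1, t2, equal_nan=True)

    def test_bounds(self, rng):
        dosA = rng.choice([0, 1, 2, -1], size=(30, 10)).astype(np.int8)
        dosB = rng.choice([0, 1, 2, -1], size=(30, 10)).astype(np.int8)
        g = self._two_pop(dosA, dosB)
        vals = windowed_fst(g, "A", "B", {"chr1": 20_000}).values()
        vals = vals[np.isfinite(vals)]
        assert (vals <= 1.0 + 1e-12).all()


class TestTracks:
    def _track(self, values, chrom="chr1", window=20_000, step=2_000):
        rows = [(chrom, i * step, i * step + window, v)
                for i, v in enumerate(values)]
        return WindowTrack("x", pd.DataFrame(
            rows, columns=["chrom", "start", "end", "value"]))

    def test_smooth_constant_track_stays_constant(self):
        track = self._track([3.0] * 200)
        out = smooth_track(track, chrom_lengths={"chr1": 418_000})
        assert np.allclose(out.values(), 3.0)

    def test_smooth_output_window_count(self):
        track = self._track([1.0] * 200)
        L = 418_000
        out = smooth_track(track, chrom_lengths={"chr1": L})
        assert len(out.frame) == (L - 100_000) // 10_000 + 1

    def test_single_nonzero_window_spreads_by_midpoint(self):
        vals = [0.0] * 200
        vals[100] = 5.0     # window [200k, 220k), midpoint 210k
        out = smooth_track(self._track(vals), chrom_lengths={"chr1": 418_000})
        hit = out.frame[out.frame["value"] > 0]
        # 100-kb windows at 10-kb step containing midpoint 210,000
        assert len(hit) == 10
        assert (hit["start"] <= 210_000).all() and (hit["end"] > 210_000).all()

    def test_top_quantile_selects_five_of_hundred(self):
        # separate chromosomes so selected windows do not merge
        rows = [(f"c{i}", 0, 100, float(i + 1)) for i in range(100)]
        track = WindowTrack("x", pd.DataFrame(
            rows, columns=["chrom", "start", "end", "value"]))
        regions = top_quantile_regions(track, q=0.05)
        assert len(regions) == 5
        assert sorted(iv.chrom for iv in regions) == [f"c{i}" for i in
                                                      range(95, 100)]

    def test_constant_track_selects_everything(self):
        track = self._track([2.0] * 50)
        regions = top_quantile_regions(track, q=0.05)
        assert regions.total_bp() == 49 * 2_000 + 20_000

    def test_overlapping_selected_windows_merge(self):
        vals = [0.0] * 100
        vals[40] = vals[41] = 10.0
        regions = top_quantile_regions(self._track(vals), q=0.02)
        assert len(regions) == 1
        assert (regions.intervals[0].start, regions.intervals[0].end) == \
            (80_000, 102_000)

    def test_pi_ratio_missing_on_zero_denominator(self):
        num = self._track([1.0, 2.0])
        den = self._track([0.5, 0.0])
        ratio = pi_ratio_track(num, den)
        assert ratio.values()[0] == pytest.approx(2.0)
        assert np.isnan(ratio.values()[1])

    def test_intersect_identical_and_disjoint(self):
        a = IntervalSet([("c", 0, 10_000)])
        b = IntervalSet([("c", 5_000, 15_000)])
        c = IntervalSet([("c", 5_000, 8_000)])
        out = intersect_sweeps({"t1": a, "t2": b, "t3": c})
        assert [(i.start, i.end) for i in out.regions] == [(5_000, 8_000)]
        same = intersect_sweeps({"t1": a, "t2": a})
        assert same.regions == a
        none = intersect_sweeps({"t1": a, "t2": IntervalSet([("c", 90_000,
                                                              95_000)])})
        assert len(none.regions) == 0
        assert jaccard(a, a) == 1.0


class TestLDDecay:
    def test_duplicated_site_r2_one(self):
        col = [2, 2, 0, 0, 2, 0, 2, 0]
        g = gm([1_000, 3_000], [col, col])
        out = ld_decay(g, bin_size=1_000)
        assert len(out) == 1
        assert out.iloc[0]["mean_r2"] == pytest.approx(1.0)
        assert out.iloc[0]["bin_start"] == 2_000

    def test_pairs_beyond_max_dist_excluded(self):
        col = [2, 2, 0, 0, 2, 0]
        g = gm([0, 900_000], [col, col])
        assert len(ld_decay(g, max_dist=500_000)) == 0

    def test_independent_sites_mean_r2_near_one_over_n(self, rng):
        n = 500
        dos = rng.choice([0, 2], size=(60, n)).astype(np.int8)
        g = gm(list(range(0, 6_000, 100)), dos)
        out = ld_decay(g, bin_size=10_000)
        mean_r2 = (out["mean_r2"] * out["n_pairs"]).sum() / out["n_pairs"].sum()
        assert mean_r2 == pytest.approx(1 / n, rel=0.35)

    def test_maf_filter_applied(self):
        rare = [2] + [0] * 99
        common = [2] * 50 + [0] * 50
        g = gm([100, 200], [rare, common])
        assert len(ld_decay(g, maf_min=0.05)) == 0


class TestFourfold:
    def test_prefix_set_derived_from_codon_table(self):
        assert "GG" in FOURFOLD_PREFIXES       # glycine
        assert "TG" not in FOURFOLD_PREFIXES   # TGA stop vs TGG Trp
        assert len(FOURFOLD_PREFIXES) == 8

    def _genome_plus(self):
        cds = "ATGGGATGCTGA"                   # ATG GGA TGC TGA
        chrom = cds + "T" * 48
        gene = GeneModel("g", "chr1", "+", [(0, 12)])
        return {"chr1": chrom}, [gene]

    def test_plus_strand_extraction(self):
        chroms, genes = self._genome_plus()
        # SNPs at: GGA third pos (5, kept), TGC third pos (8, dropped),
        # intergenic (30, dropped)
        g = gm([5, 8, 30], [[0, 2]] * 3)
        out = extract_4dtv(g, genes, chroms)
        assert list(out.variants["pos"]) == [5]

    def test_minus_strand_extraction(self):
        cds = "ATGGGATGCTGA"
        chrom = "T" * 20 + revcomp(cds) + "T" * 28
        gene = GeneModel("g", "chr1", "-", [(20, 32)])
        # coding index 5 (third pos of GGA) maps to genomic 31 - 5 = 26
        g = gm([26, 25, 40], [[0, 2]] * 3)
        out = extract_4dtv(g, gene and [gene], {"chr1": chrom})
        assert list(out.variants["pos"]) == [26]

    def test_idempotent_and_subset(self):
        chroms, genes = self._genome_plus()
        g = gm([2, 5, 8, 11, 30], [[0, 2]] * 5)
        once = extract_4dtv(g, genes, chroms)
        twice = extract_4dtv(once, genes, chroms)
        assert list(once.variants["pos"]) == list(twice.variants["pos"])
        assert set(once.variants["pos"]) <= {2, 5, 8, 11}   # coding only

    def test_unframed_cds_skipped_with_warning(self, caplog):
        gene = GeneModel("bad", "chr1", "+", [(0, 10)])     # length 10
        g = gm([5], [[0, 2]])
        with caplog.at_level("WARNING"):
            out = extract_4dtv(g, [gene], {"chr1": "A" * 60})
        assert len(out.variants) == 0 and "not divisible by 3" in caplog.text


class TestPAVShift:
    def test_proportional_table_not_significant(self):
        presence = np.array([[1] * 10 + [0] * 10 + [1] * 30 + [0] * 30],
                            dtype=np.int8)
        labels = ["W1"] * 20 + ["C1"] * 60
        df = pav_frequency_shift(presence, ["p1"], labels)
        assert df.iloc[0]["p_value"] == pytest.approx(1.0)
        assert not df.iloc[0]["significant"]

    def test_strong_shift_detected(self):
        presence = np.array([[1] * 2 + [0] * 18 + [1] * 40 + [0] * 20],
                            dtype=np.int8)
        labels = ["W1"] * 20 + ["C1"] * 60
        df = pav_frequency_shift(presence, ["p1"], labels)
        assert df.iloc[0]["p_value"] < 1e-3
        assert df.iloc[0]["significant"]

    def test_frequencies_over_called_genotypes(self):
        row = [1] * 8 + [0] * 37 + [-1] * 5          # wild: 8 of 45 called
        presence = np.array([row + [1] * 30 + [0] * 30], dtype=np.int8)
        labels = ["W1"] * 50 + ["C1"] * 60
        df = pav_frequency_shift(presence, ["p1"], labels)
        assert df.iloc[0]["freq_wild"] == pytest.approx(8 / 45)
        assert round(100 * df.iloc[0]["freq_wild"], 1) == 17.8

    def test_small_group_untested(self):
        presence = np.array([[1, 0, -1, -1, -1, 1, 0, 1, 0, 1]], dtype=np.int8)
        labels = ["W1"] * 5 + ["C1"] * 5
        df = pav_frequency_shift(presence, ["p1"], labels, min_group=5)
        assert not df.iloc[0]["tested"]
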