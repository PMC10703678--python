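"""Windowed population-genetic statistics and composite selective-sweep scans.

The windowed estimators re-implement the VCFtools conventions: per-site
heterozygosity h = 2*c*(n-c)/(n*(n-1)) summed over a window and divided
by the window length in bp for pi, and the Weir & Cockerham (1984)
variance components with the weighted window estimator
sum(a)/sum(a+b+c) for F_ST.  Sweep candidates are the top 5% of each
track (after optional 100-kb/10-kb smoothing), and the final sweep set
is the base-pair intersection of all supplied tracks.

XP-CLR scores are consumed as a precomputed per-window track; only
smoothing and thresholding are applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import bh_adjust
from .genome import GeneModel
from .intervals import IntervalSet

WINDOW = 20_000
STEP = 2_000
SMOOTH_WINDOW = 100_000
SMOOTH_STEP = 10_000

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Variants x accessions alt-allele dosage with population labels.

    Dosage in {0, 1, 2}; -1 missing.  Selfing panels are typically all
    0/2 but heterozygous calls are tolerated and counted for the Het
    filter.
    """

    variants: pd.DataFrame              # chrom, pos (0-based), ref, alt[, id]
    dosage: np.ndarray                  # (n_variants, n_samples) int8
    samples: list[str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage shape does not match variants x samples")

    def columns_for(self, pop: str | list[str]) -> np.ndarray:
        pops = [pop] if isinstance(pop, str) else list(pop)
        unknown = [p for p in pops if p not in set(self.labels.values())]
        if unknown:
            raise ValueError(f"unknown population label(s): {unknown}")
        return np.array([i for i, s in enumerate(self.samples)
                         if self.labels.get(s) in pops])

    def subset_samples(self, cols: np.ndarray) -> "GenotypeMatrix":
        samples = [self.samples[i] for i in cols]
        return GenotypeMatrix(self.variants, self.dosage[:, cols], samples,
                              {s: self.labels[s] for s in samples if s in self.labels})

    def maf(self) -> np.ndarray:
        d = self.dosage
        called = d >= 0
        n = 2 * called.sum(axis=1)
        c = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, c / np.maximum(n, 1), np.nan)
        return np.minimum(f, 1 - f)

    def missing_rate(self) -> np.ndarray:
        return (self.dosage < 0).mean(axis=1)

    def het_rate(self) -> np.ndarray:
        called = (self.dosage >= 0).sum(axis=1)
        het = (self.dosage == 1).sum(axis=1)
        return np.where(called > 0, het / np.maximum(called, 1), 0.0)


@dataclass
class WindowTrack:
    """Per-window statistic; windows half-open, fixed size and step."""

    statistic: str
    frame: pd.DataFrame                 # chrom, start, end, value (NaN = missing)

    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(float)


def _windows(chrom_len: int, window: int, step: int) -> list[tuple[int, int]]:
    if chrom_len < window:
        return []
    return [(s, s + window) for s in range(0, chrom_len - window + 1, step)]


def _site_het(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (h, n_called_alleles): h = 2 c (n - c) / (n (n - 1))."""
    called = dosage >= 0
    n = 2 * called.sum(axis=1)
    c = np.where(called, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(n >= 2, 2.0 * c * (n - c) / (n * np.maximum(n - 1, 1)), 0.0)
    return h, n


def windowed_pi(gt: GenotypeMatrix, pop: str | list[str] | None,
                chrom_lengths: dict[str, int],
                window: int = WINDOW, step: int = STEP) -> WindowTrack:
    """Sliding-window nucleotide diversity (sum of per-site h over bp).

    Windows containing zero called sites are flagged missing (NaN).
    """
    cols = gt.columns_for(pop) if pop is not None else np.arange(len(gt.samples))
    if cols.size == 0:
        raise ValueError(f"population {pop!r} has no samples")
    dos = gt.dosage[:, cols]
    h, n = _site_het(dos)
    rows = []
    for chrom in sorted(chrom_lengths):
        mask = (gt.variants["chrom"] == chrom).to_numpy()
        pos = gt.variants.loc[mask, "pos"].to_numpy()
        hc = h[mask]
        nc = n[mask]
        usable = nc >= 2
        pos, hc = pos[usable], hc[usable]
        for s, e in _windows(chrom_lengths[chrom], window, step):
            inside = (pos >= s) & (pos < e)
            k = int(inside.sum())
            val = hc[inside].sum() / window if k else np.nan
            rows.append((chrom, s, e, val))
    return WindowTrack("pi", pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


def wc_fst_components(dosA: np.ndarray, dosB: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components (a, b, c).

    dosA/dosB: (n_sites, n_samples) diploid dosages, -1 missing.
    Sites where either population has < 2 called allele copies, or that
    are monomorphic across both populations, return NaN components.
    """
    comps = []
    for dos in (dosA, dosB):
        called = dos >= 0
        n_i = called.sum(axis=1).astype(float)                    # diploid counts
        c_alt = np.where(called, dos, 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, c_alt / (2 * n_i), np.nan)
            h_i = np.where(n_i > 0,
                           np.where(called, dos == 1, False).sum(axis=1) / np.maximum(n_i, 1),
                           np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (n1 < 1) | (n2 < 1) | (nbar <= 1) | ~np.isfinite(pbar)
    mono = (pbar <= 0) | (pbar >= 1)
    for arr in (a, b, c):
        arr[bad | mono] = np.nan
    return a, b, c


def windowed_fst(gt: GenotypeMatrix, popA: str | list[str], popB: str | list[str],
                 chrom_lengths: dict[str, int],
                 window: int = WINDOW, step: int = STEP) -> WindowTrack:
    """Weir–Cockerham weighted F_ST per sliding window: sum(a)/sum(a+b+c)."""
    colsA = gt.columns_for(popA)
    colsB = gt.columns_for(popB)
    if colsA.size == 0 or colsB.size == 0:
        raise ValueError("both populations must be non-empty")
    a, b, c = wc_fst_components(gt.dosage[:, colsA], gt.dosage[:, colsB])
    ok = np.isfinite(a)
    rows = []
    for chrom in sorted(chrom_lengths):
        mask = (gt.variants["chrom"] == chrom).to_numpy() & ok
        pos = gt.variants.loc[mask, "pos"].to_numpy() if mask.any() else np.array([])
        ac, bc, cc = a[mask], b[mask], c[mask]
        for s, e in _windows(chrom_lengths[chrom], window, step):
            inside = (pos >= s) & (pos < e) if pos.size else np.array([], bool)
            if inside.any():
                denom = (ac + bc + cc)[inside].sum()
                val = ac[inside].sum() / denom if denom != 0 else np.nan
            else:
                val = np.nan
            rows.append((chrom, s, e, val))
    return WindowTrack("fst", pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


def pi_ratio_track(pi_num: WindowTrack, pi_den: WindowTrack,
                   name: str = "pi_ratio") -> WindowTrack:
    """Per-window ratio (e.g. pi_wild / pi_cultivated).

    Missing where either input window is missing or the denominator is
    zero (flagged, never infinite).
    """
    if len(pi_num.frame) != len(pi_den.frame):
        raise ValueError("tracks have different window sets")
    num = pi_num.values()
    den = pi_den.values()
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(np.isfinite(num) & np.isfinite(den) & (den > 0),
                       num / np.maximum(den, 1e-300), np.nan)
    frame = pi_num.frame[["chrom", "start", "end"]].copy()
    frame["value"] = val
    return WindowTrack(name, frame)


def track_from_frame(df: pd.DataFrame, statistic: str,
                     value_col: str = "score") -> WindowTrack:
    frame = df[["chrom", "start", "end"]].copy()
    frame["value"] = df[value_col].to_numpy(float)
    return WindowTrack(statistic, frame)


def smooth_track(track: WindowTrack, window: int = SMOOTH_WINDOW,
                 step: int = SMOOTH_STEP,
                 chrom_lengths: dict[str, int] | None = None) -> WindowTrack:
    """Mean of input-window values whose MIDPOINTS fall in each output window."""
    frame = track.frame
    rows = []
    if chrom_lengths is None:
        chrom_lengths = {c: int(g["end"].max())
                         for c, g in frame.groupby("chrom", sort=True)}
    for chrom in sorted(chrom_lengths):
        sub = frame[frame["chrom"] == chrom]
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        vals = sub["value"].to_numpy(float)
        for s, e in _windows(chrom_lengths[chrom], window, step):
            inside = (mids >= s) & (mids < e) & np.isfinite(vals)
            val = vals[inside].mean() if inside.any() else np.nan
            rows.append((chrom, s, e, val))
    return WindowTrack(track.statistic + "_smooth",
                       pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


def top_quantile_regions(track: WindowTrack, q: float = 0.05) -> IntervalSet:
    """Windows at or above the empirical (1-q) order-statistic quantile,
    merged into intervals.  Inclusive threshold, no interpolation."""
    frame = track.frame
    vals = frame["value"].to_numpy(float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("all windows missing; cannot threshold")
    v = np.sort(vals[finite])
    k = min(max(int(np.ceil((1 - q) * len(v))), 0), len(v) - 1)
    threshold = v[k]
    sel = frame[finite & (vals >= threshold)]
    return IntervalSet(
        (r.chrom, int(r.start), int(r.end)) for r in sel.itertuples(index=False)
    ).merge()


@dataclass
class SweepSet:
    regions: IntervalSet
    provenance: dict[str, IntervalSet]


def intersect_sweeps(tracks: dict[str, IntervalSet]) -> SweepSet:
    """Base-pair intersection supported by ALL tracks, merged."""
    if len(tracks) < 2:
        raise ValueError("need at least 2 interval sets")
    names = sorted(tracks)
    inter = tracks[names[0]]
    for name in names[1:]:
        inter = inter.intersect(tracks[name])
    return SweepSet(inter.merge(), dict(tracks))


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    inter = a.intersect(b).total_bp()
    union = a.total_bp() + b.total_bp() - inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# LD decay

def ld_decay(gt: GenotypeMatrix, max_dist: int = 500_000, maf_min: float = 0.01,
             het_max: float = 0.8, bin_size: int = 1_000,
             max_pairs_per_site: int | None = None) -> pd.DataFrame:
    """Mean composite r^2 per distance bin.

    Sites are filtered by MAF >= maf_min and heterozygous-call fraction
    <= het_max; r^2 is the squared Pearson correlation of genotype
    dosages (composite LD for unphased data), over same-chromosome
    pairs within max_dist.
    """
    keep = (gt.maf() >= maf_min) & (gt.het_rate() <= het_max)
    if keep.sum() < 2:
        return pd.DataFrame(columns=["bin_start", "bin_end", "mean_r2", "n_pairs"])
    variants = gt.variants.loc[keep].reset_index(drop=True)
    dos = gt.dosage[np.flatnonzero(keep)].astype(float)
    dos[dos < 0] = np.nan
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for chrom, grp in variants.groupby("chrom", sort=True):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for ii in range(len(idx)):
            upper = np.searchsorted(pos, pos[ii] + max_dist, side="right")
            js = np.arange(ii + 1, upper)
            if max_pairs_per_site is not None:
                js = js[:max_pairs_per_site]
            for jj in js:
                x, y = dos[idx[ii]], dos[idx[jj]]
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 4:
                    continue
                sx, sy = np.std(x[ok]), np.std(y[ok])
                if sx == 0 or sy == 0:
                    continue
                r = np.corrcoef(x[ok], y[ok])[0, 1]
                b = int((pos[jj] - pos[ii]) // bin_size)
                sums[b] = sums.get(b, 0.0) + r * r
                counts[b] = counts.get(b, 0) + 1
    rows = [{"bin_start": b * bin_size, "bin_end": (b + 1) * bin_size,
             "mean_r2": sums[b] / counts[b], "n_pairs": counts[b]}
            for b in sorted(sums)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fourfold-degenerate (4DTv) site extraction

def _fourfold_prefixes() -> frozenset[str]:
    from Bio.Seq import Seq
    out = set()
    for b1, b2 in product("ACGT", repeat=2):
        aas = {str(Seq(b1 + b2 + b3).translate()) for b3 in "ACGT"}
        if len(aas) == 1:
            out.add(b1 + b2)
    return frozenset(out)


FOURFOLD_PREFIXES = _fourfold_prefixes()


def extract_4dtv(gt: GenotypeMatrix, genes: list[GeneModel],
                 chromosomes: dict[str, str]) -> GenotypeMatrix:
    """Subset to SNPs at third positions of fourfold-degenerate codons.

    Strand-aware; a SNP inside multiple overlapping CDS is kept only if
    fourfold-degenerate in all of them.  Genes whose CDS length is not a
    multiple of 3 are skipped with a warning.
    """
    import logging
    logger = logging.getLogger(__name__)
    status: dict[tuple[str, int], bool] = {}
    for g in genes:
        if g.cds_length % 3 != 0:
            logger.warning("gene %s: CDS length %d not divisible by 3; skipped",
                           g.gene_id, g.cds_length)
            continue
        seq = chromosomes[g.chrom]
        coding_positions: list[int] = []    # genomic positions in coding order
        exons = g.exons if g.strand == "+" else list(reversed(g.exons))
        for s, e in exons:
            rng = range(s, e) if g.strand == "+" else range(e - 1, s - 1, -1)
            coding_positions.extend(rng)
        cds = g.cds_sequence(seq)
        for ci, gpos in enumerate(coding_positions):
            key = (g.chrom, gpos)
            if ci % 3 == 2:
                ok = cds[ci - 2:ci] in FOURFOLD_PREFIXES
            else:
                ok = False      # first/second codon positions are never 4DTv
            status[key] = status.get(key, True) and ok
    keep = np.array([
        status.get((r.chrom, int(r.pos)), False)
        for r in gt.variants.itertuples(index=False)
    ])
    return GenotypeMatrix(gt.variants.loc[keep].reset_index(drop=True),
                         gt.dosage[keep], gt.samples, gt.labels)


# ---------------------------------------------------------------------------
# PAV frequency shift between populations

def pav_frequency_shift(presence: np.ndarray, pav_ids: list[str],
                        sample_labels: list[str], wild_label: str = "W1",
                        alpha: float = 0.05, min_group: int = 5) -> pd.DataFrame:
    """Fisher exact test of presence frequency, wild vs cultivated.

    presence: (n_pav, n_samples) with 1 present / 0 absent / -1 missing;
    any label other than ``wild_label`` counts as cultivated.  Returns
    per-PAV frequencies, P, BH-adjusted P and significance; PAVs with
    fewer than ``min_group`` called genotypes in either group are
    flagged untested.
    """
    labels = np.array(sample_labels)
    wild = labels == wild_label
    cult = ~wild
    rows = []
    pvals, tested_rows = [], []
    for i, pid in enumerate(pav_ids):
        row = presence[i]
        w_called = row[wild] >= 0
        c_called = row[cult] >= 0
        w_p = int((row[wild] == 1).sum())
        w_n = int(w_called.sum())
        c_p = int((row[cult] == 1).sum())
        c_n = int(c_called.sum())
        tested = w_n >= min_group and c_n >= min_group
        if tested:
            _odds, p = stats.fisher_exact([[w_p, w_n - w_p], [c_p, c_n - c_p]],
                                          alternative="two-sided")
            tested_rows.append(len(rows))
            pvals.append(p)
        else:
            p = np.nan
        rows.append({"pav_id": pid,
                     "freq_wild": w_p / w_n if w_n else np.nan,
                     "freq_cultivated": c_p / c_n if c_n else np.nan,
                     "n_called_wild": w_n, "n_called_cultivated": c_n,
                     "p_value": p, "p_adjusted": np.nan,
                     "significant": False, "tested": tested})
    df = pd.DataFrame(rows)
    if pvals:
        padj = bh_adjust(np.array(pvals))
        for k, ri in enumerate(tested_rows):
            df.loc[ri, "p_adjusted"] = padj[k]
            df.loc[ri, "significant"] = padj[k] <= alpha
    return df
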