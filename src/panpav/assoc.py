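"""GWAS post-processing: thresholds, candidate regions, gene haplotypes,
phenotype tests and hypergeometric enrichment.

Association P values are consumed from an external mixed-model run (a
plain dosage trend test is provided for synthetic end-to-end use); this
module owns everything downstream: the 0.05/n Bonferroni threshold, the
iterative 200-kb candidate-region extension (equivalent to
single-linkage clustering of significant variants with gaps <= 200 kb),
gene-haplotype grouping, Kruskal–Wallis + Nemenyi phenotype tests with a
compact letter display, and upper-tail hypergeometric term enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import bh_adjust
from .genome import GeneModel
from .popscan import GenotypeMatrix


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """(P threshold, -log10 threshold) for the uniform 0.05/n rule."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p = alpha / n_tests
    return p, round(-math.log10(p), 2)


def variant_filters(gt: GenotypeMatrix, maf_min: float = 0.05,
                    missing_max: float = 0.1) -> GenotypeMatrix:
    """Retain variants with MAF >= maf_min and missing rate <= missing_max.

    Defaults are the SNP settings (0.05, 0.1); PAV panels use (0.05, 0.5).
    """
    keep = (gt.maf() >= maf_min) & (gt.missing_rate() <= missing_max)
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(gt.variants.loc[keep].reset_index(drop=True),
                          gt.dosage[idx], gt.samples, gt.labels)


@dataclass
class CandidateRegion:
    chrom: str
    start: int          # first significant variant position
    end: int            # last significant variant position
    members: list[tuple[int, float]]        # (pos, P)
    peak: tuple[int, float]                 # smallest P, ties -> leftmost


def define_candidate_regions(results: pd.DataFrame, threshold: float,
                             ext: int = 200_000) -> list[CandidateRegion]:
    """Cluster significant variants into candidate regions.

    ``results``: columns chrom, pos, p.  Implemented as single-linkage
    clustering of significant variants with inter-variant gap <= ext,
    which equals the literal iterative 200-kb extension scan (seed at a
    significant variant, extend while new significant variants appear,
    bound the region at the last significant variant).
    """
    sig = results.loc[results["p"] <= threshold].sort_values(["chrom", "pos"])
    regions: list[CandidateRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        pvs = grp["p"].to_numpy(float)
        start_i = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > ext:
                members = list(zip(pos[start_i:i].tolist(), pvs[start_i:i].tolist()))
                peak = min(members, key=lambda m: (m[1], m[0]))
                regions.append(CandidateRegion(chrom, int(pos[start_i]),
                                               int(pos[i - 1]), members, peak))
                start_i = i
    return regions


def iterative_region_scan(results: pd.DataFrame, threshold: float,
                          ext: int = 200_000) -> list[tuple[str, int, int]]:
    """Literal iterative procedure (the oracle for region definition).

    Seed at the leftmost unassigned significant variant; repeatedly
    extend the search window by ``ext`` past the current last
    significant variant until no further significant variant falls
    inside; bound the region at the last significant variant found.
    """
    sig = results.loc[results["p"] <= threshold].sort_values(["chrom", "pos"])
    out: list[tuple[str, int, int]] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        used = np.zeros(len(pos), bool)
        for i in range(len(pos)):
            if used[i]:
                continue
            last = pos[i]
            used[i] = True
            extended = True
            while extended:
                extended = False
                inside = (~used) & (pos > last) & (pos <= last + ext)
                if inside.any():
                    last = pos[np.flatnonzero(inside)].max()
                    used[inside] = True
                    extended = True
            out.append((chrom, int(pos[i]), int(last)))
    return out


def reliable_regions(per_environment: list[list[CandidateRegion]],
                     min_environments: int = 2) -> list[tuple[str, int, int, int]]:
    """Regions supported by >= min_environments overlapping result sets.

    Returns (chrom, start, end, n_environments) for each region of the
    union that overlaps regions from at least ``min_environments``
    distinct environment/year result sets.
    """
    out = []
    all_regions = [(ei, r) for ei, regs in enumerate(per_environment) for r in regs]
    for ei, r in all_regions:
        support = {ei}
        for ej, r2 in all_regions:
            if ej != ei and r2.chrom == r.chrom and r2.start <= r.end and r.start <= r2.end:
                support.add(ej)
        if len(support) >= min_environments:
            out.append((r.chrom, r.start, r.end, len(support)))
    return sorted(set(out))


def trend_test(gt: GenotypeMatrix, phenotype: pd.Series) -> pd.DataFrame:
    """Per-variant score test on dosage (stand-in for a mixed model).

    Pearson correlation test of dosage vs trait over called genotypes;
    population-structure correction is out of scope here.
    """
    y_all = phenotype.reindex(gt.samples).to_numpy(float)
    rows = []
    for i in range(len(gt.variants)):
        d = gt.dosage[i].astype(float)
        ok = (d >= 0) & np.isfinite(y_all)
        if ok.sum() < 4 or np.std(d[ok]) == 0 or np.std(y_all[ok]) == 0:
            p = 1.0
        else:
            p = float(stats.pearsonr(d[ok], y_all[ok]).pvalue)
        v = gt.variants.iloc[i]
        rows.append({"chrom": v.chrom, "pos": int(v.pos), "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene haplotypes

@dataclass
class HaplotypeTable:
    gene_id: str
    sites: list[tuple[str, int]]                   # (chrom, pos) selected
    assignments: dict[str, str]                    # accession -> haplotype string
    groups: list[tuple[str, list[str]]]            # (hap string, accessions) by size
    small_groups: set[str] = field(default_factory=set)

    def group_name(self, hap: str) -> str:
        for k, (h, _members) in enumerate(self.groups, 1):
            if h == hap:
                return f"Hap{k}"
        raise KeyError(hap)


def gene_haplotypes(gt: GenotypeMatrix, gene: GeneModel, flank: int = 2_000,
                    site_filter=None, min_group: int = 10) -> HaplotypeTable:
    """Haplotype strings over variants in the gene body +/- flank.

    Accessions with a missing or heterozygous call at any selected site
    are excluded.  Groups are numbered by descending size (Hap1 =
    largest); groups below ``min_group`` are kept but flagged small.
    """
    v = gt.variants
    inside = ((v["chrom"] == gene.chrom)
              & (v["pos"] >= gene.start - flank)
              & (v["pos"] < gene.end + flank)).to_numpy()
    idx = np.flatnonzero(inside)
    if site_filter is not None:
        idx = np.array([i for i in idx if site_filter(v.iloc[i])], dtype=int)
    if idx.size == 0:
        raise ValueError(f"no variant sites selected for {gene.gene_id}")
    sites = [(v.iloc[i].chrom, int(v.iloc[i].pos)) for i in idx]
    assignments: dict[str, str] = {}
    for j, acc in enumerate(gt.samples):
        alleles = []
        for i in idx:
            d = int(gt.dosage[i, j])
            if d == 0:
                alleles.append(str(v.iloc[i].ref))
            elif d == 2:
                alleles.append(str(v.iloc[i].alt))
            else:           # missing or heterozygous
                alleles = None
                break
        if alleles is not None:
            assignments[acc] = "".join(alleles)
    by_hap: dict[str, list[str]] = {}
    for acc, hap in assignments.items():
        by_hap.setdefault(hap, []).append(acc)
    groups = sorted(by_hap.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    small = {h for h, members in groups if len(members) < min_group}
    return HaplotypeTable(gene.gene_id, sites, assignments, groups, small)


# ---------------------------------------------------------------------------
# Phenotype tests

@dataclass
class PhenotypeTestReport:
    gene_id: str
    test: str                       # "kruskal-wallis" | "wilcoxon" | "untestable"
    statistic: float
    p_value: float
    groups: list[str]               # Hap1, Hap2, ... tested
    letters: dict[str, str]         # compact letter display
    pairwise_p: dict[tuple[str, str], float]


def _nemenyi_pairwise(samples: list[np.ndarray]) -> np.ndarray:
    """Two-sided Nemenyi post-hoc P values from joint mean ranks."""
    k = len(samples)
    all_vals = np.concatenate(samples)
    ranks = stats.rankdata(all_vals)
    n_total = len(all_vals)
    mean_ranks = []
    off = 0
    for s in samples:
        mean_ranks.append(ranks[off:off + len(s)].mean())
        off += len(s)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(samples[i]), len(samples[j])
            se = math.sqrt(n_total * (n_total + 1) / 12.0 * (1.0 / ni + 1.0 / nj))
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * math.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, 1e6))
            out[i, j] = out[j, i] = min(1.0, p)
    return out


def compact_letter_display(names: list[str], pairwise_p: np.ndarray,
                           alpha: float = 0.05) -> dict[str, str]:
    """Greedy insert-and-absorb letters: groups sharing a letter do not
    differ significantly at alpha."""
    k = len(names)
    letters: list[set[int]] = []    # each letter = set of group indices
    for i in range(k):
        placed = False
        for letter in letters:
            if all(pairwise_p[i, j] > alpha for j in letter):
                letter.add(i)
                placed = True
        if not placed:
            new = {i}
            for j in range(k):
                if j != i and all(pairwise_p[j, m] > alpha for m in new):
                    new.add(j)
            letters.append(new)
    # drop letters that are subsets of others
    letters = [s for a, s in enumerate(letters)
               if not any(s < letters[b] for b in range(len(letters)) if b != a)]
    out = {name: "" for name in names}
    for li, s in enumerate(letters):
        ch = chr(ord("a") + li)
        for i in sorted(s):
            out[names[i]] += ch
    return out


def haplotype_phenotype_test(haps: HaplotypeTable, phenotype: pd.Series,
                             min_group: int = 10,
                             alpha: float = 0.05) -> PhenotypeTestReport:
    """Kruskal–Wallis across haplotype groups with Nemenyi post-hoc.

    Two eligible groups fall back to a two-sided Wilcoxon rank-sum;
    fewer than two eligible groups are untestable.  Replicated
    phenotype values should be reduced to per-accession means upstream.
    """
    names, samples = [], []
    for k, (hap, members) in enumerate(haps.groups, 1):
        vals = phenotype.reindex(members).dropna().to_numpy(float)
        if len(members) >= min_group and vals.size >= min_group:
            names.append(f"Hap{k}")
            samples.append(vals)
    if len(names) < 2:
        return PhenotypeTestReport(haps.gene_id, "untestable", float("nan"),
                                   float("nan"), names, {}, {})
    if len(names) == 2:
        res = stats.ranksums(samples[0], samples[1])
        sig = res.pvalue <= alpha
        letters = {names[0]: "a", names[1]: "b" if sig else "a"}
        return PhenotypeTestReport(haps.gene_id, "wilcoxon", float(res.statistic),
                                   float(res.pvalue), names, letters,
                                   {(names[0], names[1]): float(res.pvalue)})
    if all(np.all(s == samples[0][0]) for s in samples):
        # identical constant phenotype: H = 0, P = 1
        return PhenotypeTestReport(haps.gene_id, "kruskal-wallis", 0.0, 1.0, names,
                                   {n: "a" for n in names}, {})
    H, p = stats.kruskal(*samples)
    pw = _nemenyi_pairwise(samples)
    letters = compact_letter_display(names, pw, alpha)
    pairwise = {(names[i], names[j]): float(pw[i, j])
                for i in range(len(names)) for j in range(i + 1, len(names))}
    return PhenotypeTestReport(haps.gene_id, "kruskal-wallis", float(H), float(p),
                               names, letters, pairwise)


# ---------------------------------------------------------------------------
# Enrichment

def hypergeometric_enrichment(gene_set: set[str], term_map: dict[str, set[str]],
                              universe: set[str], alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment P(X >= k) per term, BH-adjusted.

    Population = universe size, successes = term size within universe,
    draws = gene-set size, observed = overlap.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    M = len(universe)
    N = len(gene_set)
    rows = []
    for term, members in sorted(term_map.items()):
        K = len(members & universe)
        if K == 0:
            continue
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
        rows.append({"term": term, "overlap": k, "term_size": K,
                     "set_size": N, "universe_size": M, "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
        df["enriched"] = df["p_adjusted"] <= alpha
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df
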