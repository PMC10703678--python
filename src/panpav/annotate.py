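"""PAV annotation: TE content, genic context, gene impact and expression impact.

A PAV is TE-derived when at least 90% of its footprint is covered by the
union of TE intervals (deletions: the reference interval; insertions:
the inserted sequence matched against the TE template library or a
donor-TE interval).  Genic context follows the precedence
coding > intron > upstream 2 kb > downstream 2 kb > intergenic, with the
flank windows strand-aware.  Expression impact compares carrier and
non-carrier FPKM with a two-sided Wilcoxon rank-sum screen at the usual
thresholds (|fold change| >= 1.5, BH-adjusted P <= 0.05); genes with
FPKM < 1 are flagged silenced.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel
from .intervals import IntervalSet
from .merge import PAVCluster

TE_THRESHOLD = 0.90
UPSTREAM_BP = DOWNSTREAM_BP = 2_000

CONTEXTS = ("coding", "intron", "upstream2kb", "downstream2kb", "intergenic")


@dataclass
class PAVAnnotation:
    cluster_id: str
    te_status: str               # "TE-derived" | "non-TE"
    te_class: str | None
    genic_context: str
    nearest_gene_id: str | None
    distance_to_gene: int


def classify_te(pav_chrom: str, pav_start: int, pav_end: int,
                te_intervals: list[tuple[str, int, int, str]],
                threshold: float = TE_THRESHOLD) -> tuple[str, str | None]:
    """TE status of a reference-interval footprint (DEL).

    Coverage is the UNION of the (possibly overlapping) TE intervals,
    not their sum; te_class is the class covering the most bases.
    """
    length = pav_end - pav_start
    if length <= 0:
        raise ValueError(f"zero-length PAV footprint {pav_chrom}:{pav_start}-{pav_end}")
    union = IntervalSet(
        (c, max(s, pav_start), min(e, pav_end))
        for c, s, e, _cls in te_intervals
        if c == pav_chrom and s < pav_end and pav_start < e
    )
    covered = union.total_bp()
    if covered / length < threshold:
        return "non-TE", None
    per_class: dict[str, int] = {}
    for c, s, e, cls in te_intervals:
        if c != pav_chrom:
            continue
        ov = max(0, min(e, pav_end) - max(s, pav_start))
        if ov:
            per_class[cls] = per_class.get(cls, 0) + ov
    best = max(sorted(per_class), key=lambda k: per_class[k])
    return "TE-derived", best


def classify_te_insertion(inserted_seq: str, te_library_seqs: list[str],
                          te_library_classes: list[str],
                          threshold: float = TE_THRESHOLD) -> tuple[str, str | None]:
    """TE status of an inserted sequence, by identity to the TE templates.

    Identity = 1 - editdistance / inserted length against each template
    (the template may be tiled to cover longer insertions).
    """
    if not inserted_seq:
        raise ValueError("zero-length inserted sequence")
    best_id, best_cls = 0.0, None
    L = len(inserted_seq)
    for seq, cls in zip(te_library_seqs, te_library_classes):
        tpl = seq if len(seq) >= L else (seq * (L // len(seq) + 1))[:L + len(seq)]
        d = edlib.align(inserted_seq, tpl, mode="HW", task="distance")["editDistance"]
        ident = 1.0 - d / L
        if ident > best_id:
            best_id, best_cls = ident, cls
    if best_id >= threshold:
        return "TE-derived", best_cls
    return "non-TE", None


def genic_context(pav_chrom: str, pav_start: int, pav_end: int,
                  genes: list[GeneModel],
                  flank: int = UPSTREAM_BP) -> tuple[str, str | None, int]:
    """(context, nearest gene, distance) under the context precedence.

    Upstream/downstream windows are strand-aware: upstream of a minus
    strand gene lies to the right of its genomic end.  Distance is the
    gap to the nearest gene BODY (0 when touching or overlapping).
    """
    pav_end = max(pav_end, pav_start + 1)   # insertion junction as a point
    best_rank = len(CONTEXTS) - 1
    nearest: str | None = None
    nearest_dist = -1
    for g in genes:
        if g.chrom != pav_chrom:
            continue
        if g.start < pav_end and pav_start < g.end:
            dist = 0
            if any(s < pav_end and pav_start < e for s, e in g.exons):
                rank = 0       # coding
            else:
                rank = 1       # intron
        else:
            dist = g.start - pav_end if g.start >= pav_end else pav_start - g.end
            dist = max(dist, 0)
            if g.strand == "+":
                up = (g.start - flank, g.start)
                down = (g.end, g.end + flank)
            else:
                up = (g.end, g.end + flank)
                down = (g.start - flank, g.start)
            if up[0] < pav_end and pav_start < up[1]:
                rank = 2
            elif down[0] < pav_end and pav_start < down[1]:
                rank = 3
            else:
                rank = 4
        best_rank = min(best_rank, rank)
        if nearest is None or dist < nearest_dist:
            nearest, nearest_dist = g.gene_id, dist
    if nearest is None:
        return "intergenic", None, -1
    return CONTEXTS[best_rank], nearest, nearest_dist


@dataclass
class GeneImpact:
    gene_id: str
    status: str                 # lost | pseudogenized | intact
    causal_cluster_ids: list[str]


def gene_impact(clusters: list[PAVCluster], genes: list[GeneModel]) -> list[GeneImpact]:
    """Classify gene loss and pseudogenization from DEL/INS clusters.

    lost: carried deletions jointly cover 100% of CDS bases.
    pseudogenized (not lost): a deletion removes a complete exon, or
    DEL/INS hitting the CDS shifts its length by a non-multiple of 3, or
    a deletion removes the start or stop codon.
    """
    impacts: list[GeneImpact] = []
    for g in genes:
        if not g.exons:
            continue
        dels = [c for c in clusters
                if c.subtype == "DEL" and c.chrom == g.chrom
                and c.start < g.end and g.start < c.end]
        inss = [c for c in clusters
                if c.subtype == "INS" and c.chrom == g.chrom
                and g.start <= c.start < g.end]
        causal: list[str] = []
        cds_len = g.cds_length
        del_union = IntervalSet(
            (g.chrom, max(c.start, g.start), min(c.end, g.end)) for c in dels)
        cds_deleted = sum(del_union.overlap_bp(g.chrom, s, e) for s, e in g.exons)
        status = "intact"
        if cds_deleted >= cds_len:
            status = "lost"
            causal = [c.cluster_id for c in dels]
        else:
            whole_exon = any(
                any(c.start <= s and e <= c.end for c in dels) for s, e in g.exons)
            frame_shift = False
            for c in dels:
                removed = sum(max(0, min(c.end, e) - max(c.start, s))
                              for s, e in g.exons)
                if 0 < removed and removed % 3 != 0:
                    frame_shift = True
                    causal.append(c.cluster_id)
            for c in inss:
                in_exon = any(s <= c.start < e for s, e in g.exons)
                if in_exon and len(c.representative.inserted_seq) % 3 != 0:
                    frame_shift = True
                    causal.append(c.cluster_id)
            cds_exons = g.exons if g.strand == "+" else list(reversed(g.exons))
            if g.strand == "+":
                start_codon = (cds_exons[0][0], cds_exons[0][0] + 3)
                stop_codon = (cds_exons[-1][1] - 3, cds_exons[-1][1])
            else:
                start_codon = (cds_exons[0][1] - 3, cds_exons[0][1])
                stop_codon = (cds_exons[-1][0], cds_exons[-1][0] + 3)
            codon_hit = any(
                c.start < iv[1] and iv[0] < c.end
                for c in dels for iv in (start_codon, stop_codon))
            if whole_exon or frame_shift or codon_hit:
                status = "pseudogenized"
                if whole_exon:
                    causal.extend(c.cluster_id for c in dels
                                  if any(c.start <= s and e <= c.end for s, e in g.exons))
        if status != "intact" and not causal:
            causal = [c.cluster_id for c in dels + inss]
        impacts.append(GeneImpact(g.gene_id, status, sorted(set(causal))))
    return impacts


@dataclass
class ExpressionImpact:
    gene_id: str
    mean_fpkm_carriers: float
    mean_fpkm_noncarriers: float
    fold_change: float
    silenced_carriers: float     # fraction with FPKM < 1
    silenced_noncarriers: float
    p_value: float
    p_adjusted: float
    significant: bool
    tested: bool


SILENCED_FPKM = 1.0
PSEUDOCOUNT = 0.1


def expression_impact(fpkm: pd.DataFrame, genotypes: pd.DataFrame,
                      fc_min: float = 1.5, alpha: float = 0.05,
                      min_group: int = 3) -> list[ExpressionImpact]:
    """Carrier vs non-carrier FPKM screen per gene.

    ``fpkm``: genes x accessions; ``genotypes``: genes x accessions with
    1 carrier / 0 non-carrier / -1 missing (row index aligned on gene).
    Fold change uses a 0.1 pseudo-count; significance is a two-sided
    Wilcoxon rank-sum with BH adjustment across tested genes.
    """
    results: list[ExpressionImpact] = []
    pvals: list[float] = []
    tested_idx: list[int] = []
    common = [g for g in fpkm.index if g in genotypes.index]
    for gid in common:
        expr = fpkm.loc[gid]
        gt = genotypes.loc[gid]
        carriers = expr[[a for a in expr.index if gt.get(a, -1) == 1]].to_numpy(float)
        noncar = expr[[a for a in expr.index if gt.get(a, -1) == 0]].to_numpy(float)
        mc = float(np.mean(carriers)) if carriers.size else float("nan")
        mn = float(np.mean(noncar)) if noncar.size else float("nan")
        fc = (mc + PSEUDOCOUNT) / (mn + PSEUDOCOUNT) if carriers.size and noncar.size \
            else float("nan")
        sil_c = float(np.mean(carriers < SILENCED_FPKM)) if carriers.size else float("nan")
        sil_n = float(np.mean(noncar < SILENCED_FPKM)) if noncar.size else float("nan")
        tested = carriers.size >= min_group and noncar.size >= min_group
        if tested:
            p = float(stats.mannwhitneyu(carriers, noncar,
                                         alternative="two-sided").pvalue)
            tested_idx.append(len(results))
            pvals.append(p)
        else:
            p = float("nan")
        results.append(ExpressionImpact(gid, mc, mn, fc, sil_c, sil_n, p,
                                        float("nan"), False, tested))
    if pvals:
        padj = bh_adjust(np.array(pvals))
        for k, ri in enumerate(tested_idx):
            r = results[ri]
            r.p_adjusted = float(padj[k])
            r.significant = (r.p_adjusted <= alpha
                             and (r.fold_change >= fc_min or r.fold_change <= 1 / fc_min))
    return results


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted P values (monotone, capped at 1)."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def annotate_pavs(clusters: list[PAVCluster],
                  te_intervals: list[tuple[str, int, int, str]],
                  genes: list[GeneModel],
                  te_library_seqs: list[str] | None = None,
                  te_library_classes: list[str] | None = None,
                  threshold: float = TE_THRESHOLD) -> list[PAVAnnotation]:
    """One annotation row per PAV cluster."""
    out: list[PAVAnnotation] = []
    for c in clusters:
        rep = c.representative
        if c.subtype == "DEL":
            status, cls = classify_te(c.chrom, rep.ref_start, rep.ref_end,
                                      te_intervals, threshold)
        elif te_library_seqs:
            status, cls = classify_te_insertion(rep.inserted_seq, te_library_seqs,
                                                te_library_classes or
                                                ["TE"] * len(te_library_seqs), threshold)
        else:
            status, cls = "non-TE", None
        ctx, gene, dist = genic_context(c.chrom, rep.ref_start, rep.ref_end, genes)
        out.append(PAVAnnotation(c.cluster_id, status, cls, ctx, gene, dist))
    return out


def annotation_table(annotations: list[PAVAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cluster_id": a.cluster_id, "te_status": a.te_status,
        "te_class": a.te_class or ".", "genic_context": a.genic_context,
        "nearest_gene_id": a.nearest_gene_id or ".",
        "distance_to_gene": a.distance_to_gene,
    } for a in annotations])
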