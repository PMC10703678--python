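"""Merge per-accession SVs into the nonredundant population PAV set.

Merge rules: deletions (and inversions) are linked when their reciprocal
overlap — |intersection| divided by each event's length, taking the
minimum of the two ratios — exceeds 0.90; insertions are linked when
their junctions lie within 10 bp and the inserted sequences share more
than 80% identity (1 - edit distance / longer length).  Clusters are
single-linkage connected components of the link relation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synteny import StructuralVariant, SyntenyNet, seq_identity

PRESENT, ABSENT, MISSING = 1, 0, -1


@dataclass
class MergeParams:
    del_inv_overlap_min: float = 0.90
    ins_max_distance: int = 10
    ins_identity_min: float = 0.80
    reciprocal: bool = True     # one-sided mode divides by max length only

    def __post_init__(self) -> None:
        if not (0 < self.del_inv_overlap_min <= 1):
            raise ValueError("del_inv_overlap_min must be in (0, 1]")
        if self.ins_max_distance < 0:
            raise ValueError("ins_max_distance must be >= 0")
        if not (0 < self.ins_identity_min <= 1):
            raise ValueError("ins_identity_min must be in (0, 1]")


def link(a: StructuralVariant, b: StructuralVariant, params: MergeParams) -> bool:
    """Symmetric merge-link test; only defined within one subtype."""
    if a.subtype != b.subtype:
        raise ValueError(f"link tested across subtypes: {a.subtype} vs {b.subtype}")
    if a.ref_chrom != b.ref_chrom:
        return False
    if a.subtype in ("DEL", "INV"):
        inter = min(a.ref_end, b.ref_end) - max(a.ref_start, b.ref_start)
        if inter <= 0:
            return False
        len_a = a.ref_end - a.ref_start
        len_b = b.ref_end - b.ref_start
        if params.reciprocal:
            ratio = min(inter / len_a, inter / len_b)
        else:
            ratio = inter / max(len_a, len_b)
        return ratio > params.del_inv_overlap_min
    if a.subtype == "INS":
        if abs(a.ref_start - b.ref_start) >= params.ins_max_distance:
            return False
        return seq_identity(a.inserted_seq, b.inserted_seq) > params.ins_identity_min
    return False


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclass
class PAVCluster:
    cluster_id: str
    subtype: str
    members: list[StructuralVariant]
    representative: StructuralVariant
    genotypes: dict[str, int] = field(default_factory=dict)  # accession -> 1/0/-1

    @property
    def chrom(self) -> str:
        return self.representative.ref_chrom

    @property
    def start(self) -> int:
        return self.representative.ref_start

    @property
    def end(self) -> int:
        return self.representative.ref_end

    @property
    def accessions(self) -> set[str]:
        return {m.accession_id for m in self.members}

    def n_carriers(self) -> int:
        if self.genotypes:
            return sum(1 for g in self.genotypes.values() if g == PRESENT)
        return len(self.accessions)


def merge_pavs(svs: list[StructuralVariant],
               params: MergeParams | None = None,
               subtypes: tuple[str, ...] = ("DEL", "INS", "INV")) -> list[PAVCluster]:
    """Single-linkage clustering under the merge-link relation.

    DEL/INV link by reciprocal overlap; INS by junction distance plus
    sequence identity.  The representative is the member linking
    directly to the most cluster members (ties: longest, then leftmost).
    Clusters are sorted by (chrom, representative start) and numbered.
    """
    params = params or MergeParams()
    chosen = [sv for sv in svs if sv.subtype in subtypes]
    uf = _UnionFind(len(chosen))

    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, sv in enumerate(chosen):
        by_key[(sv.subtype, sv.ref_chrom)].append(i)

    for (subtype, _chrom), idxs in by_key.items():
        if subtype in ("DEL", "INV"):
            idxs = sorted(idxs, key=lambda i: chosen[i].ref_start)
            for ai in range(len(idxs)):
                a = chosen[idxs[ai]]
                for bi in range(ai + 1, len(idxs)):
                    b = chosen[idxs[bi]]
                    if b.ref_start >= a.ref_end:
                        break
                    if link(a, b, params):
                        uf.union(idxs[ai], idxs[bi])
        else:  # INS: junction sweep
            idxs = sorted(idxs, key=lambda i: chosen[i].ref_start)
            for ai in range(len(idxs)):
                a = chosen[idxs[ai]]
                for bi in range(ai + 1, len(idxs)):
                    b = chosen[idxs[bi]]
                    if b.ref_start - a.ref_start >= params.ins_max_distance:
                        break
                    if link(a, b, params):
                        uf.union(idxs[ai], idxs[bi])

    groups: dict[int, list[StructuralVariant]] = defaultdict(list)
    for i, sv in enumerate(chosen):
        groups[uf.find(i)].append(sv)

    clusters: list[PAVCluster] = []
    for members in groups.values():
        rep = _pick_representative(members, params)
        clusters.append(PAVCluster("", members[0].subtype, members, rep))
    clusters.sort(key=lambda c: (c.chrom, c.start, c.subtype, c.end))
    for k, c in enumerate(clusters, 1):
        c.cluster_id = f"{c.subtype}_{k:06d}"
    return clusters


def _pick_representative(members: list[StructuralVariant],
                         params: MergeParams) -> StructuralVariant:
    if len(members) == 1:
        return members[0]
    support = []
    for m in members:
        n = sum(1 for o in members if o is not m and link(m, o, params))
        support.append(n)
    order = sorted(range(len(members)),
                   key=lambda i: (-support[i], -members[i].length,
                                  members[i].ref_start, members[i].accession_id))
    return members[order[0]]


def genotype_from_assemblies(clusters: list[PAVCluster],
                             nets: dict[str, SyntenyNet],
                             params: MergeParams | None = None) -> pd.DataFrame:
    """Presence/absence/missing per (cluster, accession) from assemblies.

    present: the accession contributed a member SV; absent: the
    accession's net covers the representative interval syntenically with
    no linked SV; missing: the interval falls in an uncovered net zone.
    """
    params = params or MergeParams()
    accessions = sorted(nets)
    mat = np.full((len(clusters), len(accessions)), MISSING, dtype=np.int8)
    for i, cl in enumerate(clusters):
        rep = cl.representative
        s, e = rep.ref_start, max(rep.ref_end, rep.ref_start + 1)
        carriers = cl.accessions
        for j, acc in enumerate(accessions):
            if acc in carriers:
                mat[i, j] = PRESENT
            else:
                net = nets[acc]
                if net.covers_ref(rep.ref_chrom, s, e):
                    mat[i, j] = ABSENT
                else:
                    mat[i, j] = MISSING
        cl.genotypes = {acc: int(mat[i, j]) for j, acc in enumerate(accessions)}
    return pd.DataFrame(mat, index=[c.cluster_id for c in clusters], columns=accessions)


@dataclass
class EvalReport:
    true_positive: int
    false_positive: int
    false_negative: int
    flagged: str = ""

    @property
    def precision(self) -> float:
        d = self.true_positive + self.false_positive
        return self.true_positive / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.true_positive + self.false_negative
        return self.true_positive / d if d else 0.0

    @property
    def f1(self) -> float:
        return f1_score(self.precision, self.recall)

    def as_dict(self) -> dict:
        return {"TP": self.true_positive, "FP": self.false_positive,
                "FN": self.false_negative,
                "precision": round(self.precision, 2),
                "recall": round(self.recall, 2), "f1": round(self.f1, 2)}


def f1_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _match_quality(call: StructuralVariant, truth: StructuralVariant) -> float:
    if call.subtype in ("DEL", "INV"):
        inter = min(call.ref_end, truth.ref_end) - max(call.ref_start, truth.ref_start)
        return inter / max(call.ref_end - call.ref_start, truth.ref_end - truth.ref_start)
    return seq_identity(call.inserted_seq, truth.inserted_seq) \
        - abs(call.ref_start - truth.ref_start) * 1e-6


def evaluate_calls(calls: list[StructuralVariant], truth: list[StructuralVariant],
                   params: MergeParams | None = None) -> EvalReport:
    """Greedy one-to-one matching of calls to truth under the link test."""
    params = params or MergeParams()
    if not truth and calls:
        return EvalReport(0, len(calls), 0, flagged="empty truth: recall undefined, reported 0")
    pairs = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth):
            if c.subtype != t.subtype:
                continue
            if link(c, t, params):
                pairs.append((_match_quality(c, t), ci, ti))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_c: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _q, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        tp += 1
    return EvalReport(tp, len(calls) - tp, len(truth) - tp)


def frequency_spectrum(clusters: list[PAVCluster]) -> tuple[Counter, float]:
    """Histogram of carrier counts and the fraction with <= 2 carriers.

    Missing genotypes are excluded on both sides of the per-cluster
    carrier count.
    """
    counts: Counter = Counter()
    for c in clusters:
        counts[c.n_carriers()] += 1
    total = sum(counts.values())
    low = sum(n for k, n in counts.items() if k <= 2)
    return counts, (low / total if total else 0.0)


def low_frequency_fraction(n_low: int, n_total: int) -> float:
    """Share of PAVs carried by at most two accessions, as a percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_low / n_total
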