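"""Chain/net construction from gapless alignment anchors and syntenic SV calling.

The model follows the classic whole-genome alignment workflow: gapless
anchor blocks are chained by sparse dynamic programming into colinear
chains, chains are netted greedily into a single-coverage tiling of both
genomes, and structural variants are read off the coordinate gaps
between adjacent anchors within accepted chains.

Five SV subtypes are emitted:

* ``DEL`` — reference bases absent from the query (ref gap, no query gap),
* ``INS`` — query bases absent from the reference (query gap, no ref gap),
* ``TDUP`` — an insertion whose sequence is a tandem copy of the flanking
  reference sequence (>= 80% identity over the inserted length),
* ``INV`` — a minus-strand chain flanked by plus-strand coverage over a
  colinear query territory,
* ``CPX`` — a double-sided gap (both genomes diverge) not explained by an
  accepted inversion chain.

Events must exceed ``min_size`` bases (default 51, i.e. strictly greater
than 50 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .genome import revcomp

logger = logging.getLogger(__name__)

SV_SUBTYPES = ("DEL", "INS", "INV", "TDUP", "CPX")

#: events of exactly 50 bp are excluded (strictly > 50 bp)
DEFAULT_MIN_SIZE = 51
DEFAULT_MIN_NET_SPAN = 10_000
TDUP_IDENTITY_MIN = 0.80
INV_QUERY_COLINEAR_MAX = 100_000


@dataclass(frozen=True)
class AlignmentBlock:
    """Gapless anchor: equal-length ref and query intervals, one strand.

    Query coordinates are forward-strand half-open even for strand '-';
    a minus block aligns the reverse complement of its query interval.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str
    n_matches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -: {self!r}")
        if self.ref_end - self.ref_start != self.query_end - self.query_start:
            raise ValueError(f"block is not gapless (ref/query lengths differ): {self!r}")
        if self.ref_end <= self.ref_start:
            raise ValueError(f"empty block: {self!r}")
        if self.n_matches > len(self):
            raise ValueError(f"n_matches exceeds block length: {self!r}")

    def __len__(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class Chain:
    """Colinear run of blocks on one (ref_chrom, query_chrom, strand)."""

    blocks: list[AlignmentBlock]
    gap_open: float = 0.0
    gap_extend: float = 0.0

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("empty chain")
        b0 = self.blocks[0]
        for b in self.blocks:
            if (b.ref_chrom, b.query_chrom, b.strand) != (b0.ref_chrom, b0.query_chrom, b0.strand):
                raise ValueError("chain mixes chromosomes or strands")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.ref_start < a.ref_end:
                raise ValueError("chain blocks not increasing on reference")
            if a.strand == "+" and b.query_start < a.query_end:
                raise ValueError("chain blocks not increasing on query (+)")
            if a.strand == "-" and b.query_end > a.query_start:
                raise ValueError("chain blocks not decreasing on query (-)")

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def ref_chrom(self) -> str:
        return self.blocks[0].ref_chrom

    @property
    def query_chrom(self) -> str:
        return self.blocks[0].query_chrom

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.blocks[0].ref_start, self.blocks[-1].ref_end

    @property
    def query_span(self) -> tuple[int, int]:
        qs = min(b.query_start for b in self.blocks)
        qe = max(b.query_end for b in self.blocks)
        return qs, qe

    @property
    def score(self) -> float:
        return chain_score(self.blocks, self.gap_open, self.gap_extend)


def _gap_sizes(a: AlignmentBlock, b: AlignmentBlock) -> tuple[int, int]:
    """(ref gap, query gap) between adjacent chain blocks a -> b."""
    g_r = b.ref_start - a.ref_end
    if a.strand == "+":
        g_q = b.query_start - a.query_end
    else:
        g_q = a.query_start - b.query_end
    return g_r, g_q


def _adjacency_penalty(a: AlignmentBlock, b: AlignmentBlock,
                       gap_open: float, gap_extend: float) -> float:
    g_r, g_q = _gap_sizes(a, b)
    if g_r == 0 and g_q == 0:
        return 0.0
    return gap_open + gap_extend * (g_r + g_q)


def chain_score(blocks: list[AlignmentBlock], gap_open: float, gap_extend: float) -> float:
    s = float(sum(b.n_matches for b in blocks))
    for a, b in zip(blocks, blocks[1:]):
        s -= _adjacency_penalty(a, b, gap_open, gap_extend)
    return s


def _colinear(a: AlignmentBlock, b: AlignmentBlock) -> bool:
    """Can block b follow block a in a chain (strict, no overlap)?"""
    if (a.ref_chrom, a.query_chrom, a.strand) != (b.ref_chrom, b.query_chrom, b.strand):
        return False
    if b.ref_start < a.ref_end:
        return False
    if a.strand == "+":
        return b.query_start >= a.query_end
    return b.query_end <= a.query_start


def chain_blocks(blocks: list[AlignmentBlock], gap_open: float = 50.0,
                 gap_extend: float = 0.01) -> list[Chain]:
    """Partition anchors into maximal-score colinear chains.

    Sparse DP over colinear predecessors finds the best-scoring chain
    among unassigned blocks; the chain is extracted and the DP repeats
    until every block is assigned.  Output is sorted by descending
    score, ties broken by (ref_chrom, ref_start).
    """
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be >= 0")
    remaining = sorted(blocks, key=lambda b: (b.ref_chrom, b.ref_start, b.query_start))
    chains: list[Chain] = []
    while remaining:
        n = len(remaining)
        dp = [float(b.n_matches) for b in remaining]
        parent = [-1] * n
        for i in range(n):
            for j in range(i):
                if _colinear(remaining[j], remaining[i]):
                    cand = dp[j] + remaining[i].n_matches - _adjacency_penalty(
                        remaining[j], remaining[i], gap_open, gap_extend)
                    if cand > dp[i]:
                        dp[i] = cand
                        parent[i] = j
        best = max(range(n), key=lambda i: (dp[i], -remaining[i].ref_start))
        path = []
        k = best
        while k != -1:
            path.append(remaining[k])
            k = parent[k]
        path.reverse()
        chains.append(Chain(path, gap_open, gap_extend))
        used = set(id(b) for b in path)
        remaining = [b for b in remaining if id(b) not in used]
    chains.sort(key=lambda c: (-c.score, c.ref_chrom, c.ref_span[0]))
    return chains


@dataclass
class SyntenyNet:
    """Single-coverage tiling: accepted (possibly trimmed) chains.

    Accepted block intervals are pairwise disjoint on the reference and
    on the query (block granularity).  ``uncovered`` records reference
    intervals not covered by any accepted block — PAV genotyping treats
    them as missing-data zones.
    """

    chains: list[Chain] = field(default_factory=list)
    uncovered: list[tuple[str, int, int]] = field(default_factory=list)

    def covers_ref(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) lies entirely within accepted ref blocks
        of a single chain (allowing pure-insertion junction gaps)."""
        for c in self.chains:
            if c.ref_chrom != chrom:
                continue
            rs, re = c.ref_span
            if rs <= start and end <= re:
                # check no ref gap of the chain cuts into [start, end)
                ok = True
                for a, b in zip(c.blocks, c.blocks[1:]):
                    if a.ref_end < end and b.ref_start > start and b.ref_start > a.ref_end:
                        if max(start, a.ref_end) < min(end, b.ref_start):
                            ok = False
                            break
                if ok:
                    return True
        return False

    def ref_uncovered_overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(c == chrom and s < end and start < e for c, s, e in self.uncovered)


def _overlaps_any(ivs: list[tuple[int, int]], s: int, e: int) -> bool:
    return any(a < e and s < b for a, b in ivs)


def build_net(chains: list[Chain], min_span: int = DEFAULT_MIN_NET_SPAN,
              ref_lengths: dict[str, int] | None = None) -> SyntenyNet:
    """Greedy kent-style netting.

    Chains are visited in descending score order (ties by ref position);
    blocks overlapping previously accepted territory on either axis are
    trimmed away; chains whose surviving ref span falls below
    ``min_span`` are dropped.
    """
    order = sorted(chains, key=lambda c: (-c.score, c.ref_chrom, c.ref_span[0]))
    accepted: list[Chain] = []
    ref_cov: dict[str, list[tuple[int, int]]] = {}
    qry_cov: dict[str, list[tuple[int, int]]] = {}
    for chain in order:
        keep = [
            b for b in chain.blocks
            if not _overlaps_any(ref_cov.get(b.ref_chrom, []), b.ref_start, b.ref_end)
            and not _overlaps_any(qry_cov.get(b.query_chrom, []), b.query_start, b.query_end)
        ]
        if not keep:
            continue
        span = keep[-1].ref_end - keep[0].ref_start
        if span < min_span:
            continue
        trimmed = Chain(keep, chain.gap_open, chain.gap_extend)
        accepted.append(trimmed)
        for b in keep:
            ref_cov.setdefault(b.ref_chrom, []).append((b.ref_start, b.ref_end))
            qry_cov.setdefault(b.query_chrom, []).append((b.query_start, b.query_end))

    uncovered: list[tuple[str, int, int]] = []
    if ref_lengths:
        for chrom, length in sorted(ref_lengths.items()):
            ivs = sorted(ref_cov.get(chrom, []))
            pos = 0
            for s, e in ivs:
                if s > pos:
                    uncovered.append((chrom, pos, s))
                pos = max(pos, e)
            if pos < length:
                uncovered.append((chrom, pos, length))
    accepted.sort(key=lambda c: (c.ref_chrom, c.ref_span[0]))
    return SyntenyNet(accepted, uncovered)


@dataclass
class StructuralVariant:
    """One called event anchored on the reference coordinate system."""

    accession_id: str
    subtype: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    inserted_seq: str = ""
    query_chrom: str = ""
    query_start: int = -1
    query_end: int = -1

    def __post_init__(self) -> None:
        if self.subtype not in SV_SUBTYPES:
            raise ValueError(f"unknown SV subtype {self.subtype!r}")

    @property
    def length(self) -> int:
        if self.subtype in ("INS", "TDUP"):
            return len(self.inserted_seq)
        return self.ref_end - self.ref_start


def seq_identity(a: str, b: str) -> float:
    """1 - editdistance/longer-length; 1.0 when both empty."""
    if not a and not b:
        return 1.0
    longer = max(len(a), len(b))
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / longer


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    if hasattr(genome, "fetch"):
        return genome.fetch(chrom, start, end)
    seq = genome[chrom]
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(f"coordinates outside {chrom}: {start}-{end}")
    return seq[start:end]


def _query_gap_seq(chain: Chain, a: AlignmentBlock, b: AlignmentBlock, query_genome) -> str:
    """Query sequence between adjacent blocks, in reference orientation."""
    if chain.strand == "+":
        return _fetch(query_genome, a.query_chrom, a.query_end, b.query_start)
    return revcomp(_fetch(query_genome, a.query_chrom, b.query_end, a.query_start))


def call_svs(net: SyntenyNet, ref_genome, query_genome,
             min_size: int = DEFAULT_MIN_SIZE, accession_id: str = "query") -> list[StructuralVariant]:
    """Read SVs off adjacent-anchor gaps and inverted chains in the net."""
    svs: list[StructuralVariant] = []

    # inversions: minus chains whose ref span is flanked by plus coverage
    # on a colinear query territory
    plus = [c for c in net.chains if c.strand == "+"]
    minus = [c for c in net.chains if c.strand == "-"]
    inv_ref_spans: list[tuple[str, int, int]] = []
    for mc in minus:
        rs, re = mc.ref_span
        if re - rs < min_size:
            continue
        qs, qe = mc.query_span
        flanked = False
        for pc in plus:
            if pc.ref_chrom != mc.ref_chrom or pc.query_chrom != mc.query_chrom:
                continue
            prs, pre = pc.ref_span
            pqs, pqe = pc.query_span
            # plus coverage around the minus chain on ref and nearby on query
            if prs <= rs and re <= pre and abs(pqs - qs) <= INV_QUERY_COLINEAR_MAX + (pqe - pqs):
                flanked = True
                break
            if (pre <= rs or prs >= re) and min(abs(pqs - qe), abs(qs - pqe)) <= INV_QUERY_COLINEAR_MAX:
                flanked = True
                break
        if flanked:
            inv_ref_spans.append((mc.ref_chrom, rs, re))
            svs.append(StructuralVariant(
                accession_id, "INV", mc.ref_chrom, rs, re, "",
                mc.query_chrom, qs, qe))

    # adjacency gaps within chains
    for chain in net.chains:
        for a, b in zip(chain.blocks, chain.blocks[1:]):
            g_r, g_q = _gap_sizes(a, b)
            big_r = g_r >= min_size
            big_q = g_q >= min_size
            if not big_r and not big_q:
                continue
            if big_r and not big_q:
                svs.append(StructuralVariant(
                    accession_id, "DEL", a.ref_chrom, a.ref_end, b.ref_start, "",
                    a.query_chrom,
                    min(a.query_end, b.query_end), min(a.query_end, b.query_end)))
            elif big_q and not big_r:
                seq = _query_gap_seq(chain, a, b, query_genome)
                junction = a.ref_end
                subtype = "INS"
                # tandem duplication: inserted sequence repeats the flanking
                # reference sequence
                L = len(seq)
                left = _fetch(ref_genome, a.ref_chrom, max(0, junction - L), junction)
                right = _fetch(ref_genome, a.ref_chrom, b.ref_start,
                               min(b.ref_start + L, _ref_len(ref_genome, a.ref_chrom)))
                ref_start, ref_end = junction, junction
                if seq_identity(seq, left) >= TDUP_IDENTITY_MIN:
                    subtype = "TDUP"
                    ref_start, ref_end = junction - L, junction
                elif seq_identity(seq, right) >= TDUP_IDENTITY_MIN:
                    subtype = "TDUP"
                    ref_start, ref_end = b.ref_start, min(b.ref_start + L,
                                                          _ref_len(ref_genome, a.ref_chrom))
                if chain.strand == "+":
                    q_iv = (a.query_end, b.query_start)
                else:
                    q_iv = (b.query_end, a.query_start)
                svs.append(StructuralVariant(
                    accession_id, subtype, a.ref_chrom, ref_start, ref_end, seq,
                    a.query_chrom, q_iv[0], q_iv[1]))
            else:
                # both gaps large: inversion territory (handled above) or CPX
                if any(c == a.ref_chrom and max(a.ref_end, s) < min(b.ref_start, e)
                       for c, s, e in inv_ref_spans):
                    continue
                seq = _query_gap_seq(chain, a, b, query_genome)
                svs.append(StructuralVariant(
                    accession_id, "CPX", a.ref_chrom, a.ref_end, b.ref_start, seq,
                    a.query_chrom, -1, -1))

    svs.sort(key=lambda v: (v.ref_chrom, v.ref_start, v.subtype))
    return svs


def _ref_len(genome, chrom: str) -> int:
    if hasattr(genome, "chromosomes"):
        return len(genome.chromosomes[chrom])
    return len(genome[chrom])


def filter_svs(svs: list[StructuralVariant],
               gaps: list[tuple[str, int, int]] | None = None,
               centromeres: list[tuple[str, int, int]] | None = None,
               inv_gap_margin: int = 10) -> list[StructuralVariant]:
    """Drop DEL/INS/TDUP hitting assembly gaps or centromere repeats, and
    INV within ``inv_gap_margin`` bp of a gap.  Other records pass."""
    gaps = gaps or []
    centromeres = centromeres or []

    def hits(track, chrom, s, e):
        return any(c == chrom and ts < e and s < te for c, ts, te in track)

    kept: list[StructuralVariant] = []
    for sv in svs:
        if sv.subtype in ("DEL", "INS"):
            s, e = sv.ref_start, sv.ref_end
            if sv.subtype == "INS":
                s, e = sv.ref_start, sv.ref_start + 1  # junction point
            if hits(gaps, sv.ref_chrom, s, e) or hits(centromeres, sv.ref_chrom, s, e):
                logger.debug("filtered %s %s:%d-%d (gap/centromere overlap)",
                             sv.subtype, sv.ref_chrom, sv.ref_start, sv.ref_end)
                continue
        elif sv.subtype == "INV":
            if hits(gaps, sv.ref_chrom, sv.ref_start - inv_gap_margin,
                    sv.ref_end + inv_gap_margin):
                logger.debug("filtered INV %s:%d-%d (gap within %d bp)",
                             sv.ref_chrom, sv.ref_start, sv.ref_end, inv_gap_margin)
                continue
        kept.append(sv)
    return kept
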