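"""Genome assembly and gene-model containers shared across the pipeline.

Coordinates are 0-based half-open throughout; GFF3 conversion to 1-based
inclusive happens only at the file boundary (:mod:`panpav.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

NUCLEOTIDES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """Protein-coding gene: exons double as the CDS in this pipeline.

    Exons are (start, end) half-open on the forward strand, sorted and
    non-overlapping; the coding frame starts at the first exon base in
    transcription order (phase 0) and total CDS length must be a
    multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons {s1,e1} and {s2,e2}")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon {(s, e)}")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS in coding orientation."""
        parts = [chrom_seq[s:e] for s, e in self.exons]
        seq = "".join(parts)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class GenomeAssembly:
    """One accession's assembly plus its annotation tracks.

    te_intervals: (chrom, start, end, te_class) with te_class in {LTR, DNA};
    gap_intervals and centromere_intervals: (chrom, start, end).
    """

    accession_id: str
    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    te_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    gap_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    centromere_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, s, e, _cls in self.te_intervals:
            self._check(chrom, s, e, "TE")
        for chrom, s, e in self.gap_intervals:
            self._check(chrom, s, e, "gap")
        for chrom, s, e in self.centromere_intervals:
            self._check(chrom, s, e, "centromere")
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.gene_id} beyond end of {g.chrom}")

    def _check(self, chrom: str, s: int, e: int, what: str) -> None:
        if chrom not in self.chromosomes:
            raise ValueError(f"{what} interval on unknown chromosome {chrom}")
        if not (0 <= s < e <= len(self.chromosomes[chrom])):
            raise ValueError(f"{what} interval out of bounds: {chrom}:{s}-{e}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.chromosomes[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"coordinates outside {chrom}: {start}-{end}")
        return seq[start:end]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())
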