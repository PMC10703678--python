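"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
VCF (1-based) are converted at this boundary.  Every text emission other
than FASTA carries a provenance comment line with the tool version, a
config hash and the seed, so a run can be traced from its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneModel
from .synteny import AlignmentBlock, StructuralVariant

logger = logging.getLogger(__name__)

VERSION = "0.1.0"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance_line(seed=None, config=None, comment: str = "#") -> str:
    return (f"{comment}panpav v{VERSION} seed={seed if seed is not None else 'NA'} "
            f"config={config_hash(config) if config is not None else 'NA'}")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(chromosomes: dict[str, str], path: str) -> None:
    """60-column wrapped FASTA."""
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in chromosomes.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3

def write_gff3(genes: Sequence[GeneModel], path: str, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(provenance_line(seed, config) + "\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\tpanpav\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tpanpav\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.t1;Parent={g.gene_id}\n")
            exons = g.exons if g.strand == "+" else list(reversed(g.exons))
            phase = 0
            for i, (s, e) in enumerate(exons, 1):
                fh.write(f"{g.chrom}\tpanpav\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.t1.exon{i};Parent={g.gene_id}.t1\n")
                fh.write(f"{g.chrom}\tpanpav\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                         f"ID={g.gene_id}.t1.cds;Parent={g.gene_id}.t1\n")
                phase = (3 - ((e - s) - phase) % 3) % 3


def read_gff3(path: str) -> list[GeneModel]:
    """Read the flat gene/mRNA/exon/CDS dialect this package writes."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = \
                line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[fields["ID"]] = {"chrom": chrom, "strand": strand, "exons": []}
            elif ftype == "exon":
                gid = fields["Parent"].rsplit(".t1", 1)[0]
                genes[gid]["exons"].append((int(start) - 1, int(end)))
    return [GeneModel(gid, info["chrom"], info["strand"], sorted(info["exons"]))
            for gid, info in genes.items()]


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: Iterable[tuple], path: str, seed=None, config=None) -> None:
    """(chrom, start, end[, name...]) records as BED with provenance header."""
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, config) + "\n")
        for iv in sorted(intervals):
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rec = [parts[0], int(parts[1]), int(parts[2])] + parts[3:]
            out.append(tuple(rec))
    return out


# ---------------------------------------------------------------------------
# PAF

def write_paf(blocks: Sequence[AlignmentBlock], ref_lengths: dict[str, int],
              query_lengths: dict[str, int], path: str) -> None:
    """One PAF line per gapless block, with a cg:Z: tag of a single M run."""
    with open(path, "w") as fh:
        for b in blocks:
            cols = [
                b.query_chrom, query_lengths[b.query_chrom], b.query_start, b.query_end,
                b.strand, b.ref_chrom, ref_lengths[b.ref_chrom], b.ref_start, b.ref_end,
                b.n_matches, len(b), 60, f"cg:Z:{len(b)}M",
            ]
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_paf(path: str) -> list[AlignmentBlock]:
    """PAF -> gapless anchor blocks by walking the cg:Z: CIGAR.

    M/=/X runs become blocks; I and D runs split blocks (so SV calling
    stays pure coordinate arithmetic).  Records lacking a cg tag fall
    back to one coarse block spanning the whole alignment (flagged with
    a warning), which is only exact for gapless alignments.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: malformed PAF line ({len(parts)} columns)")
            qname, _qlen, qstart, qend = parts[0], int(parts[1]), int(parts[2]), int(parts[3])
            strand = parts[4]
            tname, _tlen, tstart, tend = parts[5], int(parts[6]), int(parts[7]), int(parts[8])
            cg = None
            for tag in parts[12:]:
                if tag.startswith("cg:Z:"):
                    cg = tag[5:]
                    break
            if cg is None:
                logger.warning("%s:%d: no cg:Z: tag; emitting coarse single block", path, lineno)
                n = min(int(parts[9]), min(tend - tstart, qend - qstart))
                length = min(tend - tstart, qend - qstart)
                blocks.append(AlignmentBlock(tname, tstart, tstart + length,
                                             qname, qstart, qstart + length, strand, n))
                continue
            rpos = tstart
            q_fwd = qstart          # forward-strand cursor (+)
            q_rev_end = qend        # backward cursor (-): current block ends here
            for m in _CIGAR_RE.finditer(cg):
                length, op = int(m.group(1)), m.group(2)
                if op in "M=X":
                    if strand == "+":
                        blocks.append(AlignmentBlock(tname, rpos, rpos + length,
                                                     qname, q_fwd, q_fwd + length,
                                                     strand, length))
                        q_fwd += length
                    else:
                        blocks.append(AlignmentBlock(tname, rpos, rpos + length,
                                                     qname, q_rev_end - length, q_rev_end,
                                                     strand, length))
                        q_rev_end -= length
                    rpos += length
                elif op in "DN":
                    rpos += length
                elif op == "I":
                    if strand == "+":
                        q_fwd += length
                    else:
                        q_rev_end -= length
                elif op in "SH":
                    continue
                else:
                    raise ValueError(f"{path}:{lineno}: unsupported CIGAR op {op!r}")
    return blocks


# ---------------------------------------------------------------------------
# VCF (via pysam; plain-text v4.2)

def _vcf_header(contigs: dict[str, int], samples: Sequence[str],
                sv: bool, seed=None, config=None) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    h.add_line(f"##source=panpav_v{VERSION}")
    h.add_line(provenance_line(seed, config, comment="##provenance="))
    for name, length in contigs.items():
        h.contigs.add(name, length=length)
    if sv:
        h.add_meta("INFO", items=[("ID", "SVTYPE"), ("Number", "1"), ("Type", "String"),
                                  ("Description", "Structural variant type")])
        h.add_meta("INFO", items=[("ID", "SVLEN"), ("Number", "1"), ("Type", "Integer"),
                                  ("Description", "Structural variant length")])
        h.add_meta("INFO", items=[("ID", "END"), ("Number", "1"), ("Type", "Integer"),
                                  ("Description", "End position on the reference")])
        h.add_meta("INFO", items=[("ID", "NCARRIER"), ("Number", "1"), ("Type", "Integer"),
                                  ("Description", "Number of carrier accessions")])
    h.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                ("Description", "Genotype")])
    for s in samples:
        h.add_sample(s)
    return h


_GT_CODE = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}


def write_snp_vcf(variants: pd.DataFrame, dosage: np.ndarray, samples: Sequence[str],
                  contigs: dict[str, int], path: str, seed=None, config=None) -> None:
    """SNPs as VCF v4.2.  ``variants``: chrom, pos (0-based), ref, alt;
    ``dosage``: (n_variants, n_samples) alt-allele dosage, -1 missing."""
    header = _vcf_header(contigs, samples, sv=False, seed=seed, config=config)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for i, row in enumerate(variants.itertuples(index=False)):
            rec = vf.new_record(contig=row.chrom, start=int(row.pos),
                                alleles=(row.ref, row.alt))
            rec.id = f"snp{i}" if "id" not in variants.columns else str(row.id)
            for j, s in enumerate(samples):
                rec.samples[s]["GT"] = _GT_CODE[int(dosage[i, j])]
            vf.write(rec)


def write_pav_vcf(records: Sequence[dict], samples: Sequence[str],
                  contigs: dict[str, int], path: str, seed=None, config=None) -> None:
    """PAV clusters as VCF v4.2 with SVTYPE/SVLEN/END.

    Each record dict: chrom, pos (0-based), id, svtype (DEL/INS), svlen,
    end (0-based half-open), ref, alt, genotypes (list over samples:
    1 present, 0 absent, -1 missing).
    """
    header = _vcf_header(contigs, samples, sv=True, seed=seed, config=config)
    code = {0: (0, 0), 1: (1, 1), -1: (None, None)}
    with pysam.VariantFile(path, "w", header=header) as vf:
        for r in records:
            # standard SV anchor-base convention: POS is the base before the
            # event, so printed END - POS = SVLEN for deletions
            start0 = max(0, int(r["pos"]) - 1)
            rec = vf.new_record(contig=r["chrom"], start=start0,
                                alleles=(r["ref"], r["alt"]))
            rec.id = str(r["id"])
            rec.info["SVTYPE"] = r["svtype"]
            rec.info["SVLEN"] = (-int(r["svlen"]) if r["svtype"] == "DEL"
                                 else int(r["svlen"]))
            gts = r.get("genotypes")
            if gts is not None:
                for j, s in enumerate(samples):
                    rec.samples[s]["GT"] = code[int(gts[j])]
            vf.write(rec)


def read_vcf(path: str) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """VCF -> (variant table, dosage matrix, samples).

    Variant table columns: chrom, pos (0-based), id, ref, alt, and
    svtype/svlen/end when present.  Dosage counts alt alleles per
    sample; -1 is missing.
    """
    rows = []
    dosages = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            row = {"chrom": rec.contig, "pos": rec.start, "id": rec.id,
                   "ref": rec.ref, "alt": rec.alts[0] if rec.alts else "."}
            if "SVTYPE" in rec.info:
                # undo the anchor-base convention: event starts after POS
                row["pos"] = rec.start + 1
                row["svtype"] = rec.info["SVTYPE"]
                row["svlen"] = abs(int(rec.info["SVLEN"]))
                row["end"] = rec.stop
            rows.append(row)
            dos = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dos.append(-1)
                else:
                    dos.append(sum(1 for a in gt if a != 0))
            dosages.append(dos)
    table = pd.DataFrame(rows)
    dosage = np.array(dosages, dtype=np.int8) if dosages else np.zeros((0, len(samples)), np.int8)
    return table, dosage, samples


# ---------------------------------------------------------------------------
# TSV

def write_table(df: pd.DataFrame, path: str, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, config) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def sv_table(svs: Sequence[StructuralVariant]) -> pd.DataFrame:
    return pd.DataFrame([{
        "accession_id": v.accession_id, "subtype": v.subtype,
        "ref_chrom": v.ref_chrom, "ref_start": v.ref_start, "ref_end": v.ref_end,
        "length": v.length, "inserted_seq": v.inserted_seq,
        "query_chrom": v.query_chrom, "query_start": v.query_start,
        "query_end": v.query_end,
    } for v in svs])


def svs_from_table(df: pd.DataFrame) -> list[StructuralVariant]:
    return [StructuralVariant(
        r.accession_id, r.subtype, r.ref_chrom, int(r.ref_start), int(r.ref_end),
        "" if pd.isna(r.inserted_seq) else str(r.inserted_seq),
        str(r.query_chrom), int(r.query_start), int(r.query_end))
        for r in df.itertuples(index=False)]
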