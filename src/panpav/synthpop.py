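"""Synthetic pangenome and population generator with known ground truth.

Emulates the statistical structure the downstream analyses assume for a
selfing crop panel:

* an ancestral reference genome with protein-coding genes, TE copies
  drawn from a small template library (so TE-derived insertions recur at
  high identity), assembly gaps and one centromere per chromosome;
* per-accession derived assemblies carrying implanted deletions,
  insertions (a configurable fraction TE-derived), inversions, tandem
  duplications and complex replacements, together with exact-anchor
  alignment blocks and a truth set in reference coordinates;
* a structured population (one wild subpopulation plus three cultivated
  ones) of homozygous diploid SNP and PAV genotypes whose allele
  frequencies follow a Balding–Nichols divergence model calibrated so
  realized windowed diversity approximates the configured per-site
  targets, with one designated low-diversity/high-differentiation sweep
  region;
* phenotypes driven by designated causal variants at a configured
  heritability, and FPKM matrices where PAV-carrier genes are
  down-shifted.

All randomness flows from one integer seed through named per-task
generators, so adding a generator does not perturb the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import GeneModel, GenomeAssembly, revcomp
from .synteny import AlignmentBlock, StructuralVariant

BASES = np.frombuffer(b"ACGT", dtype="S1")


class CapacityError(ValueError):
    """Requested feature density exceeds chromosome capacity."""


def named_rng(seed: int, name: str) -> np.random.Generator:
    """Independent generator keyed by (seed, task name)."""
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions.

    Diversity targets default to the published per-site estimates for
    the wild (6.7e-4) and cultivated (4.2e-4) gene pools; the TE-derived
    insertion fraction defaults to the observed 68.3% share of
    TE-derived PAVs.
    """

    seed: int = 0
    # ancestral genome
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 120
    n_te: int = 240
    te_library_size: int = 10
    te_length_range: tuple[int, int] = (400, 3000)
    te_divergence_range: tuple[float, float] = (0.01, 0.05)
    n_gaps_per_chrom: int = 2
    gap_length: int = 2_000
    centromere_fraction: float = 0.04
    # per-accession SVs
    sv_counts: dict[str, int] = field(default_factory=lambda: {
        "DEL": 18, "INS": 18, "INV": 1, "TDUP": 2, "CPX": 1})
    delins_size_range: tuple[int, int] = (100, 5_000)
    inv_size_range: tuple[int, int] = (20_000, 40_000)
    tdup_size_range: tuple[int, int] = (100, 1_000)
    cpx_size_range: tuple[int, int] = (100, 2_000)
    te_derived_fraction: float = 0.683
    min_sv_spacing: int = 300
    # population
    n_wild: int = 30
    n_cultivated: int = 200
    n_cultivated_subpops: int = 3
    target_pi_wild: float = 0.00067
    target_pi_cultivated: float = 0.00042
    subpop_fst: float = 0.05
    snp_missing_rate: float = 0.02
    het_rate: float = 0.0          # selfing lines: heterozygous calls off by default
    sweep_chrom_index: int = 0
    sweep_start: int = 300_000
    sweep_length: int = 100_000
    sweep_reduction: float = 5.0
    # population PAVs
    n_pav_loci: int = 300
    n_shifted_pavs: int = 50
    shifted_freq_wild: float = 0.1
    shifted_freq_cultivated: float = 0.7
    pav_missing_rate: float = 0.05
    # phenotypes & expression
    n_traits: int = 2
    n_causal: int = 5
    heritability: float = 0.8
    n_expressed_genes: int = 400
    n_pav_genes: int = 100
    fpkm_pav_downshift: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.heritability <= 1.0):
            raise ValueError(f"heritability must be in (0, 1], got {self.heritability}")
        for name in ("te_derived_fraction", "centromere_fraction", "snp_missing_rate",
                     "pav_missing_rate", "het_rate", "shifted_freq_wild",
                     "shifted_freq_cultivated"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes", "chromosome_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v < 0 for v in self.sv_counts.values()):
            raise ValueError("sv_counts must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def mutate_sequence(rng: np.random.Generator, seq: str, divergence: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_mut = int(round(divergence * len(arr)))
    if n_mut:
        pos = rng.choice(len(arr), size=min(n_mut, len(arr)), replace=False)
        arr[pos] = rng.choice(BASES, size=len(pos))
    return arr.tobytes().decode()


@dataclass
class TELibrary:
    sequences: list[str]
    classes: list[str]


def make_te_library(config: SimulationConfig, rng: np.random.Generator) -> TELibrary:
    if not (5 <= config.te_library_size <= 20):
        raise ValueError("te_library_size must be in 5..20")
    lo, hi = config.te_length_range
    seqs, classes = [], []
    for i in range(config.te_library_size):
        seqs.append(random_sequence(rng, int(rng.integers(lo, hi + 1))))
        classes.append("LTR" if i % 2 == 0 else "DNA")
    return TELibrary(seqs, classes)


def _place_features(rng: np.random.Generator, chrom_len: int,
                    occupied: list[tuple[int, int]], lengths: list[int],
                    pad: int, what: str, max_tries: int = 200) -> list[tuple[int, int]]:
    """Sample non-overlapping intervals of the given lengths."""
    placed: list[tuple[int, int]] = []
    occ = sorted(occupied)
    for L in lengths:
        for _ in range(max_tries):
            if chrom_len - L - pad <= pad:
                raise CapacityError(f"{what}: feature of {L} bp does not fit "
                                    f"on a {chrom_len} bp chromosome")
            s = int(rng.integers(pad, chrom_len - L - pad))
            e = s + L
            if not any(a - pad < e and s < b + pad for a, b in occ):
                placed.append((s, e))
                occ.append((s, e))
                break
        else:
            raise CapacityError(
                f"{what}: could not place a {L} bp feature after {max_tries} tries; "
                f"requested density exceeds chromosome capacity")
    return placed


def simulate_ancestral_genome(config: SimulationConfig,
                              te_library: TELibrary | None = None
                              ) -> tuple[GenomeAssembly, TELibrary]:
    """Ancestral (reference) genome with annotation tracks."""
    rng_seq = named_rng(config.seed, "ancestral-sequence")
    rng_feat = named_rng(config.seed, "ancestral-features")
    if te_library is None:
        te_library = make_te_library(config, named_rng(config.seed, "te-library"))

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chromosomes: dict[str, str] = {}
    te_intervals: list[tuple[str, int, int, str]] = []
    gap_intervals: list[tuple[str, int, int]] = []
    cen_intervals: list[tuple[str, int, int]] = []
    genes: list[GeneModel] = []

    n_genes_per = _split_count(config.n_genes, config.n_chromosomes)
    n_te_per = _split_count(config.n_te, config.n_chromosomes)

    gene_counter = 0
    for ci, chrom in enumerate(chrom_names):
        L = config.chromosome_length
        seq = np.frombuffer(random_sequence(rng_seq, L).encode(), dtype="S1").copy()

        # centromere in the middle: tandem repeat of a 137-bp monomer
        cen_len = int(L * config.centromere_fraction)
        cen_s = (L - cen_len) // 2
        monomer = random_sequence(rng_seq, 137)
        cen_seq = (monomer * (cen_len // len(monomer) + 1))[:cen_len]
        seq[cen_s:cen_s + cen_len] = np.frombuffer(cen_seq.encode(), dtype="S1")
        cen_intervals.append((chrom, cen_s, cen_s + cen_len))
        occupied = [(cen_s, cen_s + cen_len)]

        # assembly gaps (N runs)
        gaps = _place_features(rng_feat, L, occupied,
                               [config.gap_length] * config.n_gaps_per_chrom,
                               pad=100, what="gaps")
        for s, e in gaps:
            seq[s:e] = b"N"
            gap_intervals.append((chrom, s, e))
        occupied += gaps

        # TE copies from the library, 1-5% diverged per copy
        idx = rng_feat.integers(0, len(te_library.sequences), size=n_te_per[ci])
        te_lens = [len(te_library.sequences[i]) for i in idx]
        te_pos = _place_features(rng_feat, L, occupied, te_lens, pad=20, what="TEs")
        for (s, e), i in zip(te_pos, idx):
            div = rng_feat.uniform(*config.te_divergence_range)
            copy = mutate_sequence(rng_feat, te_library.sequences[i], div)
            seq[s:e] = np.frombuffer(copy.encode(), dtype="S1")
            te_intervals.append((chrom, s, e, te_library.classes[i]))
        occupied += te_pos

        # genes: 2-6 exons, CDS length divisible by 3, ATG...stop structure
        gene_spans = []
        gene_structs = []
        for _ in range(n_genes_per[ci]):
            n_ex = int(rng_feat.integers(2, 7))
            exon_lens = [int(rng_feat.integers(40, 120)) * 3 for _ in range(n_ex)]
            intron_lens = [int(rng_feat.integers(80, 400)) for _ in range(n_ex - 1)]
            span = sum(exon_lens) + sum(intron_lens)
            gene_structs.append((exon_lens, intron_lens))
            gene_spans.append(span)
        gene_pos = _place_features(rng_feat, L, occupied, gene_spans, pad=200, what="genes")
        for (gs, _ge), (exon_lens, intron_lens) in zip(gene_pos, gene_structs):
            strand = "+" if rng_feat.random() < 0.5 else "-"
            exons = []
            pos = gs
            for k, el in enumerate(exon_lens):
                exons.append((pos, pos + el))
                pos += el
                if k < len(intron_lens):
                    pos += intron_lens[k]
            gene_counter += 1
            gid = f"gene{gene_counter:05d}"
            genes.append(GeneModel(gid, chrom, strand, exons))
            # stamp start/stop codons so the CDS is structurally plausible
            cds_exons = exons if strand == "+" else list(reversed(exons))
            if strand == "+":
                seq[exons[0][0]:exons[0][0] + 3] = np.frombuffer(b"ATG", dtype="S1")
                seq[exons[-1][1] - 3:exons[-1][1]] = np.frombuffer(b"TGA", dtype="S1")
            else:
                seq[cds_exons[0][1] - 3:cds_exons[0][1]] = \
                    np.frombuffer(revcomp("ATG").encode(), dtype="S1")
                seq[cds_exons[-1][0]:cds_exons[-1][0] + 3] = \
                    np.frombuffer(revcomp("TGA").encode(), dtype="S1")
        chromosomes[chrom] = seq.tobytes().decode()

    genome = GenomeAssembly("ancestral", chromosomes, genes, te_intervals,
                            gap_intervals, cen_intervals)
    return genome, te_library


def _split_count(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


# ---------------------------------------------------------------------------
# Derived accession genomes

@dataclass
class TruthSet:
    svs: list[StructuralVariant] = field(default_factory=list)
    causal_variants: list[tuple[str, float]] = field(default_factory=list)
    population_labels: dict[str, str] = field(default_factory=dict)


def _sample_sv_events(config: SimulationConfig, ancestral: GenomeAssembly,
                      rng: np.random.Generator,
                      te_library: TELibrary) -> list[dict]:
    """Non-overlapping event requests on the ancestral coordinate system."""
    size_ranges = {"DEL": config.delins_size_range, "INS": config.delins_size_range,
                   "INV": config.inv_size_range, "TDUP": config.tdup_size_range,
                   "CPX": config.cpx_size_range}
    chroms = sorted(ancestral.chromosomes)
    events: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    pad = config.min_sv_spacing
    for subtype in ("INV", "DEL", "CPX", "TDUP", "INS"):   # big events placed first
        lo, hi = size_ranges[subtype]
        for _ in range(config.sv_counts.get(subtype, 0)):
            size = int(rng.integers(lo, hi + 1))
            if size <= 50:
                size = 51
            for _try in range(300):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                L = len(ancestral.chromosomes[chrom])
                footprint = 1 if subtype == "INS" else size
                s = int(rng.integers(pad, L - footprint - pad))
                e = s + footprint
                if any(a - pad < e and s < b + pad for a, b in occupied[chrom]):
                    continue
                ev = {"subtype": subtype, "chrom": chrom, "start": s,
                      "end": s if subtype == "INS" else e, "size": size}
                if subtype == "INS":
                    if rng.random() < config.te_derived_fraction:
                        i = int(rng.integers(0, len(te_library.sequences)))
                        base = te_library.sequences[i]
                        if len(base) < size:
                            base = (base * (size // len(base) + 1))
                        div = rng.uniform(*config.te_divergence_range)
                        ev["seq"] = mutate_sequence(rng, base[:size], div)
                        ev["te_derived"] = True
                        ev["te_class"] = te_library.classes[i]
                    else:
                        ev["seq"] = random_sequence(rng, size)
                        ev["te_derived"] = False
                elif subtype == "CPX":
                    ev["seq"] = random_sequence(rng, max(51, int(size * 0.8)))
                occupied[chrom].append((s, e if e > s else s + 1))
                events.append(ev)
                break
            else:
                raise CapacityError(f"could not place a {subtype} of {size} bp; "
                                    "reduce sv_counts or sizes")
    events.sort(key=lambda ev: (ev["chrom"], ev["start"]))
    return events


def check_sv_requests(events: list[dict]) -> None:
    """Reject overlapping SV requests, naming the conflicting pair."""
    by_chrom: dict[str, list[dict]] = {}
    for ev in events:
        by_chrom.setdefault(ev["chrom"], []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda ev: ev["start"])
        for a, b in zip(evs, evs[1:]):
            a_end = max(a["end"], a["start"] + 1)
            if b["start"] < a_end:
                raise ValueError(
                    f"overlapping SV requests on {chrom}: "
                    f"{a['subtype']}@{a['start']}-{a['end']} vs "
                    f"{b['subtype']}@{b['start']}-{b['end']}")


def derive_accession_genome(ancestral: GenomeAssembly, config: SimulationConfig,
                            accession_id: str, seed: int | None = None,
                            te_library: TELibrary | None = None,
                            events: list[dict] | None = None,
                            ) -> tuple[GenomeAssembly, TruthSet, list[AlignmentBlock]]:
    """Apply implanted SVs to the ancestral genome.

    Returns the derived assembly, the truth set (reference coordinates)
    and exact-anchor alignment blocks ancestral -> derived.
    """
    if seed is None:
        seed = config.seed
    rng = named_rng(seed, f"derive-{accession_id}")
    if te_library is None:
        te_library = make_te_library(config, named_rng(config.seed, "te-library"))
    if events is None:
        events = _sample_sv_events(config, ancestral, rng, te_library)
    check_sv_requests(events)

    truth = TruthSet()
    chroms: dict[str, str] = {}
    blocks: list[AlignmentBlock] = []
    by_chrom: dict[str, list[dict]] = {c: [] for c in ancestral.chromosomes}
    for ev in events:
        by_chrom[ev["chrom"]].append(ev)

    for chrom in sorted(ancestral.chromosomes):
        ref = ancestral.chromosomes[chrom]
        parts: list[str] = []
        r0 = 0          # ref cursor
        q0 = 0          # query cursor

        def emit_syntenic(up_to: int) -> None:
            nonlocal r0, q0
            if up_to > r0:
                L = up_to - r0
                parts.append(ref[r0:up_to])
                blocks.append(AlignmentBlock(chrom, r0, up_to, chrom, q0, q0 + L, "+", L))
                r0, q0 = up_to, q0 + L

        for ev in sorted(by_chrom[chrom], key=lambda ev: ev["start"]):
            st = ev["subtype"]
            s, e = ev["start"], ev["end"]
            if st == "DEL":
                emit_syntenic(s)
                truth.svs.append(StructuralVariant(accession_id, "DEL", chrom, s, e))
                r0 = e
            elif st == "INS":
                emit_syntenic(s)
                seq = ev["seq"]
                parts.append(seq)
                sv = StructuralVariant(accession_id, "INS", chrom, s, s, seq,
                                       chrom, q0, q0 + len(seq))
                truth.svs.append(sv)
                q0 += len(seq)
            elif st == "INV":
                emit_syntenic(s)
                seg = revcomp(ref[s:e])
                parts.append(seg)
                blocks.append(AlignmentBlock(chrom, s, e, chrom, q0, q0 + (e - s),
                                             "-", e - s))
                truth.svs.append(StructuralVariant(accession_id, "INV", chrom, s, e,
                                                   "", chrom, q0, q0 + (e - s)))
                r0, q0 = e, q0 + (e - s)
            elif st == "TDUP":
                # extra tandem copy of ref[s:e) inserted right after e
                emit_syntenic(e)
                seg = ref[s:e]
                parts.append(seg)
                truth.svs.append(StructuralVariant(accession_id, "TDUP", chrom, s, e,
                                                   seg, chrom, q0, q0 + len(seg)))
                q0 += len(seg)
            elif st == "CPX":
                emit_syntenic(s)
                seq = ev["seq"]
                parts.append(seq)
                truth.svs.append(StructuralVariant(accession_id, "CPX", chrom, s, e, seq))
                r0 = e
                q0 += len(seq)
        emit_syntenic(len(ref))
        chroms[chrom] = "".join(parts)

    derived = GenomeAssembly(accession_id, chroms)
    expected = ancestral.total_length \
        - sum(v.ref_end - v.ref_start for v in truth.svs if v.subtype == "DEL") \
        + sum(len(v.inserted_seq) for v in truth.svs if v.subtype in ("INS", "TDUP")) \
        + sum(len(v.inserted_seq) - (v.ref_end - v.ref_start)
              for v in truth.svs if v.subtype == "CPX")
    assert derived.total_length == expected, "sequence-length conservation violated"
    return derived, truth, blocks


# ---------------------------------------------------------------------------
# Population simulation

#: expected heterozygosity 2*E[p(1-p)] for p ~ U(0.05, 0.95)
_UNIFORM_FREQ_LO, _UNIFORM_FREQ_HI = 0.05, 0.95


def _expected_het_uniform(lo: float, hi: float) -> float:
    # E[2p(1-p)] for p ~ U(lo, hi), in closed form
    m1 = (lo + hi) / 2
    m2 = (hi - lo) ** 2 / 12 + m1 ** 2
    return 2 * (m1 - m2)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    if fst <= 0:
        return p.copy()
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return rng.beta(np.maximum(a, 1e-3), np.maximum(b, 1e-3))


@dataclass
class PopulationSim:
    """Bundle of all population-scale simulated inputs."""

    samples: list[str]
    labels: dict[str, str]
    snp_variants: pd.DataFrame          # chrom, pos, ref, alt
    snp_dosage: np.ndarray              # (n_snp, n_samples) in {0,1,2,-1}
    pav_variants: pd.DataFrame          # chrom, pos, end, svtype, id, shifted
    pav_presence: np.ndarray            # (n_pav, n_samples) in {0,1,-1}
    phenotypes: pd.DataFrame            # accession + trait columns
    fpkm: pd.DataFrame                  # genes x accessions
    truth: TruthSet
    sweep_region: tuple[str, int, int]
    pav_gene_map: dict[str, str]        # gene_id -> pav id (down-shifted genes)
    chrom_lengths: dict[str, int]


def simulate_population(config: SimulationConfig) -> PopulationSim:
    if config.n_wild + config.n_cultivated < 4:
        raise ValueError("need at least 4 accessions")
    rng_snp = named_rng(config.seed, "population-snps")
    rng_pav = named_rng(config.seed, "population-pavs")
    rng_phe = named_rng(config.seed, "population-phenotypes")
    rng_exp = named_rng(config.seed, "population-expression")

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = {c: config.chromosome_length for c in chrom_names}

    samples = [f"W{i + 1:03d}" for i in range(config.n_wild)]
    labels = {s: "W1" for s in samples}
    per = _split_count(config.n_cultivated, config.n_cultivated_subpops)
    for k, n_k in enumerate(per, start=1):
        for i in range(n_k):
            name = f"C{k}_{i + 1:03d}"
            samples.append(name)
            labels[name] = f"C{k}"
    n_samples = len(samples)
    wild_idx = np.array([i for i, s in enumerate(samples) if labels[s] == "W1"])
    sub_idx = {f"C{k}": np.array([i for i, s in enumerate(samples) if labels[s] == f"C{k}"])
               for k in range(1, config.n_cultivated_subpops + 1)}

    # --- SNPs: density calibrated to the wild diversity target
    e_het = _expected_het_uniform(_UNIFORM_FREQ_LO, _UNIFORM_FREQ_HI)
    density = config.target_pi_wild / e_het
    base_fst = 1.0 - config.target_pi_cultivated / config.target_pi_wild
    sweep_chrom = chrom_names[config.sweep_chrom_index]
    sweep_s, sweep_e = config.sweep_start, config.sweep_start + config.sweep_length
    sweep_fst = 1.0 - (1.0 - base_fst) / config.sweep_reduction

    rows = []
    dosage_cols = []
    for chrom in chrom_names:
        L = chrom_lengths[chrom]
        n_sites = int(round(density * L))
        pos = np.sort(rng_snp.choice(L, size=n_sites, replace=False))
        p_w = rng_snp.uniform(_UNIFORM_FREQ_LO, _UNIFORM_FREQ_HI, size=n_sites)
        in_sweep = (chrom == sweep_chrom) & (pos >= sweep_s) & (pos < sweep_e)
        fst_site = np.where(in_sweep, sweep_fst, base_fst)
        p_c = np.empty(n_sites)
        for f in np.unique(fst_site):
            m = fst_site == f
            p_c[m] = _balding_nichols(rng_snp, p_w[m], float(f))
        dos = np.empty((n_sites, n_samples), dtype=np.int8)
        carrier_w = rng_snp.random((n_sites, len(wild_idx))) < p_w[:, None]
        dos[:, wild_idx] = np.where(carrier_w, 2, 0)
        for sub, idxs in sub_idx.items():
            p_k = _balding_nichols(rng_snp, p_c, config.subpop_fst)
            carrier = rng_snp.random((n_sites, len(idxs))) < p_k[:, None]
            dos[:, idxs] = np.where(carrier, 2, 0)
        if config.het_rate > 0:
            het_mask = rng_snp.random(dos.shape) < config.het_rate
            dos[het_mask & (dos == 2)] = 1
        miss = rng_snp.random(dos.shape) < config.snp_missing_rate
        dos[miss] = -1
        ref = rng_snp.choice(BASES, size=n_sites).astype("U1")
        alt = np.array([_other_base(rng_snp, r) for r in ref])
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}))
        dosage_cols.append(dos)
    snp_variants = pd.concat(rows, ignore_index=True)
    snp_dosage = np.vstack(dosage_cols)

    # --- PAV loci with a designated frequency-shifted subset
    n_pav = config.n_pav_loci
    pav_chrom = np.array([chrom_names[i % len(chrom_names)] for i in range(n_pav)])
    pav_pos = np.sort(rng_pav.integers(0, config.chromosome_length - 5000, size=n_pav))
    pav_len = rng_pav.integers(100, 5000, size=n_pav)
    shifted = np.zeros(n_pav, dtype=bool)
    shifted[rng_pav.choice(n_pav, size=config.n_shifted_pavs, replace=False)] = True
    freq_w = rng_pav.uniform(0.05, 0.9, size=n_pav)
    freq_c = freq_w.copy()
    freq_w[shifted] = config.shifted_freq_wild
    freq_c[shifted] = config.shifted_freq_cultivated
    presence = np.empty((n_pav, n_samples), dtype=np.int8)
    presence[:, wild_idx] = (rng_pav.random((n_pav, len(wild_idx)))
                             < freq_w[:, None]).astype(np.int8)
    cult_idx = np.concatenate([sub_idx[k] for k in sorted(sub_idx)])
    presence[:, cult_idx] = (rng_pav.random((n_pav, len(cult_idx)))
                             < freq_c[:, None]).astype(np.int8)
    miss = rng_pav.random(presence.shape) < config.pav_missing_rate
    presence[miss] = -1
    pav_ids = [f"pav{i + 1:05d}" for i in range(n_pav)]
    pav_variants = pd.DataFrame({
        "chrom": pav_chrom, "pos": pav_pos, "end": pav_pos + pav_len,
        "svtype": np.where(np.arange(n_pav) % 2 == 0, "DEL", "INS"),
        "id": pav_ids, "shifted": shifted,
    })

    # --- phenotypes driven by designated causal SNPs
    truth = TruthSet(population_labels=dict(labels))
    pheno = {"accession": samples}
    for t in range(config.n_traits):
        causal = rng_phe.choice(len(snp_variants), size=config.n_causal, replace=False)
        effects = rng_phe.normal(0.0, 1.0, size=config.n_causal)
        dos = snp_dosage[causal].astype(float)
        dos[dos < 0] = 0.0
        g = effects @ dos
        var_g = float(np.var(g))
        if config.heritability >= 1.0 or var_g == 0.0:
            noise = np.zeros(n_samples)
        else:
            sd = np.sqrt(var_g * (1 - config.heritability) / config.heritability)
            noise = rng_phe.normal(0.0, sd, size=n_samples)
        pheno[f"trait{t + 1}"] = g + noise
        for ci, eff in zip(causal, effects):
            v = snp_variants.iloc[int(ci)]
            truth.causal_variants.append((f"trait{t + 1}:{v.chrom}:{int(v.pos)}", float(eff)))
    phenotypes = pd.DataFrame(pheno)

    # --- FPKM: PAV-carrier genes down-shifted
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_expressed_genes)]
    base = rng_exp.lognormal(mean=1.5, sigma=1.0, size=config.n_expressed_genes)
    fpkm = base[:, None] * rng_exp.lognormal(0.0, 0.15,
                                             size=(config.n_expressed_genes, n_samples))
    pav_gene_idx = rng_exp.choice(config.n_expressed_genes, size=config.n_pav_genes,
                                  replace=False)
    pav_for_gene = rng_exp.choice(n_pav, size=config.n_pav_genes, replace=False)
    pav_gene_map: dict[str, str] = {}
    for gi, pi in zip(pav_gene_idx, pav_for_gene):
        carriers = presence[pi] == 1
        fpkm[gi, carriers] *= config.fpkm_pav_downshift
        pav_gene_map[gene_ids[gi]] = pav_ids[pi]
    fpkm_df = pd.DataFrame(fpkm, index=gene_ids, columns=samples).round(4)
    fpkm_df.index.name = "gene_id"

    return PopulationSim(samples, labels, snp_variants, snp_dosage, pav_variants,
                         presence, phenotypes, fpkm_df, truth,
                         (sweep_chrom, sweep_s, sweep_e), pav_gene_map, chrom_lengths)


def _other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[int(rng.integers(0, 3))]


def simulate_xpclr_track(config: SimulationConfig, window: int = 20_000,
                         step: int = 2_000) -> pd.DataFrame:
    """Surrogate XP-CLR score track (chrom, start, end, score).

    XP-CLR itself is consumed, not computed, by this pipeline; this
    surrogate emulates its shape: exponential background noise with
    scores elevated inside the designated sweep region.
    """
    rng = named_rng(config.seed, "xpclr-surrogate")
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sweep_chrom = chrom_names[config.sweep_chrom_index]
    sweep_s = config.sweep_start
    sweep_e = config.sweep_start + config.sweep_length
    rows = []
    for chrom in chrom_names:
        L = config.chromosome_length
        for start in range(0, L - window + 1, step):
            end = start + window
            score = float(rng.exponential(1.0))
            if chrom == sweep_chrom:
                ov = max(0, min(end, sweep_e) - max(start, sweep_s))
                score += 10.0 * ov / window
            rows.append((chrom, start, end, score))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
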