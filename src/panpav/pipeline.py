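"""End-to-end convenience pipelines over the library modules.

These are the same call sequences the CLI wires together: simulate a
pangenome panel, call SVs per accession from exact-anchor alignments,
merge them into the nonredundant PAV set, and score the calls against
the implanted truth; plus the composite selective-sweep scan.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import IntervalSet
from .merge import (EvalReport, MergeParams, PAVCluster, evaluate_calls,
                    genotype_from_assemblies, merge_pavs)
from .popscan import (GenotypeMatrix, SweepSet, intersect_sweeps, jaccard,
                      pi_ratio_track, smooth_track, top_quantile_regions,
                      track_from_frame, windowed_fst, windowed_pi)
from .synteny import (StructuralVariant, SyntenyNet, build_net, call_svs,
                      chain_blocks, filter_svs)
from .synthpop import (PopulationSim, SimulationConfig, derive_accession_genome,
                       simulate_ancestral_genome, simulate_population,
                       simulate_xpclr_track)


@dataclass
class RoundTripResult:
    ancestral: object
    calls: dict[str, list[StructuralVariant]]       # filtered calls per accession
    truths: dict[str, list[StructuralVariant]]      # filtered truth per accession
    nets: dict[str, SyntenyNet]
    clusters: list[PAVCluster]
    report: EvalReport                              # DEL/INS only, aggregated

    @property
    def precision(self) -> float:
        return self.report.precision

    @property
    def recall(self) -> float:
        return self.report.recall


def sv_roundtrip(config: SimulationConfig, n_accessions: int = 5,
                 min_truth_size: int = 0,
                 min_net_span: int = 10_000) -> RoundTripResult:
    """Simulate accessions, call and merge SVs, score against truth.

    Both call and truth sets pass the same gap/centromere filter, so
    precision and recall measure recovery outside the filtered zones.
    ``min_truth_size`` additionally restricts scoring to truth events of
    at least that many bp.
    """
    ancestral, _te_lib = simulate_ancestral_genome(config)
    ref_lengths = {c: len(s) for c, s in ancestral.chromosomes.items()}
    calls: dict[str, list[StructuralVariant]] = {}
    truths: dict[str, list[StructuralVariant]] = {}
    nets: dict[str, SyntenyNet] = {}
    tp = fp = fn = 0
    for i in range(n_accessions):
        acc = f"ACC{i + 1:02d}"
        derived, truth, blocks = derive_accession_genome(
            ancestral, config, acc, seed=config.seed)
        chains = chain_blocks(blocks)
        net = build_net(chains, min_span=min_net_span, ref_lengths=ref_lengths)
        raw = call_svs(net, ancestral, derived, accession_id=acc)
        flt = filter_svs(raw, ancestral.gap_intervals, ancestral.centromere_intervals)
        truth_flt = filter_svs(truth.svs, ancestral.gap_intervals,
                               ancestral.centromere_intervals)
        calls[acc] = flt
        truths[acc] = truth_flt
        nets[acc] = net
        rep = evaluate_calls(
            [v for v in flt if v.subtype in ("DEL", "INS")],
            [v for v in truth_flt if v.subtype in ("DEL", "INS")
             and v.length >= min_truth_size])
        tp += rep.true_positive
        fp += rep.false_positive
        fn += rep.false_negative
    all_calls = [v for acc in sorted(calls) for v in calls[acc]]
    clusters = merge_pavs(all_calls, MergeParams())
    genotype_from_assemblies(clusters, nets)
    return RoundTripResult(ancestral, calls, truths, nets, clusters,
                           EvalReport(tp, fp, fn))


@dataclass
class SweepScanResult:
    sim: PopulationSim
    sweeps: SweepSet
    truth_region: IntervalSet
    jaccard: float
    tracks: dict


def sweep_scan(config: SimulationConfig, q: float = 0.05) -> SweepScanResult:
    """Composite sweep scan: top-5% pi-ratio, F_ST and smoothed XP-CLR."""
    sim = simulate_population(config)
    gt = GenotypeMatrix(sim.snp_variants, sim.snp_dosage, sim.samples, sim.labels)
    cultivated = sorted({l for l in sim.labels.values() if l != "W1"})
    pi_w = windowed_pi(gt, "W1", sim.chrom_lengths)
    pi_c = windowed_pi(gt, cultivated, sim.chrom_lengths)
    ratio = pi_ratio_track(pi_w, pi_c)
    fst = windowed_fst(gt, "W1", cultivated, sim.chrom_lengths)
    xpclr = track_from_frame(simulate_xpclr_track(config), "xpclr_raw")
    xpclr_smooth = smooth_track(xpclr, chrom_lengths=sim.chrom_lengths)
    sets = {
        "pi_ratio": top_quantile_regions(ratio, q),
        "fst": top_quantile_regions(fst, q),
        "xpclr": top_quantile_regions(xpclr_smooth, q),
    }
    sweeps = intersect_sweeps(sets)
    truth = IntervalSet([sim.sweep_region])
    return SweepScanResult(sim, sweeps, truth,
                           jaccard(sweeps.regions, truth),
                           {"pi_wild": pi_w, "pi_cultivated": pi_c,
                            "pi_ratio": ratio, "fst": fst,
                            "xpclr_smooth": xpclr_smooth})
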