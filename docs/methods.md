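# Methods

`panpav` implements an assembly-based presence/absence-variation (PAV)
analysis for a selfing crop pangenome: syntenic structural-variant (SV)
calling from whole-genome alignment anchors, nonredundant PAV
construction and annotation, gene-family occupancy analysis, composite
selective-sweep scanning, and GWAS post-processing.  A synthetic-data
module generates every input with known ground truth, so the whole
pipeline is exercised and scored end to end.

## Syntenic SV calling (`synteny`)

Alignments are consumed as gapless anchor blocks: equal-length
reference/query intervals on one strand.  The PAF reader splits aligner
CIGARs at every I/D run, so an anchor never hides an indel and SV
calling reduces to coordinate arithmetic between adjacent anchors —
the same contract as the classic chain/net workflow.

**Chaining.** Anchors are chained by dynamic programming over strictly
colinear predecessors (increasing on both axes, same chromosomes and
strand).  The score is the sum of anchor match counts minus a per-gap
penalty `gap_open + gap_extend * (ref_gap + query_gap)` (defaults 50 and
0.01; the defaults only matter for pathological anchor sets, since real
syntenic anchors dominate any penalty).  The best chain is extracted and
the DP repeats on the remaining anchors, so each anchor joins at most
one chain.  On small inputs this procedure is verified against an
exhaustive search over all colinear anchor subsets.

**Netting.** Chains are accepted greedily by descending score (ties by
reference position).  A candidate's blocks that overlap previously
accepted territory on either the reference or the query axis are
trimmed away at block granularity; chains whose surviving reference
span falls below `min_span` (default 10 kb) are dropped.  The result is
single coverage on both axes — the filter that removes nonorthologous
and nonsyntenic alignments.  Reference intervals covered by no accepted
block are recorded as missing-data zones for genotyping.

**Calling.** For each adjacent anchor pair within a chain, with
reference gap `g_r` and query gap `g_q` and a minimum size of 51 bp
(events of exactly 50 bp are excluded; the floor is strictly >50 bp):

| condition | call |
|---|---|
| `g_r >= min`, `g_q < min` | DEL over the reference gap |
| `g_q >= min`, `g_r < min` | INS at the junction, sequence from the query |
| both `>= min` | CPX (unless an accepted inversion chain explains the gap) |

An INS whose sequence matches the immediately flanking reference
sequence at >= 80% identity (edlib global alignment over the inserted
length) is reclassified as a tandem duplication (TDUP) anchored on the
duplicated reference unit.  A minus-strand chain flanked by plus-strand
coverage on a colinear query territory (within 100 kb) is called INV
over its reference span.  A strictly colinear chain cannot contain a
backward-stepping adjacency, so duplication detection via sequence
identity is the coherent operator definition here; it recovers
simulated tandem duplications at exact coordinates.

**Filtering.** Deletions and insertions whose reference footprint
(insertions: the junction point) intersects an assembly gap or
centromere interval are removed; inversions are removed when a gap lies
within 10 bp of their span.  Everything else passes unchanged.

## PAV merging and evaluation (`merge`)

Per-accession SVs are merged into population clusters under the link
relation: deletions/inversions link when the reciprocal overlap — the
intersection divided by each event's length, minimum of the two
ratios — exceeds 0.90 (a one-sided mode dividing by the longer length
only is available behind a flag); insertions link when their junctions
are less than 10 bp apart and the inserted sequences share more than
80% identity (1 − edit distance / longer length — symmetric and
deterministic, no alignment heuristics).  Clusters are single-linkage
connected components, verified against a brute-force transitive-closure
oracle.  The representative is the member linking directly to the most
other members (ties: longest, then leftmost, then accession id) — the
medoid under the link relation, chosen because no published rule
exists.  Inversions are clustered but excluded from the PAV matrix,
which holds deletions and insertions only.

Assembly-based genotypes per (cluster, accession): *present* when the
accession contributed a member SV, *absent* when its net covers the
representative interval syntenically with no linked SV, *missing* when
the interval falls in an uncovered net zone.  Call sets are scored
against truth by greedy one-to-one matching under the same link
relation, reporting precision, recall and F1.

## Annotation (`annotate`)

A PAV is *TE-derived* when >= 90% of its footprint is covered by the
union (not the sum) of TE intervals; insertions are matched against the
TE template library by edlib infix alignment, with the identity
measured over the inserted length.  The 90% boundary is inclusive.
Genic context uses the precedence coding > intron > upstream 2 kb >
downstream 2 kb > intergenic with strand-aware flanks; the reported
distance is to the nearest gene body (0 when touching).  A gene is
*lost* when carried deletions jointly cover 100% of its CDS;
*pseudogenized* when a deletion removes a complete exon, start or stop
codon, or when CDS-hitting events shift the coding length by a
non-multiple of three.  These loss/pseudogenization criteria are
operator definitions of this package.

Expression impact compares carrier and non-carrier FPKM per gene with a
two-sided Wilcoxon rank-sum test and Benjamini–Hochberg correction,
keeping the conventional decision thresholds (|fold change| >= 1.5,
adjusted P <= 0.05, fold change computed with a 0.1 pseudo-count so
silenced genes give bounded ratios).  A rank test on FPKM was chosen
over a count-model fit because the pipeline consumes FPKM matrices, not
read counts; the decision rule is unchanged.  Genes with FPKM < 1 are
flagged silenced.  Groups below 3 members are reported untested.

## Gene-family occupancy (`pangene`)

With N genomes, a family present in all N is *core*, in N−2..N−1
*softcore*, in exactly one genome *private*, otherwise *dispensable*
(the N=32 instantiation gives the 32 / 30–31 / 2–29 / 1 windows).  For
small N the windows can collide; the documented precedence is
core → softcore → private → dispensable.  Rarefaction draws, for each
subsample size k, `n_draws` (default 100) uniform genome subsets
without replacement and reports mean and spread of the pan (union) and
core (intersection) family counts.

Per-family diversity uses the alignment formula
`pi = D / L / (N(N−1)/2)`, with L the number of conserved columns and D
the total pairwise mismatches over those columns.  "Conserved" is
interpreted as gap-free (and N-free) columns, and D as per-pair
mismatches — the pairs denominator in the formula requires pairwise
counting rather than segregating sites.

## Population scans (`popscan`)

`windowed_pi` follows the VCFtools convention: per site
`h = 2c(n−c)/(n(n−1))` over called allele copies, summed per 20-kb
window at a 2-kb step and divided by the window length in bp.
`windowed_fst` implements the Weir–Cockerham (1984) variance components
a, b, c per site with the weighted window estimator Σa/Σ(a+b+c); sites
monomorphic across both populations are skipped, and the estimator may
be slightly negative near zero differentiation.  The π-ratio track is
π_wild/π_cultivated per window, flagged missing (never infinite) on
zero or missing denominators.

XP-CLR is consumed as a precomputed per-window score track; the module
applies only 100-kb/10-kb midpoint smoothing and thresholding.
Smoothing precedes thresholding (the alternative order is a flag).
Sweep candidates per track are windows at or above the empirical
order-statistic (1−q) quantile with q = 0.05 — inclusive threshold, no
interpolation — merged into intervals; the final sweep set is the
base-pair intersection supported by all supplied tracks.

LD decay reports mean composite r² (squared Pearson correlation of
genotype dosages) per 1-kb distance bin for same-chromosome pairs
within 500 kb, after MAF >= 0.01 and heterozygosity <= 0.8 filters.
4DTv extraction keeps SNPs at third positions of fourfold-degenerate
codons (prefix set derived from the standard codon table at import),
strand-aware, requiring degeneracy in every overlapping CDS.  The
wild-vs-cultivated PAV frequency shift is a two-sided Fisher exact test
on the presence × population 2×2 table of called genotypes with BH
correction; the exact test was chosen because group sizes per PAV are
small and unbalanced.

## GWAS post-processing (`assoc`)

The significance threshold is the uniform 0.05/n rule.  Variant filters
default to MAF >= 0.05 with missing rate <= 0.1 (SNP panels) or <= 0.5
(PAV panels).  Candidate regions are defined by iterative 200-kb
extension from each significant variant, implemented as single-linkage
clustering of significant variants with inter-variant gaps <= 200 kb
and bounded at the first/last significant member — the two procedures
are proven equal by a 1,000-layout randomized equivalence test.  Region
peaks are the smallest P, ties leftmost.  A region is *reliable* when
overlapping regions appear in at least two environment/year result
sets.  Mixed-model association itself is consumed from external
results; a plain dosage trend test is provided for synthetic end-to-end
runs and does not correct for population structure.

Gene haplotypes are allele strings over homozygous calls at the
variants within the gene body ± 2 kb; accessions with a missing or
heterozygous call at any selected site are excluded, groups are
numbered by descending size (Hap1 largest) and groups under 10 members
are flagged small.  Phenotypes are compared across groups with
Kruskal–Wallis plus a Nemenyi post-hoc (studentized-range distribution
on joint mean ranks) and a compact letter display; two groups fall back
to the two-sided Wilcoxon rank-sum.  Term enrichment is the upper-tail
hypergeometric P(X >= k) with BH correction.

## Synthetic data (`synthpop`)

The generator emulates the statistical structure the analyses assume,
not the biology of any real genome:

* **Ancestral genome** — i.i.d. random sequence with one tandem-repeat
  centromere per chromosome (default 4% of its length), N-run assembly
  gaps (2 per chromosome, 2 kb), TE copies drawn from a library of 10
  templates at 1–5% per-copy divergence (so TE-derived insertions recur
  at >= 80% identity and exercise the insertion merge rule), and
  multi-exon genes with phase-0 CDS, ATG/TGA stamped at the termini.
  Features are placed uniformly without overlap; an explicit capacity
  error is raised when the requested density cannot be placed.
* **Derived accessions** — non-overlapping implanted events per
  accession (defaults 18 DEL, 18 INS, 1 INV, 2 TDUP, 1 CPX; DEL/INS
  100–5,000 bp, INV 20–40 kb so inversion chains survive the 10-kb net
  span floor, TDUP units 100–1,000 bp, CPX replacements 100–2,000 bp).
  68.3% of insertions are TE-derived, matching the published share of
  TE-derived PAVs.  Alignment blocks are emitted directly from the
  event coordinates (exact anchors); sequence-length conservation is
  asserted on every derived genome.
* **Population** — one wild group (n = 30) and three cultivated
  subpopulations (n = 200 total), genotyped as homozygous diploid calls
  (selfing lines; a heterozygosity rate is a config option, default
  off).  Wild allele frequencies are uniform on (0.05, 0.95); the SNP
  density is set analytically to d = π_wild / E[2p(1−p)] so realized
  windowed diversity matches the target (defaults π_wild = 6.7e-4,
  π_cultivated = 4.2e-4, the published estimates).  Cultivated
  frequencies follow a Balding–Nichols divergence model whose F is
  derived from the diversity ratio (F = 1 − π_c/π_w ≈ 0.37), which
  yields both the diversity contrast and realistic differentiation from
  one parameter; within the designated sweep region (100 kb) the
  cultivated diversity is reduced a further 5-fold via
  F_region = 1 − (1−F)/5.  A designated PAV subset (50 of 300) is
  frequency-shifted from 0.1 (wild) to 0.7 (cultivated); phenotypes are
  sums of designated causal-SNP effects plus Gaussian noise at the
  configured heritability (default 0.8); FPKM is log-normal per gene
  with carriers of gene-linked PAVs multiplied by 0.3.
* All randomness flows from one seed through named per-task generators
  (SeedSequence keyed by a hash of the task name), so adding a
  generator does not perturb the others and identical configurations
  are byte-identical on disk.

What the generator does **not** emulate: linkage disequilibrium and
recombination (sites are independent given the frequency model),
coalescent genealogies, demographic history, alignment error or
breakpoint ambiguity (anchors are exact unless a real aligner is
substituted), read-level noise, and gene-expression count models.
Passing recovery tests therefore demonstrates the correctness of the
coordinate arithmetic, merge logic and statistical procedures under the
stated conditions, not their robustness to aligner artifacts on real
assemblies.

## Problem sizes

The bundled checks run at desk scale, chosen so the full suite
completes in seconds: the SV round trip uses 5 accessions × 5 Mb with
200 implanted events each (recovering >= 90% of deletions/insertions
outside filtered zones at >= 90% precision, with exact coordinates for
exact-anchor events); the sweep scan uses 2 × 1 Mb chromosomes,
230 accessions and ~3,700 SNPs per run over 10 seeds; the null
calibration of the haplotype test uses 1,000 simulations (3 × 20
samples).  Headline worked examples (Bonferroni threshold, F1 triples,
occupancy and frequency shares) are recomputed from the published
counts and are exact.

## Known limitations

* Reciprocal-alignment confirmation is a flag on the caller, not a
  second full calling pass; the reference-vs-query direction defines
  the call set.
* TDUP/CPX delimitation is an operator definition (see above); complex
  nested rearrangements all fall to CPX.
* The net's greedy acceptance is kent-style, not an optimal interval
  scheduling; ties are broken deterministically by position.
* `genotype_from_assemblies` treats any linked member SV as presence;
  partial/heterozygous assembly representation is out of scope.
* The trend test supplied for synthetic GWAS runs does not correct for
  population structure and must not be used for real panels.
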