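# Methods

## Scope and model

The package maps a fully penetrant recessive defect from very few affected
individuals by autozygosity: affecteds descending from a common ancestor on
both parental paths are homozygous for an ancestral haplotype around the
causal allele, so the causal region must lie inside a run of homozygosity
(ROH) shared — and identical by descent — across all affecteds. Downstream,
the region is interrogated with a case-homozygous/control-absent variant
filter and a transcript-level consequence analysis. All genomic coordinates
are 1-based with inclusive intervals; interval length is end − start + 1
(reported in Mb at two decimals).

## ROH scanning

The scanner is the standard SNP-array windowed algorithm. For each marker,
the hit rate is the fraction of overlapping windows of `window_snps`
consecutive markers that contain at most `window_max_het` heterozygous and
`window_max_missing` missing calls; windows are clamped at chromosome ends
(markers near an end overlap fewer windows, and a chromosome shorter than
the window is scanned as one truncated window). Markers with hit rate ≥
`hit_rate_threshold` form candidate runs; runs are broken at inter-marker
gaps above `max_gap_kb` and at heterozygous calls beyond `max_het_in_roh`,
and maximal surviving stretches are emitted when they satisfy `min_snps`,
`min_kb` and the marker-density bound `min_density_kb_per_snp`. Missing
calls inside a final segment are allowed (only heterozygous calls are
bounded); segment boundaries are reported at marker positions.

Defaults (all exposed on `RohParams`): 500 kb, 20 SNPs, 40-SNP windows,
0 het per final segment, 1 het / 5 missing per window, hit-rate threshold
0.05, 1000 kb maximum gap, 50 kb/SNP density. The first four are the
standard settings for sparse (~1 SNP / 60 kb) arrays; the rest are the
scanning tool family's published defaults. The scanner is verified against
a brute-force oracle that replicates the hit-rate mask and then enumerates
every (start, end) pair.

## IBD and carriers without phasing

Inside an ROH the genotype determines the haplotype, so haplotype identity
between two affecteds is decided from genotypes alone: a marker mismatches
when the two animals carry *different homozygotes*; markers with missing
(or, defensively, heterozygous) calls are skipped and counted. A shared
region is IBD iff the mismatch count is zero. Statistical phasing is
deliberately not used; this genotype rule is exact within zero-het runs.

Cohort carrier classification is an unphased compatibility rule against a
query allele vector: homozygous carrier (query homozygote at every marker,
up to `max_mismatch` exceptions, default 0), heterozygous carrier (every
genotype contains the query allele, at least one heterozygous), non-carrier
(query allele absent beyond the tolerance). Missing calls make a sample
*ambiguous* whenever resolving them optimistically vs. pessimistically
changes the verdict. Compatibility overstates carriage relative to phased
matching; with ~45-marker queries the two coincide in practice, and
ambiguous is an explicit outcome rather than a guess. Haplotype frequency
is (n_het + 2·n_hom) / (2·n_unambiguous).

## Homozygote depletion

With allele frequency q and N sampled animals, homozygotes are
Binomial(N, q²) under Hardy–Weinberg proportions and random sampling.
`binomial_exact` (default) reports P(X ≤ observed); for observed = 0 this
is (1 − q²)^N. The Poisson(Nq²) form is offered as the common
approximation; both agree within 10% for Nq² ≤ 10 at q ≤ 0.05. The
expected count Nq² and the "1 in 1/q²" recurrence rate are reported with
their conventional roundings alongside raw values. Exact
(Clopper–Pearson) intervals summarise small fertility proportions, and
Fisher's exact test (conditional odds ratio) compares case/control arms.

## Variant filtering and annotation

The three-criterion filter requires (a) position inside the mapped
interval, (b) homozygous-alternate in every case, (c) homozygous-alternate
in zero controls. A missing control genotype never counts as homozygous
(criterion c is about *observed* homozygotes); a record lacking a case
genotype entry is rejected conservatively and tallied. Per-stage counts
are logged and reported. Genotype-quality thresholds are not applied;
qualities pass through as qualifiers.

Annotation uses a single-transcript gene model (exons, strand, CDS, locus
sequence). The canonical splice regions are exactly the first two (donor,
GT) and last two (acceptor, AG) intronic bases in transcript orientation;
extended splice-region classes are not implemented. Coding SNVs are
translated in codon context (synonymous / missense / stop-gained); exonic
non-CDS positions are UTR; multi-base variants are anchored at their
left-aligned reference interval, and an indel spanning an exon/intron
boundary — or any in-CDS indel, whose outcome is not a codon substitution —
is surfaced as `complex` rather than guessed. Severity ranking:
splice_donor = splice_acceptor = stop_gained > missense > synonymous >
UTR > intronic > intergenic, with position as tie-break.

## Splice-disruption outcome

Cryptic-site selection is a minimal nearest-GT rule: candidate GT
dinucleotides on the transcript strand are collected within
`search_window_bp` (default 50) exonic bases upstream and intronic bases
downstream of the destroyed donor in the mutant pre-mRNA; the nearest
wins, ties exonic-first; with no candidate the exon is skipped. No
position-weight-matrix scoring is attempted — the rule is meant to recover
an experimentally demonstrated site from sequence geometry, not to predict
splice strength ab initio.

The mutant mRNA is rebuilt, the CDS re-translated, and the outcome
summarised by the signed transcript change, frameshift flag
(|change| mod 3 ≠ 0), first altered residue, premature-stop residue and
truncation fraction (L − (stop − 1)) / L — with L = 332 and stop = 200
this renders as 40% — plus RT-PCR product lengths obtained by exact primer
matching on each isoform (a junction-spanning primer simply finds no site
in an isoform lacking its junction). A stop is *premature* when the mutant
protein is shorter than the change itself implies (any shortening under a
frameshift; shorter than wild type ± the codon delta for in-frame
changes), so an in-frame deletion terminating at the natural stop is not
flagged. A premature stop more than 50 nt upstream of the last exon-exon
junction is flagged as a likely nonsense-mediated-decay substrate (the
standard rule; decay is not modelled quantitatively).

## Synthetic data: what it emulates and what it does not

Generators produce every input with *exact* truth. The genotype model is
marker-independent sampling at a configurable background heterozygosity
(default 0.35) — no background linkage disequilibrium, no allele-frequency
spectrum, no genotyping-batch structure — because no pipeline stage
exploits those features and independence makes every planted truth
scorable exactly. Three deliberate constructions keep truth exact rather
than merely probable: case autozygosity ends with a forced heterozygous
call at the first flanking marker (so run boundaries are sharp);
heterozygous-carrier controls carry the complement allele on their second
haplotype at every planted marker; and a non-carrier whose random
background is accidentally carrier-compatible has one genotype flipped to
the opposite homozygote. Missing calls (default rate 0.27%) avoid planted
and boundary markers. Consequently, passing recovery tests demonstrates
algorithmic correctness on idealised data, not robustness to real-array
artefacts (clustered markers, LD, batch missingness).

Default cohort structure: 29 chromosomes × 1434 markers, two affected
homozygotes, planted haplotype at 2.5% carrier frequency with homozygous
controls excluded (rare homozygous draws are demoted to carriers; bias
~q²). Marker spacing defaults to ~42 kb so a planted run clears the
scanner's 50 kb/SNP density bound — a stylized, denser stand-in for real
maps whose genome-wide mean spacing is sparser but locally variable.

The gene fixture is a synthetic reverse-strand nine-exon gene (no real
genomic sequence): 999-nt CDS (332 codons + stop) with cumulative coding
length 472 at the exon-4 donor, a unique in-exon GT ten transcript bases
upstream of the donor, downstream sequence engineered so the shifted frame
first stops at codon 200 with divergence from residue 155, and a primer
pair (exon-3/4 junction forward, exon-6 reverse) giving a 368-bp wild-type
product. Intron 4's first 50 bases use an A/C alphabet so the mutant
intron is GT-free in the search window — the construction guarantees the
nearest-GT rule has exactly one candidate, a documented test-design
choice. The generator verifies itself at build time by translating both
isoforms independently of the predictor and fails loudly on any violation.

Fertility tables are binomial draws at configured arm probabilities
(defaults: 0/9 vs 42/89 conceptions; 36/320 vs 105/150 cleavage; 3/320 vs
34/150 embryo yield).

## Numerical and design choices

- PLINK 1 binary trio is read/written by a built-in codec (variant-major,
  2-bit codes, zero padding) with byte-identical round-trips; VCF goes
  through pysam with multiallelic records split per alternate allele
  (the filter criteria are per-allele).
- Marker call-rate filtering is strict (> threshold); the per-individual
  call rate is computed and logged but never filtered on.
- Carrier-matching tolerance `max_mismatch` defaults to 0; whether a
  published carrier count was obtained by phased matching or genotype
  compatibility is generally unstated, so both the rule and its tolerance
  are explicit configuration, logged per run.
- The depletion default is the exact binomial, since the only stated
  assumption behind such tests is Hardy–Weinberg proportions. Note that
  published depletion P values for this design cannot always be
  reproduced from that assumption alone; the implementation reports what
  the stated methods give and records the method label in the result.
- The truncation convention (L − (stop − 1))/L is one of two off-by-one
  possibilities; it is fixed here and stated in reports rather than
  silently assumed.
- Pipeline reports are rendered from stage artifacts only (no computation
  at render time); re-runs with identical inputs are byte-identical.

## Problem sizes

Tests and the acceptance script use scaled synthetic instances chosen as
the smallest sizes that exercise every code path: oracle-checked scans on
≤ 1000-marker chromosomes, 100-cohort filter batteries at 60 variants
each, 50–100 region-recovery trials on 720-marker chromosomes, and one
8557-animal single-chromosome cohort emulation for the carrier
arithmetic.

## Known limitations

- Single-transcript gene models only; no genome-wide annotation sets, no
  extended splice-region or UTR-regulatory classes, no protein-impact
  scores.
- Splice model is geometric (nearest GT); no PWM/MaxEnt strength scoring,
  no multi-site competition, no quantitative NMD modelling.
- Carrier classification from unphased data is a compatibility statement,
  not proof of carriage.
- The synthetic genotype model's independence assumptions (above) bound
  what green tests imply about real array data.
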