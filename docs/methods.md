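# Methods

## Coordinates and conventions

All intervals are 0-based half-open (BED convention) internally; VCF
positions are converted on load. Interval merging is strand-agnostic and
bookend-inclusive (touching intervals merge), matching the convention of
counting merged candidate loci. N bases are excluded from GC/CpG/GpC
denominators; G4Hunter scores them 0. chrY is excluded by default from
mutation and conservation analyses (configurable via
`PipelineConfig.exclude_chroms`). Every loader and filter logs counts in
and out.

## G4 detection

**Consensus scan.** The motif is `G{3,}([ACGTN]{1,7}G{3,}){3,}` and its
C-complement, reported on the minus strand. Loops may contain G: the
regex backtracks, so a single long G-run can serve as run–loop–run, which
is required for oligos such as the 25-mer with an internal 7-G run. The
scanner anchors a greedy match at every G-run start (not just after the
previous match), then merges overlapping spans into maximal extents; this
agrees with a breadth-first parse enumerator on random sequences (tested
on 100 × 500 bp).

**G4Hunter.** Per-base scores are `±min(run length, 4)` for G/C runs and
0 otherwise. Width-*w* windows (step 1) with mean |score| ≥ *s* are kept;
runs of consecutive qualifying windows merge into one region spanning
first window start to last window end, scored by its mean base score,
with strand from the sign. Sequences shorter than *w* are scored as one
full-length window so short oligos can be scored at all. Published
G4Hunter variants differ in post-threshold trimming; the default here is
merge-without-trimming, with `refine="trim-to-runs"` available to trim
region ends to the first/last base of the scoring sign.

## GC-adjusted enrichment

Fold enrichment of a region is its G4 bp density over the genome-wide
density, so the genome as a single bin has fold exactly 1 and the
length-weighted mean of bin densities equals the background. Because fold
tracks GC strongly, significance uses a quadratic regression of fold on
GC fraction fitted by least squares over non-overlapping training
windows; the training window size is selected from a candidate grid by
10-fold cross-validation (degree fixed at 2; the grid defaults to
0.5/1/2/4 Mb and is configurable — at desk scale tests use 10–25 kb).
A region's p-value is `2·min(pct, 1−pct)` where `pct` is its residual's
percentile among training residuals, floored at `1/(n+1)` (the raw
percentile gives p = 0 at the extremes) and capped at 1; BH adjustment is
applied within chromosomes. Under uniform synthetic planting the test's
type-I error at α = 0.05 sits in [0.02, 0.08] when the training window
size equals the reporting bin size; training at a coarser size than the
reporting bins (as when training on multi-megabase windows and reporting
fine bins) makes fine-bin residuals over-dispersed relative to the null
and the test anti-conservative for depleted bins — the example script
therefore trains at the reporting size.

## Matched controls

For each G4 the search draws up to 5 uniform random same-chromosome
anchors and tests windows of identical length at shifts 0, +1, −1, +2, −2,
… up to 10,000 attempts per anchor (both budgets configurable; the
attempt budget is otherwise unspecified in the procedure this follows).
Acceptance requires GC fraction and CpG/GpC counts within the reciprocal
tolerance `|a−b| ≤ tol·max(a,b)` (tol = 0.10); zero-vs-zero counts pass,
zero-vs-nonzero fail. Window metrics come from per-chromosome prefix
sums, so each shift costs O(1). Accepted candidates overlapping the union
of both detectors' G4s are removed post hoc. Controls may overlap each
other unless `disjoint_controls` is set.

## Methylation

Region methylation is the unweighted mean of per-CpG call levels inside
the region (not bp-weighted); regions without calls are flagged uncovered
and excluded. States: hypo < 0.2 ≤ methylated < 0.8 ≤ hyper. The
compartment profile is a Dirichlet over the three states with uniform
prior α = (1,1,1): one multinomial(1, q) draw per step at the MLE
q = n/Σn updates the posterior, whose mean after m steps is
`(α + drawn)/(3 + m) → q`. Stopping requires every point of the trailing
100-step window to lie within tol = 1e-4 of the current posterior mean;
endpoint-only comparisons can trigger spuriously when the random walk
returns near its start. At the stopping time the residual sampling noise
is ~0.005, so independent seeds agree to ~0.01, not to the tolerance
itself. Group comparisons use two-sided Mann–Whitney U and KS with
Bonferroni (default) across compartments.

## Variants

Classification is strictly sequential on allele lengths: equal & unit →
substitution; equal & longer → MNP; unit ref, longer alt → insertion
(small iff inserted length ≤ 50 bp); ref longer than alt → deletion
(small iff ≤ 50 bp); the remaining case (multi-base ref with longer alt)
falls outside the rule table and is labelled `complex`, excluded from
per-class enrichment by default. Multi-allelic rows are split first, one
alternate per record, with per-allele AF carried. Mutation windows are
midpoint ± 50 bp (midpoint = `pos + ⌊len(ref)/2⌋`), clipped at chromosome
ends.

Two enrichment read-outs are provided, because "enrichment near
mutations" is genuinely ambiguous: `g4_enrichment_at_mutations` measures
G4 bp density inside the merged class windows relative to the genome-wide
G4 density (with the GC-adjusted residual test at the pooled window GC,
and the same computation on matched controls), while
`mutation_rate_enrichment` measures the mutation rate per bp inside
G4 ± 50 bp relative to the rate outside. The latter is the consistent
estimator of the generator's planted proximity factor ρ and is what the
recovery tests check; the former is the figure-style density fold.

## Microstructure

Canonical G4s are consensus motifs with exactly four G-runs (≥ 3 G);
loops are the gaps between runs; flanks are 500 bp each side. The profile
vector has 500 + 4×20 + 3×30 + 500 = 1,170 positions. A substitution in a
run/loop of length L occupies base span `[x, x+1)`, mapped to bin span
`[x·B/L, (x+1)·B/L)` and allocated to bins proportionally to overlap —
total mass is conserved exactly. Flank substitutions land in their single
1-bp position. Minus-strand motifs are mirrored so position 0 is the
motif-strand 5′ flank. `fold` is mass over mean mass (mean exactly 1);
because a flank position is 1 bp while a run bin covers L/20 bp, a
uniform mutation field is *not* flat in `fold` — `density_fold`
additionally divides by the accumulated per-position bp width and is flat
at 1 under the null, which is what the flat-null test asserts.

Trinucleotides collapse into 32 canonical classes (lexicographic minimum
of a triplet and its reverse complement; classes are closed under reverse
complement). Genome counts slide width-3 windows skipping N. Mutability
is substitutions-with-context per genome occurrence. G4 enrichment
expands merged G4s by 1 bp, counts class occurrences inside, and counts a
substitution only when its full trinucleotide occurrence lies inside the
expanded region so numerator and denominator cover identical windows
(without this the binomial test is anti-conservative, ~9% type-I at
α = 0.05). Per class, a two-tailed binomial test compares the observed
G4 substitution count against the genome-wide per-occurrence rate, BH
across the 32 classes.

## Pangenome conservation

MAF blocks are read with Biopython; the reference row is chosen by source
prefix. Overlapping reference spans violate the MAF contract and raise.
A G4 is located when one block fully covers its reference interval;
reference gaps stretch the aligned column span. Per-haplotype identity is
the percentage of columns where the haplotype base equals the reference
base (gaps count as mismatch). "Conserved" defaults to found with ≥ 50%
identity in at least one haplotype (`rule="any"`; `mean` and `all` are
provided because the upstream alignment score definition is not
restated). H_i counts haplotype rows in the block. Bin share uses
`bin(x) = 1 + ⌊B·x/S⌋` with B = 2000, assigning each aligned G4 by its
start and end (straddlers count in both bins), and averages
`H_i / haplotype_total` (default 88, the pangenome haplotype count; set
to the simulated count at desk scale). Sharing statistics operate on
distinct motif sequences per haplotype; the pairwise matrix is Jaccard.

## PRDM9 peaks

Peak windows are midpoint ± 1000 bp (the `half` parameter accepts 2000
for the wider axis). Occurrence at an offset is window-level presence of
G4 coverage. Profiles are normalised by the window mean (mean exactly 1);
bootstrap bands resample peaks with replacement (N = 1000, 2.5th/97.5th
percentiles); fewer than 10 peaks refuses the bootstrap. The proximal
summary reports the maximum normalised enrichment and whether its argmax
lies within ±250 bp of the midpoint, ties broken toward offset 0.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at desk scale (default 2 × 1 Mb chromosomes, seed-deterministic;
a single seed fans out to per-stage generators via `SeedSequence` spawn
keys so stages regenerate independently):

- **Genome**: i.i.d. background at 41% GC (the human genome-wide value);
  planted motifs `G{r1} L1 G{r2} L2 G{r3} L3 G{r4}` with run lengths
  uniform 3–5 and loop lengths uniform 1–7 from a G-free loop alphabet,
  flanked by forced A so the planted interval is the maximal local match
  (recall is exactly 1 by construction). An optional region receives
  ρ_bin-fold planting density.
- **Variants**: exact multinomial class counts from the mixture (70%
  substitution, 5% MNP, 10%/2.5% small/large insertion, 10%/2.5%
  small/large deletion — substitution-dominated, as in germline callsets);
  positions uniform within two disjoint strata, with the G4 ± 50 bp
  stratum at ρ_mut times the background per-bp rate; REF read from the
  genome; indel lengths straddle the 50/51 boundary; AF ~ Beta(2, 5).
- **Methylation**: per-region state from the mixture, levels from
  Beta(1,9)/Beta(5,5)/Beta(9,1), 1–20 calls per region. Component overlap
  means a small fraction of regions classify away from their planted
  state; at 5,000 regions the recovered mixture still lands within ±0.03.
- **MAF**: blocks of 10–50 kb tiling the reference disjointly; each of H
  haplotypes (default 10 at desk scale) substitutes bases independently
  at the divergence rate, with optional short deletions (default off, so
  identity has the clean binomial expectation 1 − d); the reference row
  stays ungapped (gapped-reference handling is unit-tested on
  hand-constructed blocks).
- **Peaks**: fraction q centred within ±200 bp of a planted G4 midpoint,
  remainder uniform.

What the simulator does **not** emulate: satellite higher-order repeat
grammar, regional GC heterogeneity and isochores, linked variants or
phasing, insertion columns in the reference MAF row, and replication
timing. Passing recovery tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
property of real assemblies.

## Problem sizes

The test suite runs on 0.3–1 Mb genomes with 10⁴–2×10⁴ variants, 5,000
methylation regions, 6–10 haplotypes and 200–400 peaks; calibration
checks pool 5 genome replicates (residual test) and 12 variant replicates
× 32 classes (binomial test). These sizes give standard errors safely
inside the asserted tolerances while keeping the suite fast on one CPU.

## Known limitations

- The consensus scanner's maximal-span semantics (union of greedy
  anchored matches) matches the brute-force enumerator on all tested
  sequences but greedy backtracking is not formally leftmost-longest.
- Empirical residual p-values are discrete with floor 1/(n+1); small
  training sets bound attainable significance after BH.
- The density fold at mutation windows is not the planted rate factor ρ
  (see Variants above); both quantities are exposed.
- Full-genome reproduction of published candidate counts depends on the
  unspecified post-processing variant of the upstream G4Hunter script;
  the `refine` switch brackets the plausible choices.
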