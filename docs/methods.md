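# Methods

## Probe design model

Infinium methylation probes are 50-mers complementary to bisulphite-converted
genomic DNA around a target CpG.  Sodium bisulphite converts unmethylated
cytosines to uracil (read as T after amplification) and leaves
5-methylcytosine intact; methylation is modelled as occurring only at CpG
dinucleotides.  Conversion of a window therefore has three modes:
`methylated` (CpG C kept, other C → T), `unmethylated` (every C → T) and
`degenerate` (CpG C → Y), the last encoding the either-state body CpGs of
Type II probes.  Whether a window-terminal C is a CpG is decided from the
genomic base following the window, never from the window cut.

The four-character IlmnID suffix fixes the geometry.  Working in
target-strand space `S` (the `Forward_Sequence` context for T designs, its
reverse complement for B designs) with the target C at index `u`:

| design | window in `S` | probe | extension reads |
|---|---|---|---|
| Type I, C | `S[u : u+50]` | revcomp of converted window | next base (`S[u-1]`) |
| Type I, O | `S[u-50 : u]` | converted window | converted target C |
| Type II, C | `S[u+1 : u+51]` | revcomp of degenerate window | converted target C |
| Type II, O | `S[u-50 : u]` | degenerate window | converted target C |

Type I emits two probes (Allele A = unmethylated, Allele B = methylated);
Type II one degenerate probe.  The O-strand Type I placement follows from the
documented fact that such probes extend at the target C itself: the probe
must abut, not cover, the target.  A consequence worth knowing: an O-strand
Type I probe whose window contains no body CpG has identical Allele A/B
bodies — discrimination is carried entirely by the extension readout — so
allele divergence is asserted only at CpG-derived positions, not universally.
For C-strand Type I designs the manifest's `Next_Base` is the incorporated
ddNTP (A/T → red channel, C/G → green); for O-strand designs the extension
readout is epitype-dependent and the designer records the methylated-template
base.  These placements are conventions validated by exact round-tripping
against the synthetic designer; on a real manifest a small fraction of rows
is expected to disagree and is reported, never "fixed".

## Coordinates

Internally every located probe carries the 1-based plus-strand position of
the interrogated cytosine (Illumina `MAPINFO` convention); BED-style 0-based
half-open intervals (SeSAMe dialect) are converted at the boundary.  Point vs
2-nt-range agreement widens the point to its CpG dinucleotide under both
possible strand conventions before intersecting, so the check is symmetric in
which strand's C produced the point.  Probes with `CHR = chr0` are retained
in tables but excluded from all location-keyed operations.

## Cross-hybridisation scan

Four genome variants are built: forward, fully C→T-converted forward
(the unmethylated limit; the unconverted genome serves as the methylated
proxy), reverse complement, and converted reverse complement.  Probes are
aligned on **both query strands** against each variant — necessary because a
probe complementary to a converted-strand segment matches no variant on the
plus strand alone.  The built-in aligner is exhaustive at toy scale: a
vectorised Hamming scan (degenerate-aware: R ≡ A/G, Y ≡ C/T, never a
mismatch) enumerates every ungapped window, and a seed-and-extend pass
(exact 10-mers, which pigeonhole-guarantee detection at ≤ 4 edits; edlib
infix alignment with k = 6 in candidate windows) adds indel alignments.
Genome-scale runs are delegated to external BLAT and ingested as PSL.

Filtering uses matches ≥ 47 and score ≥ 44 with
`score = matches − mismatches − query_gap_openings − target_gap_openings`
(for ungapped 50-mers, `score = 2·matches − 50`, so 47 matches ⇔ score 44).
Every scanned probe lands in exactly one of: no homology, no homology at
MAPINFO, not cross-hybridising, cross-hybridising (≥ 1 passing alignment
beyond the on-target one).

**Transposition.**  The interrogated cytosine's query offset is computed from
the on-target blocks and walked through each off-target's blocks; offsets
falling in an alignment gap are skipped and counted.  Because Type II and
opposite-strand windows abut rather than cover the target C (up to 2 nt away
for bottom-strand O designs), the offset map extrapolates linearly up to two
bases beyond a terminal block.  Off-target bases are read from the
unconverted genome in orientation *relative to the on-target alignment* (the
MAPINFO anchor reads C on the plus strand by convention); a C followed by G
in that orientation is CpG, otherwise CpH, with contig-end successors flagged
undecidable.

## Cross-platform model

Arrays are analysed as M-values, `M = log2(β/(1−β))` with
`β = C/(C+T+100)`; WGBS counts as `log2((C+0.5)/(T+0.5))`, i.e.
`logit2((C+0.5)/(C+T+1))`.  All RMSE and consensus computations run in
M/logit space; β-space input is transformed at the boundary (boundary values
require an explicit clip, default 1e-6 where implicit).

The row-linear consensus fit regresses each platform's per-site values on the
across-platform sample means (an inter-platform adaptation of the ASTM E691
interlaboratory design): slope = sensitivity, residual scatter = precision
with denominator n − 2 (two fitted parameters).  When every platform enters
the consensus, slopes average to exactly 1 per site.  A centred (Mandel)
parameterisation is available; it changes only the intercept.

Matching drops any site with detection p > 0.05 in any sample on any array,
or zero WGBS coverage in any sample; duplicate-location EPICv2 probes resolve
to the probe appearing first in the manifest; every exclusion is logged with
its reason.  Technical replicates are chosen by fewest detection-p failures.

**Replicate adjudication.**  Each member of a replicate set, and the set's
sample mean, get sensitivity/precision by regressing on a *shared* consensus:
the mean of the set mean, EPICv1 and WGBS over the samples complete in every
member and platform.  Sharing the regressor makes the slope linear in the
response, so the set-mean sensitivity equals the member average — exactly
intermediate of the member extremes, which a per-member consensus only
approximates (and occasionally violates).  Verdicts: `superior` (strictly
best slope and scatter vs all members and the mean), `inferior` (strictly
worst both), otherwise `best_sensitivity` plus either `best_precision` (a
member) or `best_precision_by_group_mean` (the mean is most precise).
Sensitivity ties break by better precision, then manifest order, and are
logged.  Without EPICv1, minimum RMSE against WGBS decides
`superior_by_WGBS`/`inferior_by_WGBS`, upgraded to
`superior_group_mean_WGBS` when the sample mean beats every member; sets
under the dropout threshold are `insufficient`.  The 12-of-18 complete-pair
rule is parameterised (`min_pairs`) so other sample counts scale.

**Cross-reactivity evidence.**  A probe with ≥ 1 CpG off-target and ≥ 12/18
complete array/WGBS pairs is flagged `Y` when some off-target's WGBS tracks
the probe (lower RMSE) better than the stated target; the minimising
coordinate is suggested.  M/logit space is used throughout, consistent with
the cross-platform analysis.

## Genomic annotation

TSS windows default to [−1500, +500] around each transcript start,
strand-aware and configurable — the window is a convention, deliberately
surfaced in configuration rather than hidden, and genic percentages depend on
it and on the gene-model release.  Precedence is TSS > gene body >
intergenic.  CpG shores are the 2000 bp flanking each island (distance to the
nearest island edge ≤ 2000), open sea beyond; islands win over shores.
Feature overlap (enhancers, super-enhancers — same operation, different BED)
counts closed containment of the C position against deduplicated intervals.

## Synthetic data generator

The generator defines the study conditions: 18 matched samples on three
platforms (EPICv2, EPICv1, WGBS); latent per-site methylation from a beta
mixture — weights 0.4/0.4/0.2 on Beta(1,12), Beta(12,1), Beta(6,6) — giving
the bimodal-plus-intermediate shape typical of array data with
enhancer-like sites; platform observations `M = α_p + β_p·μ_M + ε`,
ε ~ N(0, σ_p²) with array σ = 0.15 and WGBS generative slope 1.3, reflecting
its greater dynamic range; WGBS counts binomial at Poisson(12) coverage,
logit-transformed; detection-p failures and zero-coverage cells planted as
independent 1% Bernoulli masks.  Identical config + seed gives byte-identical
output.

What the generator does *not* emulate: dye bias and channel effects, spatial
batch structure, conversion-error noise in WGBS (counts are purely binomial),
repeat-driven multi-mapping, and genome-scale sequence composition.  Passing
tests therefore demonstrate the correctness of the algorithms under the
stated model, not the field performance of any particular array.

Off-target planting copies a probe's plus-strand design footprint to a
destination with a requested number of substitutions and 1-nt deletions
(kept away from the transposition anchor and window edges) and records the
expected matches, score and transposed coordinate.  Indel plantings are
rejection-sampled against rival alignment interpretations (indel-free,
probe-end-clipped, or flank-recruiting target-skip alignments that would tie
the intended one), using degenerate-aware per-position acceptance sets; with
two deletions, rarer split-gap rivals are not enumerated, so exact-coordinate
guarantees are only made for plantings with ≤ 1 indel.

## Numerical and scale choices

Acceptance-scale problem sizes — 504 probes for the design round trip, a
30 kb genome for aligner-oracle equivalence, 200 sites × 18 samples for slope
recovery, 200 seeded repetitions for replicate adjudication (planted member:
slope 1.0, σ = 0.05; competitor: slope 0.4, σ = 1.0, the strong-separation
regime) — are chosen so the whole script runs in seconds while leaving
standard errors far below the effect sizes being checked.  OLS fits use the
closed form; degenerate fits (zero consensus variance, < 3 samples,
< 2 platforms) raise rather than return NaN.

## Known limitations

* The design-window conventions reproduce the synthetic designer exactly but
  have not been validated row-by-row against a real EPICv2 manifest here; on
  real data a residual fraction of discrepant sequences is expected.
* The built-in aligner targets toy genomes; it is exhaustive, not fast, and
  real-genome scans should come from BLAT via PSL.
* rs/nv allele chemistry is pass-through: such probes are carried in tables
  but not recomputed or scanned for design correctness.
* `K450locmatch2`-style older-array internal replicates are represented as
  multiple match rows rather than dedicated columns.
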