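# Methods

## Scope and data model

The pipeline reconstructs the bespoke computational stages of a two-species
comparison of fruit development: chimera splitting of de novo transcripts
against a reference cDNA set, reciprocal-best-hit (RBH) construction of a
1:1 ortholog-transcriptome, mature-miRNA collapsing and small-RNA counting,
and a two-factor negative-binomial differential-expression analysis over
2 species × 3 structures (bud, flower, fruit) × 3 replicates.  Sequencing,
read preprocessing, assembly and external annotation services are out of
scope; their products (FASTA transcript sets, 12-column tabular hit files,
count matrices) are the pipeline's inputs, and a synthetic-data module
generates ground-truthed stand-ins for all of them.

## Built-in aligner

For desk-scale synthetic runs the pipeline carries its own local aligner:
exact k-mer seeding (default word size 11, two seed words required per
(subject, diagonal) — the classic two-hit heuristic), ungapped extension
with +1/−2 match/mismatch scores to the optimal local interval containing
the seed, and Karlin–Altschul-style e-values `E = m·n·2^(−bits)` with
λ = 1.33, K = 0.621.  Because synthetic divergence is substitution-only,
ungapped extension loses nothing there; real-data users supply hit tables
from an external search instead, and the e-value model only needs to rank
hits consistently.  Coordinates are 1-based inclusive; minus-strand subject
hits are encoded by `s_start > s_end`.  Subject "tail" lengths — the
unaligned subject sequence beyond a hit, used by the chimera boundary
correction — are defined in the direction of travel along the query, so
they are strand-safe: the downstream tail is `L − s_end` on the plus strand
and `s_end − 1` on the minus strand.

## Chimera resolution

A transcript is a chimera candidate when its two best reference subjects
(ranked by e-value, then bitscore, then subject id; hits per subject merged
to one spanning query interval) occupy *different regions* of the query.
The reference gives no quantitative criterion, so the package uses: both
merged intervals at least 100 nt, and their overlap below 50% of the
shorter interval — nested or near-coincident intervals are paralog signal,
not fusion evidence, and two best subjects that are isoforms of one
reference gene never trigger a call.  The split rule then branches on the
overlap of the two merged intervals:

* overlap < 150 nt (including negative overlaps, i.e. gaps): split at the
  floor midpoint of the overlap/gap region.  Midpoint splits partition the
  sequence exactly.
* overlap ≥ 150 nt: part 1 ends at `q_end_1 + downstream_tail(subject 1)`
  and part 2 starts at `q_start_2 − upstream_tail(subject 2)`, both clamped
  to the transcript.  The fragments may overlap; they always jointly cover
  the transcript.  Degenerate splits (an empty or full-length fragment)
  leave the transcript unsplit with a logged warning.

One pass splits at most once per transcript (only the best two subjects are
ever considered), and resolution is idempotent on data without nested
double fusions.

## Ortholog-transcriptome

Co-best hits tie on the exact (e-value, bitscore, alignment length) triple.
RBH candidates must align over > 250 nt with a transcript length ratio
≥ 0.5 (transcript lengths, not aligned lengths).  Pruning enforces 1:1:
pairs are visited by decreasing cross-species alignment length (ties:
bitscore, then ids) and kept when both transcripts and both per-species
reference-gene slots are free; isoforms mapping to different reference
genes coexist.  Kept pairs take the reference gene of their best reference
hit as name — species A's assignment wins a disagreement (logged) — or a
sequential `ORTHO######` number when neither member has a reference hit.

## miRNA catalog

Mature miRNAs are collapsed into counting groups as the connected
components of the graph linking equal-length sequences at Hamming
distance ≤ 1; the link is transitive, so a group can span more than one
substitution end to end.  A read counts for a group when the shorter of
read and member is contained full-length in the longer with at most one
substitution — a whole-read simplification of seed-tolerant read mapping,
stated as such.  Reads matching multiple groups are discarded (the
collapsing exists precisely to avoid multi-mapping); group counts plus
discarded plus unmatched reads always equal the sample total.  Ortholog
miRNA groups are those present (count ≥ 1) in both species.

## Differential expression

Counts follow `K ~ NB(μ, α)` with `μ = exp(Xβ + o)`,
`Var = μ + αμ²`.  `X` is the treatment-coded design
`species + structure + species:structure` (reference levels species A,
structure bud; 6 columns, interaction df 2).  Offsets
`o = log(size factor) + log(length/1000)` put library depth and transcript
length into the model rather than into the counts, preserving the NB
mean–variance relation; reported "normalized counts" (filtering, PCA)
use the divided form, and miRNA features skip the length term.  Size
factors are DESeq-style median-of-ratios.  Features whose normalized counts
(raw counts for miRNAs) sum below 19 across samples are discarded; the
aggregation is configurable (sum/mean/max) because a per-sample reading of
the threshold would discard nearly everything.

**Fitting.**  A vectorized IRLS/Fisher-scoring loop fits all features
simultaneously (batched 6×6 weighted least-squares solves, step-halving on
likelihood decreases, deviance tolerance 1e-8).  For dispersions below
1e-6 the log-likelihood switches to a Poisson-limit expansion to avoid
catastrophic cancellation in the gamma terms.

**Dispersion.**  Per feature, the Cox–Reid adjusted profile likelihood
`APL(α) = ℓ(β̂(α)) − ½ log det(XᵀWX)` is evaluated on a 25-point log grid
(1e-8 … 10) with warm-started refits and quadratic interpolation; a
mean–dispersion trend (binned common-dispersion maximizers, interpolated in
log mean) shrinks the per-feature maximizer in log space with prior weight
10 against the residual df.  On Poisson data the estimates collapse to the
lower bound; at true α = 0.1 with 18 samples the median estimate lands
within [0.05, 0.2].

**Engines and consensus.**  Engine 1: the 2-df likelihood-ratio test
(full vs reduced model, χ² tail) for the interaction and Wald tests for
the 7 pairwise contrasts (species B vs A within each structure;
flower−bud and fruit−flower within each species).  Engine 2:
quasi-likelihood F-tests — per-feature quasi-dispersion = full-model
deviance / 12, squeezed toward its location with a prior df estimated by
moment matching of log s² against its χ² expectation (trigamma inverse),
F = (deviance drop / df) / s²ₚₒₛₜ on (df, prior+12) df.  BH adjustment is
applied per test family and per engine.  A feature is called only when
both engines reach padj ≤ α (default 0.001) and |log2FC| > 1 (for the
interaction: the larger-magnitude of the two transition-interaction
contrasts, which also sets the reported direction).  The |log2FC| rule is
applied to the interaction as well as the pairwise contrasts.  Measured on
the synthetic null (2000 features, dispersion 0.1), the LRT rejects at
0.050–0.058 for nominal 0.05 and BH at α = 0.001 yields well under one
call per 2000 features.

**Enrichment and PCA.**  Term enrichment is the two-sided Fisher exact
test per term with BH FDR across terms; fold enrichment
`(overlap/|called|)/(|term|/|universe|)` is reported for under- as well as
over-representation.  PCA uses `log2(normalized + 1)` with feature
centering and no scaling — a pragmatic stand-in for variance-stabilizing
transforms, which are deliberately not reproduced.

## Synthetic data: what it emulates, and what not

The generators plant every quantity the downstream stages must recover:

* Reference genes are i.i.d. random sequences (default 500–2000 nt); a
  fraction carry a second isoform made by an internal deletion or
  alternative 3' end of 5–20%, so isoforms share ≥ 80% of sites.
* Species transcripts are independently substitution-mutated copies of
  every reference isoform (divergence = per-site substitution rate), so
  planted junction coordinates stay exact and mean identity equals
  1 − divergence.  Chimeras concatenate mutated copies of two distinct
  genes.  Plain concatenations make the two reference hits abut (overlap
  ≈ 0 → midpoint branch, split lands on the recorded junction); fusions
  meant for the corrected-boundary branch interleave the junction
  (X-head | Y-head | X-tail | Y-tail with 100 nt blocks) so the merged hit
  intervals overlap by ~200 nt — with independent random genes a plain
  fusion cannot produce a large hit overlap, which in real data comes from
  gene-family homology.
* Counts are NB draws under the full design.  DDEG features receive both
  interaction coefficients at the requested magnitude (default 2 on the
  log2 scale) with independent random signs; DEG features receive species
  or structure main effects only.  Baseline reference-cell means are
  2^U(5,11) by default (32–2048 counts), i.e. comfortably above the low-
  count filter, which is what a filtered real dataset looks like.
* Small-RNA reads copy a mature sequence with exactly 0 or 1 substitutions;
  per-sample read numbers are Poisson around the supplied abundances.

Not emulated: sequencing errors and quality scores, adapters, contaminant
and organelle reads, indels, gene families and repeats, GC or length biases
in counting.  Passing tests therefore demonstrate the correctness of the
*algorithms* under their stated models, not robustness to artifacts that
preprocessing is assumed to have removed.

## Benchmark scales and measured behavior

The acceptance benchmarks (tests and `scripts/acceptance.py`) use: 500
genes / 50 planted fusions / 2% divergence for chimera resolution; 1000
genes / 20% two-isoform / 3% divergence for orthologs; 2000 features × 10
seeds for null calibration and one 2000-feature run with 10% planted
interactions for power; 40 miRNA families at 20% read mismatch; and the
default demo configuration twice for byte-identity.  These sizes keep a
full run in minutes on one CPU while leaving every rate estimated from
thousands of items.

One recovery target is knowingly not reached: with 3 replicates,
dispersion 0.1 and both interaction coefficients at |log2FC| = 2 with
random signs, same-sign coefficient pairs are partially absorbed by the
species main effect in the reduced model, leaving a noncentrality of ~19
for the 2-df LRT against an effective χ² threshold of ~19 after BH at
α = 0.001 — so even the oracle test with the true dispersion recovers only
~73–76% of planted DDEGs, and the consensus engine measures ~72–78%
depending on seed.  The false-discovery proportion among consensus calls
stays at or near zero.  This is a property of the test geometry at these
effect sizes, not an estimator deficiency; the conditions are kept as they
are rather than planting more favorable effects.

## Determinism and provenance

Every generator and the pipeline take explicit integer seeds
(`numpy.random.default_rng`); stage outputs are plain FASTA/TSV with a
leading comment carrying the configuration hash and seed, and the run
manifest records all parameters and per-stage record counts.  Reruns with
identical configuration are byte-identical.  Configuration files are flat
`key=value` text with a versioned schema; unknown keys are errors, because
a silently ignored threshold typo is the main reproducibility hazard in a
pipeline of this shape.

## Known limitations

* The aligner is ungapped and exhaustive per diagonal; it is not suitable
  for genome-scale searches or indel-rich comparisons.
* Triple chimeras are split at most once per pass; coverage-based chimera
  evidence is not used.
* The QL engine's prior-df moment matching assumes a roughly χ²-shaped
  quasi-dispersion distribution; with very few features it falls back to a
  fixed prior df of 10.
* Fisher enrichment treats terms independently (no graph propagation or
  parent–child correction).
* The two DE engines share one fitter, so their consensus removes
  borderline calls but is not a check against an independent codebase;
  the test suite cross-checks coefficients against an independent GLM
  implementation instead.
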