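# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `lctseq`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`.

## Coordinates and references

All internal coordinates are 0-based half-open; GTF and RepeatMasker
`.out` (1-based inclusive, `C` for minus strand) are converted at parse
time, BED passes through unchanged.

The L1 library keeps `LINE/L1` repeats intersecting
`[gene.start − w, gene.end + w)` of at least one coding gene on the same
chromosome, with w = 50,000 bp and any 1 bp intersection qualifying
("within 50 kb" read inclusively). Element sequences are extracted as
plus-strand genomic sequence by default — matching `bedtools getfasta`
without `-s` — with `stranded=True` available to reverse-complement
minus-strand elements; the aligner searches both strands, so detection is
insensitive to this choice, but junction coordinates on minus-strand
elements differ between the two conventions.

Transcriptome masking replaces repeat-derived stretches with `N`. The
internal masker aligns each transcript against a repeat sequence library
and masks any window at ≥ 90% identity over ≥ 30 aligned bp; overlapping
windows merge. These two thresholds are this package's auditable stand-in
for profile-HMM repeat discovery: 30 bp is comfortably above the 18 bp
anchor floor (so no unmasked repeat seed can anchor a transcript-side
hit) and 90% tolerates diverged repeat copies without eating unique exon
sequence. Masking is idempotent (property-tested).

## Local alignment kernel

The aligner is blastn-flavored Smith–Waterman with affine gaps: match +1,
mismatch −2, and a gap of length k costing 5 + 2k (gap existence 5,
extension 2 — the blastn convention). Default filters: score ≥ 16 and
aligned length ≥ 18; the short-anchor mode for 18–30 bp fragments lowers
these to 14/11 and shrinks the seed word size from 11 to 7. Both strands
are always searched; results sort by score with deterministic tie-breaks
(lexical reference id, then leftmost reference start).

Execution strategy: for small problems (reference × query ≤ 2·10⁵ cells)
the full DP matrix is computed directly; larger references go through
seed-and-extend — exact k-mer seed hits grouped by diagonal band
(bandwidth 12), each band expanded to a padded reference window and
resolved with the full DP on that window. The DP engine is
`Bio.Align.PairwiseAligner` (C implementation); seeding, strand and
coordinate bookkeeping, filtering and tie-breaking are owned by this
package. Seed-and-extend is exact whenever a true alignment contains one
exact word of the seed length, which error-free and 95%-identity reads
virtually always do; the property and acceptance tests verify exact
agreement with an independent pure-Python full-DP oracle on instances up
to 80 bp, where the exhaustive path is active.

Read classification against the unmasked transcriptome: a read is
`fully_aligned` when its best hit leaves < 5 bp total unaligned at ≥ 95%
identity (no chimeric signal; discarded), `soft_clipped` when ≥ 20 bp
hang off one side, otherwise `unmapped`. Both non-full classes enter the
chimera search. The 20 bp clip threshold guarantees a 100 bp read split
50/50 is always soft-clipped.

## Junction calling and breakpoint refinement

For each surviving read the best L1 hit is found, the read is flipped if
needed so the L1 hit is plus-strand, and the un-L1 remainder (≥ 18 bp) is
short-anchored in the masked transcriptome. Evidence is accepted when the
two query intervals overlap or gap by ≤ 3 bp and together leave ≤ 10 bp
of the read unexplained.

Local alignment edges are unreliable exactly at the breakpoint: an anchor
happily extends a few bases into the other segment through a mismatch
when the net score is positive, and junction microhomology makes several
placements equivalent. The junction is therefore *refined*: every split
position within 15 bp of the anchors' meeting point is scored as (read
bases matching the transcript projection on one side) + (read bases
matching the L1 projection on the other), and the best split wins, with
ties broken toward the transcript-maximal placement. The simulator emits
junctions in the same canonical form (the first L1 base differs from the
transcript continuation), which is what makes exact-coordinate recovery a
well-posed test.

Candidates extend `read_length − 1` bp along the unmasked transcript and
the L1 element from the junction (truncated and flagged at reference
ends). Deduplication collapses identical sequences and substrings into
the longest candidate, mirroring 100%-identity cd-hit clustering
(which also absorbs substrings). The repeat-fusion filter removes
candidates whose non-L1 flank matches any repeat (all classes) at ≥ 90%
identity over ≥ 80% of the flank; flanks under 20 bp are not testable and
pass with a warning.

Support counting re-aligns every non-fully-aligned read against the
candidate set: a support read covers the candidate end-to-end (≤ 3 bp
trimmed per read end, identity ≥ 0.95 to absorb sequencing errors) and
crosses the junction by ≥ 10 bp on each side (j_min; prevents flank-only
matches counting as expression). Each read is credited to its single
best-scoring candidate, so near-identical L1 copies cannot double-count.
Events need ≥ 5 support reads; the support count is the event's
expression value. This is also the designed recovery path for junction
reads whose L1 (or transcript) overhang is below the 18 bp direct-anchor
floor: they cannot nominate a candidate but do support one.

Annotation places the junction against the CDS span in transcript
coordinates (before → 5′UTR, inside → coding, after → 3′UTR, no CDS →
noncoding) and sets the splice-junction flag when the junction lies
strictly less than 3 bp from an internal exon boundary, measured in
transcript coordinates (equivalent to genomic distance at these scales
because the junction and boundary share an exon).

## Cohort statistics

* Normalization: `log2(count / depth × 10⁶ + 1)`. The pseudocount of 1 is
  required because absent events are structural zeros.
* Differential calling: Welch two-sample t-test on normalized values
  (called at p ≤ 0.05 **and** log2FC > 0 — tumor-upregulated only) and a
  two-sided Fisher exact test on presence/absence (p ≤ 0.05); the final
  set is their union. The expression test is an ordinary two-sample test
  by design — at cohort sample sizes the empirical-Bayes variance
  moderation of microarray-era pipelines changes little, and the
  selection rule is what defines the call. Raw p-values drive all calls;
  Benjamini–Hochberg q-values are emitted for information only.
* Activity and correlates: activity = Σ support reads / depth × 10⁶.
  Pearson r with two-sided t-distribution p per feature; features at
  p ≤ 0.0001 split by sign of r. Methylation enters as the per-sample
  median of M = log2(β/(1−β)); copy number as the per-sample Σ|GISTIC2|.
* Cox: univariate Newton–Raphson on the Breslow partial likelihood
  (risk sets include tied times), Wald p, step damped to |Δβ| ≤ 2,
  convergence |Δβ| < 1e-9 within 50 iterations. Perfectly concordant
  small datasets have no finite MLE and raise rather than returning a
  boundary value. Verified against lifelines (Efron ties; identical on
  tie-free data) and a grid-search oracle.
* Panel genes: bulk-positive correlates (p ≤ 0.0001, r > 0) that are
  LCT+/− differential in strictly more than 3 single-cell comparisons.
* Stratification: per-gene z-scores (sample SD, ddof = 1) summed into an
  aggregate score; exhaustive grid over all observed (score, LCT) value
  pairs as thresholds; groups 1–4 = {low/low, high score, high LCT,
  high/high}. The 36-month fatality rate is the crude fraction of a group
  dead by 36 months (censored-before-horizon samples count in the
  denominator — at these cohort sizes an explicit choice in favor of
  simplicity over Kaplan–Meier estimates). Among threshold pairs whose
  high/high group reaches the 50% target the largest group wins, then
  higher rate, then lower thresholds; if no pair reaches the target the
  best-rate pair is returned flagged `target_not_met`. Output is invariant
  to sample order.

## Single cell

Detection runs on the cDNA read only (10x v2: R2; v3: R1) in single-end
mode. Barcodes of supporting reads are clustered greedily in descending
read-count order (count replaces cd-hit's length ordering, which cannot
discriminate equal-length barcodes); a barcode joins a cluster iff its
end-to-end ungapped identity to the centroid is **strictly greater** than
0.85, with `N` counting as a mismatch. The representative is the member
present in the expression-matrix whitelist (ties by count), else the
highest-count member; clusters sharing a whitelist representative merge
with a log message. Greedy clustering equals the all-pairs transitive
closure whenever true barcodes are well separated relative to the error
rate — the planted regime the tests verify — but can split chains that
closure would join; this is intentional (chains across distinct cells are
exactly the merges to avoid).

The Wilcoxon rank-sum test is exact for combined n ≤ 20 with tie-free
data (verified against full rank-assignment enumeration for n ≤ 12) and
uses the tie-corrected normal approximation otherwise. Calls require
p < 0.01 and logFC > 0.25 (mirror set for down-regulation).

## The synthetic-data generator

The generator emulates: spliced coding transcripts (500–1500 bp, 3–8
exons, UTR fractions 0.15/0.25) laid out one gene per toy chromosome with
introns of 80–300 bp; an L1 library (400–800 bp, pairwise identity < 0.8
by rejection) placed 200–2000 bp downstream of genes; Alu-like decoy
sequences (300 bp); chimeras = transcript prefix + 250 bp L1 segment with
a controlled fraction of junctions exactly at exon boundaries (the rest
≥ 5 bp interior); uniform fragment sampling with substitution errors
(no indels — matching the identity-threshold contracts; indel robustness
is out of scope); barcoded cells with rejection-sampled barcodes
(pairwise identity ≤ 0.85) and per-base barcode errors; and cohort count
matrices with enriched events (tumor/normal presence 0.5/0.05, null
presence 0.2 in both groups, support 5 + Poisson(10) when present) plus
exponential survival with a risk-group hazard ratio. The standard
detection scene adds, per chimera, a fixed number of reads guaranteed to
span the junction by ≥ 15 bp on each side, giving exact control over
support counts. All generators are pure functions of (parameters, seed).

What passing on this data does **not** show: performance on real reads
with indels, quality-dependent errors, alternative isoforms, overlapping
genes, polymorphic L1 insertions absent from the reference annotation, or
expression-level dispersion (counts are presence-gated Poisson, not
negative binomial). The generator's sequences are uniform random, so
mappability is uniformly good; real transcriptomes contain paralogs and
low-complexity stretches that will cost precision.

## Problem sizes used by the acceptance script

Detection runs at 200 transcripts / 30 L1 elements / 20 chimeras / 5
decoys with ~1100 reads — the scale at which every stage (including
seed-and-extend and support re-alignment) is exercised while a full run
stays interactive on one CPU. Oracle comparisons use 200 random alignment
instances ≤ 80 bp, ~2300 Fisher tables (exhaustive at small margins plus
randomized tables with margins to 30), all admissible Wilcoxon group
sizes with combined n ≤ 12, 15 replicates × n = 200 per Cox effect size,
50 planted barcodes with 5 errored copies each, and 8-sample
stratification toys (exhaustive enumeration is quadratic in distinct
observed values).

## Known limitations

* One junction representation per candidate: inversions (transcript and
  L1 on opposite strands within one read) are carried through the
  bookkeeping but not exercised by the generator.
* The detector reports the L1 *family* element, not the genomic source
  locus — identical copies are indistinguishable by construction.
* Fisher and Welch calls use raw p-values by design (the selection rules
  are defined that way); the emitted q-values let a user apply FDR
  control if desired.
* `import_alignments` trusts external SAM/BLAST records; NM/AS tags are
  used when present and approximated otherwise.
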