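# Methods

## The survey procedure

The pipeline locates candidate *cdiA* loci from a nucleotide homology
search and decides, per locus, whether it sits on a chromosome or a
plasmid. Stages, in order:

1. **Parse** BLAST tabular hits (12+ columns, standard order). Rows with
   `sstart > send` encode minus-strand alignments and are normalized at
   parse time, with the orientation kept as a strand field. External
   coordinates are 1-based inclusive (BLAST/GFF3); everything internal is
   0-based half-open; BED output is half-open. Conversion happens only at
   the I/O boundary.
2. **Filter.** A hit is removed iff
   `(length < 2000 ∧ pident < 80.5) ∨ (length < 3000 ∧ E = 0) ∨
   (length < 1000)`, with strict inequalities and boundary values kept.
   The `E = 0` comparison is exact floating equality on the parsed value:
   tabular output prints a literal `0.0` when the e-value underflows.
   Note the clause removes *short hits with underflowed e-values* — the
   most significant short alignments — which is counter-intuitive; it may
   be intended as `E ≠ 0`. We implement it as stated and expose
   `FilterRule.evalue_exact_zero_flag` to disable the clause rather than
   guess the intent.
3. **Chain.** *cdiA* is a single ~9 kb ORF whose alignment to a diverged
   homolog is often split into several HSPs by the indel-rich FHA-repeat
   regions. Surviving hits on the same (replicon, strand) are sorted and
   merged while consecutive intervals overlap or lie within `max_gap`
   (default 1000 bp) of each other; the locus span is the envelope of its
   hits. The gap default is deliberately ≪ gene length: it re-joins split
   alignments of one gene without bridging two adjacent systems (the
   synthetic generator keeps distinct implants ≥ 5 kb apart for the same
   reason). Chaining output is position-sorted, so it is invariant to
   input hit order.
4. **Windows.** Each locus is extracted with 20 kb upstream and 30 kb
   downstream of flanking context. The margins are interpreted relative
   to the gene's reading strand — *cdiB* lies upstream and *cdiI*
   downstream of *cdiA* in the operon, so gene-relative orientation is
   the biologically meaningful choice — and the minus strand therefore
   swaps the roles of the two margins and reverse-complements the output.
   Windows are clamped at replicon ends (clamping is flagged in the BED/
   GFF3/FASTA output so truncated flanks are auditable); circular
   replicons are treated as linear by default, with opt-in wrap-around,
   because downloaded flat files are linearized.
5. **Classify.** Case-insensitive substring matching on the definition
   line: "plasmid" → plasmid; "complete genome" or "chromosome" →
   chromosome; otherwise length > 4 Mbp → chromosome; else unknown.
   Default precedence is *plasmid first*: plasmid definition lines
   routinely also contain "complete genome"/"complete sequence" of the
   parent strain, so testing chromosome keywords first misclassifies
   plasmids. This is the single most consequential ambiguity in the
   procedure; the alternative precedence is one config switch and both
   modes are tested.
6. **Intactness.** A locus counts as a full-length *cdiA* iff its chained
   span strictly exceeds 9070 bp. The bar is applied to the chained span
   as a stand-in for an annotated gene length, since this pipeline does
   not re-annotate.
7. **Deduplicate.** Public assemblies over-represent some strains. We
   keep one representative per (strain, exact window sequence) pair —
   strain parsed as the token following "strain" in the definition line,
   with an accession fallback and a user-suppliable override map; ties
   resolved to the lexicographically first accession, then leftmost
   position. Loci of the same strain with *different* sequences are all
   kept: a strain may genuinely carry two distinct systems on one
   plasmid. "Unique, non-duplicated strain sequences" is not an
   operationally defined criterion; this rule is our documented choice.
8. **Summarize.** Counts per class; percentages over chromosome + plasmid
   loci only (unknowns reported separately, excluded from the
   denominator), rounded to one decimal; a per-plasmid table (accession,
   number of systems, plasmid size, strain). The pipeline counts *loci*;
   because one plasmid may carry two systems, the per-plasmid table can
   have fewer rows than the plasmid locus count.

## Competition statistics

CI = (I_end/T_end)/(I_0/T_0). CI is undefined for non-positive counts;
a count below the plating detection limit must be substituted explicitly
by the caller, not passed as zero. Replicate summaries report the
arithmetic mean ± SEM (sample SD/√n) and, because CIs span orders of
magnitude and are plotted on log axes, the geometric mean and SEM of
log₁₀ CI. Group comparisons use the classical unpaired two-tailed
equal-variance Student's *t*-test (df = nA + nB − 2), on log₁₀ CI by
default; the raw scale is an option since the choice of scale is a
modelling decision, not a property of the data. A degenerate input (both
groups zero-variance) returns t = 0, p = 1 for equal means and
t = ±∞, p = 0 otherwise, flagged as degenerate. The default
inhibitor:target mixing ratio is 10:1 (5:1 for the short toxicity-assay
variant); the simulator exposes the ratio directly.

## Flow cytometry

Events are consumed as tabular exports (one row per event, one column
per channel); FCS parsing and spillover compensation are out of scope.
Gates are reproducible functions of a control sample rather than manual
placements: the default readout gate is the empirical 0.995 quantile of
an unstained/knockout control (≥ 100 control events required), so the
expected false-positive floor is 0.5 %. The depolarized fraction is
#(events above marker *and* readout gates) / #(events above the marker
gate), with a floor of 20 000 marker-positive events (the usual
acquisition target) below which an error is raised rather than an
under-powered estimate returned. Reporter expression is the
background-subtracted *median* single-cell intensity — medians, not
event-wise subtraction, are the summary statistic — and fold ratios
require a positive denominator.

## Synthetic data: what it emulates, and what it does not

The generator produces replicon communities (default 9 chromosomes of
4.2–5.5 Mbp and 1 plasmid of 80–250 kb, bracketing observed
*cdi*-plasmid sizes of ~120–210 kb) of uniform-random nucleotide
composition, each implanting a 9372 bp cassette — just above the 9070 bp
intactness bar, leaving room for truncation tests; truncated implants
retain 5000 bp. Implants are mutated by point substitution at rate
(100 − identity) % (identity drawn from 85–99 % by default); there are
no indels, so implant footprints equal retained template length exactly
and planted truth is exact. Definition lines carry the classification
keywords, so end-to-end recovery is deterministic.

Simulated hit tables emit one HSP per implant or, with configurable
probability, 2–3 HSPs tiling the footprint with gaps below the chaining
threshold. The e-value model is deliberately minimal: e-value is 0 iff
bitscore (2·len·pident/100) exceeds a cap of 6000 — only the "= 0 vs
≠ 0" distinction matters to the filter, and the cap guarantees that a
zero e-value implies an alignment longer than 3000 bp, as with real
underflow, so genuine split HSPs are never destroyed by the as-printed
removal clause. Decoy hits are constructed to fail the filter (either
< 1000 bp, or 1000–2000 bp at < 80.5 % identity).

Competition trajectories draw log₁₀ CI ~ Normal(true, σ) and solve the
target end-count from the drawn CI at fixed inhibitor growth; flow
samples are two-component lognormal mixtures on the readout channel
(log-means 4.6 and 7.6, log-SD 0.4, ≈3 log-SD apart so a 99.5 %-quantile
gate separates them almost perfectly), with every event marker-positive.

Passing tests on these data therefore demonstrate the *logic* of the
pipeline — filter algebra, chaining, coordinate arithmetic,
classification, deduplication, estimator calibration — not robustness to
real-genome features the generator omits: repeats and GC skew, indels,
partial homology outside the implant, mosaic definition lines, gated
debris, or instrument effects (spillover, saturation).

## Numerical choices and degenerate inputs

* Quantiles use numpy's default linear interpolation on the sorted
  sample.
* Percentages round half-even to one decimal (93.157… → 93.2); an empty
  survey reports NA percentages rather than 0/0.
* An empty hit file is a valid input producing an empty summary, not an
  error; a hit on a replicon absent from the FASTA/metadata aborts with
  the stage and accession named.
* SEM of a single replicate is NaN (undefined), not 0.
* All generators take integer seeds and are fully deterministic;
  re-running the survey on identical inputs reproduces byte-identical
  artifacts (the JSON report contains no timestamps or absolute paths).

## Problem sizes

The test suite runs mostly on scaled-down communities (replicon sizes
~10⁵ bp) because classification rests on definition lines, not size; the
full-scale defaults (multi-Mbp chromosomes) are exercised once
end-to-end and in the acceptance script. Calibration checks use 10⁵
random hits for the filter oracle, 10⁴ null trials for the *t*-test
type-I error, 2 × 10⁴ events per flow sample, and 10³ repeated
simulations for estimator-bias checks.

## Known limitations

* Locus calling is homology chaining plus a size bar, not annotation: a
  pseudogenized *cdiA* with > 9070 bp of contiguous homology would count
  as intact, and two systems closer than `max_gap` on the same strand
  would merge.
* Replicon classification trusts definition lines; mislabeled or
  uninformative descriptions fall through to the size rule or "unknown".
* The strain parser handles the common "strain X" pattern only; unusual
  definition lines should use the override map.
* The survey is query-driven: it restricts to sequences similar to the
  query gene, not to a taxon.
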