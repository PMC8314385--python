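# Methods

## Scope and data model

`panelcnv` detects copy-number variants from read depth on targeted capture
panels. The unit of analysis is a *batch*: a set of samples captured and
sequenced together, over a shared panel footprint (every coding exon
extended by `flank_bp` intronic bases, 20 by default). Internally all
coordinates are 0-based half-open; BED input keeps its native 0-based
half-open convention and depth TSVs their 1-based one, and output tables
print 1-based inclusive intervals. Footprint positions absent from a depth
file are depth 0 (capture dropout), not errors, so matrices stay
rectangular.

Batch QC flags samples whose median per-base depth falls below 200× — the
depth regime the windowed caller is designed for — and warns when fewer
than four samples are available, since the per-position reference is a
cross-sample median and degenerates in tiny batches.

## Normalization

Two stages map raw depth to copy ratios:

1. **Library-size factors.** f_s = mean(batch totals) / total_s, computed
   from total footprint coverage. This makes f_s · total_s equal for all
   samples while keeping normalized depths on the raw-depth scale, so
   depth-based thresholds (the 200× QC floor, the reference floor below)
   remain interpretable. A consequence worth knowing: a real CNV inside a
   sample shifts that sample's total, so its ratios carry a relative bias of
   roughly the event's share of total coverage. On realistic panels
   (hundreds of kilobases) this is far below the calling margins; the toy
   panels used in validation are sized so the bias stays under ~0.5%.
2. **Per-position reference.** r_i = median across samples of normalized
   depth. The median ignores a single-sample event at clinical batch sizes
   (≥ 5 unaffected samples leave r_i untouched in the noiseless case). An
   `exclude_self` option recomputes r_i per sample leave-one-out for very
   small batches or batches with many events. Positions with
   r_i < `min_ref_depth` (default 50) give unstable ratios and are masked —
   masked positions carry no ratio at all rather than 0, so capture
   dropouts cannot masquerade as deletions.

An alternative **quantile-normalization mode** replaces each sample's depth
distribution by the rank-wise batch-mean distribution (ties receive the
mean of the target values over the tied span) before the reference stage.
On noiseless proportional batches the two modes give identical ratios; the
quantile mode is the better choice when depth distributions differ in shape
and not just scale. Factor mode is the default.

## Four-allele mode for homology groups

Where a gene has a highly similar pseudogene (PMS2/PMS2CL is the canonical
pair), short-read mapping cannot reliably separate the homologs, so
per-locus ratios are meaningless. The pipeline instead consumes a
position-level homology map (an externally produced alignment of the
homologs; constructing it is out of scope) and sums depth across all
members at each aligned column before normalization. The diploid baseline
is then 2k alleles for k members — four for a pair — and the merged track
is pushed through the same factor/median pipeline. Losing one allele gives
3/4 = 0.75, gaining one gives 5/4 = 1.25, and the calling cutoffs move
inward to ≤ 0.8 / ≥ 1.2 accordingly. Merging conserves reads exactly
(integer equality), and member positions are excluded from the two-allele
path to avoid double reporting. Calls are reported on the first member's
coordinates with `group_scope=homology`: read depth alone cannot attribute
the event to gene versus pseudogene, which is flagged rather than guessed.

## Window calling

Windows of `window_bp` = 10 slide with `stride_bp` = 1 over each contiguous
footprint block — never across the gap between targets or a gene boundary.
A window is masked when more than half its positions are masked; otherwise
its mean is the arithmetic mean of unmasked ratios. Window means are
classified with inclusive cutoffs — deletion ≤ 0.65, duplication ≥ 1.35 at
unique loci (0.8/1.2 on the merged scale). Comparisons are padded by 1e-9
so a mean that equals the cutoff analytically is not pushed off it by
floating-point summation order.

Maximal runs of same-state qualifying windows become segments; up to one
intervening masked window is bridged so a single dropout does not split one
biological event (bridged bases do not contribute to the call's mean
ratio). The segment interval is the union of the member windows *trimmed
inward so both terminal positions individually satisfy the cutoff*. The
trim exists because a window overlapping an event by as few as 7 of 10
bases can qualify, which would otherwise pad a noiseless event by up to
3 bp per side — enough to promote a 25 bp event past the span filter. With
trimming, a noiseless spiked event is called at exactly its own interval.
Refined intervals shorter than `min_span_bp` = 30 are suppressed, which
operationalizes the detection floor of this window scheme: sub-30 bp events
are the territory of the sequence aligner, not the depth caller. In
noiseless simulation, spans < 30 bp are never called and spans ≥ 40 bp
always are.

Copy number is round(baseline · mean ratio), half away from zero upward
(0.5 → 1 copy, 1.25 on the four-allele scale → 5 alleles). The raw mean
ratio is always reported alongside, so borderline or mosaic-looking events
stay visible; mosaic fraction estimation itself is out of scope. Calls
never cross gene boundaries: an event spanning two adjacent genes appears
as one call per gene, matching per-gene reporting conventions.

## Nomenclature

Breakpoints on capture data are only localizable to the uncaptured intron
between two exons, so calls are rendered as uncertainty intervals:
`GENE:c.(A+F_B-F)_(C+F_D-F)del|dup` with F = flank_bp + 1 (21 for the
default 20 bp flank — the first intronic base the capture does not cover),
`(?_-F)` at the transcript start and `(*F_?)` past the stop codon. cDNA
coordinates come from the transcript table verbatim (UTR tokens `-N`/`*N`
included); no sequence alignment is involved. Sub-exon calls fall back to
the exon-level span with a flag, since window boundaries do not resolve
cDNA breakpoints. The parser inverts the renderer (whitespace-tolerant, as
clinical reports often insert spaces) and additionally accepts base-resolved
two-coordinate strings, which arise when breakpoints have been sequenced by
orthogonal methods; those are parse-only. Reports are TSV (with the full
configuration in `#` header lines) and optional VCFv4.2 with symbolic
`<DEL>`/`<DUP>` alleles, INFO END/SVLEN/SVTYPE and per-sample FORMAT CN,
using the standard padding-base convention (POS is the base before the
event).

## Simulator

The generator emulates exactly the structure the normalization assumes:
expected depth = mean_depth · L_s · E_i · copies/2, with per-sample library
sizes L_s ~ lognormal(0, `library_size_cv`) and a per-position capture
efficiency profile E_i ~ lognormal(0, `capture_effect_sd`) *shared by all
samples in the batch* — shared position effects are what the median
reference cancels, and the simulator's job is to reproduce that
cancellation, which is verified as a property (noiseless ratios are
invariant to the capture profile). Defaults are the assay's stated
conditions: 200× mean depth; noise is `none` (rounded expectations, for
exact convention checks) or Poisson. Negative-binomial overdispersion is a
documented extension point, not implemented. Seeds are explicit in the
config; identical (config, seed) gives bit-identical matrices.

What the simulator does **not** model: GC and mappability bias, batch-
varying capture profiles, read-level artifacts, mosaicism, sex chromosomes.
Passing recovery tests therefore demonstrate the algorithm's correctness
under its own assumptions — uniform-quality batches with shared capture
chemistry — not robustness to assay drift, which real deployments handle
through the QC gate.

Recovery scoring marks a truth event recovered when a same-sample,
same-type call reciprocally overlaps it by ≥ 0.5; precision is the matched
fraction of calls. With no calls at all precision is reported as 1.0
(nothing asserted, nothing wrong).

## Validation problem sizes

Convention checks (ratio anchors 0.5/1.5 and 0.75/1.25) run on a noiseless
8-sample batch over a ~33 kb toy panel — large enough that the spiked
event's footprint share, and hence the factor bias above, is ≲ 0.4%.
Cutoff flip points are swept on constant-ratio tracks at 0.01 resolution.
Stochastic parameter recovery uses 20 replicates of 16-sample batches at
200× Poisson depth with whole-exon (120 bp) heterozygous deletions and
duplications, scored against spiked truth; sensitivity and precision both
exceed 0.95 there. These sizes were chosen as the smallest that make the
quantities stable; everything runs in seconds on one CPU.

## Known limitations

- Cutoffs (0.65/1.35, 0.8/1.2) are fixed configuration, inherited from
  laboratory validation of this assay class; they are not re-derived from
  the data, and batches violating the depth/uniformity assumptions need the
  QC gate, not looser cutoffs.
- The factor-normalization bias for very large events (multi-gene or
  whole-panel aneuploidy) is not corrected; `exclude_self` mitigates the
  reference side but not the factor side.
- Homology calls cannot assign the event to a specific homolog.
- Breakpoints are never base-resolved; intervals are exon-level with
  flank-width uncertainty.
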