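# Methods

## Calibration model

Each CUT&RUN reaction is assumed to receive a fixed quantity of
spike-in chromatin (default 1:20 spike:primary cell ratio), so the
spike-in fragment count N_spike of a library measures its combined
recovery efficiency and sequencing depth. The per-sample factor
`C / N_spike` (C = 10,000 by default, configurable) converts counts to a
common absolute scale. Two consequences the package tests and relies on:

* **Depth invariance.** Jointly changing sequencing depth leaves
  spike-scaled signal unchanged in expectation, since primary and spike
  counts scale together. The titration benchmark simulates a depth series
  at the fixed spike ratio, verifies raw window counts track spike reads
  linearly (R² > 0.99), and verifies scaled window signal is constant up
  to spike-count sampling noise.
* **Load response.** A sample with less primary chromatin signal (e.g. a
  globally suppressed mark) yields proportionally *more* spike reads at
  equal depth, which is exactly what makes the calibration informative;
  the planted 10× contrast benchmark checks this mechanism end to end.

Note the spike:primary *cell ratio itself* must be constant across the
samples being compared: changing the ratio rescales the calibration by
the ratio, which is why the titration benchmark varies depth, not ratio,
and checks the ratio response separately (spike read share linear in the
planted ratio).

## Coverage and the binned distributions

Per-bin coverage sums fragment base pairs, attributing a
boundary-spanning fragment pro-rata to each bin, so the track total
equals total fragment bp exactly (an invariant the tests assert). Bins
default to 5 kb for the ranked bin-count curves; descending sort with
ties broken by genomic position makes the ranking deterministic. The
head/tail ratio (mean of the top 1% of bins over the mean of the bottom
50%) is the package's one-number summary of curve steepness: genome-wide
(replication-coupled) deposition gives a flat curve near 1, promoter
turnover a steep head.

bedGraph output is bin-resolution (values at 6 decimals, zero bins
omitted). Base-pair-resolution output would be equivalent at bin width 1
but is not the default because broad-domain work never needs it.

## Domain calling

The caller keeps the core of sparse-enrichment peak calling: candidate
blocks are maximal runs of strictly positive binned signal, scored by
total signal in the block (area under the curve). With a control track,
blocks scoring strictly above the control's maximum block score survive;
without one, blocks above the (1 − q) score quantile survive (top
fraction q). This presumes background regions are genuinely sparse —
true of nuclease-footprinting data at practical depth, and of the
simulations, whose genome sizes are chosen so background bin occupancy
stays below ~50% (zero bins then delimit blocks). With control equal to
signal the result is empty by construction.

This is deliberately not a reimplementation of a published caller;
externally called peak BEDs can be substituted at the `read_region_bed`
boundary and flow through the rest of the pipeline unchanged.

## Differential domains

Merged per-condition domain lists are partitioned: every start/end of
any input becomes a boundary, and the maximal segments of constant
set-membership between boundaries form a disjoint exact cover of the
union (verified against a per-bp brute-force oracle on random
instances). Segments sharing a boundary coordinate with another segment
are "adjacent" — adjacency arises precisely where membership changes.
The dominant-segment filter then keeps adjacent segments ≥ 10 kb and
free-standing segments ≥ 3 kb (strict: exactly-threshold lengths are
kept; both members of a short adjacent pair may be dropped; in chains of
≥ 3 adjacent segments the rule applies to each segment independently).
The filter's purpose is to keep one dominant piece per region of
partitioning overlap and to discard boundary-jitter slivers, which is
also how the pipeline absorbs replicate-to-replicate boundary noise.
Membership labels are carried through as annotation.

## Clustering and quantification

Clustering features are spike-scaled raw counts per region,
log2(x+1)-transformed (an untransformed mode exists). k-means is Lloyd's
algorithm, best of `restarts` initializations (default 25), deterministic
given a seed. The number of clusters is chosen by scanning k = 2..15 and
taking the k with the largest discrete second difference of the
within-cluster-distance curve, ties to the smaller k; the curve is
anchored at k = 1 (total sum of squares, computed in closed form) so the
smallest scanned k is itself a candidate. Because the knee is a
curvature argmax, a pure noise matrix selects k = 2, the scan minimum.

Quantification for per-cluster summaries scales counts by fragments per
kilobase (1000/region length) and then by the per-sample spike constant,
making medians comparable across both region sizes and samples.
Five-number summaries use linear-interpolation quartiles.

Overlap summaries count query intervals overlapping any reference
interval by ≥ 1 bp (configurable minimum), with percents rounded
half-up at the reported precision. Promoter/expression coupling is the
squared Pearson correlation of log2(x+1) values.

## Synthetic data: what it emulates, what it does not

The generator plants one of four regimes on a toy genome (default 2 × 5
Mb primary + 500 kb spike; the validation workloads use larger genomes,
below). Fragment starts are drawn from the piecewise-constant intensity
(background × planted multipliers), lengths are truncated normal
(170 ± 25 bp, ≥ 50 bp, nucleosomal), and spike fragments are uniform
over the spike genome at an intensity share implied by the spike cell
ratio and relative genome masses — with defaults this lands spike reads
at ~0.1–0.3% of a library, matching practice. Defaults: broad domains at
20× background covering ~10% of the genome (10 domains of 10–200 kb on
the toy genome), promoter peaks of 1 kb at 50× background, background
1 fragment/kb (relative).

Deliberately not modeled: sequence composition and mappability, GC bias,
PCR duplicates, fragment-length dependence on chromatin state,
heterogeneous spike-in chromatin, and biological replicate variability
beyond sampling noise. Passing tests therefore demonstrate that the
*computational* pipeline recovers planted structure under realistic
counting statistics — not robustness to alignment or library artifacts.

## Validation workload sizes

Chosen once so each benchmark finishes in seconds to ~1 minute on one
CPU while keeping counting noise small relative to the tolerances:

* Domain-call recovery: 2 × 150 Mb genome, 300 domains (10–100 kb) at
  20×, 1M fragments, IgG control at 200k, 100 bp bins.
* End-to-end class recovery: 2 × 50 Mb genome, 200 domains per class
  (shared/A-only/B-only, 10–25 kb, 20×), 2 conditions × 2 replicates at
  250k fragments + IgG at 125k; scored by adjusted Rand index between
  knee-k-means clusters and planted classes.
* Planted 10× contrast: 2 × 20 Mb genome, 60 domains, 1.2M fragments per
  sample so spike read counts reach the low thousands (as in real
  libraries) and the fold ratio's sampling error stays a few percent.
* Titration: depths 100k–800k on the toy genome.
* Regime contrast: 1M fragments, 200 TSSs with peaks planted at half —
  the TSS decile ratio is computed from rows ordered by their own
  (noisy) signal, so the uniform regime's ratio exceeds 1 by selection
  bias alone; 1M fragments keeps that bias well under the 1.5 bound
  while the peaky regime sits far above 5.

## Known limitations

* The caller's positive-run block definition degrades when background
  occupancy approaches saturation (very deep libraries on small
  genomes); bin width should be reduced, or an external caller used.
* Partition adjacency is exact-coordinate sharing; domains separated by
  a 1 bp gap are free-standing by definition.
* Knee selection assumes the within-cluster-distance curve is convex at
  the true k; a non-monotone curve (sampling noise at large k) is logged
  and the curvature argmax is still returned.
* TSS profile rows at chromosome edges are zero-padded rather than
  dropped, which slightly deflates their ordering scores.
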