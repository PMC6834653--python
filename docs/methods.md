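# Methods

## The screen being modeled

A pooled shRNA senescence-bypass screen is a positive-selection experiment.
Cells carry a doxycycline-inducible oncogene whose expression drives them
into senescence — a durable growth arrest, not death — within about a week.
A lentiviral library of barcoded hairpins (thousands of genes, 5–6 hairpins
per gene) is introduced at low multiplicity so each cell carries one
hairpin; an aliquot is frozen as the baseline; one arm grows without
induction as a general-growth control; induced arms grow for the full
culture period. Clones whose hairpin depletes a gene the senescence
response needs keep dividing after everyone else arrests, so their barcodes
dominate the induced samples. The analysis is a transparent threshold rule,
not a p-value ranking: normalize to reads per million, require a raw-read
floor in the induced samples, require a fold-change floor against *both*
the baseline and the uninduced control, and call genes with at least two
enriched hairpins.

## Generative model (`senescreen.simulate`)

Growth is deterministic in expectation; randomness enters at the three
points where it is biologically discrete:

1. **Infection.** Initial cells per hairpin ~ Poisson(`representation`),
   default 400 cells/hairpin. The transduced fraction (default 0.40) is
   recorded for provenance only — untransduced cells are removed by
   puromycin selection before the screen proper and are not modeled.
2. **Growth.** Exponential at rate ln2/`doubling_time_days` (default
   1.5 d). Hairpins against escape-essential genes multiply the rate by
   `fitness_cost` (default 0.9) in *every* arm: genes like Mediator
   subunits are broadly required, so even partial knockdown slows growth.
   The baseline arm is the frozen aliquot and is returned unchanged.
3. **Escape commitment.** In the induced arm all cells grow until
   `t_senescence_onset_days` (default 7 of 21 days). At onset each
   hairpin's escaper count is a Poisson draw with mean
   (cells at onset) × p_escape. The default escape link sets
   p_escape = e (the hairpin's knockdown efficiency) for hairpins against
   planted escape genes — a cell escapes iff its knockdown is functionally
   sufficient, consistent with partial (~50–70%) knockdown being enough to
   bypass arrest — and p_escape = `p_background_escape` (default 1e-4)
   otherwise. The link is a pluggable callable. Escapers grow for the
   remaining 14 days; arrested cells persist at their onset count
   (senescent cells do not lyse), which produces the realistic non-zero
   background counts that make the read filter meaningful.
4. **Sequencing.** Counts per sample are Dirichlet-multinomial at
   `seq_depth` reads (default 5×10⁶). `dispersion` is the *mean Dirichlet
   pseudocount per hairpin*: the Dirichlet concentration for hairpin i is
   alpha_i = dispersion × n × p_i, where p is the abundance proportion
   vector and n the library size. With the default 1000 this gives ~3%
   extra coefficient of variation for an evenly represented hairpin —
   mild PCR/sequencing over-dispersion — and dispersion → ∞ recovers exact
   multinomial sampling. This per-hairpin scaling was chosen over the
   plain total-concentration parameterization because it keeps the noise
   level interpretable independently of library size.

Knockdown efficiencies are Beta(`knockdown_dist`) per hairpin, default
Beta(6, 4) (mean 0.6, central 90% ≈ 0.33–0.83), emulating the 50–70%
knockdown typically achievable for essential genes. Escape genes are a
uniform random draw of round(`frac_escape_genes` × genes), default 1%.

All randomness flows from one seed through named substreams
(`substream(seed, "seq", "dox_1")`, …), so every stage is independently
reproducible and induced replicates share the infected pool while drawing
escape commitment and sequencing noise independently.

Media changes every few days are deliberately *not* modeled as population
bottlenecks: a media refresh is not a passage. Branching-process
stochasticity of growth, cell-cycle structure, off-target effects and dose
response are likewise out of scope; expectations suffice for the counting
statistics this pipeline computes.

## Synthetic libraries (`senescreen.library`)

Barcodes are uniform random ACGT strings of `barcode_length` (default
18 nt, a typical clonal-tag length) accepted by rejection so every pair
differs at ≥ `min_hamming` positions (default 3). The rejection check uses
a pigeonhole index — two barcodes at distance < m must agree exactly on one
of m contiguous segments — so generating a 27,500-barcode library takes
seconds rather than the quadratic all-pairs scan (which remains available
as `ScreenLibrary.min_pairwise_distance()` for validation). Libraries read
from TSV are structurally validated (uniqueness, alphabet, equal lengths)
but their pairwise distance is not checked unless requested, since real
vendor libraries make no distance guarantee. Synthetic gene symbols are
`G000001`-style.

## Barcode counting (`senescreen.counting`)

Reads are `anchor5 + barcode + anchor3 + padding`. Extraction tries the
exact anchor at offset 0, then (by default) scans for the anchor anywhere
with ≤ 1 mismatch, taking the leftmost acceptable position. Assignment is
exact-hash first; with `max_mismatch=1` the 3L single-substitution
neighbours of the observed barcode are looked up, rescuing the read if
exactly one library barcode sits at distance 1 and discarding it as
ambiguous if two or more do. On a distance-≥3 barcode set, a read whose
true barcode gained ≤ 1 substitution can never be rescued to the wrong
hairpin: that would place two library barcodes within distance 2. Matching
is substitution-only; indels are not modeled because amplicon barcodes sit
at fixed offsets. Per-sample stats (`exact + rescued + ambiguous +
unassigned = total`) are verified before results are returned.

## Enrichment and hit calling (`senescreen.enrichment`)

Numerical/design choices where the procedure itself is underdetermined:

- **Pseudocount 0.5 RPM**, added symmetrically to numerator and
  denominator of every fold change. It bounds ratios for zero counts and
  is the standard treatment for count ratios; results are insensitive to
  its exact value at screen depths.
- **Replicate aggregation** defaults to the mean of dox-replicate RPM
  before the fold change (`replicate_mode="mean"`); `"both"` instead
  requires each replicate's own fold change to clear the threshold, as a
  sensitivity analysis.
- **Read filter on raw counts** (">100 reads" is most naturally raw
  reads), strict inequality, default `any_dox` (one replicate above the
  floor suffices); `all_dox` selectable.
- **Strict inequalities** for both thresholds ("more than fivefold",
  "more than 100 reads").
- The baseline is a single sample; multiple uninduced controls are
  aggregated by mean.
- No multiple-testing machinery: the procedure is threshold-based by
  design.

Monotonicity holds by construction: raising any of the three thresholds
can only shrink the enriched set and the hit set (property-tested).

## What the simulator does and does not establish

Passing the recovery tests shows the pipeline's statistics correctly invert
the generative model at realistic depth, representation and noise — planted
escape genes with Beta(6,4) knockdown are recovered with sensitivity ≥ 0.8
and ≤ 1 false-positive gene per 500-gene run, and matched null screens
yield zero hits. It does not establish performance on real screens, where
hairpin efficacy correlates within genes, PCR noise is structured rather
than exchangeable Dirichlet, off-target effects create correlated false
signal, and library representation can be skewed by cloning. The generator
is a calibrated test harness, not a claim about any particular dataset.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale: 500 genes × 5 hairpins
(2,500 hairpins) for recovery/null/concordance experiments, 10 simulation
seeds each, 5×10⁶ reads per sample; 10⁵ reads for FASTQ round trips and
rescue-safety checks; full-scale (4,922 genes, 27,500 hairpins) library
generation is exercised once. Closed-form growth checks use relative
tolerance 1e-9; Poisson/binomial moment checks use 3–5 standard errors;
the deterministic hit-rule comparisons are exact. Degenerate inputs fail
loudly: zero-total samples, all-zero abundances, missing roles, duplicate
ids/barcodes and malformed FASTQ records all raise named errors rather
than propagating NaNs.

## Known limitations

- Expectation-based growth understates drift for hairpins seeded at very
  low representation; at the default 400 cells/hairpin this is negligible.
- The anchor scan tolerates one mismatch only; heavily degraded anchors
  drop reads into `unassigned` rather than recovering them.
- `replicate_concordance` uses the first two replicates of a role; screens
  with more replicates get a single representative pair, not a matrix.
- The permutation-FDR extension mentioned in early designs was dropped:
  the threshold rule has no error-rate claim to calibrate, and the null
  simulator already measures specificity directly.
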