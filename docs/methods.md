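# Methods

This note documents the models, parameter choices, and numerical
conventions behind each pipeline, what the synthetic generators do and do
not emulate, and the known limitations.

## Focus-pair distance analysis

**Detection.** Images are background-corrected with a morphological white
top-hat (disk radius `background_radius_px`, default 10 px), which removes
any structure wider than the structuring element while preserving
diffraction-limited spots. Local maxima of the corrected image with
intensity above `maxima_prominence` and at least `min_separation_px`
(default 2 px) apart are taken as foci and, by default, refined to the
intensity-weighted centroid of their 3×3 neighborhood. The prominence
threshold is deliberately a free parameter: exposure times in such
experiments span 100 ms–3 s and no single absolute threshold transfers
across them. Sub-pixel refinement is optional (`subpixel=False` reproduces
integer-pixel maxima).

**Pairing.** Matching is one-directional: each GFP focus takes its closest
CFP focus by Euclidean distance, and a CFP focus may serve several GFP foci
(replicated chromosomal regions often show two GFP foci near one CFP
focus). GFP foci with no CFP partner in the image are counted as unmatched
and excluded from distances. Exact distance ties resolve to the
lowest-index CFP focus, making results deterministic. A mutual-nearest
filter and a maximum-distance gate exist but are off by default, since the
measurement exports whole-image coordinates without per-cell gating.

**Statistics.** Distances are scaled at 62 nm/px (100× objective). Medians
and quartiles use inclusive linear interpolation between order statistics
(the convention is not externally fixed; this is numpy's default
`percentile`). Conditions are compared with a two-sided Mann–Whitney U
test, but the de-clustering *call* follows the fold rule: treatment median
≥ 2.5× control median. With hundreds of foci per condition even trivial
shifts reach p < 0.001, so the effect-size rule, not the p-value, carries
the decision. An absolute threshold variant (`nm_threshold`, e.g. 230 nm —
roughly the resolution floor below which distances are indistinguishable)
can be enabled alongside; the fold rule is the default because the two
published formulations disagree slightly and the fold form is
self-normalizing.

**Cell measurements.** Lengths arrive in pixels (segmentation is out of
scope) and are scaled to µm; nucleoid (DAPI) intensity per cell is the
in-mask mean minus the image background, estimated as the median of
out-of-mask pixels.

## Mu contact mapping

**Binning.** The genome ([0, L), 0-based) is cut into `n_bins` bins of
width L/n, edges floored to integers and the last bin extended to L, so the
partition is exact and widths differ by < 1 bp. Bins are 1-indexed;
insertion positions are BED starts (0-based, half-open). The binning origin
is coordinate 0 by default and configurable, since published bin numbering
depends on an unstated origin.

**Normalization.** f_b = (I_b/ΣI)/(R_b/ΣR) first removes sequencing depth
(both numerator and denominator are within-replicate proportions) and then
divides out each bin's share of mapped reads — the proxy for replication
copy number, since ori-proximal bins of an asynchronous population are
present at up to twice the terminus copy number and accumulate
correspondingly more insertions and reads. No model-based copy-number call
is made. Zero-coverage bins are masked (NaN) and excluded from the
percent-of-max rescaling, which sets the largest unmasked f_b to exactly
100. Percent-of-max is applied per replicate *before* averaging, so the
reported SD includes replicate scaling noise. f_b is invariant to scaling
all counts or all coverage by a constant.

**Condition comparison.** Per-bin two-sample t tests are equal-variance
(pooled) by default, with Welch available. Degenerate cases follow fixed
conventions: two identical constant groups give p = 1; constant groups with
different means give p = 0 with infinite t. No multiple-testing correction
is applied across the handful of *rrn* bins; each bin is starred
independently at α = 0.05.

## Pulldown enrichment

**Normalization.** Target replicate i is depth-matched to control replicate
i by scaling the target column to the control column's total, then
log-ratios are log2((t+1)/(c+1)) with a pseudocount of 1 (integer counts
with zeros are routine). Depth-matching within the pair keeps counts on the
control's raw scale, where the pseudocount has its usual magnitude, and
makes the ratios exactly invariant to rescaling a target replicate. The
i↔i replicate pairing is arbitrary but deterministic; a pooled-control
option exists.

**z-scores and calls.** Within each replicate, z = (x − median)/(1.4826 ·
MAD) over proteins, so the null bulk sits at z ≈ 0 even in the presence of
a minority of true positives; plain mean/SD is available for sensitivity
analysis but is strictly less sensitive when real enrichment is present,
because the signal itself inflates the SD (the package's validation
demonstrates this ordering explicitly). If the MAD is zero the scale falls
back to mean/SD; if that is also zero, all z are 0. A protein is enriched
when z > 2.5 in *every* replicate (the geometry of plotting per-experiment
z-scores against each other and calling the top-right region); an
any-replicate rule is available.

**FDR.** Rather than parametric per-protein p-values, an empirical FDR is
computed by rebuilding the entire normalize→z pipeline under every
non-identity target/control label swap within replicate pairs (2³−1 = 7
swaps at n = 3) and comparing each protein's observed min-z with the pooled
null: FDR(s) = E[null proteins ≥ s] / observed proteins ≥ s, capped at 1.

**Known limitation.** The robust scale is not immune to contamination: with
~5% of proteins strongly enriched the MAD inflates by roughly 6%, which
costs noticeable sensitivity under the strict all-replicates rule (measured
~82% vs ~90–95% at a ≲1% enriched fraction, 10× enrichment, baseline mean
20). For screens expecting many hits, the any-replicate rule or a larger
replicate count mitigates this.

## Synthetic data

The generators produce data with the statistical structure each pipeline
assumes — no more.

* **Foci fields.** Pair separations are log-normal, parameterized by their
  median (exact by construction: exp(μ) with μ = log(median)) and a
  log-scale spread σ = 0.6; the law is strictly positive and heavy-tailed
  like observed distance distributions, but the true distributional family
  is unknown — the published summaries give only medians and quartiles, so
  the log-normal is a stand-in, not an inference. Default medians: 134 nm
  (clustered) and 566 nm (de-clustered). Cells occupy non-overlapping
  rectangles (sparse monolayer); foci are symmetric Gaussian spots
  (σ = 1.5 px, amplitude 1200) on a constant background (200) with i.i.d.
  Gaussian noise (SD 10), quantized to 16 bit. Not emulated: chromatic
  shift, aberration, uneven illumination, autofluorescence, or cell-shaped
  masks — so passing tests show the pipeline recovers distances from
  well-formed spot images, not that it is robust to real optics.
* **Mu insertions.** Per-bin insertion probability ∝ contact profile ×
  copy number c(b) = 2^(g·(1−d(b))), d(b) the normalized circular bin
  distance from the ori bin: g = 0 is flat, g = 1 the full 2× ori:ter
  marker-frequency gradient of an asynchronous exponential culture. The
  donor bin's propensity is multiplied by (1 + local_contact_weight).
  Insertions are multinomial (fixed total, default 10⁵, matching a fixed
  sequencing depth), placed uniformly within bins; coverage reads (default
  2×10⁶) are multinomial ∝ bin width × c(b). Not emulated: sequence
  preference of integration, mappability, or read-level artifacts.
* **Spectral counts.** Negative-binomial with mean 20 and shape 10
  (variance μ + μ²/10, i.e., a ~32% biological CV floor — typical for
  label-free spectral counting), three replicates; planted proteins have
  their target mean multiplied by a fold (10× in the standard power
  scenario). Not emulated: peptide-level sharing, abundance-dependent
  detection dropout, or protein-size effects on counts.

Every generator returns exact ground truth (distances, contact profile,
planted set) and is bit-reproducible for a fixed seed
(`numpy.random.default_rng`).

## Validation design and problem sizes

The test suite and `scripts/acceptance.py` size simulations to finish in
seconds while keeping the statistical checks meaningful: distance-pipeline
recovery uses 500 cells per condition over 5–10 independent fields;
gradient-removal and contact-recovery checks use 10⁵ insertions × 20
simulated experiments (χ² flatness at α = 0.01 against the coverage-based
expectation); enrichment error control uses 200 proteins × 3 replicates ×
20 experiments. The pulldown pipeline's supplement-layout validation runs
on a synthetic stand-in for a seven-sgRNA experiment (the published raw
tables are not programmatically available), with one protein planted in
exactly four samples to exercise the cross-sample membership count; both
z conventions are run on it, documenting that the robust convention
dominates mean/SD in sensitivity there.

## Degenerate inputs, at a glance

Empty images, all-zero insertion or coverage vectors, empty pair sets,
zero-total count columns, empty masks, and zero uninduced CFU all raise
`ValueError` rather than returning silently coerced values; blank spectral
cells are the single exception, becoming 0 with a logged warning, because
sparse supplementary tables commonly omit zeros.
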