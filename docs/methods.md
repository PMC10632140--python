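# Methods

This note documents the models, estimators and numerical choices behind
`gliosynapse`, and what the synthetic generators do and do not emulate.

## Single-cell state analysis

**Transform and gene universe.** Input expression is TPM, genes × cells.
The working scale is `log2(TPM/10 + 1)`; the divide-by-10 compresses the
dynamic range of full-length scRNA-seq TPM before the pseudocount. A gene is
*analysable* when its mean log2 expression across the malignant cells is
strictly greater than 0.25; all scoring and co-expression uses this
universe. The transform refuses to run twice, and the synthetic generator's
inverse (`TPM = 10·(2^x − 1)`) makes transform/inverse an exact round trip.

**Signature scores.** A cell's score for a gene set is

    score = mean(relative expression of signature genes)
          − mean(relative expression of bin-matched control genes)

where *relative* expression is gene-centred across cells, and controls come
from 30 equal-frequency bins of genes ranked by mean log2 expression: each
signature gene contributes the other genes of its bin, bin means averaged
over signature genes. This deterministic variant of the classic
sampled-control score has two useful exact properties used in the tests: a
constant matrix scores 0 everywhere, and the whole-universe signature scores
exactly 0. A sampled-control variant (`sampled_controls=True`, 100 controls
per gene, seeded) is available. Centring and binning are done within each
tumour sample by default (`per_sample=True`), then pooled; a cohort-wide
mode exists because the within-sample convention is a judgement call for
cohorts with very small samples.

**State assignment.** A cell is assigned the argmax of its AC-like, OC-like
and OPC-like scores when the maximum is strictly greater than 0.5, else
`unresolved`. Exact ties at the maximum are `unresolved` (conservative;
measure-zero on real data). Assignment is monotone: raising a winning score
never changes the label.

**Hierarchy coordinates.** The two-axis placement used for plotting is
`lineage = AC − OC` and `stemness = OPC − max(AC, OC)`. This is this
package's own two-axis summary of the score triplet — a documented stand-in
for the published hierarchy-plot construction, which is specified only by
citation in the source literature. Any analysis here that consumes the
coordinates (kNN smoothing) only needs a faithful 2-D neighbourhood
structure, not the exact published axes.

## NTRK2 co-expression

**Detection rate** per state is the fraction of assigned cells with
expression above zero; `log2(TPM/10+1) > 0 ⇔ TPM > 0`, so the scale choice
is immaterial. Unresolved cells are excluded; an empty state yields missing,
never zero.

**kNN smoothing** (visualization) replaces each cell's value with the mean
over its k = 10 Euclidean-nearest *other* cells in the (lineage, stemness)
plane. Implementation is a full pairwise-distance stable argsort, so
distance ties break by ascending cell index and the output is fully
deterministic; a self-inclusive mode is flag-gated. Smoothed values are
bounded by the raw range.

**Per-state correlation.** The analysable-gene matrix is centred gene-wise
once across the pooled assignable cells; the correlation of a gene with the
target in a state is then the normalized inner product of the two centred
rows restricted to that state's cells, *without re-centring per state*.
This follows the stated order of operations (centre across assignable
cells, then correlate within each state); with per-state re-centring the
global centring would be a no-op. A target or gene that is constant within
a state yields missing values (flagged), and missing never passes a
threshold. Selection keeps genes with |r| > 0.25 in at least one state
(union set) and r > 0.25 per state (positive sets); thresholds are strict
and the target gene is excluded from the reported sets.

The published counts for the curated cohort matrix (11,518 analysable
genes; 351/201/720 assignable cells; 519 union and 145/138/97 positive
genes) require that cohort's expression matrix, which must be downloaded;
the pipeline reproduces the *procedure* and is validated here on synthetic
data with planted truth. Exact replication of those counts also depends on
scoring internals that the original description leaves unspecified.

## Puncta colocalization

Stages run in the order: rolling-ball background subtraction (default ball
radius 2.5 µm, clipped at 0), DoG detection per channel, proximity
matching. DoG uses σ_small = 0.2 µm and σ_large = 0.4 µm (converted to
pixels), appropriate for ~0.5 µm synaptic puncta; detections are local
maxima of the DoG response above `min_response`, with non-maximum
suppression at the σ_small scale. The default threshold is 3× the robust
(MAD-based) SD of the DoG image, with a tiny absolute floor so an exactly
blank channel yields zero detections.

A postsynaptic punctum is colocalized when any presynaptic punctum centre
lies within 1.5 µm (Euclidean, centre-to-centre, boundary inclusive —
"within" read as ≤). Matching is one-to-many and only the post-side
percentage is reported. Centre-to-centre distance is the documented choice;
edge-to-edge would need a punctum size model the detection does not
produce. Coordinates are 0-based pixel centres, x = column, y = row.

## Trace quantification

ΔF/F uses `F0 = mean(baseline window) − background` (error if ≤ 0) and
`ΔF/F(t) = (F(t) − background − F0)/F0`; the peak is the maximum over
post-stimulus samples (per-series maximum when several stimuli were
delivered; configurable via the baseline window). ΔF/F is invariant to
scaling the trace and background by a common positive factor.

Transient duration is the length of the maximal contiguous run of
ΔF/F > 0 containing the peak, in seconds; a flag-gated alternative sums all
supra-zero samples. Two estimator properties worth knowing:

* *Run-extension bias.* With symmetric zero-mean noise, each boundary of a
  supra-zero run extends while adjacent baseline noise stays positive —
  an expected p/(1−p) = 1 extra sample per side at p = 0.5, i.e. about +2
  samples regardless of noise amplitude. Tests assert recovery against this
  analytic expectation.
* *Peak order-statistic bias.* Taking the max of d noisy samples inflates
  the peak by ≈ (noise SD/F0)·E[max of d standard normals].

The SEP/PSD95 ratio divides the pH-sensitive SEP–GluA2 signal by the
co-localized PSD95–RFP signal sample-wise (all RFP samples must be
positive), cancelling common drift such as photobleaching; ΔF/F is then
applied to the ratio series. An acid quench drives ΔF/F to ≈ −1.

Band densitometry normalizes each lane's band density to its loading
density and expresses it as a percentage of the control-lane mean, so
controls average exactly 100% by construction.

## Categorical statistics

The two-sided Fisher exact p-value uses the probability-mass criterion:
with margins fixed, sum the hypergeometric probabilities of all tables no
more probable than the observed one (relative tie margin 1e−7, as in the
standard implementations). This differs from doubling one tail and is
validated against exact integer enumeration for every table with margins
≤ 30. The reported odds ratio is the conditional maximum-likelihood
estimate. Responder fractions are plain counts (e.g. 5 of 43 cells with
evoked EPSCs ⇒ 11.6%).

## Synthetic generators

* **Expression.** Log2-space Gaussian around per-gene means (uniform in
  [0.5, 3.5] log2 units; SD 0.5), +2.0 log2 units on a state's 30 signature
  genes in that state's cells, inverted to TPM, then 10% dropout. Planted
  correlations use one standard-normal latent factor: the target's
  deviation *is* the factor and gene g loads ρ_g on it plus √(1−ρ_g²)
  idiosyncratic noise, so the latent correlation is exactly ρ_g for any
  mixture of ρ values. Negative latent log values are clipped before
  inversion (kept rare by drawing target/correlated-gene means in
  [1.5, 3.0]); the reported truth is the pre-clip, pre-dropout latent
  matrix, and dropout is applied after correlation construction. Not
  emulated: UMI/negative-binomial count noise, ambient RNA, batch effects —
  so passing tests demonstrate correctness of the estimators under the
  assumed Gaussian-log model, not robustness to real scRNA-seq noise.
* **Images.** Isotropic Gaussian spots (σ 0.2 µm) with amplitudes uniform
  in [0.5, 1]×1000 on a constant background (100) with Gaussian noise
  (SD 5), 0.1 µm pixels on a 64 µm field. Colocalized post puncta sit
  within 0.5 µm of distinct pre puncta; non-colocalized ones are kept at
  least 3 µm from every pre punctum so the planted fraction is unambiguous
  at the 1.5 µm analysis radius. Same-channel spots are ≥ 1.2 µm apart
  (pre: + 2×offset) so detection does not merge them. No 3-D stacks, no
  structured background, no PSF anisotropy.
* **Traces.** `background + baseline + transient (+ noise)` with a boxcar
  (default) or linearly decaying transient of amplitude `peak_dff ×
  baseline`. Defaults: baseline 100, background 20, peak ΔF/F 0.5, onset
  at sample 20, 12 samples at 1 Hz — the sampling rate and transient scale
  of slice GCaMP6s imaging.

Same seed ⇒ bit-identical outputs; planted truths are emitted alongside the
data, never re-inferred.

## Problem sizes and defaults

The test suite and `scripts/acceptance.py` use 300 cells × 1,000 genes for
assignment recovery, 1,500 cells (500 per state) for correlation recovery,
200 + 200 puncta on a 640² image for colocalization, and 60-sample traces —
sizes at which binomial/sampling error is comfortably inside the asserted
tolerances while a full run stays under a minute. Pipeline parameter
defaults (30 bins, 0.5 state threshold, 0.25 analysable and correlation
thresholds, k = 10, 1.5 µm radius) are the analysis's stated values.

## Known limitations

* The hierarchy coordinates are a stand-in (above); absolute positions are
  not comparable with published hierarchy plots, neighbourhoods are.
* The bin-matched control scheme is deterministic; published scores using
  sampled controls will differ by the sampling noise of the controls.
* Colocalization is 2-D and centre-to-centre; overlapping puncta closer
  than σ_small merge into one detection.
* The Fisher enumeration guarantee is exercised for margins ≤ 30; beyond
  that the implementation relies on the hypergeometric pmf's accuracy.
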