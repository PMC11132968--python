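# Methods

## The measurement model

A gemma is imaged in two confocal channels: a nuclear fluorescent reporter
driven by the promoter under study, and a constitutive plasma-membrane
marker used only to locate the tissue. Because gemmae are lenticular discs
with two opposing apical notches, reporter activity is summarized as a 1D
intensity profile along the axis through the notches. Four landmarks define
that axis — the start of the gemma, the two notch tips, and the end — and
are supplied manually (from a sidecar CSV) or by the synthetic generator;
automatic notch detection is deliberately out of scope.

The image stage is conventional: maximum-intensity projection of the Z-stack;
rolling-ball background subtraction implemented as grayscale opening with a
disc structuring element (default radius 50 px, configurable — the radius
must exceed the nuclear spot scale so foreground survives); rotation by
−atan2(Δy, Δx) about the notch midpoint with bilinear interpolation and zero
padding (a further half-turn is applied if needed so the landmarks come out
ordered); and the plot-profile convention for a rectangular selection — one
value per column, the mean over the ROI rows. The default ROI is the bounding
box of the Otsu-thresholded membrane channel's largest connected component;
the ROI height is a free choice exposed in the API, since "a rectangle
covering the gemma" does not pin it down.

## Profile normalization

Raw profiles are made comparable in a fixed order — smooth, align, fold,
max-normalize — enforced by the pipeline runner:

* **Smoothing.** A penalized cubic smoothing spline with the dimensionless
  `spar` parameter (default 0.4) mapped to the roughness penalty by
  λ = r·256^(3·spar−1), r = tr(XᵀWX)/tr(Ω), with x rescaled to [0, 1] — the
  convention of R's `smooth.spline`, against which the implementation was
  cross-checked (max deviation ~0.01 on noisy test signals; a frozen
  concordance fixture is in the test suite). The basis uses a reduced knot
  set on the usual n → nknots schedule; the penalty matrix Ω is computed
  exactly by 2-point Gauss–Legendre quadrature per knot span (the integrand
  is piecewise quadratic for cubic splines). Smoothing precedes alignment.
  Fitted negatives are clipped to zero.
* **Landmark alignment.** A piecewise-linear axis map sends the measured
  landmarks onto reference positions (start = 0, end = 1); intensities are
  linearly resampled onto a uniform grid of 500 points. The reference
  defaults to the per-dataset mean segment lengths, with the two edge
  segments averaged so the notches sit symmetrically at r and 1 − r —
  the symmetry the folding step requires. Default reference: (0, 0.2, 0.8, 1).
* **Folding.** out(x) = ½·(in(x) + in(1 − x)) on [0, 0.5]. On an even grid
  the first half of the grid is kept; on an odd grid the exact midpoint is
  kept as a self-paired value. Folding about the midpoint (equivalently the
  midpoint between the symmetric reference notches) was chosen over
  re-centering each half locally; the latter would require per-notch
  landmarks after alignment and makes no difference when the reference is
  symmetric.
* **Max normalization.** Division by the profile maximum; identically-zero
  profiles are returned unchanged with a warning flag rather than raising.

## Expression domains

Folded normalized profiles (rows) are clustered agglomeratively with
Euclidean distance and complete linkage (the defaults of the R
`hclust`/`cutree` idiom), cut into k flat clusters with ties broken by row
order; labels are canonicalized by first appearance so the result is
deterministic and permutation-equivariant. k defaults to 5; because no
selection criterion accompanies that number, `select_k` chooses k by maximum
mean silhouette over a range (ties to the smaller k). An optional second cut
splits the sharpest notch-peaked cluster in two (off by default).

Each cluster mean is summarized by the **mode** of the distribution obtained
by treating intensity as a weight over axis positions: the default estimator
is the argmax of a Gaussian-kernel-smoothed weighted density (bandwidth
3 grid steps, reflecting boundaries, ties to the leftmost position); a
weighted half-sample mode is available as an alternative estimator flag.
The published analysis used a Grenander-type mode estimator whose exact
parameters are not recoverable; the kernel argmax is a documented surrogate
and the two agree on unimodal profiles in the tests.

Anatomical labels follow a rule table on the folded axis (notch at 0.2,
gemma center at 0.5), evaluated in this order: near-constant profiles
(coefficient of variation < 0.15) are **even ubiquitous** — this rule runs
first because the mode of a flat profile is arbitrary and must not reach the
position-based rules; then mode within 0.05 of the notch with half-width at
half maximum < 0.08 → **SCZ/DDCZ**; half-width 0.08–0.2 → **TZ**; notch mode
with monotone decay past 0.3 of the axis → **PZ** (the decay is tested on
six coarse bins of the tail so residual point noise cannot break strict
monotonicity); mode within 0.1 of the center → **CZ-biased ubiquitous**;
anything else → **other**. All thresholds live in `DomainRules` and were
calibrated once on the standard synthetic archetypes.

## Synthetic data

The generator plants known ground truth for every stage.

* **Archetypes.** Five nonnegative templates on the normalized axis:
  Gaussian notch peaks of σ = 0.03 (stem-cell zone) and σ = 0.10 (transition
  zone), an exponential decay from each notch with decay length 0.30
  (peripheral zone), a central Gaussian of σ = 0.12, and a constant. The
  free shape parameters (decay length, center width) were set once so that
  the five templates are mutually well separated in L2 after max
  normalization (pairwise distances of the same order) and so that each
  template lands in the intended branch of the domain rule table; with a
  longer decay length the peripheral-zone template becomes nearly flat and
  no clustering criterion could — or should — distinguish the two.
* **Profile sets.** Rows are archetype(x)·(1 + ε), ε ~ N(0, sd) per grid
  point, clipped at zero: multiplicative noise is the standard model for
  signal-proportional fluorescence variability. Defaults: 40 replicates per
  archetype, sd 0.1, 500-point grid.
* **Images.** The tissue is an ellipse of aspect 1.3:1 with two wedge
  notches cut inward along the major axis; the start/end landmarks are
  inset 16% from the ellipse tips, i.e. they mark the gemma margin where
  the disc has substantial thickness rather than the vanishing-chord rim.
  Nuclei sit on a jittered grid (≈2,600 in a 384 px image, matching
  cell-scale packing) clear of the tissue border, rendered as Gaussian
  spots of σ = 2.5 px whose planted brightness is the archetype at the
  nucleus's axis position. Because the rectangular plot-profile convention
  divides each column by the full ROI height, columns where the disc is
  thin would be attenuated regardless of expression; by default each spot
  is therefore rescaled by the inverse of the realized per-column spot mass
  (**rim compensation**), which makes the planted 1D field exactly
  recoverable by the rectangle convention and gives the generator a
  well-defined ground truth. Disable it for optically realistic images.
  Imaging noise is Poisson shot noise at a configurable photon scale plus
  additive Gaussian read noise. A planted axis tilt exercises the rotation
  stage. What the synthetic images do **not** emulate: chlorophyll
  autofluorescence, depth attenuation, nucleus size variation, cell-shape
  texture in the membrane channel — so passing tests show the pipeline's
  geometry and normalization are correct, not that it is robust to every
  optical artifact of real confocal data.
* **Toy genomes.** One gene per requested 5′UTR length on a single contig,
  alternating strands, with GFF3 gene/mRNA/five_prime_UTR/CDS features;
  requested enzyme sites and N-runs are written at recorded offsets upstream
  of the TSS, and all chance BsaI/SapI occurrences elsewhere are scrubbed,
  so a scan finds exactly the planted features.
* **Expression tables.** Per-gene TPM = sinh(a), a ~ N(class mean, sd) on
  the asinh scale (negative draws truncated at zero, a negligible bias for
  the default means), so class-wise asinh means match the planted values;
  expressing-cell counts follow the same scheme, rounded.

## Part design

Coordinates are 1-based inclusive throughout (GFF3 convention); the primary
transcript is the mRNA with the lexicographically smallest identifier. The
promoter window is exactly 1,800 bp upstream of the TSS (truncated with a
warning at contig ends; no clipping at neighboring genes by default). The
5′UTR runs from the TSS to the base before the translation start. Boundary
conventions: 5′UTR < 500 bp → fused `PROM5`; 500 ≤ length ≤ 3,000 → split
`PROM` + `5UTR`; > 3,000 → excluded (length exactly 500 goes to the split
branch; exactly 3,000 is still synthesized). "Repeated Ns" means a run of
≥ 2 consecutive N within the 1,000 promoter bases nearest the TSS; both the
run length and the window are configurable.

Domestication processes recognition-site hits left to right. For each hit
the 3rd footprint base is substituted first, preferring a transition
(A↔G, C↔T), falling back outward through the remaining footprint positions
and the two transversions in alphabetical order; a candidate is accepted
only if it removes the hit without creating any new site. Parts are
non-coding, so no codon constraint applies; the fixed order makes outputs
reproducible, and an unresolvable site raises an error rather than being
left silently. Every emitted part is re-scanned before L0 flanking.

L0 records flank the part with its fusion-site pair and outward-cutting
BsaI handles (`GGTCTCA` + fusion … fusion + `TGAGACC`); the default syntax
(PROM5 GGAG→AATG, PROM GGAG→TACT, 5UTR TACT→AATG) is the common plant
Type IIS convention and fully configurable, as is the handle enzyme.
`simulate_assembly` checks that part overhangs form a unique chain from the
acceptor's first to last fusion site and returns the ligated sequence with
each fusion counted once per junction.

`annotation_stats` reports per-gene 5′UTR lengths (summed over the primary
transcript's `five_prime_UTR` intervals) and intergenic lengths as the gaps
between consecutive **gene spans** per contig, with overlaps recorded as 0;
defining intergenic distance on transcript spans instead would shrink the
gaps and is noted as the main alternative reading.

## Numerical choices and problem sizes

Simulation sizes used by the test suite and the acceptance script — 200
profiles (5 × 40) per clustering run over 20 seeds, 384 px images with
≈2,600 nuclei, 500-point grids, 100 random sequences for the domestication
property — were chosen as the smallest sizes at which the planted effects
are comfortably resolved, and run in seconds. Tie-breaks are deterministic
everywhere (cluster labels by row order, mode ties to the leftmost grid
position, domestication candidates in fixed order). Degenerate inputs are
handled explicitly: identically-zero profiles are flagged rather than
divided by zero, all-identical matrices are rejected by `select_k`,
coincident notches and degenerate landmark segments raise errors.

## Known limitations

The classifier thresholds of the optional auto-flagger and the domain rule
table are calibrated on the synthetic archetypes, not on real images. The
smoothing spline agrees with the reference implementation to ~1% of signal
amplitude, not bit-for-bit (different knot placement at the reduced-knot
boundary). Percentages are rounded to the nearest integer; one published
table value (50 of 367 printed as 13%) rounds down instead and therefore
differs by one point from this package's output. External genome-scale
statistics (real annotation medians) run through `annotation_stats` but are
not validated offline.
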