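# Methods

## Unit of measurement

A nucleus is an 8-bit grayscale image (0-255, 255 brightest) with a binary
segmentation mask holding exactly one 8-connected foreground component
(holes allowed and excluded from the pixel set), calibrated by the pixel
edge length (default 0.1 um/pixel, the sample spacing of 100x oil-immersion
photomicrographs). RGB input is converted with ITU-R BT.601 luminance
weights (0.299, 0.587, 0.114), rounded half-up; the weights are exposed
because the conversion used by any given acquisition system is rarely
documented, and different weights shift absolute gray statistics. Every
feature reads in-mask pixels only — a metamorphic test randomises the
background and asserts bit-identical features.

## Morphometry

* **Area**: foreground pixel count; physical area = count x pixel_size^2.
* **Perimeter**: length of the closed 8-connected chain traced through the
  centres of the outer boundary pixels (Moore neighbour tracing, Jacob's
  stopping criterion); axial steps count 1, diagonal steps sqrt(2); an
  isolated pixel gets its unit-square boundary, 4.0; hole boundaries are
  not counted. This estimator is exact on axis-aligned rectangles (a 5x5
  square gives 16.0) but overshoots smooth contours by ~5% (staircase
  bias): the chain length of a digital circle is ~1.05 x 2*pi*r.
* **Form factor**: circularity `4*pi*A/P^2` by default, clipped to <= 1
  because the discrete perimeter makes small convex shapes exceed 1 (the
  5x5 square's raw value is 1.227). With the chain perimeter a large
  digital disk scores ~0.90-0.91, not 1.0 — a direct consequence of the
  staircase bias above; circularity remains maximal for disks among shapes
  of equal area, which is the property that matters for ranking nuclei.
  The alternative `axis_ratio` (minor/major axis of the second-moment
  ellipse) is insensitive to boundary roughness.
* **Gray statistics**: mean and sample SD (n-1) over in-mask pixels.

## Co-occurrence texture

The GLCM accumulates ordered gray-level pairs over four unit-distance
directions (0, 45, 90, 135 degrees) and both orientations, restricted to
pairs whose two pixels are both in-mask, then normalises to probabilities
p(i,j). Defaults: distance 1, all four directions pooled into one
symmetric matrix, G = 256 levels (no requantization); all three are
configurable (G in {16, 32, 64, 128, 256}, equal-width bins). Pooling
directions yields one value per feature per nucleus, matching how
karyometry studies report texture.

Feature conventions that have no single canonical definition are made
explicit: *inertia* and *contrast* are exposed as two names for
`sum (i-j)^2 p` (they are reported as separate but numerically identical
quantities in the karyometry literature this package follows);
*diagonal moment* is the absolute-difference first moment `sum |i-j| p`
(dissimilarity); *energy* is reported both normalised (`sum p^2`, in
(0, 1]) and raw (`sum counts^2`), because published "energy" values in the
thousands cannot arise from the normalised form. Entropy uses log2
(bits), with 0 log 0 := 0.

## Blanket fractal dimension

Upper/lower envelopes of the intensity surface evolve on mask pixels only:

    u_0 = l_0 = g
    u_e = max(u_{e-1} + 1, 3x3-neighbourhood max of u_{e-1})
    l_e = min(l_{e-1} - 1, 3x3-neighbourhood min of l_{e-1})

with out-of-mask neighbours ignored (the estimate is intrinsic to the
segmented nucleus; a 4-neighbourhood is available). The blanket volume
`V(e) = sum_mask (u_e - l_e)` is fitted by OLS as
`log V(e) = c + (3 - FD) log e` over e = 1..10 (eps_max and the fit range
configurable); R^2 of this regression is reported as a feature. A flat
surface gives `V(e) = 2 e N` exactly, hence FD = 2, R^2 = 1; estimates
outside [2, 3] (0.05 tolerance) are flagged, never clipped. Gray inversion
leaves V(e) unchanged exactly (envelope duality), which is tested.

Known bias: over a finite scale range the blanket estimator compresses the
FD scale toward the middle — fractional-Brownian surfaces with
H in {0.8, 0.5, 0.2} (theoretical FD = 3 - H = 2.2 / 2.5 / 2.8) measure
about 2.20 / 2.36 / 2.49 under the defaults. Ordering and monotonicity in
H are preserved, which is what the downstream class comparisons use;
absolute FD values should not be compared across implementations.

## Statistics and classification

The statistical unit is the patient: per-nucleus features are averaged per
patient per cell class over at least `min_nuclei` nuclei (default 30,
matching standard consecutive-cell counting practice); pooling nuclei
across patients is available only as an explicit sensitivity mode.

* paired t (two-sided) for within-patient class contrasts; zero-variance
  differences raise a degenerate-test error rather than returning p = 0.
* pooled-variance Student t for cohort contrasts (Welch via flag).
* one-way repeated-measures ANOVA for the global three-class test:
  subject effect removed, F = MS_class/MS_error, df = (2, 2(n-1)), no
  sphericity correction (none is standard in this literature; with k = 3
  and the effect sizes involved the correction is immaterial, and the
  2-class case reduces exactly to F = t^2, which is tested). If both the
  class effect and the error variance vanish the test reports F = 0,
  p = 1 (no evidence); a real class effect with zero error is degenerate.

The four-outcome rule at alpha = 0.05 (p = alpha counts as significant,
matching how boundary p-values are treated in the source tables):
global test not significant, or neither paired test significant ->
`not_defined`; both paired tests significant -> `intermediate`; only
blast-vs-atypical significant -> `close_to_promyelocytes`; only
atypical-vs-promyelocyte significant -> `close_to_blasts`. The rule is a
total function of the three p-values (property-tested over random
triples). No multiple-testing adjustment is applied across the 14
features — each feature is interpreted on its own, as is conventional for
this descriptive design; a Holm layer can be added by callers.

## Synthetic data

The generator emulates the *measurable structure* of stained bone-marrow
nuclei, not their photorealistic appearance.

**Masks**: an ellipse with the target area (~100-120 um^2 at 0.1 um/pixel,
i.e. ~10-12 thousand pixels) and axis ratio, its outline radius perturbed
by random low-order harmonics (k = 2..5) of relative amplitude
`boundary_irregularity`; rejected and regenerated (up to 10 times) if the
region splits or misses the target area by > 10%.

**Textures**: fractional-Brownian-motion fields by spectral synthesis
(power spectrum ~ f^-(2H+2)), plus dark Gaussian "chromatin clumps", then
an affine rescale to the target in-mask mean/SD and clipping to [0, 255].
Two conventions matter and are deliberate:

* *Oversampled synthesis*: synthesis at the target resolution is
  band-limited at Nyquist and therefore too smooth at the 1-2 pixel scale,
  which inflates the blanket slope; the field is synthesised on a 2x finer
  grid and decimated, folding sub-pixel power back into the samples as
  point-sampling of a continuous fBm surface would.
* *Amplitude*: the blanket estimator is not amplitude-invariant (its +-1
  vertical step sets an absolute scale), so fractal-recovery experiments
  standardise the adjacent-pixel height-difference RMS (30 gray levels, a
  relief large enough that the fractal term dominates the vertical term
  across e = 1..10 for all H studied; chosen by a calibration run and
  fixed).

Preset recipes `blast_like` and `promyelocyte_like` encode the published
sign pattern of the blast-promyelocyte contrast (promyelocytes: larger,
more indented nuclei; smoother, more homogeneous, lower-entropy/lower-FD
chromatin); `blend_recipes(lam)` interpolates them for the atypical class.

**Cohorts**: per-patient per-class feature means follow a mixed model —
class mean + patient random effect (variance rho*sigma^2, default
rho = 0.5) + residual ((1-rho)*sigma^2) — with the atypical mean
`lam*mu_blast + (1-lam)*mu_pro`. Default class means are the published
MDS blast/promyelocyte values with sigma set to half the class gap (a
2-SD separation) for features that differ; default sizes are the study's
(30 MDS patients, 19 normal, 30 nuclei per class). Ground-truth labels
follow from lam alone (0 -> close to promyelocytes, 1 -> close to blasts,
interior -> intermediate, zero gap -> not defined).

What the generator does **not** emulate: staining variability and colour,
touching/overlapping cells, segmentation error, nucleoli as explicit
structures, optical blur, or any spatial correlation between features
beyond the shared patient effect. Passing recovery tests therefore shows
the pipeline measures what it claims on surfaces with known roughness and
cohorts with known structure — not that it would segment or normalise real
smears, which are out of scope (masks are consumed as given).

## Experiment sizes and numerical choices

* Fractal recovery experiments use 256x256 surfaces, 20 seeds per H; the
  image-level demo cohorts use reduced nuclei (~2500 px) and 6 patients —
  sizes chosen so the full battery runs in well under a minute while
  leaving the conclusions (ordering, recovery rates) unchanged at larger
  sizes.
* Classification-recovery simulations use 30 patients, 200 replicates, and
  a 2-SD class gap; at lam = 0.5 the implied paired-test effect size is
  d = 1 per contrast, so recovery of `intermediate` is expected in ~99% of
  replicates and the >= 80% / >= 90% test thresholds are not tight.
* Rounding is half-up throughout (grayscale conversion, texture
  quantization to 8-bit); probabilities are normalised to sum to 1 within
  1e-12; OLS fits use scipy's linregress; all randomness flows from
  numpy `SeedSequence` spawning, so every artefact is a pure function of
  (recipe, seed).

## Limitations

* Absolute published feature means (gray level ~129, energy ~7000,
  FD ~2.13) are not reproducible from first principles: the original
  acquisition's grayscale conversion, GLCM distance/quantization and
  blanket scale range are undocumented, and the underlying images are not
  public. The package therefore validates against oracle equivalence,
  exact limits, parameter recovery and the published p-value/label
  pattern, not against absolute table values.
* The chain perimeter's staircase bias (~+5% on smooth outlines)
  propagates into circularity (~-10% for disks); comparisons between
  nuclei measured with the same estimator are unaffected.
* The blanket FD compresses the [2, 3] scale over the default e-range;
  only within-pipeline contrasts are meaningful.
* The repeated-measures ANOVA assumes sphericity; with three classes and
  patient-mean data this is mild, and a Greenhouse-Geisser layer could be
  added if needed.
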