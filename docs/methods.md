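# Methods

This note documents the models, numerical choices and limitations of the
package. Units are nanometres for lengths and arbitrary linear intensity
units unless stated.

## Data model and conventions

Volumes are `(z, y, x)` float stacks with in-plane pixel size and z-step
in nm. For expanded samples, lengths follow the *post-expansion*
convention: a segment's physical length is pixel count × pixel size in
the image as acquired; dividing by the expansion factor converts to
pre-expansion (biological) scale. 16-bit acquisitions are promoted to
float without rescaling so intensity ratios (retention) stay meaningful.
Metadata lives in JSON sidecars, not TIFF tags — bit-exact and diff-able.
No detector-offset subtraction is applied at I/O time; background handling
is the preprocessing stage's job.

## Resolution calibration

**Model.** The bead is a uniform circle (disk) of diameter *d*; the
optics are an isotropic 2-D Gaussian of FWHM *g*. The observable is the
FWHM *F* of a line profile through the bead centre.

**Forward model.** The central cross-section of disk ⊗ Gaussian is
computed by 1-D quadrature over chords with Gaussian-CDF factors
(separability), sampled far finer (≳20×) than the FWHM; the half-maximum
crossing is located by linear inversion on that grid. This is exact to
well below 0.1 nm at the default sampling.

**Inverse.** Given (*F*, *d*), `deconvolve_bead` brackets *g* in
(10⁻³·F, 2F) and runs Brent's method on FWHM(g) − F; the map is strictly
monotone so the root is unique. As d → 0, g → F (delta object).
Quadrature subtraction is deliberately *not* used: disk ⊗ Gaussian widths
do not subtract in quadrature, and at d/F ≈ 0.3 the quadrature
approximation errs by several nm.

**Rayleigh conversion.** R = 1.22·g, applied to the deconvolved Gaussian
PSF FWHM. With the calibration inputs F = 320 nm, d = 100 nm this yields
g ≈ 314.4 nm and R ≈ 383.6 nm; at a 4.2-fold expansion the effective
resolution is R/4.2 ≈ 91 nm. An alternative reading applies an
Airy-equivalent factor (≈1.194) directly to the measured FWHM without
object deconvolution and lands within half a percent of the same number;
the deconvolve-then-Rayleigh order is the one implemented because it
reflects the stated calculation order, and the two cannot be
distinguished from the printed value alone.

**Stack calibration.** Beads are detected on the brightest slice as local
maxima of a 1-px-smoothed image above median + 5·MAD, duplicates within
one PSF FWHM merged. Each bead contributes two orthogonal profiles
through its intensity centroid, sampled at pixel pitch by cubic-spline
interpolation (linear interpolation convolves the profile with a 1-px
triangle kernel and biases the fitted FWHM upward by several nm at these
sampling ratios). Fits with R² ≤ 0.5 are discarded; FWHMs are averaged
over beads and directions before deconvolution. Axial resolution is not
estimated.

## Synthetic phantoms

The generator emulates the study's sample classes, with full ground truth
and strict determinism (identical spec + seed ⇒ bitwise-identical
output).

* **Beads**: uniform circles rendered on a 5×-oversampled grid (area
  weighting of sub-pixel coverage), Gaussian-blurred there, then
  point-sampled at pixel centres. Point sampling rather than box binning
  is used so the rendered PSF is the requested PSF — binning would
  re-broaden the very quantity the calibration measures. Centres are
  placed ≥3 PSF FWHM apart by rejection sampling.
* **Tissue**: nuclei are random ellipsoids (with darker chromosome
  regions carved inside, at ~⅓ the nuclear protein density); vessels are
  tubes along curvature-bounded random walks; somata are blobs carrying a
  nucleus; dendrites are thin branching filaments seeded at somata. The
  morphology is a reduced-scale cartoon — sizes are chosen so several
  objects of each kind fit a 96-px field, and no quantitative morphometry
  (spine scale, vessel tortuosity statistics) is claimed. Default protein
  densities rank vessels (1.5) > nuclei (1.0) > somata (0.8) > dendrites
  (0.6) > chromosome regions (0.35), giving the CH₃ composite distinct
  but overlapping contrast per structure class.
* **SRS forward model**: CH₃ = Σ (density × retention × structure map)
  + smooth hydrogel CH₂ field + uniform water O–H term, blurred by the
  in-plane PSF, then noised. Both background weights default to 0,
  emulating full deuteration of gel and water; nonzero weights model
  residual spectral crosstalk. The model is linear by construction.
* **Fluorescence channels**: nuclei → DAPI-like, vessels → lectin-like,
  somata+dendrites → MAP2-like, somata → NeuN-like; each is the blurred,
  noised structure support.
* **Noise**: Poisson–Gaussian by default (shot noise at a configurable
  photon scale plus Gaussian read noise) since the detector is
  shot-noise-limited; a pure-Gaussian mode exists for analytic tests.
  The default tissue phantom uses photon_scale 1000 and read σ 0.01,
  i.e. roughly SNR 30 at unit intensity.
* **Expansion**: geometry is zoomed by the linear ratio on all three axes
  (same microscope, so features grow in pixels) and conserved signal is
  divided by ratio³ — fourfold expansion means 64-fold dilution. The
  interpolation's small boundary mass drift is renormalized away so total
  signal is conserved exactly, which is the physical constraint.
  Retention multiplies the structure signal of the post image only (the
  unprocessed render always uses retention 1 — retention describes what
  survives homogenization). An optional smooth random displacement field
  of given RMS models distortion. Lipid removal is modeled only as the
  absence of a lipid channel post-expansion, with no spectral model.

What passing tests on these phantoms does *not* show: performance on real
tissue texture, depth-dependent aberrations, registration under lipid
contrast change, or epitope-loss effects — none of which the generator
attempts to emulate.

## Expansion-ratio registration

Maximum-intensity projections of both stacks are windowed (Hann), their
Fourier magnitudes high-passed and log-polar resampled; phase correlation
of the two log-polar maps gives rotation (angular axis) and scale (log
radial axis), with the peak search restricted to the physically allowed
window (|rotation| ≤ 30°, scale ∈ [1/8, 8]) so the broadband DC lobe
cannot capture it. The scale estimate is then refined by bounded
golden-section search maximizing the translation-invariant normalized
cross-correlation of the rescaled pair (the spectral estimate is
quantized to the log-polar grid; the refinement removes that
quantization). The physical ratio multiplies the recovered pixel scale by
the pixel-size ratio of the two acquisitions. A correlation peak below
0.1 raises a registration error — never a silent fallback. On seeded
noiseless phantoms with true ratios in [3, 4.5] the median ratio error is
≈0.1%; the acceptance bound is 1.5%.

Registration is 2-D (on MIPs) because pre/post z-sampling differs
physically; no non-rigid registration is attempted, and distortion is
only reported as an intensity-weighted residual, not corrected.

## Retention quantification

ρ = mean(expanded|mask) · E³ / mean(original|mask), loss = 100·(1−ρ).
The cubic exponent is the volumetric dilution of an isotropic expansion;
generator and quantifier share it by construction. Inputs are assumed
background-subtracted. The estimator is exact for structures large
compared to the PSF; for objects within a few PSF widths, boundary blur
moves different signal fractions out of the pre- and post-masks and
biases ρ upward by a few percent — hence retention validation uses a
whole-cell phantom (8 µm cells vs 0.32 µm PSF), the regime of per-cell
intensity comparisons, where the bias is below 1%. `segment_cells`
(Otsu on a 1-px-smoothed MIP, holes filled, objects < 100 px dropped)
provides masks when none are supplied.

## Virtual staining

**Preprocessing.** Rolling-ball background subtraction (radius 50 px at
full scale) implemented as grayscale opening against the ball
structuring function h(r) = √(R²−r²) — erosion then dilation, ±∞ border
padding — followed by per-slice percentile windowing to [0, 1] at the
(1, 99.9) percentiles. An all-zero slice normalizes to zeros, never a
division by zero. The percentile window is the package's own choice; only
"intensity normalization" is prescribed by the training recipe this
follows.

**Dataset.** z-slices of matched stacks become 2-D pairs (the z-step
exceeds the axial resolution, so slices are quasi-independent); the
test/train split is drawn once per image at 1:3, never per patch.

**Architecture.** 2-D U-Net, two 3×3 same-padded convolutions + ReLU per
level, 2×2 max-pool, nearest-neighbour upsampling with skip
concatenation, linear 1×1 output head. Depth and base width are knobs:
full scale is depth 4 / 32 channels; desk scale is depth 2 / 8 channels.
The implementation is pure numpy (im2col → BLAS matmul, analytic
gradients verified against finite differences at 1e-7, Adam) and fully
seeded: identical data + config + seed reproduce the loss trace exactly
in single-threaded execution.

**Training regime.** Batches of random patch positions over training
images; Adam at lr 10⁻³ on MSE; "steps" are optimizer iterations (one
batch each — a literal 50,000 passes over ≥200 stacks would be
implausible, and patch sampling makes step semantics the natural
reading). Full-scale defaults are 128-px patches, batch 32; the
desk-scale benchmarks run 64-px patches, batch 8, 400–600 steps, which
trains in ~1–2 minutes per model on one CPU core. Augmentation is off by
default (none is prescribed). A non-finite loss raises a divergence error
carrying the step index.

**Inference.** Half-overlap tiling with a Hann taper; every tile is
predicted with a mirror-padded context margin equal to the network's
receptive-field half-width (12·2^depth − 8 px) which is cropped before
blending, so tiling introduces no convolution-padding seams — tiled and
whole-image predictions agree exactly. Images smaller than a tile are
reflect-padded. One model per target channel; outputs are labelled
`v-<channel>`.

## Evaluation

Pearson r is computed by the explicit deviation-sum formula in float64;
constant input raises an undefined-correlation error rather than
returning 0. Per-image and pooled (concatenated-pixel) coefficients are
both reported since either convention is defensible; pooled r is the
headline. The sparse-channel rule ("images with signal") is
operationalized as: an image participates iff the fraction of
ground-truth pixels above median + 3·MAD exceeds 0.1% (both knobs
exposed) — sparse channels would otherwise be scored on unpredictable
background shot noise. No numeric r from real tissue is claimed: the
package's r values are phantom benchmarks only.

The noise-robustness curve degrades *training* targets with additive
Gaussian noise (σ in units of the clean targets' pooled standard
deviation), retrains from the same seed per point, and scores against
clean test targets; accuracy is non-increasing in σ within a small
stochastic tolerance.

## Benchmark problem sizes

Desk-scale benchmark configurations: identity task — 8 slices of 64²,
400 steps; vessel phantom — 16 slices of 96², 600 steps; noise curve —
8 slices of 48², 32-px patches, 150 steps per σ. These sizes are the
package's choice for a laptop-class single-core run; all thresholds
(identity pooled r ≥ 0.99, vessel pooled r ≥ 0.8, curve non-increasing
within 0.02) are met with margin at these sizes.

## Known limitations

* Bead model is a 2-D circle, not a projected sphere; axial PSF is not
  estimated.
* Phantom morphology is qualitative; no claim is made about real-tissue
  prediction accuracy, mosaic stitching, or transfer across samples.
* Registration assumes a similarity transform within ±30° and reports —
  but does not correct — residual distortion.
* The Rayleigh constant (1.22 on the Gaussian PSF FWHM) is one of two
  readings consistent with the published calibration point; see above.
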