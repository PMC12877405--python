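# Methods

`stretchquant` quantifies how vascular smooth-muscle monolayers remodel under
uniaxial cyclic stretch, from multichannel fluorescence images. Five readouts
are implemented: actin-fiber orientation, LC3B autophagosome counts,
paxillin/vinculin focal-adhesion (FA) colocalization, mitochondrial
morphology (Tomm20), and mitochondrial intensity readouts (MitoTracker mass
proxy, JC-1 membrane-potential ratio), plus the angular statistics used to
compare stretched and unstretched conditions. Because the pipelines are
bespoke image-analysis chains, every one of them is exercised against a
synthetic scene generator with exact ground truth; this note records the
models, the parameters that matter, and the choices made where the design was
genuinely open.

## Geometric conventions

Rasters are indexed `(z, y, x)` with the origin at the top-left pixel.
Orientations are measured in degrees from the image x-axis toward the y-axis
and live in [0°, 180°); every reported angle is *folded* to [0°, 90°] as the
acute angle to the declared stretch axis (0° = parallel to strain, 90° =
perpendicular). Under an isotropic orientation distribution the mean folded
angle is 45°, which serves as the unstretched baseline. Intensities are
float64 in memory; the original integer dtype is kept so files round-trip
bit-exactly. Physical pixel sizes are per-assay: 0.071 µm (LC3B), 0.183 µm
(FA and Tomm20), 0.18 µm (MitoTracker), 0.721 µm (JC-1).

## Actin-fiber orientation

Single cells cannot be segmented in a confluent monolayer, so the image is
tiled into a grid of "cell equivalents" — 5 × 3 by default, the mean number
of cells per field — and each square contributes one **main orientation**.

Per pixel, the fiber direction is taken orthogonal to the local intensity
gradient (Gaussian pre-smoothing σ = 1 px, Sobel derivatives; a pure
Gaussian-derivative operator is available via `operator="gaussian"`), with
weight equal to the squared gradient magnitude, so flat regions contribute
nothing. Per square, angles enter a weight-weighted 1°-bin histogram over
[0°, 180°), circularly smoothed with a 5-bin moving average; the main
orientation is the histogram mode (ties break toward the smaller angle, and
the mode is reported at the bin centre, so an angle lying on a bin edge is
never recovered closer than 0.5°). Squares whose total gradient energy falls
below 5% of the mean per-square energy are omitted — they contain nothing to
orient (relevant for sparse synthetic scenes; confluent monolayers fill every
square). The per-image statistic is the mean of per-square main orientations
after folding; images, not squares, are the independent unit for statistics,
because cells within a field communicate mechanically.

Validated behaviour: fixed-angle scenes recover θ within ±2° per square for
θ ∈ {0°, 30°, 60°, 90°}; shifting the generative angle shifts every recovered
orientation equally (±2°); von Mises scenes (µ = 75°, κ = 8) recover a
circular mean within ±3° over 20 seeded scenes; uniform scenes average to 45°
within Monte-Carlo error. One caveat found during development: sampled
*sinusoidal* gratings at oblique angles carry a phase-dependent ±2.5°
gradient-angle moiré (for Sobel and Gaussian derivatives alike); ridge-profile
fibers, the actual imaging target, do not show it.

## LC3B puncta

Autophagosomes appear as bright puncta; the readout is puncta per cell over
the whole monolayer (no cell mask). The chain: an intensity threshold (Otsu
by default; an explicit value reproduces a manually chosen cutoff, and the
value used is recorded in pipeline output), strict `I > t` foreground,
8-connected components, rejection of components with area < 70 px (the
boundary is pixel-exact: 69 px is rejected, 70 px kept), then marker-based
watershed on the negated Euclidean distance transform to split touching
clusters. Watershed markers are distance-transform maxima with a minimum
separation of 5 px; a connected plateau of equal-distance pixels yields one
marker, so a single round spot is never split. Splitting never merges regions
and never changes the foreground support. The count is divided by the number
of nuclei — a manual count when available (the acquisition-time protocol), or
DAPI segmentation (Gaussian σ = 2, Otsu, distance-transform watershed with
12 px peak separation so an elongated nucleus is not split by its own
elongation, minimum nucleus area 60 px).

## Focal-adhesion colocalization

An FA is defined operationally as the connected union of a paxillin spot and
a vinculin spot that overlap by at least five pixels.

1. **Cell mask** (paxillin channel): CLAHE (clip limit 2%, tiles 1/8 of each
   image dimension) → median filter (disk radius 5) → Gaussian (σ = 5) →
   binarise at the *background-peak threshold*: a 256-bin histogram over the
   image's intensity range is smoothed with a Savitzky–Golay filter (21-bin
   window, cubic); the first local maximum (≥ 5% of the histogram's peak
   height, parabolic sub-bin refinement) is the background peak; its FWHM is
   measured by linear interpolation of the half-max crossings; the threshold
   is `peak + 0.2 · FWHM`. When one flank never reaches half maximum (e.g. a
   background plateau at the lowest gray level), twice the measurable
   half-width substitutes for the FWHM and a warning is logged. A uniformly
   bright image is all cell; a blank image is an error.

   This threshold sits deliberately close to the background peak: its
   downstream contract is to *never lose cell area* (spots are only searched
   in-mask), at the price of retaining some empty background — roughly 30% of
   background pixels whenever the background noise is resolved by the
   histogram, since `0.2 · FWHM ≈ 0.47 σ`. The tests assert exactly that
   contract (≥ 99% cell coverage, majority background exclusion) rather than a
   tight mask.
2. **Spot detection** (each channel): Gaussian (σ = 3) → CLAHE (2%) →
   per-pixel z-score over a centred 35 × 35 window (reflective borders;
   windows with zero variance get z = 0) → threshold z > 1 inside the cell
   mask → 8-connected components with area *strictly* above 100 px (100 px
   rejected, 101 px kept).
3. **Mutual overlap filter**: a spot survives only if it shares ≥ 5 px with
   at least one *single* partner spot in the other channel — overlaps with
   different partners are not pooled.
4. **Union FAs**: 8-connected components of the surviving spots' union;
   components containing both channels become FA records with per-channel
   areas, union area, µm² conversions, and the fitted-ellipse orientation
   folded to [0°, 90°]. A component drawing on several spots of one channel
   is merged into one FA and flagged `multi_partner`. Per-image summaries are
   per-FA means (mean Pxn/Vcl spot area, coverage fractions
   Σchannel/Σunion, mean FA area, FAs per cell); coverage fractions are
   asserted to lie in (0, 1] on every run.

End-to-end accuracy on 20-pair synthetic scenes: FA count exact, union areas
within ±10% of truth, orientations within ±3°. The 5-px overlap boundary is
verified on spots segmented at the generator's render threshold, where the
constructed overlap is pixel-exact; the z-score detector legitimately jitters
spot supports by a few pixels, so a 5-px constructed overlap is not a
meaningful boundary probe *through* it.

## Mitochondrial readouts

**Tomm20 morphology** (per z-plane): median (disk 2) → white top-hat
(disk 5) → CLAHE (2%) → Sauvola local threshold (window 31 px = 2·radius+1,
k = 0.2) → binary opening (disk 2) to separate touching objects →
skeletonize. Object *number* is the count of skeleton connected components;
object *area* is the mean area of the pre-skeleton binary objects (skeleton
pixels carry no area; this reading preserves both quoted outputs — skeleton
length is also exposed for the alternative reading). Per image, plane values
are averaged, counts divided by the cell count, and mean object area by the
total cell-mask area (from the actin channel). One numerical guard is ours:
Sauvola's rule `t = m(1 + k(s/R − 1))` was designed for documents and places
the threshold *below* the local mean wherever a window is nearly uniform,
which turns signal-free background into foreground; the local threshold is
therefore intersected with a robust noise floor (median + 3·MAD of the
top-hat image), which removes only pixels indistinguishable from background
noise. With it, 20-branch scenes are counted exactly with and without the
standard noise model, and a straight 100-px branch's skeleton length is
recovered within ±4 px (diagonal skeleton steps count √2).

**MitoTracker intensity**: maximum projection → subtract the morphological
opening with a 251 × 251 square (background estimate) → subtract the
minimum → Otsu threshold divided by three (to include dim cell pixels) →
opening and closing (disk 3, our parameterisation of the named operations) →
remove objects with area below 1,000 px (999 removed, 1,000 kept) → corrected
intensity = mean gray value of the *projection* inside the mask minus the
mean outside. Measuring both means on the projection makes the corrected
intensity exactly invariant to a global additive offset. `normalized` scales
by the unstretched-control mean. Noiseless plateau scenes are recovered
within ±2%.

**JC-1 ratio**: MIP each channel, sum them, Gaussian (σ = 3), global z-score
normalisation, subtract a gray-level opening (disk radius 15 — chosen larger
than the bright cell regions so the opening acts as a background estimate;
configurable), threshold the result at 0.6; the readout is mean(red MIP) /
mean(green MIP) inside that mask. The construction is invariant to scaling
both channels by the same constant. Generated ratios {0.5, 1, 2.5} are
recovered within ±2% and a {0.5, 1, 2, 4} series is strictly increasing.

## Statistics

Angular distributions are compared with the two-sample Kolmogorov–Smirnov
test (exact null distribution when `n1·n2 ≤ 10 000`, asymptotic otherwise);
scalar readouts with the two-sided Mann–Whitney U test (exact U distribution
when both n ≤ 8 and no ties, tie-corrected normal approximation otherwise).
Both agree with brute-force permutation enumeration to 10⁻⁹ at n = 5 per
group, and the KS test holds its 5% level within [0.03, 0.07] over 2,000
uniform-null simulations at n = 60 per group, with power > 0.9 against a
von Mises (µ = 75°, κ = 4) folded alternative. Uncertainty is summarised by
percentile-bootstrap 95% intervals over the independent unit (images or
cells — the unit is a parameter because different readouts use different
units); for cumulative curves the band is pointwise over a 1° grid.
Control normalisation divides by the unstretched-control mean. No
multiple-testing correction is applied by default (pairwise panel tests are
reported as-is); a Benjamini–Hochberg helper is exposed.

## Synthetic scenes and what they do not emulate

Each generator renders a noiseless scene plus a truth record per object, with
Poisson-plus-Gaussian noise applied separately
(`Poisson(s·I)/s + N(0, σ_r) + offset`, clipped at zero; the standard model
uses s = 1, σ_r = 2, offset = 10). Placement is rejection sampling with a
bounded retry count that fails loudly, so truth counts are never corrupted by
accidental overlaps. All generators are bit-deterministic under a fixed seed.

* **Fibers**: anti-aliased segments with Gaussian cross-section (default
  length 60 px, FWHM width 3 px, 200 fibers per 270 × 360 frame — a fiber
  density and scale typical of confluent monolayer fields), orientations from
  uniform / fixed(θ) / axial von Mises laws.
* **Puncta**: 2-D Gaussians truncated at 3σ whose half-max radius is the
  nominal spot radius; truth records the exact pixel area above the
  half-amplitude reference threshold, making the 70-px filter testable
  exactly. Cluster pairs are placed 2.25 radii apart — close enough that
  additive tails keep the pair connected above threshold, far enough that the
  union is a genuine dumbbell with two distance-transform maxima. Nuclei are
  ellipses in a DAPI channel.
* **Adhesions**: rotated super-ellipses (exponent 2.5, aspect 3.5, nominal
  area 250 px ≈ 8.4 µm², a mature FA) in `pxn` and `vcl`; pair members share
  *exactly* `overlap_px` foreground pixels at the render threshold (the
  partner slides along the shared axis until the intersection reaches the
  target; excess pixels are carved from its rim). A moderate cytoplasmic
  paxillin plateau surrounds each site so the pxn-derived cell mask covers
  the vinculin spots, as in real confluent fields.
* **Mitochondria**: random-walk polylines (2-px steps, heading noise 0.15
  rad, reflecting off borders) dilated to 5 px width (≈ 0.9 µm at the Tomm20
  pixel size; thinner ribbons cannot survive the pipeline's own disk-2
  opening), packed with ≥ 5 px clearance; an actin channel carries a large
  cell region for masking.
* **JC-1 / plateau cells**: soft-edged elliptical cells where the red channel
  is exactly `ratio ×` the green channel pixelwise over zero background, so
  the foreground ratio is exact under any mask; JC-1 cells are ~10 px in
  radius (the coarse 0.721 µm pixel), smaller than the segmentation's opening
  element. Plateau-cell scenes for intensity assays put cells at an absolute
  level over a constant background, giving corrected intensity an exact
  reference.

Not emulated: optical PSF and 3-D rendering fidelity, photobleaching,
spatially varying illumination, cell-to-cell intensity heterogeneity, and
the textured cytoplasm of real micrographs. Passing tests therefore
demonstrate algorithmic correctness (thresholds, filters, boundary semantics,
measurement accuracy, calibration) — not robustness to every artefact of real
microscopy.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: 30 scenes of 200
fibers for the orientation baseline, 12–20-pair adhesion scenes at 640–768 px,
20-branch mitochondrial scenes at 320 px, 2,000 null simulations for KS
calibration — sizes chosen so the full suite completes in well under a minute
of compute per module while keeping Monte-Carlo error small relative to every
tolerance. All randomness descends from explicit integer seeds (the pipeline
derives named per-stage substreams from one config seed via SHA-256), and
rerunning any pipeline with the same config reproduces every CSV byte for
byte.

## Known limitations

* The orientation estimator quantises to 1° bins; systematic accuracy is
  ±1.5° on dense textures and the uniform-baseline mean carries a ≈ −1°
  small-sample bias at 30 scenes.
* The FA cell mask is permissive by construction (see above); it is not a
  cell segmentation and should not be used to measure cell area.
* Tomm20 "average area" is ambiguous between binary-object area and skeleton
  length; binary-object area is the headline value, skeleton length is
  exposed via `skeleton_length`.
* The JC-1 z-score normalisation is global; a local variant would behave
  differently on fields with strong illumination gradients.
* `mutual_overlap_filter` merges an A-spot overlapping two B-spots into one
  FA (connected-component union) and flags it, rather than splitting it.
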