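# Methods

## Scope and model of the assay

The package models a fixed-cell, single-plane high-content screen: each
well of a multiwell plate is imaged in one or more fields, each field is a
set of co-registered grayscale channels (DAPI for nuclei, an antibody
channel for the receptor of interest, optionally EdU, MitoTracker-like
puncta, or a JC-1 red/green pair). Analysis is strictly per-plane and
per-cell; there is no 3-D, no deconvolution, no tracking, and no
machine-learned segmentation.

## Synthetic data generator

The simulator is the package's ground-truth instrument, not a fixture: it
is first-class, tested code. It emulates the features of screening data
that the measurements depend on and nothing more.

**Geometry.** Nuclei are discs (default radius 9 px, SD 0.5, clipped to
±2 px) and the cytoplasm is a concentric annulus (default outer radius
nuclear + 7 px). This suffices because no downstream measurement uses
shape beyond area and containment. Cells are placed by rejection sampling
with centre separation ≥ 2 × cytoplasmic radius + 1 and kept ≥ 26 px from
the border so that the default cell-mask dilation cannot reach the edge
(edge handling is tested with dedicated fixtures instead). A configurable
fraction of cells (default 10%) is placed as touching pairs: both nuclei
share one radius and their centres are 1.4–1.8 radii apart, which
guarantees the dumbbell has two distance-transform maxima — close enough
to be a genuine splitting problem, far enough to be well-posed.

**Intensities.** Each condition carries four-parameter logistic (Hill)
effect curves for the receptor's nuclear level, the true
nuclear/cytoplasmic ratio, the S-phase fraction and the relative cell
density; constants are used where no curve is given. Per-cell variability
is mean-preserving lognormal (default CV 15% on levels, 10% on ratios,
25% on EdU). EdU is bimodal by construction: S-phase nuclei at 2000,
others at 150 (arbitrary units). Mitochondrial puncta (default Poisson
mean 6 per cell, radius 2 px, intensity 500) are placed in the annulus
with a minimum mutual gap so every rendered punctum is an isolated
analytic disc. JC-1 renders a green level per cell and red = green × the
condition's ratio.

**Noise.** Signal is rendered analytically, then a constant background
(default 100) with an optional linear gradient is added, then Gaussian
read noise (default SD 20 ≈ 2% of the foreground receptor level) plus an
intensity-proportional term (SD = √intensity), and the result is clipped
at zero. At zero noise every pixel equals its analytic value, which is
what makes the exactness tests possible (integrated intensity = area ×
level; measured ratio = true ratio to 1e-9 on truth masks).

**Determinism.** Each field's RNG stream is spawned from the plate seed
and the well/field index (`SeedSequence(entropy=seed, spawn_key=(well,
field))`), so a single field can be re-rendered identically without
re-rendering the plate, and identical configs produce byte-identical
truth tables and images.

**What it does not emulate** — and hence what passing tests do not show
about real data: optics (PSF, chromatic shifts, vignetting beyond a linear
ramp), autofluorescence and spectral bleed-through, irregular nuclear and
cell shapes, confluent monolayers with shared cytoplasm boundaries,
mitotic/apoptotic morphologies, plate-edge and evaporation effects, and
focus failures. Results on the simulator bound what the *operators* do
under controlled conditions; they do not certify segmentation accuracy on
real images.

**Free parameters.** Cell density per field (default 50 in a 400×400 px
field) and the absolute intensity scales are not constrained by any
published value; they are config defaults chosen so fields are dense
enough to exercise contested dilation yet sparse enough to pack reliably.

## Segmentation chain

Order: rolling-ball subtraction → adaptive mean threshold → small-object
filter → seeded watershed → cell masks → edge removal. All parameters are
logged into the result object.

- **Rolling ball** is implemented as grayscale opening with an *exact*
  flat disc (pixels with dy² + dx² ≤ r²); erosion/dilation decompose into
  per-chord 1-D running min/max filters (van Herk), so the operator is
  linear-time and bit-exact against brute-force enumeration. Borders clip
  the footprint. Default radius 25 px: several nuclear radii wide, so
  nuclei are not flattened into the background estimate, and wider than a
  whole cell so the receptor channel's cells are removed from their own
  background estimate. A radius larger than the image warns and degrades
  to the global minimum.
- **Adaptive mean threshold**: foreground iff intensity > local mean
  (window default 51 px, reflective borders, integral-image exact) +
  offset. Default offset 30 intensity units ≈ 1.5 SD of the default read
  noise; a much smaller offset admits a large fraction of background
  pixels and percolates noise into spanning components.
- **Small-object filter**: objects with area strictly below 20 px are
  discarded; area exactly 20 survives. Idempotent; label masks are
  renumbered to a contiguous 1..N.
- **Watershed**: seeds are h-maxima of the Euclidean distance map
  (8-connected), default depth 1.5 px. At the default geometry the closest
  admissible touching pairs have a saddle prominence of ~2.2 px, which
  discretization and boundary noise can erode below 2; depth 1.5 splits
  every generated pair across 40 seeds with no over-splitting, while depth
  2.0 misses ~5% of pairs. Any foreground component whose maxima are
  shallower than the depth is seeded at its distance argmax, so every
  component yields at least one label.
- **Cell masks**: per-label distance transforms inside expanded bounding
  boxes; a pixel joins the nearest nucleus within the dilation radius
  (default 10 px), ties to the lower label (labels are visited ascending
  with a strict-less update, and distances are square roots of the same
  integers on both sides of a tie, so tie detection is exact). Nuclei are
  contained in their cells and cells are pairwise disjoint by
  construction.
- **Edge rule**: a label is removed when its *cell* mask touches the
  border, even if the nucleus is interior. Both masks are renumbered with
  one shared mapping; the operation is idempotent.

## Per-cell measurements

The cytoplasmic compartment is the full cell-minus-nucleus region (not a
fixed-width ring); the translocation ratio is the ratio of *mean*
intensities, which is invariant to cell size. Records with no cytoplasm
pixels, or a zero cytoplasmic mean, keep their row with the ratio flagged
undefined. When a background radius is supplied, each measured channel is
rolling-ball subtracted first; the measured cell mask is wider than the
true annulus, so absolute ratios are biased upward by background dilution
of the denominator — a monotone distortion, which is why the recovery
guarantee is rank correlation (Spearman ≥ 0.95 at default noise) rather
than absolute agreement, with exactness asserted separately at zero noise.

**EdU.** The S-phase threshold is estimated from vehicle wells only and
frozen for the plate, so a treatment that empties the S-phase mode cannot
drag the threshold. The default estimator fits a two-component Gaussian
mixture to log10 nuclear EdU means and thresholds at the midpoint of the
two component means; the mixture is trusted only when Ashman's
D = √2·|μ₁−μ₀|/√(σ₀²+σ₁²) ≥ 4 (a unimodal distribution split in half
scores ≈ 2.7) and both weights ≥ 1%. Otherwise — or with fewer than 50
training cells — the threshold falls back to median + 3·MAD in log space.
On a unimodal lognormal the MAD rule sits ≈ 2 SD above the median and
therefore calls ≈ 2% of cells positive; a fraction of exactly zero is
only guaranteed for degenerate (constant) backgrounds.

**Mitochondria** are segmented per single optical plane with the same
operators at puncta scale (ball radius 5, window 15, minimum size 4 px)
and assigned to the cell containing their centroid. **JC-1** ratios are
means over the whole cell mask; the well summary is the median over
defined ratios.

## Screen-level statistics

Wells are summarised by median/mean/MAD of the nuclear marker level, the
median translocation ratio and %EdU⁺; empty wells are flagged, not fatal.
Normalization is fold change over the vehicle-well median, or
100·(x−vehicle)/(agonist−vehicle) when an agonist scale is requested;
fold changes are invariant under global intensity rescaling.

**Dose-response.** The 4PL is fitted over raw dose (zero doses anchor the
zero-dose plateau) with bounded least squares from a multi-start grid:
plateaus from the response extrema, IC50 from the dose bracketing the
half-max crossing and from the geometric centre of the grid, slopes
{0.5, 1, 2}; bounds keep plateaus within ±2 response spans and log10 IC50
within ±2 decades of the dose range. The reported IC50 is the fitted
midpoint (relative IC50). "No activity" is declared when the
extra-sum-of-squares F-test (3 numerator df) cannot reject the constant
model at α = 0.05, or when the responses are constant to numerical
precision; a flat result carries `converged=False` and no IC50. Fits with
an IC50 outside the tested dose range are flagged `ic50_in_range=False`
rather than suppressed. When the top dose reaches only partial
inhibition, the bottom plateau — and with it the midpoint — is weakly
identified; Monte-Carlo at 5% multiplicative noise keeps the *median*
recovered IC50 within 20% of truth, but individual fits can err by ~2×.

**Profiles and clustering.** The profile matrix has one row per condition
(compound alone and compound+agonist are distinct rows) and one column
per cell line; values are normalized medians averaged over replicate
wells, missing combinations stay masked, and clustering refuses masked
values (dropping or imputing is an explicit caller step). Distances are
Euclidean; linkage defaults to average (UPGMA) and is configurable; the
clustered scale defaults to log2 fold change so cell lines with different
absolute receptor levels are comparable. Dendrograms export to Newick
with branch lengths = parent merge height − child merge height, making
the tree ultrametric with root-to-leaf depth equal to the final merge
height.

**Biolog plates.** Each 96-well plate is corrected by subtracting the
mean of its own negative-control (empty) wells; Z-scores are computed per
carbon source across all corrected replicate columns using the population
SD, so every emitted row has mean 0 and SD 1 exactly unless it is
constant, in which case it is zeroed and flagged.

**Cell counts.** Relative cell number is the well's cell count over the
median vehicle count at the same timepoint; zero-cell wells report 0 with
a flag.

## Orchestration and formats

Fields are one 16-bit grayscale TIFF per channel
(`r{row:02d}c{col:02d}f{field:02d}_{channel}.tif`), with a manifest-CSV
escape hatch; layouts, truth tables and all results are plain CSV; configs
are YAML. Quantization to the 16-bit range rounds and clips, logging the
number of clipped pixels. Tabular outputs are written atomically
(temp + rename) with a JSON provenance sidecar (package version, seed,
config hash). Unreadable or dimension-mismatched fields are skipped with a
logged warning and the run reports partial success (CLI exit status 3)
rather than aborting.

## Problem sizes

Validation workloads are sized for a single CPU: 20 fields of ~50 nuclei
for segmentation fidelity, 200 cells for ratio recovery, 20 × 2000-cell
wells (record-level generator, no rasterisation) for the S-phase
estimator, 100 Monte-Carlo replicates for IC50 noise robustness, and a
72-field two-line screen for the end-to-end determinism check. The
record-level generator is used where rasterising and re-segmenting images
would only re-add noise that the imaging tests already cover.

## Known limitations

- Absolute translocation ratios are biased by the cell-mask/annulus
  mismatch (see above); comparisons should be made on normalized or rank
  scales.
- The watershed cannot split pairs whose distance-map saddle is shallower
  than the h-maxima depth; the generator's 1.4-radii floor is chosen to
  stay above it, and denser real clumps would under-segment.
- The flat-model F-test assumes roughly homoscedastic residuals; strongly
  dose-dependent noise would distort the "no activity" call.
- Biolog Z-scores are computed across the pooled replicate columns of
  both arms; with a single replicate per arm the Z row degenerates to
  ±1 and carries no inferential weight.
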