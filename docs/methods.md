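# Methods

`morphoscreen` re-implements, as a tested pipeline over synthetic data, the
image-quantification and screen-statistics stack of a 384-well RNAi
high-content screen read out by cell shape and YAP/TAZ nuclear
translocation: segmentation, sub-cellular region geometry, a fixed
126-feature single-cell profile, five-way linear shape classification,
plate normalisation with control-referenced Z-score hit calling, and
screen quality control (replicate correlation, siRNA reproducibility, Z'
factor).  Because the original screen's images are not required, every
stage is exercised end-to-end on a ground-truthed synthetic generator whose
defaults encode the documented screen conditions.

## Synthetic data generator

Cells are smoothed star polygons: a periodic radial profile carries the
class protrusions, anisotropic scaling gives elongation, and a smooth
random perturbation gives boundary irregularity.  The five reference
morphologies are parameterised to be visually distinctive and linearly
separable in the extracted feature space (asserted by test):

| class        | area (px^2) | protrusions | elongation | nucleus frac |
|--------------|-------------|-------------|------------|--------------|
| spindly      | 900-1500    | 2 (on-axis) | 4.0        | 0.24         |
| large_spread | 4200-6500   | 0           | 1.15       | 0.12         |
| triangular   | 1600-2600   | 3           | 1.1        | 0.18         |
| fan          | 1800-3000   | half-disc   | 1.2        | 0.16, offset 0.45 |
| small_round  | 320-620     | 0           | 1.05       | 0.32         |

Channels: nuclear stain (nucleus only), microtubules (whole cell, with a
radial MTOC-centred falloff of 0.75-1.25x that gives seeded watershed a
real valley at cell-cell contacts), F-actin (whole cell with a 1.5x edge
band), and YAP/TAZ.  The YAP/TAZ channel is piecewise constant: cytoplasm
at the base level, nucleus at base x ratio, so the mean nucleus : mean
perinuclear-band ratio equals the designed ratio exactly before noise —
the generator is its own oracle for translocation measurements.  Per-cell
biological spread of the ratio is lognormal (sd 0.10 in log10 units,
recorded per cell in the ground truth).  Channel textures are smooth
multiplicative noise fields (10-15 % amplitude); the YAP/TAZ channel
carries none so the designed ratio stays exact.

Fields place cells without overlap, with a configurable minimum clearance
(default 3 px) between non-designed neighbours so chance adjacency does
not confound contact statistics.  Designed contacts are created by sliding
an incoming cell toward an anchor until it overlaps slightly (<= 10 % of
its area) and carving the overlap away, producing an extended, zero-width
shared boundary like space-filling segmentation output.  When rejection
sampling stalls at high packing an exhaustive FFT cross-correlation search
enumerates every admissible position; if none exists the field either
raises (strict mode, the default) or stops at the achieved count,
emulating confluence.  Multinucleate cells (failed cytokinesis) carry 1.6x
the cytoplasm and their nuclei are spread along the cell's interior spine;
a cell geometrically unable to host two nuclei is rendered mononucleate.
Imaging noise is Poisson shot noise (gain 1 photon/unit) plus additive
Gaussian read noise (sd 2) over a flat background (10), applied per
channel.

Whole plates map well roles to phenotypes: mock and sample wells draw from
the baseline mixture (spindly 0.20, large_spread 0.10, triangular 0.20,
fan 0.20, small_round 0.30; multinucleation 4 %); siLATS1-like wells add
+0.3 to the log10 nucleus:ring ratio; siYAP-like wells scale the YAP/TAZ
stain level by 0.4; siECT2-like wells raise multinucleation to 0.5 and the
large-spread weight to 0.45; dilution wells (columns 1, 2, 23, 24) scale
cells per field with the plated count (0.02 cells rendered per plated
cell, capped by a 40 % fill bound).  Per-well seeds derive from the plate
seed and well position, so identical seeds are bit-identical and replicate
plates share only designed biology.  One field per well by default.

The generator emulates the statistical structure the downstream stages
consume — class geometry, translocation ratios, contact, multinucleation,
plate layout, density series, shot noise.  It does not emulate
point-spread-function optics, illumination gradients, staining variation
between plates, or debris/artefacts; passing tests therefore validate the
measurement and statistics chain, not robustness to those real-data
nuisances.  A separate feature-level simulator generates well-by-feature
tables with controlled replicate correlation for the screen-statistics and
QC validations, where hundreds of wells are needed.

## Segmentation

Nuclei: Gaussian pre-smooth (sigma 2), global Otsu threshold (overridable),
hole filling, Euclidean distance transform smoothed at sigma 3, peak
seeds at minimum separation 10 px, watershed on the negated distance map,
minimum area 50 px^2.  Cells: seeded watershed on the negated smoothed
tubulin intensity restricted to the tubulin foreground union the nuclei,
one cell per nucleus; a nucleus outside the foreground becomes its own
1-px-dilated cell with a warning.  Cells touching any image edge are
removed with their nuclei and labels are made contiguous.  Multinucleate
detection cannot use nucleus-seeded cells (mononucleate by construction),
so a cytoplasm-first pass labels connected components of the tubulin
foreground (minimum 100 px^2) and counts nucleus centroids per component;
multinucleate percentage is taken over components containing at least one
nucleus and is missing when there are none.

## Region geometry

Border percentages are realised through a per-pixel normalised radial
coordinate rho (0 at the centroid, 1 on the boundary along the ray through
the pixel, > 1 outside).  The boundary radius per angular bin (720 bins)
is the outermost mask pixel — rays with several crossings use the
outermost, keeping rho <= 1 inside — with circular interpolation over
empty bins; inside pixels are clamped to <= 1 and outside pixels strictly
above 1.  A band between inner/outer borders a >= b (percent depth from
the edge, negative = outside) is 1 - a/100 <= rho <= 1 - b/100, so inner
100 % returns the whole cell exactly.  Regions: protrusion membrane region
(10 / -5), ring (inner 40 %, outer border 20 % of the edge-to-inner-border
distance, read as depth 8 % from the edge — the alternative reading,
measured from the inner border, is available via
`regions.ring_outer_from_edge=False`), with the uneroded nucleus excluded
from the ring; eroded nucleus (erosion radius max(1, round(2 % of the
equivalent radius)), falling back to 1 px and then to the uneroded mask
with a warning); 1-px membrane bands just inside (membrane 1) and just
outside (membrane 2) the boundary, the outside band clipped by neighbour
labels.  If the mask centroid falls outside the mask (strongly non-convex
cells) the pole of inaccessibility is used.  Disc fixtures reproduce
analytic annulus areas within 5 %; ellipse shell fractions are rotation
stable within 0.5 %.

## Features

Exactly 126 per-cell features:

* 16 morphology — area, roundness 4*pi*A/P^2 (Crofton perimeter), length
  and width as the image-moment ellipse axes (a uniform rectangle of side
  L reports length 2L/sqrt(3); the width:length ratio is
  convention-free), and width:length for nucleus, cell, cytoplasm; plus
  the protrusion-region area.
* 7 region-mean intensities — YAP/TAZ over nucleus, ring, cell, cytoplasm;
  nuclear stain over nucleus; tubulin over cytoplasm and cell.
* 8 ratios — nucleus:ring and eroded-nucleus:ring YAP/TAZ with log10
  versions (log10 nucleus:ring is "the YAP/TAZ ratio"), nuclear stain and
  nuclear YAP/TAZ per nuclear area, and cell / nuclear area per whole-cell
  YAP/TAZ.  Zero denominators give missing values, never infinities.
* 80 SER textures — 8 Gaussian-derivative responses x 5 stain-region
  pairs (tubulin and actin on cytoplasm; nuclear stain, tubulin, actin on
  nucleus) x 2 scales.  Scale s uses sigma = 0.5 + s px; the 1-D
  derivative kernels are moment-corrected so flat and linear ramps respond
  exactly zero even at sub-pixel sigma.  With l1 >= l2 the
  gamma-normalised Hessian eigenvalues: spot/hole are the rectified
  (negated) Laplacian gated on eigenvalue isotropy (|l1| within a factor
  0.5 of |l2|), ridge/valley the rectified dominant eigenvalue on the
  line-like complement, saddle sqrt(-l1*l2) on mixed signs, edge the
  gradient magnitude, bright/dark the rectified residual I - L.  Each
  detector is divided by its RMS on unit white noise at the same scale
  (fixed-seed, cached) — the "normalised within the kernel" convention —
  and the six structural detectors are mutually exclusive per pixel
  (argmax of calibrated strength), so a matched blob scores spot at its
  centre and edge on its flanks.  Features are region means.
* 12 Haralick — correlation, contrast, variance, homogeneity of a
  region-restricted grey-level co-occurrence matrix (64 levels min-max
  quantised over the region, distance 1, 4 directions, symmetric, both
  pixels inside the mask) for tubulin-cytoplasm, tubulin-nucleus,
  actin-nucleus.  A constant region reports contrast 0, homogeneity 1,
  correlation missing.  The implementation is verified exactly against an
  independent brute-force pair enumeration.
* 3 Gabor — mean, min, max across 8 orientations of the per-pixel complex
  Gabor magnitude (wavelength 4 px; kernels zero-mean, unit-L2, padded to
  a common support), averaged over the actin cytoplasm.

The accounting that closes the registry at exactly 126 reads the feature
list's "nucleus" and "nucleus region" YAP/TAZ intensities as the same
nuclear-mask feature (the eroded-nucleus intensity enters only through its
ratios; the published analysis itself found the two interchangeable) and
counts Gabor as three statistics.  Membrane-band-1/2 areas, the raw and
calibrated neighbour fraction, and total YAP/TAZ ((nuclear + ring mean
YAP/TAZ) / nuclear area, the hit-selection readout for overall level) are
carried as auxiliary per-cell columns outside the 126.

The neighbour fraction is 1 - A1/(2*A2) clamped to [0, 1] (A2 = 0 means
fully enclosed, returned as 1).  Because only the outside band is clipped
by neighbours, an isolated cell sits near 0.5 raw; the calibrated value
2*raw - 1 (clamped) rescales so isolated -> 0 and enclosed -> 1 and is
cross-checked against direct shared-perimeter measurement.  Well profiles
are per-feature means over cells ignoring missing values, plus the
neighbour fraction — 127 well-level features — plus cell count and shape
counts.

Extraction computes field-wide response maps once per channel and scale
and reduces them per cell by labelled bincount sums, keeping cost linear
in image area; Haralick and geometry run per cell on bounding-box windows.
Re-running extraction on the same input is bit-identical.

## Shape classification

A regularised one-vs-rest linear discriminant (ridge classifier, alpha 1)
on z-standardised features; a multinomial-logistic alternative is
selectable in the configuration.  Constant features are dropped with a
warning; missing values are imputed with training means and the cell
flagged.  Every cell receives exactly one label — the argmax of the class
scores, ties resolved by the fixed class order — and no reject option is
enabled by default (a confidence threshold exists but is off).  Training
uses ~1,500 rendered reference cells (300 per class), mirroring the
curated training-set size of the original screen; the model serialises to
a plain-text key-value artifact that round-trips bit-exactly.  On held-out
mixtures spanning the 5-class simplex (9 mixtures, 2,000 cells each)
recovered proportions deviate at most 0.05 from ground truth.

## Screen statistics

Raw per-plate well tables are normalised plate-wise (subtract plate mean,
divide by plate sd; a median/MAD variant is selectable), normalised values
are pooled per screen, and Z-scores are computed against the pooled mock
(negative-control) wells' mean and sd — following the published order of
operations; Z-scores on raw values are available via
`screen.zscore_on_normalised=False`.  A well is a hit for a feature when
|Z| >= 1.5 (boundary inclusive), applied to the five shape proportions,
the YAP/TAZ ratio, total YAP/TAZ, and the multinucleate percentage; no
multiple-testing correction is applied, faithfully to the plain-threshold
rule.  Fold changes are raw well value / raw mock mean, computed on the
unlogged ratio for the log-scale feature.  Density dependence is ordinary
least squares of the well YAP/TAZ ratio on plated cell count (>= 3
distinct densities), with the plated counts parsed from the gene-name
column of dilution wells as in the deposited tables.

Under a null simulation the empirical hit rate matches the Gaussian
two-tail probability (13.36 %) within Monte-Carlo error, and +3 sigma
spike-ins are recovered with sensitivity >= 0.9.

## Quality control

Replicate-plate reproducibility: well-averaged feature vectors z-scored
per plate; Pearson correlation of every well on plate A against every well
on plate B; the diagonal (replicate wells) versus off-diagonal (null) is
tested with Welch's two-sample t-test (the published "pairwise t-test" is
not defined for unequal-size sets).  siRNA reproducibility: correlations
between technical replicates versus the same computation after permuting
whole feature vectors across wells (preserving within-vector covariance,
seeded); medians and adjusted Fisher-Pearson skewness are reported.
Feature columns are z-scored across wells before correlating — without
this, raw mixed-unit features (areas in px^2 next to unit ratios) make
every pair of wells correlate near 1 and the null is meaningless.
Z' = 1 - 3(sd_p + sd_n)/|mu_p - mu_n|, annotated against the screening
bands (> 0.3 acceptable, 0.5-1.0 desirable); identical control means give
a missing value.  All off-diagonal pairs are used (no subsampling).

## Numerical and design notes

* Coordinates are 0-based row-major pixel indices; masks are pixel-atomic.
* The ring-region sentence admits two readings; the default (outer border
  at 20 % of the edge-to-inner-border distance measured from the edge,
  i.e. shell 0.60 <= rho <= 0.92) yields a perinuclear ring of thickness
  comparable to the nucleus, the stated motivation.  The alternative is a
  configuration switch, never silently changed.
* The 2 % nuclear erosion is measured in equivalent radius (the
  radius/area/pixel convention is not documented upstream).
* Problem sizes in the test-suite and acceptance runs (e.g. 25-40 cells
  per well on 448-512 px demo fields, 2,000 cells per mixture) are chosen
  to make every statistical check well-powered at desk scale; the
  generator and all thresholds accept larger values unchanged.
* Proprietary upstream algorithms (the commercial analysis platform's
  segmentation, SER constants, classifier internals) are replaced by
  documented community-standard equivalents with the same contracts;
  numerical equality with the original outputs is not claimed, and the
  published screens' hit tables and Z' values — which require the
  deposited images — are out of scope.
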