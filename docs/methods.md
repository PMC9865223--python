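# Methods

## Model and assumptions

The toolkit treats vegetation mapping as hierarchical one-class-at-a-time
thresholding on engineered spectral features.  The core assumption is that
every target class has, at some (band, date) pair or pair-of-dates, a
contrast that separates it from the classes not yet identified, and that a
single scalar index built from that pair (difference, normalized complement,
or relative change) carries the contrast.  Classification is per pixel; no
spatial context, texture, or object segmentation is used, so fragmented
landscapes will show salt-and-pepper label noise by construction.

Reflectance is handled internally on the unitless [0, 1] scale.  Integer
digital-number inputs (0–10000 convention) are divided by a configurable
scale factor on read.  This keeps the index formulas' absolute constants
(the 1 in the MTM-NDQI numerator, the seasonal RE4 bounds 0.54/0.34 that
justify it) on their natural scale, while screening scores are *reported*
×10⁴ so their magnitudes sit on the familiar digital-number scale.

Grids are axis-aligned with 0-based (row, col) indices and pixel-centre
georeferencing; inputs must share a CRS (reprojection is out of scope).
Bands delivered at 20 m are upsampled to the 10 m grid by nearest-neighbour
interpolation, which for integer factors is exact block replication.

## Index development

Per-class statistics use the sample standard deviation (n−1 denominator).
A candidate feature band combination is scored by the sum, over a class
scope, of both operands' per-class standard deviations; the smallest sum
(most stable) wins, ties going to the earlier-listed candidate.  The class
scope is genuinely ambiguous in the source workflow — "most stable
inter-class difference" in the general flow, "most stable intra-class
variance" per index.  The default sums over the classes still to be
identified at that stage of the hierarchy; a `scope="target"` switch
restricts to the target class.  Neither option claims to reproduce the
published score magnitudes, whose exact scope is unstated; the published
*winners*, however, are reproduced by the selection rule on the published
scores themselves.

Candidate lists are explicit: the visual spectral analysis that proposes
candidates is expert judgement, not an algorithm.  `enumerate_combinations`
offers an exhaustive search over a stated band/phase subset as a clearly
flagged extension.

The separability check (`overlap_fraction`) is a formalisation of a
box-plot judgement: the fraction of pooled samples of two classes lying in
the intersection of their value ranges (min–max by default, IQR variant
available).  A pair overlapping above 0.25 is conventionally considered
poorly separable.

## Threshold calibration

Published rule thresholds are experiential and not printed, so thresholds
are calibrated: the candidate cut points are the midpoints of adjacent
distinct sorted pooled values, the direction points toward the target-class
training mean, and the cut minimising training misclassifications wins
(ties to the smallest threshold — fully deterministic).  This preserves the
knowledge-tree *structure* (feature order and one-class-per-rule semantics)
while making runs reproducible.  User-supplied expert thresholds can
override any rule.  Directions are derived, not hard-coded: the data decide
that Quercus takes the low MTM-NDQI side (its RE4 sum is largest) and scrub
grass the low MTM-DSI side.  The final rule is a two-sided split on MTM-RSI:
the high side is shaw, the low side falls through to Larix.

## The random-forest comparator

The ensemble is a comparator, not a contribution: scikit-learn's
`RandomForestClassifier` with 250 trees, ⌊√p⌋ candidate features per split,
and a fixed seed.  The module guarantees that contract (tree count, split
rule, seed determinism, column checking), nothing more.

## Accuracy statistics

The confusion matrix is oriented rows = classified, columns = ground truth;
PA divides the diagonal by the column (ground-truth) total and UA by the row
(classified) total.  This orientation is the one that reproduces every
published per-class figure from the published count matrix.  Full precision
is kept internally; reports round percentages and Kappa to two decimals.
One published figure is internally inconsistent at printed precision
(a PA of 80.57 where the counts give 58/72 = 80.56); comparisons against
published figures therefore allow one unit in the last printed place.

## The synthetic generator

Class means are a linear soil/green-canopy mixture driven by a per-class
greenness schedule over the six dates, with targeted adjustments in
RE2/RE3/NIR/RE4/SWIR-1 that encode the documented contrasts (see the
`simulate` module docstring for the full list).  Design choices:

* The five hard classes share one greenness schedule, so their red/NIR
  signal — and hence NDVI/RVI/DVI — is essentially identical; this is what
  makes the typical-index feature sets fail on them, mirroring the real
  system's motivation.  Absolute mean values are implementation choices
  inside the documented inequalities; no published reflectance curve is
  tabulated anywhere, so none is claimed.
* Within-class variation is independent Gaussian noise per (pixel, phase,
  band), clipped to [0, 1], sd 0.005 by default with a multiplier.  At that
  level the six rule-feature class gaps span roughly 7–15 noise standard
  deviations (so the calibrated tree is near-perfect but not trivially so),
  and ×10⁴-scaled screening sums land in the few-hundreds range typical of
  published screening tables.
* Plots are 3×3 pixels placed on a jittered grid of guarded cells, never
  overlapping; background pixels carry the bare-soil spectrum and label 0.
  Two presets mirror the study design: `survey` (270 plots, 2430 pixels)
  and `table_mirror` (70 plots whose per-class counts are one ninth of the
  published verification column totals, 630 pixels).
* There is no spatial autocorrelation beyond plot blocks, no topographic
  illumination, no clouds, and the noise is homoscedastic across bands.
  Consequently, passing tests show the *method logic* is correct and that
  the pipeline's ordering of feature sets is as documented; they do not
  show that real scenes reach any particular accuracy.

Splitting into train/verify (default 0.6) is stratified at plot level, not
pixel level, so the nine pixels of a plot never straddle the partition —
the conservative choice against spatial leakage within a plot.

## Numerical and degenerate-input choices

Division guards mask outputs (propagated as nodata) rather than raising, so
whole-raster computation survives isolated degenerate pixels: zero NIR for
RVI, zero NIR+RED for NDVI, zero operand sum for MTM-NDQI, zero October RE2
for MTM-RSI.  A pixel masked in any operand is masked in the output.  In
tree prediction, a pixel missing a value at a rule that must be consulted is
labelled `nodata`; rules already decided are unaffected.  Calibration
refuses only the fully degenerate case (target and rest a single identical
constant).

## Problem sizes

Default test and acceptance runs use scenes of 80–90 px squared with 28–270
plots (252–2430 labelled pixels), five seeds for the stochastic end-to-end
property, 250-tree forests, and 1,000 random matrices for the accuracy
oracle check.  These sizes keep full runs in the tens of seconds while
leaving the statistical margins (OA thresholds, feature-set orderings) far
from their pass boundaries.

## Known limitations

* Published experiential thresholds are unknown; the real study's map and
  its exact decision boundaries are not reproducible and not attempted.
* Whether published screening sums aggregate over the target class, the
  classes to identify, or all seven classes is unstated; both implemented
  scopes are reasonable, neither is verified against the printed magnitudes.
* TIFF georeferencing is minimal (pixel scale + tiepoint tags); CRS-aware
  tooling should wrap the I/O layer for production use.
* The verification design evaluates labelled plot pixels; the published
  count of 630 verification points is mirrored by the `table_mirror` preset
  rather than derived from the 2430-pixel survey, whose reduction rule is
  not documented.
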