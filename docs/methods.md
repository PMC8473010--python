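# Methods

## The measurement model

An approach force-distance curve over a supported bilayer has four
regimes: zero force above contact; a rising indentation branch; a
discontinuity at rupture, during which the tip traverses the membrane
(the z-extent of the discontinuity is the bilayer thickness, the force
at its onset the breakthrough force); and a steep repulsive wall on the
solid support. Rupture is bracketed by two kinks of opposite curvature:
a concave corner at onset (the slope of F stops rising) and a convex
corner at completion (the slope jumps up on the support). The analysis
treats kink detection, pairing, filtering, mapping and clustering as
separable stages, each independently testable.

## Kink detection

### Peak scan

`peakdet` is a single-pass alternating extremum scan: a running maximum
is confirmed as a peak once the signal falls a prominence `delta` below
it, then the scan looks for a minimum, and so on. Output maxima and
minima alternate and consecutive extrema differ by at least `delta`.
Extrema falling on the first or last sample are discarded: a kink needs
neighbours on both sides, and a monotone (rotated) segment would
otherwise contribute a spurious boundary "peak". Correctness is checked
in the test suite against an independently coded reference
(cumulative-extremum prefix scan) on random walks.

### Rotation

A soft kink — a slope decrease without a local maximum — becomes a local
maximum after rotating the curve in the (F, z) plane. With z in nm and
F in nN the indentation slope of a bilayer is of order 1 nN/nm, so the
degree-scale angle set {0, 4.5, 9, 13.5, 18}° spans the useful shear
range: a kink whose slope drops across tan φ is recovered at angle φ.

Two choices here deserve explanation:

* **Raw (nN, nm) coordinates by default.** Min-max normalisation of
  both axes to the unit square is tempting (it makes detection
  scale-free) but fails for force-volume ramps: with a 400 nm z-travel
  and a ~4 nm bilayer, the rotated signature of the rupture plateau in
  unit coordinates is thickness/z_range·sin φ ≈ 3·10⁻³ — the same size
  as the normalised force noise, so no prominence threshold can separate
  them. In raw coordinates the same signature is thickness·sin φ ≈
  0.3 nN at 4.5°, an order of magnitude above typical force noise.
  `DetectionConfig(coordinates="unit")` provides the normalised variant
  (useful when both axes have been pre-scaled), and in that mode
  detection is invariant to uniform rescaling of the raw units.
* **Rotation direction per curvature branch.** On the approach, z
  decreases along the sample order. For onsets (detected on F) the
  shear must tip the post-kink branch downward, for completions
  (detected on −F) the pre-kink branch upward; the two branches
  therefore use opposite rotation signs. The public `rotate_curve`
  follows the conventional matrix [[cos φ, sin φ], [−sin φ, cos φ]] on
  [F, z] rows; the detector applies it with the per-branch sign.

Detections from all angles are pooled (union over φ); a sample index
found at several angles keeps its smallest angle.

### Merging and pairing

Detections closer than `merge_threshold` (Euclidean in the detection
frame) are the same kink. Closeness is applied transitively —
connected groups of the "within threshold" relation are collapsed — and
each group keeps its smallest-angle member, the least-distorted
detection. This is idempotent and independent of input order.

Each onset kink is then paired with the first unused completion kink
strictly deeper in z; the pair's z-distance is the thickness. Unpaired
kinks are reported, not discarded silently.

### Defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `angles` | 0, 4.5, 9, 13.5, 18 | deg | covers slope drops down to tan 18° ≈ 0.32 nN/nm |
| `delta` | 0.2 | nN (rotated frame) | ~10× typical per-sample force noise (0.02 nN); below the smallest plateau signature the event filter accepts (1.5 nm·sin 18° ≈ 0.46 nN) |
| `merge_threshold` | 0.5 | mixed nN/nm | larger than inter-angle scatter of one kink, smaller than the 1.5 nm minimum kink separation of a valid event |
| `coordinates` | `"raw"` | — | see above |

In `"unit"` mode sensible values are `delta ≈ 0.05`,
`merge_threshold ≈ 0.02` (fractions of the unit square).

## Event filtering and ranking

Thresholds are closed intervals: force ≥ 0.5 nN, thickness in
[1.5, 9] nm by default — single bilayers on mica fall inside; noise
kinks (sub-threshold force) and stacked/long-range artefacts (thickness
outside the window) fall outside. Relaxing any bound never removes a
surviving event (monotonicity, property-tested). Among survivors the
event with the largest onset separation (farthest from the support) is
primary; others are secondary; more than two survivors sets a
`multiple` flag. The reported breakthrough force is the force at the
onset kink, i.e. at the start of the discontinuity.

## Maps

Missing cells (no surviving event of the requested rank) are stored as
an explicit flag with a NaN placeholder, never a sentinel value, and
rendered black. The multiset of numeric map cells always equals the
multiset of selected event values — maps never interpolate. Maps
round-trip through CSV (values + flags + metadata sidecar).

## Phase clustering

KMeans (k = 2, scikit-learn, 10 restarts, fixed seed) on z-scored
(force, thickness) — the two axes are incommensurate, and
standardisation makes the clustering scale-free. A thickness-only mode
exists because thickness-based clustering is common where the force
contrast is weak; the mode and seed are recorded in the summary. Only
curves with a surviving primary event enter the clustering. The
lower-mean-force cluster is Ld (ties are reported as degenerate rather
than broken arbitrarily). The max mismatch is max over Lo points of
(thickness − mean Ld thickness); the average mismatch
(mean Lo − mean Ld) is reported alongside for comparison with
image-based height mismatch, but is less informative when the
distributions overlap.

## Morphometry

Segmentation: Otsu threshold (or a fixed value), 8-connected
components, minimum area 4 px to suppress single-pixel noise; polarity
is a flag (AFM height: domains bright; dye-exclusion fluorescence:
domains dark). Perimeter uses the Crofton multi-direction intercept
estimator: boundary-pixel counting overestimates the perimeter of
rasterised smooth shapes and systematically deflates circularity
(a rasterised disc of radius 50 px measures ≈ 0.99 with Crofton).
Circularity = 4π·area/perimeter² is clipped to 1.0 with a flag when
discretisation pushes the raw value above 1. Height mismatch is
mean(Lo) − mean(Ld) over the mask, with a per-domain SD when at least
two domains exist. Note the estimators are tuned for smooth biological
domains: Crofton slightly *underestimates* the perimeter of polygonal
shapes (a rasterised square measures circularity ≈ 0.89, not π/4), so
cross-tool comparisons should use matching estimators.

## Synthetic data

`simulate_force_curve` renders the four-regime model piecewise linearly:
baseline, ramp at `indentation_stiffness` (default 1 nN/nm), a z-jump at
constant force spanning exactly `thickness` (the rupture is a plateau in
z rather than a force drop, because thickness is defined as the
z-length of the discontinuity — this makes the generator's truth
directly comparable to the kink-pair output), then a 10 nN/nm support
wall. Defaults: 400 nm z-travel, 2000 samples (≈ 0.2 nm spacing, far
below the 1.5 nm filter floor), contact at 15 nm, breakthrough 3 nN,
thickness 4 nm, Gaussian force noise SD 0.02 nN. The two grid samples
nearest the rupture corners are snapped onto the exact corner positions
so that noiseless recovery is exact rather than quantisation-limited.

`simulate_force_grid` draws per-cell (force, thickness) from per-phase
normal distributions — Ld 3.0 ± 0.3 nN / 2.2 ± 0.2 nm, Lo 6.0 ± 0.3 nN /
3.0 ± 0.2 nm, i.e. a sub-nm mean thickness mismatch, the regime typical
of PC/SM/cholesterol bilayers — over a disc layout (default: two
1.4 µm-radius Lo discs on a 5 µm field, Lo fraction ≈ ½, domain
diameters within the usual 0.5–3 µm range). Cell phase is decided by
disc membership of the cell centre. `simulate_domain_image` rasterises
analytic discs/ellipses (truth perimeters via Ramanujan's approximation)
into height images with an optional noise floor.

What the generators do **not** emulate: adhesion and snap-in, curve
drift and baseline tilt, elastic (Hertzian) contact curvature, stacked
bilayers, partial-cell phase mixing, spatially correlated instrument
noise, and tip convolution in images. Passing tests therefore
demonstrate the correctness of the detection/mapping logic at realistic
signal-to-noise, not robustness to every instrument artefact; curves
with strong adhesion or un-corrected baselines should be pre-processed
(as instrument export software does) before analysis.

All generators are deterministic given their seed (per-cell seeds are
spawned from the grid seed), and serialised output is byte-reproducible.

## Numerical and degenerate-input choices

* Unit auto-detection on load: magnitudes below 10⁻³ are taken as SI
  (metres/newtons) and scaled by 10⁹; idempotent on nm/nN data.
* Files holding extend + retract keep the block with z decreasing
  (configurable); ascending single-segment files are stored reversed so
  the approach convention (z descending) holds package-wide.
* Curves shorter than 3 samples yield an empty detection set, not an
  error; empty event lists yield all-missing maps.
* Statistics use the sample SD (ddof = 1); SD of a single value is NaN,
  flagged, never 0.
* Tie-breaks: merge groups with equal angles keep the smaller sample
  index; equal cluster mean forces raise (degenerate) rather than
  assigning phases arbitrarily.
* Problem sizes in the test-suite and acceptance runs (100 noisy curves,
  one to three 16 × 16 grids, 130² px images) are chosen to estimate
  each recovery statistic to well under its tolerance while keeping a
  full run in seconds on one CPU.
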