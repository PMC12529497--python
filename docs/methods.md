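# Methods

This note documents the models behind each measurement chain, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Hertz indentation

Model: spherical rigid indenter on an isotropic, incompressible
(ν = 0.5) elastic half-space, `F = (4√R/3) · E/(1−ν²) · d^{3/2}`.
Defaults mirror a millimetre-scale gel indentation experiment: R =
0.5 mm, maximal depth 200 µm (about 5% of a ~4 mm sample, inside the
small-indentation regime), indentation speed 15 µm/s (metadata only —
the model is elastic, not viscoelastic).

Estimator: the model is linear in E given `d^{3/2}`, so the weighted
projection `Ê = Σ F·x / Σ x²` with `x = (4√R/3)/(1−ν²)·d^{3/2}` is the
exact least-squares solution; its standard error comes from the residual
variance. Curves are assumed pre-zeroed (contact point at d = 0);
contact-point detection is explicitly out of scope. An optional
`depth_fraction` window restricts the fit range against thin-film
artifacts; on clean Hertzian data the estimate is window-invariant, which
the tests assert.

Two-level replicate aggregation (`summarize_samples`) averages repeats
within a sample before computing across-sample mean ± SD, matching the
usual repeated-indentation design.

Limitations: no adhesion (JKR/DMT), no finite-thickness correction, no
viscoelastic loading-rate dependence.

## Traction force microscopy

### Forward model and generator

The elastic substrate is a linear, incompressible half-space with
Young's modulus `E_gel` (defaults 30 kPa; 9 kPa is the typical soft
condition). Tractions are Gaussian patches; the default scene is a
single radially contractile patch (peak 300 Pa at radius 15 µm) centred
in a 256² px field at 0.4 µm/px — a single adherent cell's force
footprint. A contractile patch is force-balanced by symmetry, which
matters because the k = 0 (net force) component of the half-space
problem is unobservable: the Green's tensor diverges at k = 0 and both
forward and inverse transforms pin the DC term to zero. Directed patches
(net force ≠ 0) are supported for constructing balanced pairs but cannot
be recovered alone, by physics rather than by implementation.

Beads (200 nm fluorophores in the gel surface) are rendered as isotropic
Gaussian spots, σ = 2 px, density 0.02 beads/px² (≈ 20 beads per 32 px
interrogation window), amplitude 400 over a background of 100 with
additive Gaussian noise (σ = 5). Shot (Poisson) noise is deliberately
omitted so fixed seeds give bit-identical scenes. Deformed-image bead
positions use the continuous true displacement field interpolated
bilinearly at each bead — not the PIV grid — so PIV error is measurable
against an off-grid truth. Separate PRNG sub-streams drive geometry and
noise; changing the noise level does not reshuffle bead positions.

What the generator does not emulate: bead polydispersity and blinking,
focal drift, gel nonlinearity/viscoelasticity, out-of-plane
displacement, photobleaching. Recovery results on these scenes therefore
bound algorithmic error only, not all experimental error.

### PIV

Windowed cross-correlation, default 32 px windows at 50% overlap, single
pass. Two estimator details matter at subpixel displacement scales:

- the raw finite-window correlation is multiplied by the inverse of its
  triangular overlap taper (per-lag "unbiased" normalization). Without
  it the taper pulls peaks toward zero lag; with the broad correlation
  peaks produced by σ = 2 px beads this understated displacements by
  ~30%.
- the subpixel peak is located by a least-squares log-Gaussian surface
  fit on the 5×5 neighborhood of the integer peak, which averages down
  the pedestal of overlapping inter-bead correlations; the classical
  per-axis 3-point Gaussian fit is the fallback when the surface is not
  a well-formed peak. On the default scene the uniform-shift error is
  ≈ 0.01 px and the field RMS error ≈ 15% of the true RMS displacement.

Peak search is limited to ±window/2 lags; larger rigid motion belongs to
the alignment stage (phase correlation with Fourier upsampling, frames
shifted and cropped to the common overlap; shifts above 25% of the image
extent abort). Outliers are flagged by the normalized median test
against the 8-neighborhood (threshold 2, ε = 0.1 px), replaced by the
local median, and marked in `valid_mask`.

### FTTC

`t̂(k) = (ĜᵀĜ + λI)⁻¹ Ĝᵀ û(k)` per nonzero wavevector, with the
incompressible half-space Green's tensor; flagged/invalid nodes are
interpolated bilinearly before transforming (the FFT needs a complete
grid). λ is zeroth-order Tikhonov in (µm/Pa)² with default 3 × 10⁻⁸.
The default was set on the synthetic pilot suite by the discrepancy
principle — the largest λ whose forward-model residual stays at the PIV
noise floor; an L-curve scan helper (`lcurve_lambda`) is provided, but
the L-curve of these smooth patch fields has no stable corner, so it is
not used for the default. λ = 0 gives the exact adjoint inverse used by
the round-trip tests. Optional Hann windowing and power-of-two zero
padding are available for non-periodic experimental fields and default
off, keeping forward and inverse exact adjoints on the grid.

Coordinates: x = column index rightward, y = row index downward, nodes at
window centres; public outputs in µm and Pa. The scalar summary is the
spatial median of |t| (whole field, or nodes under a user-supplied cell
mask) per frame, then the arithmetic mean over frames.

## Migration

### Generator

Persistent random walks are sampled from the exact discrete-time law of
the 2-D Ornstein–Uhlenbeck velocity process: velocity and its integral
are jointly Gaussian per step, so the 10-min frame interval is a sampling
choice, not an integration step. Defaults: S = 0.4 µm/min stationary rms
speed, P = 20 min persistence, 10-min frames over 16 h (97 points per
cell), matching overnight nuclei-tracking acquisitions in the
0.1–0.6 µm/min speed range. The closure scenes seed 300 cells in a
1600 × 1600 µm arena (≈ 117 cells/mm², sub-confluent) rendered at
2 µm/px with Gaussian nuclei (σ = 3 px); the rendered field of view
extends 100 µm beyond the seeded region, as an imaging field would.
There are no walls (reflecting boundaries would break OU exactness), no
division, and no cell–cell exclusion.

### Estimators

Mean speed is the mean Euclidean step length divided by the frame
interval — deliberately the simple frame-to-frame estimator, which is
dt-dependent; comparisons must use a common frame interval (the
simulation oracle in the tests does). MSD is time-averaged over
overlapping windows, lags capped at 25% of track length to bound
estimator variance; an origin-anchored variant sits behind
``anchored=True`` for comparison.

Detection is Otsu thresholding with intensity-weighted centroids; an
optional `max_area` gate rejects merged/clumped nuclei, whose centroid
falls between the true cells (on the closure scenes these corrupted the
lag-1 MSD by ~14%). Linking is greedy mutual-nearest-neighbor with a
`max_step` gate (default 12 µm ≈ 3× the expected frame displacement), no
gap closing, minimum track length 3.

The Fürth fit profiles P on a log grid (the optimal S² is closed-form at
fixed P), refines the best grid cell with bounded scalar minimization,
and weights lags by 1/τ. `PRWModel.from_stats` drops lags supported by
fewer than 25% of the tracks: in fragmented tracking data the long-lag
tail averages only the self-selected tracks that survived without
encounters, a slower-than-average subsample that otherwise biases P low
by ~25%. Persistence estimates beyond 10× the longest fitted lag are
flagged `at_bound` (a ballistic-looking curve does not identify P).

## Morphometry

Preprocessing follows the percent-saturation contrast convention: 0.35%
of pixels are clipped, split equally between the histogram tails, then
intensities rescale to [0, 1]; the FA channel additionally gets a white
top-hat with a disk footprint (default radius 5 px; the FA-scene tests
use 8 px against the 14 px default spot length). Nuclei: Otsu two-class
threshold on a 256-bin histogram, hole filling, 8-connected labeling,
min-area 30 µm², and an explicit label-removal list standing in for
interactive manual editing so runs stay scriptable. Cells: seeded
watershed on the inverted cell-channel intensity restricted to its Otsu
foreground, one cell per nucleus, labels inherited from seeds. FAs:
Otsu within the cell footprint only, size window 0.1–30 µm², parent cell
by majority overlap.

Eccentricity comes from the second-central-moment equivalent ellipse
(√(1 − (minor/major)²)), the convention of standard profiling tools, so
synthetic ground truth (analytic ellipse eccentricity) and measurement
are commensurable; single-pixel objects define eccentricity 0. The FA
scene generator places non-overlapping anti-aliased ellipses (3×
supersampled coverage) inside an elliptical cell mask and errors out if
the requested count cannot be placed in 200 tries per object.

## Statistics

One-way fixed-effects ANOVA (scipy) across conditions; identical
constant groups are reported as F = 0, p = 1 rather than NaN. Mann–
Whitney U of each group against the control: exact enumeration when both
n ≤ 20, otherwise the normal approximation with tie and continuity
corrections. No multiple-comparison adjustment by default, matching the
each-group-vs-control reporting convention; Holm step-down is available
behind `adjust="holm"`. Significance stars default to
(10⁻⁵, 5·10⁻³, 10⁻², 5·10⁻²) → (****, ***, **, *): the top two tiers
follow the reporting convention adopted here, the rest are conventional;
the tier map is an argument, and star assignment is a pure function of p
and the tiers. Boxplot statistics use linear-interpolation quartiles and
1.5×IQR whiskers so plots are reproducible across implementations.

## Pipeline determinism and problem sizes

Every generator is a pure function of its spec including the seed
(NumPy `SeedSequence` sub-streams); `run_pipeline` writes no timestamps,
so identical config + seed reproduce every output byte. Problem sizes in
the test and acceptance runs: 100 random indentation geometries plus 100
noisy replicates; 20 random force-balanced patch fields for the
forward/inverse round trip; one 256² bead scene for the full TFM chain;
300 rendered + 3000 oracle cells for the migration closure; one 40-FA
scene for morphometry; 1000 null replicates (n = 30 per group) for test
calibration. These sizes keep the whole validation suite in the
~30-second range while leaving Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

- All validation is against the package's own forward models; agreement
  bounds algorithmic error, not instrument effects the generators do not
  emulate (drift, bleaching, out-of-plane motion, gel nonlinearity).
- Single-pass PIV only; strongly sheared displacement fields would
  benefit from multi-pass window deformation, which is out of scope.
- FTTC assumes an infinitely thick substrate; for gels thinner than a
  few correlation lengths of the traction pattern a finite-thickness
  Green's function would be required.
- The tracker neither closes gaps nor resolves merges; crowded fields
  fragment into shorter tracks, which the support-filtered Fürth fit
  tolerates but does not eliminate.
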