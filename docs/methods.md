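# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. It is the design record: everything here is
either implemented and tested in the code, or explicitly listed as a
limitation.

## Data model

A hyperspectral Raman image is a complete rectangular grid of pixels
(0-based, row-major, origin top-left, rendered y-down), each carrying one
spectrum on a shared strictly increasing wavenumber axis. The image is the
matrix **D** of shape (width·height, channels); a boolean mask marks
pixels retained after quality control, and an append-only history records
every processing stage with its parameters. Intensities are arbitrary
detector units throughout — only relative and normalized quantities are
interpreted, so no absolute intensity calibration is attempted.

Band-window intensity maps are per-pixel trapezoidal integrals over a
wavenumber window. The window edges are included by linear interpolation,
which makes the integral exactly additive over adjacent windows and
independent of whether the window bounds are grid points. No interior
baseline is subtracted inside the window; the maps summarize the data as
recorded at that stage.

## Phantom generator

The generator exists because single-grain Raman measurements of pollen are
generally not published as raw data. It renders a dried birch-like grain
on a weakly scattering slide with exact per-pixel ground truth
(concentrations, region labels, cosmic-spike positions), so every
downstream claim can be tested against truth rather than plausibility.

Geometry (defaults; all configurable through `PhantomSpec`):

- grid 40×40 px at 1 µm per pixel — matching typical mapping step sizes —
  with a grain radius of 15 µm (diameter 30 µm, inside the 20–35 µm range
  of birch pollen);
- concentric layers at radial fractions 0.55 (core), 0.75 (intine),
  1.0 (exine), plus three rim protrusions of pure sporopollenin at 120°
  spacing (radial bulge 25 %, angular profile cos⁶), reproducing the
  triangular outline of birch grains;
- four circular lipid bodies of radius 2 µm seeded uniformly inside the
  core — discrete droplets of the protein/lipid component, as such bodies
  appear in measured concentration maps.

Composition per region (area-fraction weights of unit-area templates):
substrate 0.30 background; exine annulus 0.85 sporopollenin + 0.15
intine; intine layer 0.65 intine + 0.20 protein/lipid + 0.15 starch; core
0.80 starch + 0.10 intine + 0.10 protein/lipid; lipid bodies 1.0
protein/lipid. The layer weights are design choices, not measurements:
the real layer thicknesses and concentration ratios of birch grains are
not quantified anywhere we could anchor to, so the weights are set to make
each region's dominant chemistry unambiguous while keeping realistic
cross-contamination between neighboring layers.

Spectral templates are sums of Lorentzian lines, FWHM 12 cm⁻¹ in the
fingerprint (≈2× the 6 cm⁻¹ spectral resolution of the instrument class
emulated) and 60 cm⁻¹ for the broad CH-stretch envelopes. Band positions
follow the standard assignments: sporopollenin 447, 546, 979, 1169, 1440,
1557 and 1604 cm⁻¹ (1604 strongest); starch 481, 861, 937, 1084, 1125,
1263, 1338, 1462 cm⁻¹ (481 strongest); protein/lipid 864, 960, 1006,
1077, 1263, 1302, 1447, 1657 cm⁻¹ plus CH maximum at 2925 cm⁻¹; intine
1004, 1084, 1450, 1650 cm⁻¹. Relative amplitudes are design choices: the
assignments fix positions and which band is strongest, not intensities.
Every organic template carries a dominant CH-stretch envelope near
2900 cm⁻¹, as real biological Raman spectra do — this shared envelope is
what makes a correlation-based quality control with a 0.75 threshold
meaningful. Sporopollenin's CH signal is present but weaker (amplitude
0.5 at 2940 plus 0.2 aromatic at 3065), so protrusions appear dimmed, not
dark, in CH maps. The substrate is a single weak broad Gaussian
(1055 cm⁻¹, FWHM 250 cm⁻¹). All templates are normalized to unit
trapezoidal area over 400–3100 cm⁻¹, so true concentrations are area
fractions.

Forward model per pixel: signal = C·Sᵀ, plus a per-pixel convex quadratic
baseline with random vertex and curvature scaled to 20 % of the pixel's
peak signal (a fluorescence-like background that a lower-convex-hull
correction can remove), plus additive Gaussian noise of sd 1e-4 in
detector units (peak signal-to-noise ≈ 60–140 on organic pixels — good
but not exceptional for a confocal system at ~0.5 s per spectrum), with
an optional signal-proportional term (default off) and clipping at zero
(configurable; disable the floor when measuring noise statistics).
Cosmic spikes are single-channel positive outliers with Poisson counts
(mean 0.05 per spectrum) and amplitudes 20–100× the spectrum median; all
injected positions are recorded. The default axis is 400–3100 cm⁻¹ at
2 cm⁻¹ spacing (1351 channels).

What the phantom does **not** emulate: optical effects (confocal depth
response, scattering, polarization), harmomegathic folding of dried
grains, within-layer concentration gradients, correlated (pink/readout)
noise, detector etaloning, and wavenumber miscalibration beyond what the
calibration stage is given to correct. Passing tests therefore show the
pipeline is correct under a clean layered-mixture model with realistic
baselines, noise and spikes — not that it is robust to every instrument
artifact of real measurements.

## Preprocessing chain

Stages run in a fixed order: calibrate → interpolate → rubberband →
despike → normalize → quality filter → smooth, each recorded in the image
history. After smoothing, the data are renormalized once so the final
output keeps unit area — smoothing slightly perturbs integrals, and the
unit-area contract is what makes MCR concentrations interpretable.

- **Calibration**: least-squares polynomial (degree 1 by default; single
  grating dispersion is near-affine) mapping measured reference-peak
  positions (e.g., a paracetamol table, supplied by the user — no peak
  values are hard-coded) onto their reference values; applied to the
  axis, residuals logged. Skipped when no reference table is configured.
- **Interpolation**: per-pixel linear interpolation onto the common
  target axis (default 400–3100 cm⁻¹, 2 cm⁻¹ step); extrapolation is an
  error.
- **Rubberband baseline**: the baseline is the piecewise-linear
  interpolant through the lower convex hull of (ν, intensity), endpoints
  included (Qhull, with a monotone-chain fallback for collinear input).
  Corrected = input − baseline is ≥ 0 everywhere and exactly zero at hull
  vertices; the decomposition is complementary to machine precision. A
  consequence worth knowing: the hull chord also removes the smooth
  pedestal formed by overlapping Lorentzian tails, so corrected spectra
  are systematically "sharper" than raw band models. The endmember tests
  therefore compare recovered spectra against templates passed through
  the same correction.
- **Despiking**: per spectrum, residuals against a running median
  (window 5) are scored by robust z (1.4826·MAD); channels with residual
  > zmax·scale are replaced by linear interpolation between the nearest
  clean neighbors, and every event is reported (pixel, channel, original,
  replacement). Default zmax = 25: at 2 cm⁻¹ sampling the tops of
  12 cm⁻¹-wide bands genuinely reach robust-z ≈ 10–17 against a window-5
  median, while ≥20×-median cosmic events sit above z ≈ 35, so the
  threshold is placed between the two populations (z = 8-style defaults
  flag thousands of band tops on this sampling). The scale is floored at
  0.1 % of the spectrum range so noiseless smooth spectra (MAD = 0 on
  monotone stretches) are never flagged. Only positive residuals are
  flagged — cosmic events are positive. A spectrum whose channels would
  all be flagged is masked out instead.
- **Area normalization**: each retained spectrum is scaled to unit
  trapezoidal area over 400–3100 cm⁻¹; non-positive integrals mask the
  pixel with a warning. The operation is idempotent and scale-invariant.
- **Quality filter** (two stages, mask-only — nothing is deleted):
  (1) foreground candidates are pixels whose CH-stretch band integral
  (2800–3010 cm⁻¹) exceeds an automatic two-class (Otsu) threshold; the
  split must show real contrast (candidate mean > 3× rest mean), else
  "no foreground" — an all-substrate image fails here rather than
  returning a noise-driven split. (2) candidates whose Pearson
  correlation with the candidate mean spectrum falls below the threshold
  (default 0.75) are dropped, and the test is repeated once against the
  refined mean. The reference is the data's own mean — self-contained,
  no external spectral library. Near the threshold this stage trims the
  most atypical grain pixels (e.g., pure-sporopollenin protrusion tips),
  which is the intended outlier behavior of a correlation QC.
- **Savitzky–Golay smoothing**: order 2, window 9, per spectrum; edges by
  polynomial fit on the truncated window. Order-2 exactness on quadratics
  and the coefficient-sum variance reduction are asserted in tests.

## Clustering

Pixels from one or many images (sharing one axis) are pooled and
clustered with the Pearson dissimilarity d = 1 − r — invariant to
per-spectrum affine intensity transforms — and Ward linkage applied to
these dissimilarities via the Lance–Williams recursion on squared values
(the Ward.D2 convention common in chemometric toolchains; 1 − r is not
Euclidean, which is acknowledged and standard practice). Distances are
computed over the full preprocessed axis. Merge heights are
non-decreasing; tie-breaking follows the deterministic nearest-neighbor-
chain order of the linkage implementation. Cutting at k groups yields
labels canonicalized by decreasing cluster size, making output
independent of input pixel order. Cluster means are plain arithmetic
means of member spectra. k = 5 is the default (five clusters describe the
grain layers well; three already separate exine/intine/interior). Above
`max_exact_n` pooled pixels (default 20 000) a seeded random subsample is
clustered exactly and remaining pixels are assigned to the nearest
cluster mean by Pearson dissimilarity; the result is flagged accordingly.
The rendering palette fixes clusters 1–5 to dark blue, light blue,
purple, orange, red.

## MCR-ALS

Given unit-area data rows and k initial spectra (default: HCA cluster
means clipped at zero), each cycle solves every pixel's concentrations
given S, then every component spectrum given C — both as exact
non-negative least-squares subproblems — so the residual sum of squares
is non-increasing by construction and asserted at every iteration (with
an absolute slack of 1e-12 of the total sum of squares for
floating-point noise at near-perfect fits). After each cycle the rows of
S are renormalized to unit trapezoidal area over 400–3100 cm⁻¹ and the
scales absorbed into C: this pins MCR's scale indeterminacy, and with
unit-area data makes the per-pixel concentration sum ≈ 1 a fit
diagnostic (|Σc − 1| ≲ 3× the lack-of-fit fraction for well-fit pixels).
Iteration stops when the relative change of the residual SS is below
1e-8 or after 500 cycles; convergence and iteration counts are reported
along with lack of fit (100·√(SS_res/SS_tot)) and explained variance.
Components are reported in the order of the initial spectra (matched by
maximal correlation). A component collapsing to zero is frozen at its
previous shape with a warning and qualifies the convergence flag. No
closure, unimodality or selectivity constraints are applied — only
non-negativity on both factors.

The inner solver for the many-right-hand-side NNLS subproblems is an
exhaustive active-set search over the 2ᵏ candidate supports on the normal
equations, vectorized across all right-hand sides — exact for the small
component counts used here (k ≤ 14 guarded; k = 5 typical) and orders of
magnitude faster than looping a single-RHS solver over thousands of
pixels and channels. The public single-vector `nnls` uses the
Lawson–Hanson algorithm and satisfies the KKT conditions to 1e-8.

When the quality filter has removed the substrate, only four of the five
built-in templates have support in the retained pixels; with k = 5 the
fifth component is then free to absorb residual structure (per-pixel
hull-correction differences, smoothing residue). This mirrors practice —
more components are fitted than are chemically interpreted — and the
recovery experiments that need all five templates identifiable therefore
run the chain with the quality filter disabled so substrate pixels stay
in.

## Orchestration and reproducibility

`run_pipeline` executes simulate (optional) → preprocess → HCA → MCR →
report from one config, writing every artifact with a SHA-256 manifest.
All randomness (phantom geometry, noise, spikes, subsampling) flows from
explicit seeds through seeded generators; identical config and seed give
bit-identical artifacts, including PNG figures (rendered with fixed
metadata). Every figure has a CSV twin; no number exists only in an
image.

## Problem sizes used in the test suite

The validation experiments run at the generator's default scale: single
images of 40×40 px × 1351 channels (~700 retained grain pixels), and
joint five-image sets (8 000 pooled pixels) clustered through the seeded
subsampling path at 3 000 exactly clustered pixels. Recovery statistics
(adjusted Rand index of region labels, cosine similarity of matched
endmembers) are aggregated over 10 generator seeds. Solver oracles
(active-set enumeration, brute-force hull, brute-force Ward
agglomeration, exhaustive assignment) run on small instances (≤ 8
points/variables) where exhaustive search is exact.

## Known limitations

- The rubberband correction distorts broad features that are partly
  convex from below (it removes whatever the hull chord can reach); this
  is intrinsic to the method, shared with its use in practice, and the
  reason endmember comparisons use corrected templates.
- Ward on 1 − r dissimilarities is a pragmatic chemometric convention,
  not a variance decomposition in a metric space.
- MCR-ALS finds a local optimum dependent on initialization; HCA-mean
  initialization is the documented, tested default. Rotational-ambiguity
  bounds are out of scope.
- The correlation QC references the image's own candidate mean; on
  images containing several chemically unrelated objects the reference
  would blur. The foreground detector requires CH-band contrast between
  grain and background and reports "no foreground" when there is none.
- The phantom's composition weights are plausible, not measured;
  conclusions about real grains require real data through the same
  pipeline.
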