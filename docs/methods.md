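# Methods

This note documents the models, numerical choices and limitations behind
`cartiqmap`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic phantom

The phantom emulates the mid-sagittal cross-section of a convex
osteochondral sample. The articular surface is a circular arc of constant
curvature (default 4.4/m, a typical femoral-condyle value; 0 gives a flat
slab) and the osteochondral junction is the concentric arc one cartilage
thickness deeper — constant curvature is adequate at this scale, where
the surface height varies by ≈ 0.12 mm over a 15 mm width
(sagitta ≈ w²κ/8). Defaults: width 15 mm, thickness 2.5 mm (samples of
this kind run 2–3 mm), isotropic pixels of 0.1 mm, giving ≈ 3 750 masked
pixels. Pixel membership is decided radially at pixel centres, so the
mask is exactly the set of centres between the two arcs.

Ground-truth relaxation maps are affine, strictly increasing functions of
the local fluid fraction, normalized by the composition model's global FF
range and spanning physiologic magnitudes: T1 550–750 ms, T1ρ 40–90 ms,
T2\* 15–40 ms. These links are deliberately synthetic scaffolding — the
true composition–relaxation relationship is the open scientific question,
not something the phantom asserts. Their only purposes are (a) known
ground truth for fit-closure tests and (b) a known monotone sign
structure (positive in FF and fiber angle, negative in CO/PG) that the
end-to-end statistics must recover.

Signals follow the sequence equations exactly; inversion-recovery signals
are magnitudes, as clinical reconstruction discards polarity. Noise is
Rician — magnitude of a complex Gaussian perturbation — because that is
the noise law of magnitude MRI and a Gaussian substitute would understate
noise-floor effects at low signal. The scale is σ = A_max/SNR with
SNR = 50 by default; SNR = ∞ reproduces the noiseless forward model bit
for bit. The phantom's noise floor parameter B defaults to 0; nonzero B
is exercised in dedicated fitting tests. All randomness flows from one
seeded `numpy` generator.

## Depth, zones, regions

Per-pixel normalized depth is `z = d_surf/(d_surf + d_bone)` with
Euclidean distances to the nearest point of each bounding curve. This is
rotation invariant and well defined on curved samples, where image
columns are not aligned with tissue depth. Distances are computed with a
k-d tree over curves densely resampled at 8 points per polyline segment;
a column-wise alternative (`method="column"`) is available for flat
slabs, where the two definitions coincide.

Zones use half-open intervals — SZ `[0, 0.15)`, TZ `[0.15, 0.65)`,
DZ `[0.65, 1]` — so boundary pixels go to the deeper zone; some
convention is required because the percent ranges are quoted with shared
endpoints. The central region is a 6 mm band (rounded to whole columns)
centred on the mask's centroid column; the anchor is a package choice, as
is taking the remainder as the peripheral region. Rectangular element
grids (configurable size) pool per-pixel values by plain means and are
exported for model fidelity; statistics default to per-pixel pairing.

## Composition and fiber model

The three volume-fraction profiles are continuous piecewise-linear
functions of depth with knots at 0, 0.15, 0.65 and 1. Calibration fixes
each profile's zonal means to the reference targets: for a linear piece
the zone mean is the average of its endpoint values, so the three mean
constraints leave exactly one free interior knot value per constituent,
which is set to the midpoint of its feasibility interval under
monotonicity (FF non-increasing, CO non-decreasing). PG is stored as the
conservation remainder `1 − FF − CO`, which makes the sum constraint an
identity at every depth rather than a tolerance. Piecewise-linear rather
than higher-order pieces is a deliberate simplification: the zonal means
are the only numeric calibration data available, and extra curvature
would be invented, not inferred.

The transitional-zone targets carry a small reconciliation: the reference
zonal means sum to 99 % there (70 + 9 + 20) while conservation requires
100 %, so the missing percent is distributed equally (+1/3 pp per
constituent, each staying within 0.34 pp of its reference). The
superficial and deep rows sum to 100 % and are used as printed.

The mean fiber angle is 90° (surface-parallel fibers, measured from the
local surface normal) for z < 0.15, 0° (bone-perpendicular) for z ≥ 0.65
and linear in between — continuous with Lipschitz constant 180°/unit
depth. Under uniform depth sampling the zonal means are exactly 90/45/0°.
The reported transitional-zone SD of such a ramp is ≈ 26° for uniform
sampling; pixel-weighting on curved geometries changes it, so SDs are
summarized but not asserted. Fiber dispersion uses n = 8 families at
equiangular offsets spanning a 90° fan (a package choice; the fan width
is not constrained by the calibration data) — symmetric, so the circular
mean equals the mean angle identically. The families are exported for
model fidelity but do not enter the correlation analysis, which uses the
mean angle only.

## Relaxometry

Mono-exponential fits minimize `Σ(s − [A·e^{−t/τ} + B])²` by
trust-region-reflective least squares; `B` is optional and off by
default — with a 5-point spin-lock series a third parameter is poorly
identified, and after the 60 ms echo cutoff the T2\* train has little
floor leverage. The flag `fit_noise_floor` switches it on. Inversion
recovery minimizes against the magnitude model; a grid of 10 log-spaced
T1 seeds is scored in closed form (the optimal A for fixed T1 is a linear
projection) and full optimization runs from the best two seeds, which
escapes the polarity fold at a fraction of the cost of 10 full fits.

Initialization: A₀ = max signal; τ₀ from log-linear regression of the
offset signal; B₀ = min signal when fitted. Tolerances are
xtol 1e−12/ftol 1e−12/gtol 1e−10. The time constant is capped at 10× the
longest acquisition time; a fit at the cap, an optimizer failure or an
undefined R² is flagged `converged=False`, never silently imputed, and a
constant signal yields an undefined (NaN) adjusted R² rather than an
error. QC applies the adjusted R² (the deflated-for-parameters variant)
with threshold 0.95; on noiseless phantoms every pixel passes and the
maps equal ground truth to machine precision, which the suite asserts at
the much looser 0.1 % to leave headroom across platforms.

Echo filtering keeps TE strictly below 60 ms — the default train
3.9 + n·6.9 ms (n = 0–14) retains nine echoes — and requires at least
three survivors.

## Statistics

Spearman's ρ_s is the Pearson correlation of midranks (tie-corrected).
Two-sided p-values use the t-approximation except for n ≤ 8, where an
exhaustive permutation distribution is computed; pixel-level analyses are
far above that size, so the exact branch mainly serves verification.
Significance stars follow the three-tier 0.05/0.01/0.001 scheme. Pixels
failing fit QC are excluded from all statistics. Pixel pooling across the
sample is the default pairing; element-mean pooling is available.

Curve families: `a·exp(b·φ) + c` for fractions and `a·sin(b·θ) + c` for
the angle (θ in radians internally), fitted by least squares with
multi-start over the sign and scale of `b`; the sinusoid is canonicalized
to a ≥ 0 since (a, b) → (−a, −b) leaves it invariant. "Best fit" is
implemented as SSE minimization (equivalently R² maximization).
Degenerate (constant) responses are flagged, not fitted.

Group comparisons are two-sided and nonparametric: Mann–Whitney U for the
two regions, Kruskal–Wallis for the three zones with Dunn's post-hoc
z-tests (mean-rank differences with tie correction) run only when the
omnibus p < 0.05. Dunn p-values are Bonferroni-adjusted across the three
zone pairs by default (Holm or no adjustment are selectable); Bonferroni
is the conventional companion when no adjustment is otherwise specified.
No multiplicity control is applied across the 24-cell correlation table
itself.

## Problem sizes and determinism

The default end-to-end run (150×~27-pixel phantom, three sequences,
~11 000 pixel fits) completes in well under a minute on one CPU; the
test suite uses the same default phantom for closure and sign-structure
checks and a reduced 40×9 phantom for orchestration tests. Monte-Carlo
noise checks use 100–300 replicate pixels per sequence at SNR 50. A run
is reproducible byte for byte from its YAML config and root seed.

## Limitations

- The phantom is 2-D and artifact-free: no B0/B1 inhomogeneity,
  susceptibility effects, partial-volume mixing at interfaces, bone or
  marrow signal, and no inter-sample biological variability. Passing
  tests demonstrate correctness of the computational pipeline, not
  biological validity of any composition–relaxation link.
- The composition profiles are calibrated to zonal means only; their
  within-zone shape (and hence any statistic sensitive to it, such as
  zonal SDs) is a modelling convention.
- Correlations pool pixels within a sample; no mixed-effects treatment of
  sample-level clustering is attempted.
- Segmentation (mask and bounding curves) is an input, not computed;
  cartilage outlining from morphological images is out of scope.
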