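# Methods

This document records the models implemented in `relpatlak`, the default
parameter choices with units, and the reasoning behind the numerical
decisions. Units are fixed throughout the package: time in minutes,
activity concentration in kBq/mL, rate constants in 1/min (K1 in
mL/min/cm³). All simulated activities are decay-corrected by construction.

## Kinetic model

Tissue kinetics follow the irreversible two-tissue compartment model

    dC1/dt = K1·Cp − (k2 + k3)·C1,      dC2/dt = k3·C1,

with C_T = C1 + C2 and measured voxel activity
C_PET = (1 − vb)·C_T + vb·Cp. The net influx rate is
Ki = K1·k3/(k2 + k3); the `vb` term scales the *measured* late-time Patlak
slope by (1 − vb), which is why ground-truth recovery checks use vb = 0
parameter variants.

The solver advances C1 with an exact exponential integrator for
piecewise-linear Cp on a 1-second grid (`CURVE_STEP = 1/60 min`), evaluated
as an IIR recursion via `scipy.signal.lfilter`; C2 is the cumulative
trapezoid of k3·C1. One second keeps whole-second frame boundaries on grid
nodes and puts the solver's error well below 0.5% of the curve maximum
(verified against `solve_ivp` at rtol 1e-9 in the tests). Frame values are
time-averages of the continuous solution over each frame interval, not
point samples, mirroring how a scanner integrates counts.

## Input function

The parametric input is the Feng model

    Cp(t) = (A1·t − A2 − A3)·e^{λ1 t} + A2·e^{λ2 t} + A3·e^{λ3 t},

with defaults A1 = 851.1225 kBq/mL/min, A2 = 21.8798, A3 = 20.8113 kBq/mL,
λ1 = −4.133859, λ2 = −0.1191, λ3 = −0.0104728 /min: a sharp bolus peaking
near 0.3–0.6 min at ~103 kBq/mL with a slow terminal clearance, the classic
FDG shape. Sampled inputs (image-derived or tabulated) interpolate linearly
and extrapolate beyond the last sample with a mono-exponential fitted to
the final samples.

Integrals are computed as differences of an antiderivative F(t) —
composite Simpson with step ≤ 0.05 min for the parametric form, exact
piecewise-linear integration plus the analytic tail for sampled inputs —
so interval additivity ∫ₐᶜ = ∫ₐᵇ + ∫ᵦᶜ holds to machine precision. The
0.05-min step is an order of magnitude below the bolus width; the residual
quadrature error is ~1e-5 relative near the peak and far smaller at late
times, negligible against every tolerance in use.

## Patlak estimation

Frames enter a fit iff they start at or after t* (default 40 min), so the
regression uses acquired data only. The abscissa is ∫Cp/Cp at the frame
mid-time, from 0 (standard) or from t* (relative). Voxelwise fitting is a
single closed-form least-squares pass over all voxels sharing the global
abscissa; voxels with non-finite estimates are masked out and counted. The
default voxel mask keeps voxels whose last-frame activity exceeds 1% of
its maximum, excluding air where the Cp-normalized ordinate is meaningless.

`suvr_image` reads the tissue value at t* by linear interpolation between
frame mid-times (extrapolating from the first two frames when t* precedes
the first mid-time, as it does for the 4×5-min schedule whose first
mid-time is 42.5 min). Nearest-frame sampling is available, but it
substitutes C_T(42.5)/Cp(42.5) for C_T(40)/Cp(40), which biases the
b′ = SUVr identity by ~5% on the default phantom; interpolation keeps the
identity regression slope within 0.1% of 1, so it is the default.

The global scale α is estimated as the OLS slope of Ki′ on Ki over the
shared mask. With a mono-exponential input tail Cp(t) = c·e^{λt} beyond t*,
α has the closed form 1 + λ·F(t*)/Cp(t*) and the standard and relative
abscissas are exactly affine, making per-voxel Ki′ = α·Ki an identity;
tests exploit this (Feng with A2 = 0) for machine-precision oracles. For
multi-exponential tails the affinity — hence per-organ α constancy — holds
to ~1e-5 over the 20-min window.

## Phantom and noise model

The phantom paints ellipsoidal organs (torso muscle, brain gray matter,
lungs, liver, spleen, spinal bone marrow, myocardium, an aortic blood pool)
plus up to three spherical lesions (lung, liver, pelvis) in fractional grid
coordinates, so any grid size yields the same anatomy. Blood-pool voxels
carry the frame-averaged Cp itself, which makes the image-derived input
exact on noise-free data. Defaults: 48×48×96 voxels at 4 mm — large enough
that every organ has a usable ROI, small enough for second-scale noise-free
simulation. Rate constants are typical FDG values (e.g. liver
K1 = 0.864, k2 = 0.981, k3 = 0.005, vb = 0.15 → Ki ≈ 0.0044; the hottest
lesion K1 = 0.3, k2 = 0.6, k3 = 0.15 → Ki = 0.06). This is a kinetic
phantom, not an anatomical one: no partial volume, scatter, attenuation or
motion; organs are internally homogeneous.

Noise is additive Gaussian per frame with SD =
noise_scale · sqrt(mean frame activity / frame duration): the count-rate
and duration dependence reconstruction noise exhibits, without modelling a
specific reconstruction. Negative values are retained so fits stay
unbiased. The packaged default `noise_scale = 1.0` was set a priori so the
non-denoised 20-min Ki′ map is distinctly noisy (liver SD/mean ≈ 0.7,
comfortably above the 0.3 regime the denoising study targets).

Two schedules are provided: a 29-frame 1-hour protocol (6×10 s, 2×30 s,
6×60 s, 5×120 s, 4×180 s, 6×300 s) and the late short-scan schedule of 4
contiguous 5-min frames over [40, 60] min.

## Deep-kernel denoising

A denoised volume is x ↦ K·x with K a row-stochastic kernel over the k=200
feature-nearest neighbors inside a 9×9×9 spatial window. Features are the
nz = 4 composite late frames, z-scored per composite. The conventional
kernel uses Gaussian weights (σ = 1 in per-component z-score units) on raw
features. The deep kernel passes features through a small residual map
f(v) = v + tanh(v·W1 + b1)·W2 + b2 (hidden width 16) and trains θ to
minimize the self-supervised objective Σₘ ‖z_a − K(θ)·zₘ‖², with the mean
image z_a as label — each noisy frame is averaged toward the common clean
structure. W2 is initialized to zero, so training starts from exactly the
conventional kernel and can only improve the objective; the best-objective
parameters seen during training are kept. Optimization is Adam (lr 1e-3,
300 iterations, 4096-row minibatches) with analytically derived gradients
through the softmax weights and the feature map, implemented in NumPy.
Neighbor indices are found once from the raw z-scored features and stay
frozen, so training reweights a fixed topology. Everything is seeded and
single-threaded deterministic.

Applied to the default-noise phantom, the deep kernel lowers the
self-supervised objective ~12% below the conventional kernel and reduces
liver Ki′ SD/mean by ~63% while shifting lesion mean Ki′ by under 2%.

## Cohort study and calibration

`run_cohort_study` simulates 12 healthy + 10 patient subjects on a reduced
24×24×48 grid at noise_scale 0.3, each with an individually perturbed Feng
input (bolus amplitude uniform ×0.3–2.5, bolus width ±10%, overall level
log-normal σ=0.15, intermediate and terminal clearance ±5%/±2%) and ±5%
jittered organ kinetics. The healthy-cohort mean α calibrates patient Ki′
maps onto the Ki scale; agreement against each subject's own standard
Patlak Ki over all patient lesions is summarized with Bland–Altman
statistics. A population-based input function (PIF) comparator is built by
normalizing each healthy input by its mean over the [t*, end] anchor
window — the only blood data a short scan has — averaging pointwise, and
rescaling to a subject's measured late-window blood-pool mean.

A caveat on the PIF comparison: with this late-window anchoring, the
PIF-based error and the calibrated-RP error are first-order equivalent
under bolus-shape perturbation, so their limits of agreement differ by
only ~0.1% relative (PIF slightly wider) in the bolus-only experiment,
while terminal-clearance variability actually favors the PIF. Orderings
between the two methods at this scale should not be over-interpreted; the
decisive practical difference remains that the RP method needs no
population model at all.

## Problem sizes and budgets

Defaults are sized for a single CPU: noise-free default-grid simulation and
voxelwise fits run in well under a second; the full denoising pipeline
(k-NN search plus 300 training iterations on ~78k voxels) takes on the
order of 1–2 minutes; the 22-subject cohort study a few seconds. The test
suite completes in a few minutes.

## Limitations

- The noise model is Gaussian and spatially white; no reconstruction
  correlations, resolution modelling or partial-volume effects.
- Organ TACs are homogeneous within an organ; kernel denoising is easier
  here than on real anatomy, so denoising percentages are upper-end.
- The equilibrium assumption (t* = 40 min) is taken as given; no t*
  estimation is provided.
- SUV surrogates are activity concentrations; body-weight/dose
  normalization enters only as an optional scalar.
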