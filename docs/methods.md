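# Methods

This note records the models, estimators, parameter choices and known
limitations behind `flockmetrics`. Everything quantitative stated here is
computed by the test suite or the `analysis/` drivers; nothing is quoted
from external data.

## Synthetic monolayer model

Cells are overdamped soft disks with a heading degree of freedom in a
periodic square box:

    dr_i/dt = v0 n(θ_i) + Σ_j F_rep(r_ij) + Σ_b F_bond(r_ib)
    dθ_i/dt = J sin(Θ_i − θ_i) + √(2 D_r) ξ_i(t)

with n(θ) = (cos θ, sin θ); F_rep a linear repulsion of stiffness k_rep
active below the contact distance 2a; Θ_i the circular mean heading of
cells within the alignment radius (self included); and, when k_bond > 0,
harmonic springs to the initial periodic-Delaunay neighbors at their
initial rest lengths. Alignment is implemented as torque relaxation
toward the local mean heading (a continuous-time Vicsek rule) rather than
velocity averaging, so the dynamics stay well defined at contact; with
k_rep = k_bond = 0 the model reduces to continuous-time Vicsek, and the
test suite verifies that the stationary order decreases monotonically
with rotational noise in that limit.

Units are µm and hours throughout. Positions are sampled every frame
interval (default 5 min); the integrator step is snapped to an integer
divisor of the frame interval so frame times are exact. Wrapped and
unwrapped coordinates are both stored: wrapped positions feed density and
neighbor assignment (minimum image), unwrapped ones make per-track
displacement statistics correct across the periodic boundary. A single
master seed is split into sub-streams (initialisation, rotational noise,
rendering) so that enabling rendering never perturbs the trajectories;
identical configs and seeds reproduce bit-identical tables.

### Regime presets

Shared geometry: 400 cells of radius a = 10 µm at packing fraction 0.85
(box ≈ 384 µm), alignment radius 3a, 12 h at 5-min frames — a deliberately
reduced but dynamically equivalent version of a 48-h live-imaging run,
chosen so a full 20-seed, four-regime closure study runs in minutes on one
CPU. Presets (v0 µm/h, J 1/h, D_r rad²/h, k_bond 1/h):

| regime            | v0  | J | D_r | k_bond | character |
|-------------------|-----|---|-----|--------|-----------|
| jammed_solid      | 0.5 | 1 | 0.5 | 0      | arrested  |
| disordered_fluid  | 30  | 0 | 3   | 0      | fast, uncoordinated |
| flocking_fluid    | 25  | 8 | 0.6 | 0      | fast, aligned, rearranging |
| flocking_solid    | 25  | 8 | 0.6 | 20     | fast, aligned, neighbor-preserving |

Speeds sit in the 3–30 µm/h range typical of epithelial monolayers; the
disordered preset uses the top of that range so its window-averaged V_RMS
clears the jammed threshold with margin. The flocking presets draw the
initial headings from a von Mises distribution (κ = 1.5 around a
seed-dependent direction): with fully symmetric initial conditions,
counter-propagating domains can outlive a 12-h run for some seeds — a
finite-box coarsening artifact, not a property of the regime the preset
is meant to produce. The bonded preset integrates with dt = 0.005 h
because a node coupled to ~6 springs of stiffness 20/h is otherwise at
the explicit-Euler stability edge.

The packing fraction 0.85 is above the soft-disk jamming point, so even
passive configurations creep slowly; relaxation sanity tests therefore
use a sub-jamming density (φ ≈ 0.7) where forces can balance exactly.

### Rendering and assay generators

Nuclei movies are rendered as isotropic Gaussian blobs (default σ = 3 px,
16-bit) with Poisson shot noise and Gaussian read noise. The FRAP
generator produces a disc-bleach movie whose in-disc mean follows
bg + (pre − bg)·[(1 − d) + d·f·(1 − e^{−kt})]·e^{−λt} (depth d, mobile
fraction f, recovery rate k, acquisition photobleaching λ), together with
the ground-truth record. The wetting generator produces monotone
(linear or exponential) area series with median-preserving lognormal
noise.

## PIV

Single-pass zero-normalized cross-correlation per interrogation window
(default 50 µm, 50% overlap — about five cells per window), FFT-based
with a three-point Gaussian subpixel fit (parabolic fallback when a
neighbor sample is non-positive; offsets clamped to ±1 px). Because the
window content is not periodic, circular correlation carries an implicit
triangular overlap taper (1 − |k|/w per axis) that biases broad
correlation peaks toward zero displacement; the correlation plane is
divided by that taper and the peak search restricted to |k| ≤ w/3, where
the correction is mild. Validation: texture-free windows and peaks
failing a peak-to-second-peak ratio floor (default 1.05) are invalid;
the normalized-median neighborhood test (ε = 0.1 px, threshold 2.0, the
common community default) is iterated to convergence so clustered
outliers are peeled from their edges; invalid vectors are replaced by the
median of valid neighbors but remain flagged, so all statistics can
exclude them. Border windows that do not fit are dropped, not padded.

Known limitation: near-crystalline cell arrangements (such as the
simulator's initial lattice before positional order melts, or strongly
hexatic tissue) make PIV genuinely ambiguous — the correlation plane has
equal peaks at the true displacement plus lattice vectors, and since
neighboring windows agree on the same wrong consensus, no neighborhood
filter can reject them. Closure analyses therefore skip the first ~30
simulated minutes; with that, PIV recovers the track-derived mean speed
within ~8% on rendered flocking movies, and integer/half-pixel rigid
shifts are recovered exactly / within 0.1 px.

## Kinematics

V_cm, V_RMS and ψ are means over valid windows only; undefined values
(no valid windows, zero speeds) propagate as NaN, never as zeros. V_RMS
is reported without drift correction by default, matching the headline
use of the quantity; a drift-corrected variant exists because "velocity
fluctuations" can also be read relative to V_cm. Two ψ definitions are
in circulation; the default divides by the RMS speed (√⟨|v|²⟩), the
variant by the mean speed ⟨|v|⟩. Cauchy–Schwarz guarantees default ≤
variant ≤ 1, property-tested. The motility peak is the argmax of the
NaN-aware moving-average-smoothed V_RMS (ties to the earliest frame),
and the correlation analysis window centered on it defaults to 10 h — a
package choice, configurable, as no canonical length exists.

Tracking data are put on PIV footing by `velocity_field_from_tracks`:
per-cell frame-to-frame velocities averaged in 50-µm windows at 50%
overlap (2×2 periodic bin sums). Single-cell bins were rejected: with
~1.4 cells per bin, uncorrelated cell-level noise concentrates in C(0),
deflating both ψ and the fitted L_CORR relative to what window-averaged
PIV measures.

## Velocity correlation and L_CORR

C_vv(r) is computed per frame with the periodic FFT convention (no
padding), which matches the direct average over all circular shifts to
1e-10 (tested exhaustively on small grids). Frames in the analysis
window are averaged at the map level, then radially averaged into
half-open annuli of one grid spacing. With drift correction on (the
default), the per-frame mean is removed before transforming and the
mean-variance correction C′(r) = C(r) − |⟨v⟩|² is an identity; with it
off, the correction is applied explicitly. The curve is normalized by
C′(0) so the fit model exp(−(r/L)^γ) is exact at the origin; the r = 0
bin (self-correlation) is excluded from the fit, as are lags beyond half
the box (periodic aliasing). Fit: bounded least squares with L > 0,
γ ∈ (0, 2], initialized at the interpolated 1/e crossing and γ = 1;
failures return a not-converged record with diagnostics, never a silent
fallback. Invalid vectors are inpainted by the valid-neighbor median,
capped at 30% invalid.

Recovery: on spectral-synthesis Gaussian fields with prescribed
exponential correlation (white noise filtered to S(k) ∝ (1+(kL)²)^{−3/2})
at L* ∈ {20, 50, 100} µm on 512² grids, the full pipeline recovers L
within 15% and γ within 0.15 of 1 (medians over 20 seeds).

Limitation: the radial curve inherits a smoothing floor of roughly one
window size, so correlation lengths measured for spatially uncorrelated
motion sit near the window scale rather than zero, compressing
fluid-to-fluid contrasts. On the simulator presets the flocking and
disordered L_CORR distributions separate completely across seeds
(≈ 56–81 µm vs ≈ 41–44 µm at 50-µm windows), which is the ordering the
classification relies on.

## Neighbor dynamics

The neighbor threshold is the first local minimum of the smoothed g(r)
after its first coordination peak; the peak must clear 1.2 and the valley
must dip below 1.0, which rejects both shoulder artifacts and spurious
"peaks" in the noise around g = 1 for unstructured point sets (those
raise an error advising a manual threshold; the pipeline then falls back
to 1.8× the median nearest-neighbor spacing and records the method).
Adjacency is strict (< threshold). The RDF uses minimum-image distances
in periodic boxes and a guard-region edge correction in bounded fields
of view.

d(δt) follows pairs that are neighbors at a reference time t to t + δt,
averaging |r_i(t+δt) − r_j(t+δt)| with weights 1/(N(t)·n_i(t)) over all
valid reference times; pairs whose tracks end are dropped and counted.
For periodic data the pair separation uses unwrapped coordinates plus the
image offset fixed at the reference time, so separations are continuous
across the boundary. Δd(δt) = d(δt) − d(0) starts at zero by
construction; its least-squares slope (µm/h, with 95% CI) is the
neighbor-exchange readout. P(r, δt) histograms the change of the pair
relative-position vector with the same weights, normalized to unit
integral. Both statistics match literal O(N²) implementations to 1e-10
and are exactly invariant under rigid translations and rotations. Track
gaps up to 3 frames (the usual gap-closing setting) can be linearly
interpolated; longer gaps break pairs.

## Density, shape, assays

Density is a circular counting kernel (R = 50 µm, grid pitch R/5):
count within R divided by πR², or by the disc area clipped to the field
of view near borders (numeric chord integration), or periodic for
simulated boxes. Kymographs average over the orthogonal axis; the
fluctuation map is the pixelwise temporal SD (ddof = 1). Integrating an
edge-corrected field recovers N within ~2% for interior-dominated
configurations.

Shape descriptors: ellipse axes from second central moments (the Fiji
"fit ellipse" convention), AR = major/minor, SI = p/√A. The perimeter is
the arc length of the 0.5-level marching-squares contour of the σ = 1 px
smoothed label. This was chosen after measuring the alternatives: naive
pixel-edge counting overestimates smooth contours badly, the weighted
pixel-edge estimator is ~+4% on discs, and the 4-direction Crofton
estimator is ~−5% on axis-aligned squares; the contour estimator stays
within ~1% on discs, squares, triangles and rotated squares alike
(sub-resolution labels fall back to Crofton). Border-touching labels are
flagged and excluded from population statistics by default. The
normalized AR time series drops detections with area ≤ 10 µm² (strictly
larger retained) and divides each track by its first available value.

FRAP: the bleach disc is found on the bleach frame by median filter
(radius 10 px), inversion, threshold ≥ 65200 (16-bit), connected
components filtered to areas between 2000 and 4500 µm², a minimal
enclosing circle (Welzl) per component, and a 20% *area* shrink
(radius × √0.8) to avoid partially bleached rim cells; several candidate
regions set a supervision flag. Recovery curves are double-normalized —
(I_roi − bg)/(I_ref − bg) scaled by the inverse pre-bleach ratio — which
cancels background and acquisition photobleaching and pins the pre-bleach
mean to 1. Default ROIs (configurable): zero background (a dye-free
region rarely exists in a confluent monolayer) and a far-field reference
annulus at 1.5–2.5 ROI radii. The post-bleach summary fit is
N(t) = N_∞ − A e^{−kt}. Round trip on the generator: plateau within 0.03
of the mobile fraction, rate within 15%, detected center within 2 px.

Wetting: area series (from a table or a mask stack) divided by the area
at the first time point. FUCCI: green/(green + red) nuclei.

## State classification

The rule table splits on the framecut-mean V_RMS, the fitted L_CORR and
the exchange slope, in that order (see `flockmetrics.classify`). ψ and
the SI variability are recorded as supporting evidence but do not split
states: the state definitions are expressible in the three splitting
metrics alone, and shape data may be entirely absent. Numeric thresholds
are artifact constants — the underlying tissue states are defined
comparatively — calibrated once against the simulator presets (20 seeds
per regime) and then frozen: v_rms_low = 5 µm/h, l_corr_low = 50 µm (one
PIV window; calibration placed the disordered distribution at 41–44 µm
and the flocking ones at 56–81 µm), exchange_slope_high = 0.08 µm/h
(flocking_fluid 0.16–0.29, flocking_solid ≤ 0.004), with slopes below
0.02 reported as ≈ 0. On those presets the classifier recovers the
generating regime in 100% of the calibration runs; the acceptance suite
requires ≥ 90%. A not-converged L_CORR yields an explicit
"unclassifiable" call with reasons, unless V_RMS already places the
tissue in the jammed branch. Note that both solids rearrange negligibly:
the bonded flocking solid is, if anything, stiffer than the barely
motile jammed tissue, so no ordering between their (near-zero) slopes is
asserted.

## What the synthetic data do and do not show

The generator reproduces the kinematic phenomenology of the four states
— speeds, alignment, correlation range, neighbor exchange, density
fluctuations — under controlled conditions, which is what validates the
estimators. It does not emulate cell division or extrusion, cell-size
polydispersity (its monodisperse disks order more readily than real
tissue), image artifacts beyond Poisson–Gaussian noise, uneven
illumination, or the molecular causes of the transitions (growth-factor
signaling, gap-junctional coupling). Passing tests therefore demonstrate
correctness of the measurement chain, not biological fidelity of any
particular mechanism; on real movies, segmentation/tracking quality and
field-of-view effects will dominate the error budget.
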