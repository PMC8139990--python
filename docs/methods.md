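# Methods

This note documents the models, algorithms and numerical choices behind
`aggpaint`, in the order data flows through the package, together with the
assumptions a user should keep in mind when interpreting results.

## Coordinate and unit conventions

All positions are in nanometres in field-of-view coordinates, origin at the
upper-left pixel corner, x to the right and y down. CSV ingest converts
pixel coordinates via the camera pixel pitch (98.6 nm for the
antibody-based instrument, 107 nm for the aptamer-based one); a units flag
covers exports already in nm. Times are hours in the kinetics module and
SI seconds in the transport module; concentrations convert between nM and
m⁻³ through Avogadro's number exactly.

## Localization quality filter

Rows are kept when `signal ≥ 40` (camera units) and `precision ≤ 25 nm`.
Both boundaries are inclusive — the thresholds are stated values, and
treating them as inclusive makes the filter idempotent and the boundary
behavior explicit. The localization precision model is
`σ = σ_PSF / √N_signal`, with `σ_PSF` the PSF full width at half maximum
and `N_signal` the photon count.

## Fiducial detection and drift correction

A fiducial bead is bright and present in essentially every frame; a
densely decorated aggregate can also accumulate more than 100 *distinct*
frames over a 4000-frame movie, but only in short binding bursts. The
detector therefore finds candidate locations by spatial DBSCAN
(ε = 100 nm ≈ 1 camera pixel, min 100 members, chaining accommodates slow
stage drift) and accepts a candidate only when it is present for a run of
strictly more than 100 *consecutive* frames (a configurable gap tolerance,
default 0, allows for occasional missed frames). Continuous presence is
the discriminating feature; requiring only distinct frames misclassifies
aggregates as fiducials at realistic binding rates.

Drift is estimated as the across-track mean of each track's per-frame
displacement relative to its first appearance, linearly interpolated over
uncovered frames, smoothed with a centered moving average (default 100
frames), and anchored to (0, 0) at frame 0. The moving average pads with
odd reflection so that a linear drift is unbiased at both ends of the
movie (constant-edge padding biases the estimate by rate × window/4 there,
which for typical drift is larger than the fiducial precision). With
`n` fiducials of per-axis precision σ the estimator tracks the true drift
to within ~3σ/√n at the worst frame and well under σ in RMS.

## Three-stage aggregate detection

1. Spatial DBSCAN, ε = 30 nm, min 3 localizations → docking-site regions.
2. Per region, temporal DBSCAN on frame-start times, ε = 2500 ms with
   min 1 (every localization is assigned), then bursts spanning exactly
   one distinct frame are deleted. Single-frame events are the signature
   of non-specific binding, which is shorter than one exposure. At 50 ms
   exposure the temporal ε equals 50 frames; frame-start times are used
   (the 25 ms midpoint offset is immaterial at this ε).
3. Spatial DBSCAN over burst representative positions, ε = 60 nm, min 2
   bursts → aggregate clusters. Singleton bursts are not aggregates.

DBSCAN neighborhoods are boundary-inclusive (distance ≤ ε), and a core
point needs min_samples neighbors counting itself — the common library
convention. Burst representatives default to the unweighted mean of member
positions (an inverse-variance weighted option exists). Cluster ids are
made deterministic by sorting on (earliest member frame, centroid x, y),
so repeated runs and permuted inputs give identical tables.

## Morphometry

**Length.** Member positions are rounded onto a grid of pitch
(camera pixel)/8 — 12.3 or 13.4 nm depending on the instrument, matching
the 13 nm rendering scale — the binary mask is closed with a 3×3 square
(one iteration), skeletonized to width one, and the skeleton traversed
recording 8-connectivity distances (orthogonal step 1, diagonal √2, times
the pitch). The default length is the longest endpoint-to-endpoint
geodesic (the fibril's end-to-end length); total skeleton length is
available as an option. The raster keeps a 2-pixel margin so the closing
never interacts with the image border, where the erosion half of the
operation is padded with foreground.

Two position sources are supported. Rasterizing *member localizations*
(default) is unbiased on synthetic ground truth: at the ~35 nm scale of
sonicated seeds the outward scatter of localizations approximately
compensates the ~1-pixel-per-end erosion inherent to thinning small
blobs. Rasterizing *burst representatives* (option `source="bursts"`)
produces a sparser raster that under-reads short fibrils by roughly 20%
for the same reason; it is retained because burst positions are what the
final clustering stage sees. Either way, lengths below ~2 grid pixels are
at the method's resolution floor and single-pixel skeletons report 0.

**Eccentricity** is `√(1 − λ_min/λ_max)` from the eigenvalues of the 2×2
covariance of burst positions: 0 for isotropic clusters, →1 for collinear
ones, 0 by convention for coincident points. It is invariant to rotation
and isotropic scaling.

**Cohort statistics** follow the replicate-pooled convention: per-cell
counts are pooled per biological replicate, the median taken per pool, and
the mean ± SD computed over those medians (SD is 0 with a flag for a
single replicate). Category fractions (< 10, > 50, and "seeded" meaning
strictly > 10 aggregates) are computed over all cells.

## Replication kinetics

The aggregate number per cell is modeled as `P_max·f(t)` with
`f' = k f (1 − f)`; the closed form is evaluated through the logistic
sigmoid, which is overflow-safe for large `kt` and matches adaptive ODE
integration to better than 1e-8 relative error.

The fit is Bayesian with lognormally distributed noise on the counts:
`log m_i ~ Normal(log(P_max f(t_i)), s)`. Priors: flat on `k` and `P_max`,
`1/f₀` on the initial fraction, log-flat on the nuisance scale `s`, which
is marginalized numerically. The posterior is evaluated on a deterministic
dense grid — `k` linear on [0.001, 2] h⁻¹ (400 points), `P_max` linear on
[max(data), 10·max(data)] (100 points), `f₀` logarithmic on [1e-4, 0.5]
(100 points, the 1/f₀ weight absorbed by the log spacing), `s` logarithmic
on [0.02, 1.5] (40 points). A grid was chosen over MCMC so every fit is
bit-reproducible; the default grid fits five time points in a few seconds
and halving the grid spacing moves the MAP by less than half the original
cell. Reported: MAP, marginal medians, the 95% equal-tail credible
interval for `k`, the doubling time ln 2/k at the MAP and across the CI,
and boundary flags. Because the `P_max` grid starts at max(data) by
design, the MAP sitting on that lower edge is expected for saturated time
courses and is not flagged; the upper edge is. Zero medians are replaced
by a 0.5 pseudo-count (the lognormal likelihood is undefined at zero) and
flagged.

For inhibitor experiments with a single time point, `f₀` and `P_max` are
fixed to the untreated fit and the closed form inverted:
`k = (1/t)·ln[f(1−f₀)/(f₀(1−f))]` with `f = count/P_max`; counts at or
below the initial level clamp to `k = 0` with a warning, and saturated
counts are an error. Note that a 5–15-fold count reduction at 24 h maps to
a 2–3.5-fold rate reduction for small `f₀`; the rate only collapses by an
order of magnitude when counts approach the initial level `P_max·f₀`.

The effective rate decomposes into growth and fragmentation through the
mean size µ in monomer equivalents: `k_g = k·µ`, `k_f = k/µ`, so
`k = √(k_g k_f)` and `µ = √(k_g/k_f)` hold identically. With `k` in its
credible range and µ spanning 400–40,000 (a 100 nm fibril's plausible
monomer content), the derived bands span roughly 1e-2–1e1 s⁻¹ for growth
and 1e-9–1e-6 s⁻¹ for fragmentation; these are order-of-magnitude
statements only.

## Transport budget

Seeds diffuse with the Stokes–Einstein coefficient `D = k_B T/(6πηR_H)`;
defaults are 37 °C (310.15 K; using 310 K changes D by <0.1%), the
literature viscosity of DMEM + 10% FBS (0.94×10⁻³ Pa·s) and an effective
hydrodynamic radius of 50 nm, giving D = 4.8×10⁻¹² m²/s. The steady-state
flux onto an absorbing spherical cell of radius a is `J = 4πaDc_∞`
(the time-dependent transient is neglected). Encounters over an exposure
are `J × duration`; the per-encounter seeding probability is the observed
seeded-cell fraction divided by the encounters. Seed inventories convert
monomer-equivalent concentrations to particle numbers via an explicit
monomers-per-seed argument (range 400–40,000 for ~100 nm seeds) rather
than inferring it from length. The secretion budget converts an
extracellular monomer-equivalent concentration into aggregates per cell
per day assuming ~30 monomers per secreted aggregate, scaled by the
species fraction. All formulas are implemented literally; every
intermediate is echoed in the output so inconsistencies between inputs and
quoted figures surface rather than being silently absorbed.

## Immunodepletion deconvolution

With densities N (medium-only), N₆E₁₀ (anti-amyloid-β depleted) and
N_syn211 (anti-α-synuclein depleted), the three-component system
`N = A + B + b`, `N₆E₁₀ = A + b`, `N_syn211 = B + b` solves exactly:
`A = N − N_syn211`, `B = N − N₆E₁₀`, `b = N₆E₁₀ + N_syn211 − N`.
Components driven negative by noisy means clamp to zero with flags;
percentages are reported over the depletable signal A + B. The isotype
IgG control is a validation gate (flag when it deviates from medium-only
by more than 20%) rather than an equation — it measures non-specific
antibody capture, not a mixture component. Antibody depletion is assumed
complete; no efficiency terms are modeled. Calibration of aggregate
density to monomer-equivalent nM is a least-squares line with fitted
intercept (the baseline signal is nonzero), with inverse-prediction
standard errors from the calibration residuals and explicit flags for
queries below the smallest standard ("below the detection range") or
above the largest.

## Synthetic data

`simulate_paint` emulates the statistical structure the pipeline assumes:
straight fibrils with lognormal lengths (default mean 35 nm, log-SD 0.35,
matching sonicated seed preparations); docking sites spanning the whole
fibril at ~8 nm spacing (endpoints included); per-site binding-event
starts as a per-frame Bernoulli process (default 5×10⁻⁴/frame, i.e. ~2
events per site per 4000-frame movie) with exponential dwell times
(mean 500 ms, ≥1 frame) — frame-quantized rather than continuous-time,
because the pipeline only ever sees frames; one localization per bound
frame, scattered isotropically with σ = σ_PSF/√N for that frame's
lognormal photon draw (median 2000, log-SD 0.3, σ_PSF = 250 nm);
strictly single-frame uniform background events (0.05/frame per field),
which stage 2 removes by construction; fiducials localizing every frame
with bright, tight signal; and a common stage drift (default linear,
0.03/0.02 nm per frame ≈ 130 nm over the movie, a typical uncorrected
TIRF drift) added to everything. Ground truth records every fibril,
every localization's provenance, and the true drift.

What the generator does **not** emulate: camera noise statistics (EMCCD
excess noise), PSF asymmetry or the axial dimension, photobleaching,
aggregate curvature or branching, and spatially varying background.
Passing recovery tests therefore demonstrates the correctness of the
analysis chain under its own assumptions, not robustness to every
real-data artifact.

`simulate_timecourse` draws per-cell counts as
`round(P_max·f(t)·exp(ε))`, ε ~ Normal(0, s), split evenly over
replicates.

## Problem sizes and test design

The test suite and the acceptance script size their simulations for fast,
stable statistics: end-to-end fibril recovery pools three 20-fibril scenes
(60 fibrils) because the mean measured length over a single scene has
~13% sampling spread at the 35 nm scale; the credible-interval coverage
check runs 50 fits on a half-resolution grid (same bounds), which changes
the MAP by less than one coarse cell on reference fixtures. The DBSCAN
implementation is validated against an exhaustive O(n²) reference on
random instances of up to 64 points.

## Known limitations

- Measured lengths near the grid pitch (~12–13 nm) sit at the method's
  resolution floor; degenerate clusters report 0.
- The drift estimator assumes at least one fiducial and a drift that is
  smooth on the scale of the smoothing window.
- The temporal-ε burst grouping merges binding events on nearby sites
  that overlap within 2.5 s, which slightly blurs burst positions on
  densely decorated fibrils.
- The logistic model has no cell-division dilution or nucleation terms;
  it is the minimal self-replication reduction, and the fitted `k` is an
  effective rate.
- The depletion solve assumes complete, specific depletion and uncorrelated
  mean densities.
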