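# Methods

This note documents the models, estimators, parameter choices and known
limitations of `locusdyn`. Values printed here are defaults; everything is
configurable through `SimConfig`, `PopulationConfig` and `RunConfig`
(`locusdyn.config`).

## Coordinate conventions and camera model

Images follow the acquisition geometry of the system the package emulates:
512×512 px at 109.76 nm/px, frames every 4.23 s (alternative intervals of
30 s and 120 s are supported as configuration). Pixels are 0-based with the
pixel center at integer coordinates; lab positions are (col, row) px and all
tabulated positions are nm. Cell-frame coordinates are `x` — the signed
perpendicular distance to the cell centerline (transversal) — and `y` — the
signed arc length along the centerline from the projection of the cell's
center of mass (longitudinal). Pole identity (the sign of `y`, and with it
of `x`) is arbitrary per cell; it is frozen at the first frame of a movie
and population histograms can additionally be pole-folded
(f ↦ averaged with 1−f).

The renderer produces three channels per frame: a phase-contrast-like
channel (stadium-shaped cells at intensity 400 on a 1000 background,
Gaussian σ=10 noise, 1 px blur) and two fluorescence channels in which each
locus is an integrated symmetric 2D Gaussian (PSF σ = 130 nm) carrying a
photon budget of 1500 photons, over a constant background of 100
photons/px. Camera counts are Poisson(signal + background) plus Gaussian
read noise (σ = 2) plus a constant offset of 100. No camera noise model is
inherited from the emulated experiments, so this standard
shot-plus-read-noise model is a package choice; an infinite photon budget
with zero read noise and background gives noiseless renders for bias
calibration.

## Exact fractional Gaussian noise

Per axis, a locus with MSD(τ) = D τ^α has stationary Gaussian increments
with autocovariance γ(k) = (D dt^α/2)(|k+1|^α − 2|k|^α + |k−1|^α). The
default sampler is circulant embedding (Davies–Harte): the n×n Toeplitz
covariance is embedded in a 2n circulant diagonalized by the FFT, and a
Hermitian-symmetric complex Gaussian vector is transformed back — exact
draws in O(n log n). The embedding eigenvalues are non-negative for all
α ∈ (0, 1]; numerical negatives below −1e−8 (never observed) raise, and a
dense Cholesky sampler of the same covariance serves both as a fallback and
as an independent cross-check in the test suite. The empirical increment
autocovariance matches γ(k) within 3 standard errors out to lag 20 on 10⁵
steps, and ensemble MSDs match D τ^α within 5% at lags 1–10.

## Alternative mechanisms

* **CTRW**: Gaussian jumps (per-axis scale √(D dt^α), matching the FBM
  per-frame step) separated by Pareto waiting times t₀ U^(−1/β) with
  t₀ = 1 s and tail exponent β = 0.5, sampled on the regular frame grid.
  Subdiffusive in the ensemble sense and strongly ageing.
* **Obstructed diffusion**: nearest-neighbour walk on a 20 nm lattice
  (≪ cell width) among fixed reflecting obstacles at density 0.35, with 25
  move attempts per frame. Subdiffusive at this density, steps nearly
  uncorrelated.

Parameter defaults for both were chosen once so that the diagnostics
separate the mechanisms decisively at a few hundred trajectories; the
emulated study uses these models only qualitatively.

## Synthetic populations

Each cell is a stadium of width 900 nm and length ~N(3000, 300²) nm
(clipped), carrying two attB-like loci and one element trajectory. attB
loci are anisotropic FBM — α_y = 0.426, α_x = 0.247, the study's reported
per-axis exponents — anchored at the ¼ and ¾ longitudinal fractions and
reflected inside a window of ±0.08 L longitudinally (their subcellular home
region) and the cell width transversally. The apparent diffusion
coefficients D_y = 1350 and D_x = 1050 nm²/s^α (≈50 nm per-frame steps) are
package assumptions: the emulated study reports D only graphically.

Element behaviour classes, mixed by default at
{integrated 0.50, mobile_fast 0.14, mobile_local 0.31, trapped 0.05}
(largest-remainder apportionment, so realized counts match the mixture):

* **integrated** — one attB trajectory plus a tether vector whose length
  fluctuates around 200 nm (σ = 15%) and whose direction performs a 0.3
  rad/frame random walk;
* **mobile_fast** — longitudinal fGn steps (250 nm scale, attB exponent)
  relaxed toward mid-cell by an AR(1) factor 0.85, with the excursion
  normalized to span 55–75% of the cell length. This makes the class
  cell-spanning by construction, produces frame steps well above 200 nm and
  yields the mid-cell-peaked position distribution expected of freely
  moving elements. A sinusoidal sweep was rejected at design time because a
  sinusoid dwells at its extremes — exactly where the attB loci live —
  and bleeds into the integrated class;
* **mobile_local** — intermediate-mobility FBM (D = 7800 nm²/s^α, ~120 nm
  steps) confined within ±0.08 L of mid-cell;
* **trapped** — low-mobility FBM (D = 500) confined within 100 nm of an
  anchor at 0.40–0.45 L from mid-cell (near a pole, clear of the attB home
  regions); radius of gyration < 150 nm by construction.

All positions are reflected into an interior box 150 nm inside the
boundary, which lies within the stadium everywhere; trajectories therefore
rarely touch the boundary and no confinement plateau appears in the fitted
lag range. The 14% and 45% (fast, fast+local) fractions are the study's
reported values; the integrated/trapped split of the remaining 55% is an
assumption. One global seed expands into per-cell/per-stage streams via
`numpy.random.SeedSequence` spawn keys, so results are independent of
execution order.

The two fluorescence/behaviour quantities the classifier cannot take from
the emulated study are thresholds stated only qualitatively there; the
cascade makes them explicit (and they are echoed in every output):
integration = median nearest-attB distance < 300 nm over the final half of
the series (margin over the 200 nm tether) with no distance jump > 500 nm;
mobility = any frame step > 200 nm; "cell-spanning" = longitudinal span
> 40% of the cell length. Class fractions are reported with binomial
standard errors.

## Localization

Segmentation: Otsu threshold on the phase channel (cells dark), closing,
hole filling, border-touching cells discarded. The centerline is the
skeleton of each mask pruned to its longest geodesic path, spline-smoothed,
and extended along its end tangents to the poles; cell length is its arc
length and width twice the mean distance-transform value along its central
half. Spot detection thresholds each cell at median + 5·1.4826·MAD of its
interior intensities (an absolute threshold can be supplied; for noiseless
images the MAD degenerates and a peak-relative cut is used); clusters larger
than a quarter of the cell area are rejected. Each seed is fit with
I(p) = A exp(−|p−c|²/2σ²) + B in a 7×7 window, σ bounded to [0.5, 5] px;
non-convergent fits or fits ending on the σ bounds are dropped. More than
two accepted spots per channel per cell drops the cell for that frame.
Geometry is re-fit every frame with identity and pole orientation matched
to the first frame.

Measured performance at the default camera model: ≈0 nm bias on noiseless
renders, ~7 nm per-axis RMSE on isolated spots, ~10 nm lab-frame RMSE
end-to-end in rendered populations, and 0.066 px localization SD — all well
inside the 25 nm / 0.25 px working requirements. The cell-frame transform
is exactly invariant under rigid motions of spot+geometry (tested to
0.05 px); re-estimating the centerline from a rotated image reproduces
cell-frame coordinates only to ~0.1–0.5 px because skeletonization is not
exactly rotation-equivariant — an honest reproducibility limit of
image-derived coordinates, distinct from the transform itself.

## Tracking

Per cell and channel, detections are linked greedily (nearest neighbour,
gate 800 nm per step at 4 s framing, ties broken deterministically by cost
then order), with gaps up to 2 frames closed and tracks shorter than 20
frames discarded; rejected fits are gaps, not zeros. With at most two loci
per channel global assignment is unnecessary, but a Hungarian option exists
behind a flag and agrees with the greedy linker on well-separated spots.
The element-to-target distance series takes, per frame, the minimum
Euclidean cell-frame distance to any attB locus present in that frame.

## Diffusion statistics

TA-MSD uses overlapping windows (standard SPT practice), component `r2d`,
`x` or `y`, lags up to a quarter of the span, gap pairs excluded; it equals
an O(n²) brute-force pair loop exactly. EA-MSD references each trajectory's
first observed frame. Power-law fits are OLS of log MSD on log τ over lag
indices 2–10 by default — lag 1 is excluded to stay above the
localization-noise floor of image-derived data; ground-truth simulations use
1–10 — with a pair-count-weighted option behind a flag. No static
localization-error subtraction is applied (a known limitation; the fit-range
rule is the mitigation).

VACF: per trajectory, finite-difference velocities over δ frames are
correlated by time averaging and normalized by C(0); trajectories enter the
ensemble mean with equal weight. Collapse re-indexes curves on ξ = τ/δ over
a common grid (step 0.25) and reports the RMS across-δ spread plus the RMS
deviation of the collapsed mean from the FBM closed form
C(ξ) = ((ξ+1)^α + |ξ−1|^α − 2ξ^α)/2. Note that a time-averaged CTRW VACF
also collapses under ξ (its overlap triangle is δ-scale-free); what
separates mechanisms is the *shape*: FBM matches the closed form (RMS
< 0.05 at 200 trajectories), CTRW shows no dip at ξ = 1, and obstructed
diffusion at density 0.35 shows only a weak dip (≈ −0.13, from
back-reflections in obstacle pockets) far from the FBM prediction.

The ergodicity verdict compares TA and EA exponents with a z-test whose
standard error comes from a joint trajectory bootstrap (200 resamples,
shared between the two averages). OLS standard errors were rejected here:
MSD points share trajectories across lags, so OLS understates the
uncertainty and flags FBM as non-ergodic at realistic ensemble sizes. At
400 trajectories × 150 frames the test separates FBM (|z| < 2) from CTRW
(z ≈ 3–8) reliably. Walk dimension d_w = 2/α flags compact exploration when
d_w > 2.

## Pipeline and problem sizes

`locusdyn run` executes simulate → render → localize → track → analyze →
classify with plain CSV/TIFF/JSON intermediates so every stage can be
validated in isolation and resumed from disk; trajectory-only mode skips the
imaging stages and perturbs ground truth with 20 nm/axis Gaussian
localization noise instead. Drug-like conditions are parameter presets only
(exponents, mobility scaling, class mixture) — no drug mechanism is
modelled. The analysis drivers and the acceptance script use ensembles of
59–400 trajectories of 90–160 frames and populations of 868–1223 cells —
the study's own sample sizes where it states them, and sizes at which the
estimators' sampling error is a few percent elsewhere; rendering validations
use one full-frame field of 60–100 frames.

## Known limitations

* The generator's behaviour classes are stylized: sharp class boundaries,
  no within-trajectory switching between local and fast episodes (the
  emulated dynamics are episodic), no photophysics beyond constant
  amplitude, 2D in-plane motion only.
* Passing recovery tests shows the estimators are correct at the stated
  conditions; it cannot validate the biological thresholds themselves,
  which remain explicit stand-ins for qualitative descriptions.
* Confinement plus localization noise bias pipeline-level exponents of
  confined loci downward relative to their generating values; the
  estimator-recovery analyses use unconfined ensembles for that reason.
* The MSD fit ranges and per-figure averaging conventions of the emulated
  study are not stated there; defaults (ensemble-mean fits, lags 2–10 on
  imaged data) are package choices.
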