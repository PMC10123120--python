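# locusdyn

Single-particle-tracking analysis of how a mobile conjugative DNA element
(ICEBs1) searches a rod-shaped bacterium for its unique chromosomal
integration site (*attB*), rebuilt as a tested, fully synthetic-data-driven
pipeline. The package is aimed at quantitative microbiologists and
biophysicists who study intracellular locus dynamics: it simulates the
system with known ground truth, renders two-channel fluorescence movies,
recovers trajectories by sub-pixel localization in cell-frame coordinates,
and computes the anomalous-diffusion statistics that characterize the
search.

## The model

Chromosomal loci in bacteria move subdiffusively. The mean square
displacement of a locus at lag τ follows a power law

```
MSD(τ) = ⟨(r(t+τ) − r(t))²⟩ = D τ^α ,   0 < α < 1
```

with distinct exponents along the cell's long axis (α_y) and across it
(α_x) — the chromosome's bottle-brush organization makes the motion
anisotropic. The generating process is fractional Brownian motion: the
frame-to-frame increments are fractional Gaussian noise with autocovariance

```
γ(k) = (D·dt^α / 2) · (|k+1|^α − 2|k|^α + |k−1|^α)
```

sampled exactly by circulant embedding. Three diagnostics identify the
mechanism behind the subdiffusion:

* **Ergodicity** — time-averaged and ensemble-averaged MSD exponents agree
  for FBM but not for a continuous-time random walk (CTRW), whose ageing
  breaks the equivalence;
* **Velocity autocorrelation** — with velocities u(t) = (r(t+δ) − r(t))/δ,
  the normalized autocorrelation C(τ)/C(0) of FBM collapses under ξ = τ/δ
  onto `C(ξ) = ((ξ+1)^α + |ξ−1|^α − 2ξ^α)/2`, with an antipersistent dip at
  ξ = 1 that obstructed diffusion lacks;
* **Walk dimension** — d_w = 2/α > 2 means the search path is compact
  (space-filling).

On top of the locus statistics, each transconjugant's element trajectory is
classified as `integrated` (tethered ≈200 nm to the nearest *attB*),
`mobile_fast` (cell-spanning), `mobile_local` (confined near mid-cell) or
`trapped`, and normalized longitudinal position distributions are pooled
(targets near ¼ and ¾ of the cell axis, freely moving elements near
mid-cell).

## Worked example

Run the full pipeline on synthetic trajectories (no imaging stages):

```
locusdyn run --seed 3 --out runs/demo --trajectory-only
```

which simulates a 100-cell population, tracks, analyzes and classifies it,
and prints a summary including (seed 3, defaults):

```
"r2d": { "ta": { "alpha": 0.284, ... }, "ergodic": true, ... }
"walk_dimension": { "d_w": 7.05, "compact": true }
"fractions": { "integrated": { "fraction": 0.47, ... }, "mobile_fast": { "fraction": 0.18, ... }, ... }
```

(The fitted 2D exponent of these pipeline trajectories sits below the
generating attB exponents because the population generator confines loci to
their subcellular home regions and adds localization noise; the unconfined
estimator-recovery runs in `analysis/02` recover the generating values.)

The numbered drivers under `analysis/` run the individual studies and write
tables, figures and JSON summaries under `results/`. For example

```
python analysis/02_msd_anisotropy.py
```

prints

```
2D exponent recovered: 0.359 (generated 0.36)
longitudinal 0.422 vs transversal 0.248 -> 1.70-fold anisotropy (generated 1.72-fold)
walk dimension d_w = 2/alpha = 5.58 (compact, space-filling search)
```

i.e. simulating attB-like ensembles at the study's generating exponents and
fitting the time-averaged MSD recovers both per-axis exponents and their
~1.7-fold anisotropy; the implied walk dimension above 2 means the element's
search is compact. `analysis/04_mechanism_discrimination.py` reproduces the
model-exclusion logic (CTRW breaks ergodicity with z ≈ 3.5, FBM does not;
obstructed diffusion's velocity dip −0.13 falls far short of the FBM
prediction −0.34), and `analysis/06_imaging_roundtrip.py` validates the
imaging chain (0.0 nm noiseless bias, ~7 nm RMSE at default camera noise,
200.4 ± 12.0 nm measured separation for a 200 nm tethered pair).

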