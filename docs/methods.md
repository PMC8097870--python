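# Methods

## Measurement model

A sensor foil carries an analyte-sensitive and a reference luminophore; a
camera records both as separate channels and the per-pixel ratio
`sensitive / reference` cancels common-mode illumination and dye-loading
variation. The package fixes the pipeline order

    ratio → one-point adjustment (OPA) → Gaussian smoothing → calibration
    inversion → ROI / per-well extraction → kinetics → detection → statistics

Smoothing and OPA act in **ratio space**, before calibration inversion,
because both the camera noise and the illumination mismatch arise in
intensity space where the ratio is their natural carrier; inverting first
would push the (nonlinear) calibration through the noise and bias the mean.
The order sensitivity is covered by tests.

### Calibration models

- **O₂ — Stern–Volmer**: `R(C) = R₀/(1 + K_sv·C)` with `C` in % air
  saturation. Two calibration points (0%, 100%) give the exact closed form
  `R₀ = R_obs(0)`, `K_sv = (R_obs(0)/R_obs(100) − 1)/100`; more points are
  fitted by least squares on `1/R`, which is linear in `C`.
- **pH — log-sigmoid**: `R(pH) = R_a + (R_b − R_a)/(1 + 10^{s(pKa − pH)})`,
  fitted by nonlinear least squares (starts: asymptotes from the extreme
  points, pKa from the mid-ratio crossing, `s = 1`); the fitted curve must
  be strictly monotone over the calibrated pH range or the fit is rejected.

These functional forms are the standard single-site optode models; the
model name is declared in the serialised calibration file together with the
batch id, because each physical foil batch is calibrated separately.

Out-of-range readings **clamp with flags** instead of raising: transient
super-saturation and noise excursions are expected at frame level
(O₂ ratios above `R₀` → 0% with a `clamped` flag; pH ratios beyond an
asymptote → the nearest calibrated end-point pH). NaN propagates with an
`invalid` flag and is excluded from every downstream mean.

### One-point adjustment

The OPA is a multiplicative ratio-space correction fitted from an image of
a plate at one uniform analyte value: per pixel `expected/observed`, or one
scalar per well in 96-well plate mode. The correction algebra is this
package's choice (the underlying idea — a single uniform reference plate —
fixes only what is observed, not how to apply it); multiplicative in ratio
space is the unique choice that commutes with the ratio's own
common-mode-cancellation property. A sanity band warns when the median
factor leaves [0.5, 2].

## Kinetics

ROI trajectories are means over valid pixels only; a timepoint with fewer
than 50% (configurable) valid ROI pixels becomes a flagged gap, never a
silent drop. The **linear range** is defined as the longest contiguous
window of non-gap samples whose OLS r² meets a threshold (default 0.99),
with a minimum length of `max(10, 0.3·T)` samples; ties prefer the earliest
start, and if no window qualifies the best minimum-length window is
returned flagged `sub_threshold`. This automatic rule is the package's
operational definition — published micro-respirator work selects the range
per curve without stating an algorithm — and the flag keeps manual override
honest. The slope is closed-form OLS; a constant (zero-variance) window
reports slope 0 with r² defined as 0 and a flag.

Normalisation follows the field convention: OCR = (−slope[%O₂/s]/cells)·10⁷
and ECAR = (−slope[mpH/min]/cells)·10⁴ with 1 pH/s = 60 000 mpH/min, so
falling signals give positive rates; a rising signal yields a negative rate
plus a warning rather than an error.

## Nuclei counting

Median background subtraction, Otsu (or fixed) threshold with a noise floor
of 6 robust SDs (so blank noise-only tiles count zero), 8-connected
labelling, an area gate, optional watershed declumping on the lightly
smoothed distance transform, and border exclusion. Tile scans deduplicate
the overlap strip by centroid ownership: each tile owns detections at least
half the overlap away from its interior edges, while border exclusion
applies to the scan's outer edges only.

Limitation: at confluent densities (≳60 000 cells/cm² at the default
16×-magnification rendering) nuclei overlap faster than the distance
transform can separate them and counts run ~20–35% low; the demo run shows
this honestly. The non-overlapping acceptance fixtures, where truth is
exact, require exact counts and ≤1 px centroid error.

## Spatial detection

The detection statistic is *depression below robust background*:
background = median of valid pixels (outside a supplied cell mask if any),
threshold = k·MAD (default k = 5) or an absolute value. This tracks
contrast against the surrounding well rather than absolute pO₂/pH, which
drifts between wells. Components smaller than 0.1 mm² are discarded;
labelling is deterministic (row-major first-pixel order). Region acceptance
uses IoU ≥ 0.5 against ground truth, first detection IoU ≥ 0.3 — both are
this package's operational definitions of what published work judges
visually. The published detectable colony sizes (≈0.5–1.3 mm²) are **not**
quantitative targets here: they depend on real cell biology and optics that
a desk-scale simulation cannot identify.

## Statistics

Classical equal-variance one-way ANOVA (no Welch correction) with Tukey HSD
post-hoc comparisons (Tukey–Kramer SE for unbalanced groups), stars at
p < 0.05/0.01/0.001/0.0001. Degenerate inputs: all-equal constant groups
give F = 0, p = 1; zero within-group variance with unequal means gives
F = ∞, p = 0. For exactly two groups the adjusted p is computed through the
exact q = √2·|t| identity with the pooled t-test rather than through the
studentized-range quadrature, which is only accurate to ~1e-10. Each
replicate value is treated as one independent observation.

## The simulator: what it emulates, and what not

A single effective 2-D layer under the plunger:

    ∂F/∂t = D_eff ∇²F − k·ρ(x)·(h_ref/h),   zero-flux boundaries,

with `ρ` the areal cell density and `k` the per-density rate coefficient of
the local cell type. Chamber height enters only as `h_ref/h` — lowering the
plunger thins the layer and accelerates apparent depletion, which is the
micro-respirator rationale; absolute heights are free parameters because
the trapped medium volume is not measurable in the real device. pH is a
directly diffusing deviation field with buffering folded into `k_ph`
(proton/buffer chemistry is unidentifiable from pH trajectories alone).
O₂ is clipped at zero. Integration is forward Euler with automatic
sub-stepping to the explicit stability bound `dt ≤ dx²/(4·D_eff)`; the
small grids make anything fancier unnecessary.

Optics: reference channel = `exposure_scale·G₀`, sensitive channel =
`ratio_model(F)·M(x)` times the same level, with `M(x)` a strictly positive
per-pixel illumination-mismatch field (the thing OPA corrects). Noise is a
multiplicative shot-like Gaussian term (SD ∝ √intensity) plus additive
Gaussian read noise — the standard CMOS approximation. All stochastic
output is a pure function of (scene, acquisition, seed); frame rendering
and nuclei placement use separate named substreams of the seed.

Default conditions: tumour lawns at 66 000 cells/cm² (the detection-limit
density corresponding to ≈2000 cells on 0.03 cm²), `k_o2 = 1e-6`
(%·cm²)/(cell·s) giving ≈4%/min depletion so active patches appear within
minutes and 30–60 min acquisitions (10–20 s intervals, matching short-term
protocols) span the usable range, `k_ph = 4e-9` (pH·cm²)/(cell·s) giving
≈0.5 pH over 30 min, D_eff = 1e-3 mm²/s (effective lateral diffusivity of
the thin layer, somewhat below the free-water O₂ value), read noise 5
camera units on a 1000-unit reference level. Pixels are 0.1 mm; grids of
32–64 px keep every simulation in the test suite and acceptance script in
the seconds-to-a-minute range.

Not emulated: 3-D diffusion, CO₂/bicarbonate buffering, cell growth or
motility during short-term runs, photobleaching, registration drift, or
vendor file formats. Passing tests therefore demonstrate correctness of the
analysis chain against the stated physics, not fidelity to any particular
real optical system.

## Numerical and design choices

- Division guard for the ratio: pixels with reference below 1% of the
  stack's reference maximum become NaN/invalid.
- Smoothing is normalised convolution (Gaussian, σ = smoothing factor in
  pixels, default 2), renormalising the kernel over valid pixels so NaN
  neither spreads nor biases; the vendor's "noise filter" kernel is not
  documented, Gaussian is the conventional choice.
- Well extraction uses circular discs with radius 80% of half the well
  pitch, row-major A1…H12 ordering.
- Zero-variance OLS windows use a relative tolerance (1e-12 of the signal
  scale) so constant series with float rounding are still recognised.
- The linear-range search uses prefix sums (O(T²) windows at O(1) each);
  tests compare it against a brute-force scipy.linregress scan.
- Areal density conversion offers a floor-to-thousand presentation mode
  (2000 cells / 0.03 cm² = 66 666.7 → 66 000) mirroring how detection-limit
  densities are conventionally quoted.
- The CLI (`simulate`, `calibrate`, `convert`, `rates`, `spatial`, `plate`,
  `stats`, `run`) is a thin wrapper; the library functions are the primary
  interface. The `run` command drives the fixed stage order from one
  schema-validated YAML config (unknown keys rejected by name) and records
  a manifest of SHA-256 product checksums plus the config hash; per-stage
  flags cover the load-bearing parameters rather than mirroring every
  nested config key one-to-one.
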