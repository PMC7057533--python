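# Methods

## The physical model

The bench being emulated is an energy-dispersive small-angle scattering
setup: a tungsten tube (50 kVp), two pinholes collimating a pencil beam, a
sample, and an 80×80 energy-resolving pixel detector 214 mm downstream.
Each detected photon carries a pixel position and an energy, and the
reduction maps the pair to a momentum transfer

q = 4π E sin θ / hc, with hc = 1.24 keV·nm and 2θ = atan(r / SDD)

for a pixel at radial distance r from the beam axis. Real-space
periodicities follow from d = 2π/q. Because the beam is polychromatic, a
single fixed geometry samples a wide q-range at once; the price is that
every (pixel, energy) cell must be binned in q rather than in radius.

### Forward model

Expected counts per (pixel p, energy bin E) are

λ(p, E) = exposure · flux_scale · Φ(E) · T(E) · I(q(E, 2θ_p)) · ΔΩ_p

with Φ(E) the source spectrum, T(E) optional sample self-attenuation,
I(q) the sample's relative scattering intensity, and ΔΩ_p the pixel solid
angle (pitch²/SDD² · cos³2θ, pixel-centre approximation — subpixel
variation is negligible at pitch/SDD ≈ 10⁻³). Counts are independent
Poisson draws from λ with a caller-supplied seed; paired acquisitions use
sub-seeds (sample: seed, background: seed + 1) recorded in the output.

Assumptions and simplifications, each a deliberate scope choice:

- **Source**: unfiltered Kramers continuum, Φ(E) ∝ (kVp − E)/E, no
  tungsten characteristic lines. The reduction uses only 30–45 keV, where
  W K-lines (58–69 keV) and L-lines (<12 keV) do not fall.
- **Detector**: perfect energy response by default (counts binned at true
  photon energy); an optional Gaussian energy blur (σ configurable,
  1 keV when enabled) redistributes means across energy bins before
  sampling. Charge sharing, pile-up and detector efficiency are out of
  scope.
- **Optics**: the pinholes are treated as producing an ideal pencil beam;
  no ray tracing, no direct-beam transmission signal.
- **Attenuation**: Beer–Lambert factor exp(−(μ/ρ)(E)·ρ·t) with log-log
  interpolated μ/ρ tables for a protein-like solid and PMMA (approximate
  values compiled from standard photon cross-section tabulations; they
  only need to produce a smooth, monotone transmission curve). The
  reduction deliberately applies **no** attenuation correction — the
  simulator includes the effect precisely so that the consequences of
  neglecting it downstream can be studied.

### Sample templates

Relative intensity is modelled as power-law-plus-constant baseline(s)
(a·q^(−b) + c, defaults a = 50, b = 1.5, c = 1) plus Gaussian peaks.
Gaussians are the simplest analytic peak shape and are entirely adequate at
the 1.2 nm⁻¹ reduction binning. Presets:

- **Amyloid models**: two cross-β peaks at 2π/1.0 = 6.2832 nm⁻¹ (β-sheet
  stacking, d = 10 Å) and 2π/0.47 = 13.3685 nm⁻¹ (β-strand spacing,
  d = 4.7 Å), equal amplitudes (the relative height of the two peaks is
  not constrained by anything quantitative, so equal heights is the
  neutral default and is configurable). The unheated aggregate uses
  sharper peaks (FWHM 0.8 nm⁻¹) than the heated one (1.4 nm⁻¹). Peak
  amplitude scales linearly with a β-sheet signal fraction; preparation
  concentrations 20/30/40 mg/ml map to fractions 0.5/0.75/1.0 — a
  modelling choice that reproduces the qualitative ordering of the
  concentration series, not a measured calibration.
- **PMMA**: one broad halo at 9.64 nm⁻¹ (FWHM 2.5 nm⁻¹).
- **Calibrant**: narrow peaks (FWHM 0.3 nm⁻¹) at 2π/d for user-supplied
  d-spacings. The shipped default list (0.75, 0.42, 0.32 nm) is a
  stand-in: calibration treats the list purely as input and all tests use
  synthetic calibrant data, so no literature value is load-bearing.

Mixtures (phantom scenes) concatenate scaled baseline terms and peaks, so
`combine` is linear in its weights to machine precision.

## Bench preset geometry

The default `DetectorGeometry` centres the beam on the pixel grid, but the
**bench preset** used by the run configs, analysis scripts and acceptance
script places the beam axis at the detector corner (0, 0), i.e. an offset
detector. With SDD 214 mm, 0.25 mm pitch and a centred beam, the 30–45 keV
window reaches only ≈15 nm⁻¹ at the grid corners — not enough to contain
the 13.37 nm⁻¹ strand peak comfortably, and far short of the instrument's
stated accessible range. The corner placement extends coverage to
≈29.5 nm⁻¹ (computed by `accessible_q_range`; ≈1.28–29.6 nm⁻¹ with a
1.8 mm direct-beam exclusion), which matches the 1.3–28 nm⁻¹ working range
the reduction assumes. Pixel pitch (0.25 mm) is the standard value for
this detector class and is configurable.

`flux_scale` (expected detected photons per second at unit template
intensity) defaults to 3.1×10⁵, chosen once so that a 600 s unheated-model
syringe run yields ≈5×10⁵ detected photons in the 30–45 keV window —
enough for clearly resolved peaks at desk scale. It is a simulator knob,
not a measured quantity; no detected count levels are published for the
bench.

## Reduction

1. **Energy window**: keep energy bins whose centres lie in [30, 45) keV.
   q is computed at bin centres, which is exact when the simulator bins at
   true energy on the same grid.
2. **Radial q-binning**: each (pixel, energy-bin) cell accumulates its
   counts into a uniform q grid (step 1.2 nm⁻¹ default). Bins are
   half-open [edge, edge + Δq); a value exactly on an edge goes to the
   upper bin. The grid is anchored so that **q_min = 1.3 nm⁻¹ is the first
   bin centre** (centres 1.3, 2.5, …, 6.1, …, 13.3, …). This anchor choice
   is deliberate: it places the cross-β peaks in bins centred at 6.1 and
   13.3 nm⁻¹, which round to the canonical 6 and 13 readings, whereas
   anchoring the first *edge* at 1.3 shifts them into bins centred at 6.7
   and 13.9 (rounding to 7 and 14 — the likely origin of "around 14"
   readings of the strand peak at coarse binning). Both anchors are
   available (`anchor="center" | "edge"`). Cells outside the grid span are
   dropped and their count recorded; before normalisation the bookkeeping
   is an exact integer identity (Σ bins + dropped = windowed total).
3. **Uncertainties**: σ_raw = √(raw counts); normalisation divides counts
   and σ identically.
4. **Normalisation**: by the summed solid angle of contributing cells
   and/or by the number of contributing cells (both on by default, as in
   the coarse study reduction). For **fine-binned peak refinement**
   (`fine_config`, Δq = 0.2 nm⁻¹) cell-count normalisation is switched
   off: with solid-angle normalisation alone the profile is proportional
   to I(q) wherever the scattering annuli are fully sampled (verified by
   the flat-template test), whereas the extra 1/n_cells factor ≈ 1/q adds
   a smooth tilt that biases refined Gaussian centres by up to
   ≈0.12 nm⁻¹ at the PMMA halo — comparable to the recovery tolerance.
5. **Background subtraction**: counts_s − scale·counts_b on matched grids,
   σ propagated in quadrature, scale defaulting to the exposure ratio
   (the scaling rule is otherwise unconstrained). Negative bins are
   retained — clipping would bias every downstream statistic; plotting may
   clip, statistics may not. Empty-bin flags propagate as OR.

## Calibration

Only the SDD is refined by default: it is the dominant scale factor on q
(q_obs ≈ q_true · SDD_true/SDD_candidate at small angles), while the beam
centre mainly distorts azimuthal weighting. The objective re-reduces the
calibrant histogram at Δq = 0.2 under each candidate SDD, finds peaks,
matches them one-to-one to the reference 2π/d positions (greedy
nearest-distance, ties to the lower-q observation, 1.0 nm⁻¹ window,
unmatched references penalised at tolerance²) and minimises the summed
squared mismatch. Because peak matching makes the objective non-convex in
SDD, a 121-point grid scan over [0.5, 2]×(initial guess) precedes bounded
scalar refinement; optional beam-centre refinement polishes
(SDD, row, col) with a Nelder–Mead simplex. On the synthetic bench with
the default calibrant this recovers 214 mm from a 200 mm guess with median
error ≈0.03 mm over 20 seeds (see `analysis/04_sdd_calibration.py`).

## Detection

Peaks are strict local maxima (plateaus resolve to their lowest-q bin);
prominence comes from the standard topographic definition, and
SNR = prominence / σ_bin uses the propagated Poisson sigma, which is exact
under the simulator — no fitted noise floor is needed. At the coarse
1.2 nm⁻¹ binning a peak spans ~1–2 bins, too few for a stable nonlinear
fit, so refinement is 3-point parabolic interpolation in log-intensity
(exact for a Gaussian). A profile is **amyloid** when one found peak falls
within tolerance (default 1.2 nm⁻¹, the coarse bin width) of each exact
cross-β reference (6.2832 and 13.3685 nm⁻¹ — not the rounded 6/13);
`signal_strength` is the summed SNR of the matched pair. This numerical
criterion is this package's operationalisation of "distinguishable cross-β
peaks"; no published numerical threshold exists for it.

## What the synthetic bench does and does not show

The generator reproduces the *structure* of the measurement — geometry,
q-mapping, spectrum weighting, Poisson statistics, background mixing,
attenuation — with Gaussian peaks of configurable width standing in for
the real materials' scattering. Passing tests therefore demonstrate that
the reduction and detection chain is correct and unbiased under its own
physics, and quantify recovery precision at realistic count levels. They
do not validate the template shapes against real amyloid or PMMA
scattering, detector artefacts (charge sharing, spectral distortion),
collimation blur, or sample inhomogeneity; absolute β-sheet quantitation
is explicitly out of scope.

## Problem sizes and numerical choices

Study runs use the full 80×80 detector, a 1 keV energy grid from 5 to
50 keV, and the exposure presets (600/1800 s syringe, 1200 s phantom,
≈5×10⁵–8×10⁵ windowed photons); statistical properties (calibration
recovery, sensitivity/specificity) use 20 seeded replicates. These sizes
give sub-second single runs and keep the whole suite fast while leaving
Poisson error, not discretisation, as the dominant uncertainty. Degenerate
inputs are defined rather than special-cased: a beam-centre pixel has
q = 0 and contributes nothing; empty q bins carry n_cells = 0 and zero
counts/σ; zero flux yields an all-zero profile and a negative
classification.

## Known limitations

- No attenuation correction operator (by design; the simulator can
  generate attenuated data to study the omission).
- No detector tilt/rotation or energy-scale calibration; only SDD and
  optionally beam centre.
- Equal-amplitude cross-β peaks and the concentration→fraction map are
  modelling conventions, configurable but not fitted to data.
- The shipped μ/ρ tables and calibrant d-spacings are documented
  stand-ins, adequate for exercising the pipeline, not reference data.
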