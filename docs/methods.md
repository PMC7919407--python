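# Methods

This note documents the models behind `ssrox`, the choices made where the
design was genuinely open, and what the synthetic experiments do and do not
establish about real serial-crystallography data.

## Conventions

Resolution is carried as s = 1/d² (Å⁻²) throughout.  The Wilson decay of
mean intensity is written ⟨I⟩ = Σ₀·exp(−B·s/2), equivalent to the
textbook exp(−2B·sin²θ/λ²).  Image indices are 0-based and run in
acquisition order, scan-major.  Doses are carried as rates in MGy/s and
reported per image in kGy; exposure time per image is exactly the inverse
detector frame rate.

## Ground truth

`generate_truth` enumerates the symmetry-unique reflections of a unit cell
to a resolution limit (reciprocal-space asymmetric unit via gemmi; Friedel
mates always merged; supported Laue choices: none beyond Friedel, or
4/mmm) and draws one intensity per reflection from an exponential
distribution with mean Σ₀·exp(−B·s/2) — acentric Wilson statistics.
Centric reflections are not given their own distribution; for the global
statistics evaluated here (shell means, half-set correlations) the
difference is immaterial, and it keeps the truth model one-parameter.

## Acquisition simulation

Each image draws, from independent named substreams of one master seed
(`rng.substream`; keys are stage name and image index, so adding a stage
never perturbs another stage's draws):

* **Lattices and indexing.**  The number of illuminated lattices is
  Poisson(λ).  An image is a *hit* when at least one lattice is present and
  *indexes* with probability q₁·γ^(n−1): crowded images index less often,
  which reproduces the observed anti-correlation between hit rate and index
  rate.  The geometric decay is the simplest mechanism with that property;
  its parameters are user-set, not fitted.
* **Observations.**  An indexed image records a Bernoulli subset (mean
  fraction `obs_fraction`, at least one) of the truth set.  Ewald-sphere
  geometry is deliberately not simulated: which reflections co-occur on an
  image does not enter multiplicity-driven statistics (CC½, Rsplit, Wilson
  B, the scaling law), and modelling it would add a full diffraction
  geometry for no statistical gain.  Partiality is Uniform(0, 1] per
  observation; the per-image scale is log-normal with median 1; the Lorentz
  factor L = 1/sin 2θ is applied multiplicatively (the merge engine divides
  it out).
* **Damage.**  An image exposed to dose D has its intensities damped by
  exp(−β·f·D·s/2) with f = `dose_fraction_applied` = 0.5 by default: the
  crystal accumulates dose during the exposure, so the recorded intensities
  experience the mean (half) of the per-image dose.  The
  exponential-in-s B-growth form is an assumption (damage manifested purely
  as Wilson-B growth), not a fitted damage model.
* **Counting.**  Expected signal counts are I_eff · gain · photons/image;
  the reflection sits on diffuse background of
  `background_per_photon` · photons counts.  Signal plus background is
  Poisson-drawn, Gaussian read noise is added, the background is
  subtracted (observed intensities can therefore be negative), and σ_obs
  is the counting estimate mapped back to the intensity scale with a
  one-count floor.
* **Cell drift.**  Each cell parameter follows a piecewise-linear
  trajectory: start → end up to a knot (fraction of the acquisition),
  constant after, plus per-image Gaussian jitter.  The tetragonal preset
  ties b to a (same value, same jitter draw).  Alternative drift shapes are
  out of scope.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| cell | 78.4, 78.4, 38.4, 90, 90, 90 | Å, ° | tetragonal lysozyme |
| d_min (truth) | 1.7 | Å | reference data-set limit |
| B_true | 13 | Å² | room-temperature lysozyme Wilson B |
| Σ₀ | 100 | intensity | arbitrary photon-scale unit |
| geometry | 100 scans × 222 images, 0.25°/image, 9 µm/image, 20 µm | — | reference raster scan (22 200 images) |
| beam (42 kGy cond.) | 4.8e12 ph/s, T 0.194, 100 Hz, 4.2 MGy/s | — | 9.31e9 photons and 42 kGy per image |
| λ (hit model) | 1.0 | crystals/image | hit rate 63%, near the best observed loads |
| q₁, γ | 0.85, 0.5 | — | index-of-hits ≈ 64%, matching the ~67% benchmark |
| β (damage) | 15 | Å²/MGy | with f = 0.5, B roughly doubles by 1.7 MGy |
| drift | a: 78.44→78.34, c: 38.38→38.79, knot 0.5, jitter 0.02 Å | — | observed drift magnitudes; plateau after half the run |
| obs_fraction | 0.04 | — | ≈ 550 observations/image on the 1.7 Å truth set |
| scale_sigma | 0.3 | — | crystal-size spread |
| gain | 2.1e-11 | counts/(intensity·photon) | calibration below |
| background_per_photon | 5.4e-9 | counts/photon | calibration below |
| read_noise | 1.0 | counts | detector floor, minor next to background |

**Noise calibration.**  `gain` and `background_per_photon` were fixed once
so that, under the 42 kGy condition and the default truth set, the
simulation reproduces two benchmark data-quality figures of
room-temperature serial lysozyme data: per-observation signal-to-noise of
≈ 0.14 in the highest (1.73–1.70 Å) shell — equivalently shell ⟨I/σ⟩ ≈ 2.2
at multiplicity ≈ 250 — and CC½ ≈ 0.99 at multiplicity ≈ 370.  Background
proportional to incident photons is what makes the dose trade-off real: the
per-image noise floor rises with transmission, so beyond the
room-temperature tolerable dose the extra photons per image no longer beat
the damage term.  With these defaults the simulated dose series improves to
~210 kGy, plateaus, and degrades at 830–1700 kGy, and fitted resolutions of
42 kGy merges land within a few hundredths of an Å of the benchmarks
(e.g. CC½ = 0.5 at ≈ 1.7 Å near 3000 merged images).

## Merging

Observations are divided by the Lorentz factor, mapped to the asymmetric
unit, and averaged per unique reflection.  Per-image linear scale factors
are estimated iteratively (3 iterations by default): an unscaled merge
gives a reference R, each image gets the least-squares factor
g_j = Σ I_jh·R_h / Σ R_h², scales are clamped to [0.01, 100] (degenerate
images are flagged and keep g = 1), renormalised to geometric mean 1, and
the stream is re-merged with I/g.  The merged σ is the sample standard
deviation over a reflection's observations divided by √m — per-observation
counting sigmas are unreliable for strongly partial data, so scatter-based
sigmas match Monte Carlo merging practice; σ is undefined (NaN) at m < 2.
Half sets are split by image-index parity; Rsplit uses the standard 1/√2
prefactor; CC½ is the plain Pearson correlation of half-set means over
reflections present in both halves (computed on scaled intensities), and is
flagged NaN below 3 pairs or at zero variance.  Resolution shells hold
equal counts of *possible* unique reflections (20 by default), matching the
shell populations of standard serial-crystallography reporting; shell
completeness is 100·n_unique/n_possible.

## Resolution estimate

CC½ versus s is fitted with ½(1 − tanh[(s − d₀)/r])·dcc − dcc + b by
bounded nonlinear least squares (unweighted by default; shell-count weights
optional).  The low-resolution plateau b is free (bounded ≤ 1.05) rather
than pinned at 1, because sparsely merged serial data sit below CC½ = 1
even in low-resolution shells.  Initialisation: b from the maximum CC, dcc
from the CC range, d₀ from the first crossing of the half-drop level, r
from a tenth of the s range.  Flat input (vanishing fitted amplitude) or
optimiser failure sets a non-convergence flag instead of raising.  The
threshold crossing is closed-form,
s\* = d₀ + r·artanh(1 − 2(τ + dcc − b)/dcc), valid for b − dcc < τ < b and
physical for s\* > 0; the shell abscissa is the midpoint of the shell in s,
consistent with the fit being defined on s.

## Photon scaling law

1/d² = a·ln(b·N_photon) is an ordinary least-squares line in
(ln N, 1/d²).  N_photon counts photons over the merged (indexed) images
only, each worth flux × transmission / frame rate.  Planning helpers invert
the law (images needed uses a ceiling; predictions below N₀ = 1/b raise).
The Wilson reading equates the decayed signal with a fixed measurable floor
I_min: with the mean squared atomic scattering factor of protein matter
approximated by a single exponential 21.3·exp(−B_f·s/2), B_f ≈ 10.16 Å²,

    1/d² = [2/(B + B_f)] · ln( (21.3·n·c/I_min) · N_photon ),

so a = 2/(B + B_f) and b = 21.3·n·c/I_min (n atoms per unit cell, c the
photons-to-intensity proportionality).  The slope→B mapping is a single
pluggable function (`wilson_b_from_log_slope`); the single-exponential
approximation degrades at high resolution, so B values derived from it run
high (the benchmark slope a = 0.044 Å⁻² maps to B = 35.3 Å², about twice a
directly fitted Wilson B).  Where a single slope value is needed in
examples, a = 0.044 Å⁻² is used — the value consistent with the benchmark
1/d² range of 0.25–0.40 Å⁻² at 10¹²–10¹⁴ photons.

## Dose ledger

Computed per-image doses follow rate/frame-rate exactly.  For slow-frame
conditions quoted with a rounded dose rate (23 MGy/s at 54/27/13 Hz) the
product differs from the nominal labels (426/852/1769 versus 420/830/1700
kGy); both are carried, never silently reconciled.  Percentages are
displayed with decimal half-up rounding to one decimal, full precision
retained.  Volumetric dose simulation, beam-profile and crystal-size
modelling are out of scope — the ledger is pure rate × time accounting.

## Problem sizes used in tests and the acceptance script

The end-to-end stochastic checks run at desk scale, chosen to finish in
minutes while keeping every qualitative effect visible: the image-count
series merges 125–2000 indexed images of one 42 kGy acquisition against a
1.5 Å truth set; the dose series merges 1000 indexed images per condition
across all seven dose points; recovery studies use 100–200 seeded
replicates.  The acceptance script's replicated fit study uses 18 points ×
200 seeds.  All seeds are fixed or derived from the `--seed` argument.

## Limitations

The generator reproduces the statistical structure that merging statistics
respond to — multiplicity, per-observation noise, scale and partiality
scatter, damage, drift — not diffraction physics.  It does not model Ewald
geometry or reflection co-occurrence, centric statistics, anomalous signal,
preferred orientation, indexing errors or mis-indexing, spatially varying
dose, or background anisotropy.  Passing tests therefore validate the
pipeline's estimators and bookkeeping under a faithful noise model, not
instrument-level realism.  Local (per-atom) damage metrics require refined
structures and are out of scope; the damage analysis uses Wilson-B ratios
only.  The unit-cell drift analysis provides bin statistics but no
automatic selection of drift-free regions.
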