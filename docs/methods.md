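# Methods

## The physical system and what the package models

A wild-silkmoth (comet moth) cocoon fiber is a fibroin cylinder a few tens
of micrometers across, containing on the order of 2 air voids per μm² of
cross-section. The voids have transverse extents from a couple hundred
nanometers up to about a micron, sit preferentially small-near-the-edge /
large-near-the-center, and persist along the fiber axis for tens to
hundreds of micrometers ("filamentary" voids). Biomimetic regenerated-silk
and PVDF fibers carry higher densities (5.5 and 17 voids/μm²) of shorter or
fully three-dimensional ("particulate") voids. Two optical consequences are
modeled here:

1. **Radiative cooling.** The voids scatter sunlight back out of the fiber
   (high solar reflectance) while the protein's mid-IR bonds emit thermally
   in the 8–14 μm atmospheric window. The radiometry module reduces
   measured or synthetic R/T spectra to the three standard scalars.
2. **Transverse Anderson localization.** For light launched *along* the
   fiber, the transversely random but longitudinally invariant index
   profile behaves like a 2D disordered potential: a beam first broadens
   diffusively, then saturates at the localization length ξ, with an
   exponential transverse intensity tail `I ~ exp(−2|r|/ξ)`. The transport
   mean free path follows from `ξ = l* exp(π k⊥ l*²/2)`, `k⊥ = 2/ω₀`,
   where ω₀ is the entrance beam width. Destroying the longitudinal
   invariance (particulate voids) restores ordinary diffusive spreading —
   the control experiment the regenerated-silk fiber provides in reality.

## Synthetic disorder (fibergen)

Void populations are drawn with a seeded generator:

- Count ~ Poisson(ρ·πR²) at requested density ρ; positions area-uniform on
  the disk; strict non-overlap of bounding circles by dart throwing
  (largest first, 10⁴ attempts per void, then a packing error naming the
  achieved density).
- Shapes are ellipses with eccentricity uniform in [0, 0.6] — a
  one-parameter stand-in for "irregular" voids that rasterizes exactly.
- Radial size sorting: the mean semi-major axis ramps linearly from the
  top of the size range at the fiber center to the bottom at the edge
  (truncated-normal scatter of a quarter range about the ramp).
- Default semi-major axes 0.13–0.4 μm (void extents 0.26–0.8 μm). The
  lower bound is set by rasterizability — the BPM transverse sampling rule
  (spacing ≤ λ/4n) must still resolve the smallest ellipse semi-axis at
  visible wavelengths — and the upper bound keeps the bounding-circle
  coverage at ρ = 2.2 μm⁻² (~0.34) safely below random-sequential-addition
  jamming so that packing succeeds up to R = 50 μm. This truncates the
  smallest few-hundred-nanometer voids of the real distribution; see
  "Known limitations".
- Refractive indices default to fibroin n = 1.54 and air n = 1.0 (the
  values are not part of the measured dataset; they are literature-typical
  and overridable everywhere).
- Longitudinal structure: `invariant` repeats one map; `morphing` random-
  walks the void centers so their rms transverse displacement reaches one
  mean semi-axis after one correlation length (default 50 μm) of
  propagation; `particulate` resamples an independent population per plane.

A rasterized cross-section is a complex index map on a square grid (pixel
centers at (i+0.5)·spacing), with ≥ 2 μm of background margin and the
grid padded to an FFT-friendly size. An optional rectangular sericin band
is forced void-free (and can act as the slab-waveguide core seen between
paired fibers).

## Beam propagation (bpm)

Scalar paraxial split-step Fourier scheme, symmetric operator splitting
`P(dz/2) S P(dz) S … S P(dz/2)` with the diffraction half-steps between
phase screens merged for speed; screens are `exp(i k₀ (n − n_ref) dz)` with
n_ref = n_matrix. A super-Gaussian absorber strip (width ≥ 5λ) removes
power reaching the rim; the absorbed power is tallied so total power
remains accountable to 1e-12 (double precision) — ensemble screening runs
use complex64, where accounting holds to ~1e-4.

Validity: the silk/air contrast Δn ≈ 0.54 strains the paraxial scalar
approximation; scattering angles approach the escape cone of the guided
system. The engine is therefore a *qualitative* model of the localization
phenomenology (saturating beam width, exponential tails,
invariant-vs-particulate dichotomy), not a quantitative vector solver. Two
numerical consequences matter and are documented here because they shape
the analysis defaults:

- Operator-splitting error at this contrast acts as slow numerical heating
  that leaks power into delocalized background. At dz = 0.1 μm (the
  package default, adequate for qualitative ensemble contrasts) the exit
  beam width on a fixed realization is biased ~10% high relative to the
  converged result; dz = 0.05 μm is converged (halving again changes the
  exit mean-square width by < 0.5%). Quantitative ξ estimates should use
  dz ≤ 0.05 μm.
- The heated background forms a pedestal under the localization tail;
  tail fits are therefore windowed inside the fiber radius.
- At the full silk/air contrast, the exit speckle of a *single* disorder
  realization is sensitive to the pixelation of void boundaries: halving
  the grid spacing changes the exit mean-square width by a few percent,
  non-monotonically. Grid-refinement stability to < 2% holds at moderate
  contrast (Δn ≲ 0.1–0.2, the man-made localization-fiber regime);
  ensemble-averaged quantities at full contrast are stable, single-shot
  speckle patterns are not.

Sampling rules enforced at run time: spacing ≤ λ/(4 n_max) (constructor
default) and dz ≤ λ/(2 max|n − n_ref|) (refused otherwise).

Conventions worth stating because they are genuinely open choices: the
launch beam width ω₀ is the **1/e field radius** (consistent with
k⊥ = 2/ω₀ in the localization relation; a FWHM convention would rescale
k⊥ by a constant factor), and the fiber is modeled as fibroin plus air
voids only — the sericin coating is not given its own index, since the
contrast actually experienced by guided modes under a coating is not
separately known.

## Localization analysis

Profiles average *linear* intensity azimuthally about each image's
intensity centroid (lattice-exact mean bin radii) and then over the
ensemble; the log is taken at fit time — matching the convention of
plotting log of the averaged profile. The tail window defaults to
[radius where I falls to 10% of peak, radius where I meets 10× the noise
floor], capped at the fiber radius, and is always reported in the fit
record. ξ = −2/slope of the least-squares line on (r, ln I), with the
slope's standard error propagated to ξ. A non-decaying window raises a
"not localized" error rather than returning a number.

`xi_sweep` propagates each disorder realization once to the longest
requested length, snapshotting at the intermediate lengths. Two estimator
modes exist: fitting the ensemble-averaged profile (default; what a single
long-exposure measurement resembles) and fitting per realization and
averaging (`per_seed=True`; used for trend statistics, because the linear
ensemble average is dominated by the broadest single realization).

The mean-free-path inversion solves the strictly increasing map
`l ↦ l exp(π k⊥ l²/2)` by bracketed Brent root-finding to 1e-9 relative;
for ξ = 4.6 μm and ω₀ = 2 μm it gives l* = 0.989 μm.

`hotspot_fwhm` reports the FWHM of the azimuthally averaged profile about
the (lightly smoothed) global maximum with linear half-maximum
interpolation; plateau maxima are refused as ambiguous. The ring-transport
demo illuminates a mask of 1 μm apertures on a 30 μm ring with a
uniform-phase beam and scores the exit image by
(mean intensity in the ring annulus − mean elsewhere in the fiber)/(sum),
with an annulus half-width of one aperture diameter.

## Cylinder scattering (cylscat)

Standard Bessel-series solution for a normally illuminated infinite
circular cylinder, truncated at order x + 4x^⅓ + 2 (refused above x = 200).
Polarization naming follows the fiber convention: **TE = E parallel to the
fiber/void axis** (Case I of the classical treatment), TM perpendicular —
the opposite of the slab-waveguide convention; a mapping table:

| here | classical cylinder texts | slab/waveguide texts |
|------|--------------------------|----------------------|
| TE   | Case I, E ∥ axis         | TM                   |
| TM   | Case II, E ⊥ axis        | TE                   |

Q_ext is evaluated from the forward amplitude (optical theorem) and agrees
with Q_sca to 1e-12 relative in lossless cases; Rayleigh closed forms
(Q∥ = π²x³(m²−1)²/8, Q⊥ = π²x³((m²−1)/(m²+1))²/4) anchor the small-x
limit. Transport estimates use the independent-scattering formula
l = 1/(ρ⟨σ⟩) with ⟨σ⟩ the 64-point Gauss–Legendre average of
Q_sca × diameter over a uniform size distribution; voids are treated as
cylinders embedded in fibroin (host n = 1.54). For an air void the
Rayleigh-limit TE/TM ratio is (m²+1)²/2 ≈ 1.01 — barely above unity, and
finite-size corrections push it below 1 already near x ≈ 0.1; the strong
TE preference seen in measurements therefore cannot rest on the deep
Rayleigh asymptote alone.

Because the cylinders are infinite along z, scattering is confined to the
plane perpendicular to the axis: a single fiber throws a narrow stripe in
the far field, while particulate (3D) voids scatter diffusely — documented
here as the explanation of the streak-vs-diffuse far-field contrast; the
package does not simulate the far-field pattern of the full fiber.

## Radiometry

ε = 1 − R − T, clipped to [0,1] with clipping logged (hard failure beyond
1e-3 overshoot). Planck spectral emissive power uses the hemispherical
convention (π × radiance); the implementation reproduces σT⁴ to better
than 0.1% and Wien's displacement law. Weighted scalars are trapezoid
integrals on the union of the spectrum and weight grids (exact for
piecewise-linear data), refusing coverage gaps. Defaults: solar weighting
over 0.4–2.5 μm, thermal and window weighting with Planck(300 K) over
2.5–25 μm and 8–14 μm; bounds are always reported alongside the scalars,
since published scalar values depend on them. The built-in solar weight is
a clearly-labeled synthetic stand-in (5777 K Planck × smooth parametric
atmospheric envelope with water/ozone dips); a user-supplied AM 1.5 CSV
takes precedence and flips the provenance field to "user".

## Time of flight (tof)

Synthetic traces are a Gaussian IRF (parameterized by FWHM; the measured
IRF is a pulse cross-correlation whose exact shape is instrument-specific)
convolved with a causal unit-area exponential decay, plus additive
Gaussian noise at a stated peak SNR. The fit model is
`baseline + amplitude · (IRF ⊗ exp(−t/τ)θ(t))(t − t₀)` — baseline and
time offset are fitted because measured traces sit on a noise floor with
arbitrary trigger offset. τ is initialized on a multi-start grid
{0.25, 0.5, 1, 2, 4} × (rms-width excess of trace over IRF, floored at
dt); the lowest-cost converged start wins, with τ's standard error from
the local curvature. Recovery at the measured conditions (τ = 210/155 fs,
IRF FWHM 100 fs, SNR 50) is unbiased to a few percent, and paired seeds
preserve the TE > TM lifetime ordering in ≥ 95% of cases.

## Problem sizes used by the test suite

Chosen so the default `pytest` run exercises every claim end to end at
desk scale:

- Dichotomy experiment: fiber radius 10 μm, ρ = 2.2 μm⁻², λ = 0.6 μm,
  L = 120 μm, dz = 0.1 μm, 20 seeds per arm, particulate planes
  re-sampled every 10 μm.
- Wavelength trend: fiber radius 8 μm, L = 200 μm, dz = 0.05 μm
  (converged stepping), 6 paired seeds, per-seed tail fits.
- Ring transport: fiber radius 17 μm, L = 400 μm, dz = 0.1 μm, 24
  one-micron apertures on a 30 μm ring, disordered vs void-free control.
- Density convergence: R = 50 μm, 20 seeds; count statistics: R = 12 μm,
  40 seeds.

## Known limitations

- **Wavelength trend of ξ.** Measurements show ξ increasing from 450 to
  700 nm. In this model the trend is *not robust*: at the test-suite scale
  (L = 200 μm, 6 seeds) the ensemble means come out non-decreasing
  (4.22/4.51/4.54/4.68 μm) but the per-seed scatter (σ ≈ 1.5–2 μm) exceeds
  the differences, while a longer, tighter run (L = 300 μm, 8 seeds,
  per-seed σ ≈ 0.3 μm) shows a slight *decrease* (4.00/3.84/3.62/3.48 μm).
  The package's own scattering module explains the ambivalence: for
  semi-axes 0.13–0.4 μm the TE mean free path is flat-to-non-monotone
  across the visible (the size distribution straddles the first scattering
  resonance: l* = 0.42/0.40/0.39/0.42 μm at 450/500/600/700 nm), so the λ
  dependence of ξ is left to the transverse wavenumber, which falls with λ
  and *strengthens* localization. Robustly reproducing the measured
  increase requires scattering on the Rayleigh side (mean free path
  growing with λ), i.e. a size distribution strongly weighted toward voids
  below ~200 nm extent — exactly the part of the real distribution the
  raster constraint truncates — and/or vector high-contrast effects
  outside the scalar model. The model's λ trend should therefore be
  treated as undetermined, not as confirmation of the measured one.
- The paraxial scalar approximation underestimates confinement physics at
  Δn = 0.54; absolute ξ values are indicative only (the simulated ξ at
  600 nm, ~3.5–4.5 μm, happens to sit near the measured 4.6 μm, but no
  quantitative agreement is claimed).
- Independent-scattering mean free paths ignore dependent-scattering
  corrections, which are not small at ρ = 2.2 μm⁻²; values are
  order-of-magnitude estimates (they bracket the measured ~1 μm).
- The synthetic generator emulates areal density, size range, radial
  sorting, eccentricity and longitudinal character of the voids; it does
  not emulate irregular (non-elliptical) void outlines, size–eccentricity
  correlations, wall roughness, or material dispersion/absorption spectra.
  Passing tests show the analysis chain is self-consistent on disorder
  with these statistics, not that the model reproduces any particular
  fiber's measured spectra.
- No net-cooling-power or equilibrium-temperature model; no vectorial or
  full-wave propagation; no multiple-scattering (dependent) cross-section
  corrections; no transmission-matrix or wavefront-shaping analysis.
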