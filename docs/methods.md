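# Methods

## Cavity model

The imaging channel is treated as an ideal lossless Fabry–Pérot etalon at
normal incidence under collimated illumination: two parallel mirrors of
reflectivity `R` separated by the channel height `d`, filled with medium
of index `n_m` and, where present, sample material of index `n_s(x, y)`
over a physical thickness `PT_s(x, y)`. The one-way optical thickness is

```
OT(x, y) = n_s·PT_s + n_m·(d − PT_s),        ΔOT = (n_s − n_m)·PT_s,
```

and monochromatic transmission follows the Airy function
`T = 1/(1 + F·sin²(2π·OT/λ))` with the **coefficient of finesse**
`F = 4R/(1−R)²`. Two quantities named "finesse" circulate in the field and
differ numerically: `F` (= 26.56 at R = 0.68), which sets the
peak-to-valley transmission ratio `1 + F` and hence the attainable
contrast enhancement, and the classical finesse `π√R/(1−R)` (= 8.1), the
FSR-to-linewidth ratio. Both are exposed under distinct names
(`coefficient_of_finesse`, `classical_finesse`); everywhere the package
speaks of a contrast-enhancement "finesse factor" it means `F`.

Assumptions deliberately made: the mirror coating is wavelength-flat
across the narrow 515–519 nm scan unless a reflectivity table is supplied;
polarization, oblique incidence and thin-film stack structure are not
modelled; absorption inside the resonator attenuates the transmitted beam
(double pass, `(1 − a)²`) but does not modify the finesse — the full
absorbing-etalon theory is out of scope.

The laser line is Gaussian (FWHM `δλ`, σ = FWHM/2√(2 ln 2)), matching how
measured spectra are fitted. Finite linewidth is handled by
cross-correlating the line with the Airy function:
`T_eff = ∫S(λ)T(OT, λ)dλ / ∫S(λ)dλ`, evaluated with a 61-point grid
spanning ±4σ (the quadrature agrees with the δλ → 0 Airy limit to < 1e-6
and reproduces the closed-form period mean `(1+F)^(−1/2)` to ~1e-5).

Extra round trips between the mirrors displace ghost images of a point
source by `2dk/n_m` (paraxial focal-shift approximation) with intensity
`R^{2k}` — two additional reflections per round trip. With the default
geometry the first ghost sits 75.2 μm behind the primary focus with 46% of
its intensity (a 53.8% drop per ghost). Bench measurements of such systems
report somewhat larger drops (uncoated-side losses, scattering); the model
keeps the lossless prediction and the characterization code
(`analysis.axial_peaks`) measures whatever the data contain.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| channel height `d` | 50 | μm | etched channel of the reference cuvette |
| reflectivity `R` | 0.68 | — | middle of the coating's 60–80% band |
| medium index `n_m` | 1.33 | — | aqueous buffer |
| scan range | 515–519 | nm | laser tuning range, inside the coating band |
| scan steps | 35 | — | reference acquisition protocol (~2 FSR) |
| laser FWHM `δλ` | 0.29 | nm | measured linewidth of the tunable source |
| pixel size | 0.868 | μm/px | camera sampling at 50× |
| camera | 8-bit, 20 000 e⁻ full well, 1 count read noise | | consumer CMOS class |

Derived reference values: interference order `N = round(2·1.33·50 mm/516 nm)
= 258`, free spectral range `λ²/2OT ≈ 2.0 nm`, axial resolution limit
`N·δλ/2 = 37.4 nm` (≈ 30 nm for a 0.232 nm line).

## Reconstruction pipeline

1. **Background** `I_b`: median over a user-supplied sample-free ROI
   (default), or tiled medians with bilinear interpolation for a smooth
   local field. A ROI whose contents look contaminated (> 20% of pixels
   beyond 5 MAD) triggers a warning rather than an error.
2. **Weber contrast** `C = |I − I_b|/I_b` per frame; the per-pixel maximum
   over the scan plus its argmax wavelength form the FPM contrast map
   (ties resolve to the lowest wavelength).
3. **WFM baseline**: unweighted mean of the frames within one FSR of the
   scan start. The Airy mean over a period is independent of OT, so pure
   phase objects cancel (residual contrast < 2% at the 35-step sampling);
   absorption survives.
4. **Resonance map**: per-pixel argmax of transmission over the sorted
   scan, refined by the vertex of a parabola through the peak sample and
   its neighbours (exact for symmetric peaks; < δstep/10 error in
   practice). Edge peaks and degenerate fits are flagged `unrefined`,
   all-equal traces `flat`; refined values are clipped to the scanned
   interval.
5. **Optical thickness**: `OT = N·λ_max/2` from the resonance condition
   `2·OT = N·λ`. The order `N` is calibrated once per stack on background
   pixels via `round(2·n_m·d/λ)` (round-half-to-even, so calibration is
   deterministic on exact half-integers) and shared by all pixels.
   Subtracting the background-ROI median gives ΔOT. A scan spanning
   several FSRs makes the per-pixel argmax land on whichever order is
   strongest, so raw ΔOT is only defined modulo λ/2; `wrap_delta_ot` maps
   it into the principal window [−λ/4, λ/4) and pixels beyond the window
   are flagged wrapped.
6. **Unwrapping** (`unwrap_delta_ot`): for samples thicker than λ/4 (a
   7 μm silica bead carries ΔOT = 0.84 μm) the wrapped field is converted
   to a phase of period 2π, unwrapped with the quality-guided 2-D
   algorithm of scikit-image, converted back and re-anchored to a zero
   background median. This is reliable when the true ΔOT increment
   between neighbouring pixels stays below λ/4, which for steep objects
   means rendering/acquiring at sufficiently fine pixel pitch (the bead
   recovery analyses use 0.05 μm/px).
7. **Physical thickness / refractive index**: the 740 nm dye channel is
   inverted as `PT = ln(I_s/I_b)/μ` with `μ = A/d_r` (natural-log
   convention to match that inversion; a decadic option, `μ = A·ln10/d_r`,
   covers UV/Vis-style absorbance). Negative thicknesses are clipped to
   zero and flagged. `n_s = n_m + ΔOT/PT` is evaluated only where
   `PT ≥ 0.5 μm` (default), since the quotient is noise-dominated for
   thin samples. The dye frame is modelled without any etalon term — pure
   Beer–Lambert — even though the coating also reflects at 740 nm; residual
   fringes in a real dye channel are a known model gap.

## Phantoms: what they emulate, and what they do not

- **Beads**: spherical chord thickness `2√((D/2)² − r²)`, uniform index
  (defaults 7.0 μm, n 1.45 in n 1.33 medium). No lensing/refraction at the
  bead surface — the renderer treats propagation as strictly paraxial per
  pixel, so the bench observation that refractive microspheres distort
  transmitted intensity is not reproduced.
- **Cells**: cosine-tapered disc specified directly in ΔOT (default peak
  100 nm) with Gaussian organelle bumps; material thickness derived from a
  fixed nominal `n_s = 1.38`. Real epithelial cells have textured,
  anisotropic interiors; passing tests therefore demonstrate pipeline
  correctness, not biological realism.
- **Bacteria**: Poisson-distributed point field with mean concentration ×
  observable volume; each cell a 2 × 1 px spot of fixed ΔOT (120 nm) and
  5% attenuation. No rod morphology, motility or depth distribution — the
  counting task only requires discrete spots. Counting analyses image at a
  single fixed wavelength chosen near the spot resonance (516.3 nm), where
  the background is suppressed and spots are bright.
- **Point sources**: single-pixel deltas; the physical ~50 nm particle size
  enters only through being sub-resolution. The defocus PSF is a Gaussian
  whose σ grows linearly with defocus (rate 0.05 μm/μm) calibrated to a
  1.2 μm in-focus FWHM; it is a phenomenological stand-in for a pupil
  model, adequate for FWHM and ghost-peak geometry, not for ringing or
  aberrations.

Scenes carry their generating parameters (and, for cells, the exact ΔOT
map) as ground truth for recovery tests.

## Numerical and design choices

- The resonance-to-thickness relation is implemented as `OT = N·λ_max/2`;
  the equivalent form `OT = λ_max/(2N)` that sometimes appears in print is
  dimensionally inconsistent with `OT ≈ n_m·d` at order ~258 and is
  treated as a typographical variant of the same resonance condition.
- Weber contrast uses the absolute value, so both resonant brightening
  and anti-resonant darkening count as contrast.
- The dye-channel exposure is a free intensity scale: the absorbing
  background transmits only `e^{−A}` (≈ 0.7% at A = 5), far below the
  8-bit quantization floor at unit exposure, exactly as a real operator
  would compensate by raising exposure. Recovery analyses set the scale so
  the brightest sample pixels approach full well.
- Zero-count concentration estimates report a Poisson SE from the
  count + 1 convention rather than a meaningless zero.
- Particle detection thresholds default to 5× the MAD of the contrast map
  above its median; detection is 8-connected components with an area
  filter, and merged spots are counted once (threshold-monotonicity holds
  for isolated unimodal spots, not for dense speckle).
- Acquisition files are 8-bit BMP/PNG (or lossless float TIFF) frames plus
  a versioned `key=value` metadata text file; frame ↔ wavelength pairing is
  encoded in the filename so directory listing order never matters, and
  stacks are sorted by wavelength on ingestion (stable sort, filename
  tie-break).

## Problem sizes

Simulation-backed analyses run at deliberately modest sizes chosen for
statistical adequacy: 256 × 256 px, 35 frames for the contrast-enhancement
and counting studies (20 seeds per concentration at 10⁷, 3×10⁷ and 10⁸
cells/mL); 180 × 180 px at 0.05 μm/px for the 20-seed bead dual-channel
recovery; 72 × 72 px for noiseless ΔOT round trips. These sizes put ~25 to
~1000 particles in a counting field and several hundred pixels across a
bead, which is what the corresponding statistics need.

## Known limitations

- Single shared interference order limits unambiguous ΔOT to ±λ/4;
  spatial unwrapping needs adequate sampling and a connected background.
  Dual-wavelength order disambiguation is not implemented.
- No coherent speckle, partial coherence, vignetting or chromatic effects
  in the renderer; no intra-exposure laser drift (frames are rendered at
  the fitted central wavelength only).
- The ghost-intensity model is lossless; measured ghost decay on real
  hardware can be steeper.
- Concentration uncertainty propagates Poisson counting and FOV-geometry
  terms only; it does not model detection efficiency below unity.
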