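# fpm — Fabry–Pérot microscopy toolkit

`fpm` is a computational toolkit for **Fabry–Pérot microscopy (FPM)**: a
label-free imaging scheme in which a microfluidic sample channel is coated
on both inner surfaces with a partially reflective dielectric layer, turning
the channel itself into a fixed-length Fabry–Pérot cavity. Illuminated with
a tunable narrowband laser, the cavity transmits according to the Airy
function

```
T(OT, λ) = 1 / (1 + F · sin²(2π · OT / λ)),    F = 4R / (1 − R)²
```

where `OT(x, y) = n_s·PT_s + n_m·(d − PT_s)` is the per-pixel optical
thickness of the filled channel and `F` the coefficient of finesse of the
R ≈ 0.68 coating. Scanning the wavelength and recording one frame per step
yields a stack `I(x, y, λ)` from which the toolkit reconstructs:

- **contrast maps** — absolute Weber contrast `C = |I − I_b|/I_b` per
  wavelength and its max-over-wavelength projection, versus a wide-field
  (WFM) baseline obtained by averaging one free spectral range;
- **optical thickness** — the per-pixel resonance wavelength `λ_max` gives
  `OT = N·λ_max/2` at interference order `N = round(2·n_m·d/λ)`, and
  background subtraction gives the sample's excess `ΔOT = (n_s − n_m)·PT_s`
  with ~40 nm axial resolution (`N·δλ/2` for a 0.29 nm laser line);
- **physical thickness and refractive index** — an auxiliary 740 nm frame
  of the sample in an absorbing dye gives `PT_s = ln(I_s/I_b)/μ`
  (Beer–Lambert), and combining the two channels gives
  `n_s = n_m + ΔOT/PT_s`;
- **counts and concentrations** of discrete scatterers (bacteria) from the
  observable volume (channel height × imaged area).

Because no public datasets exist for this instrument, the package includes
first-class **phantom generators** (silica beads, epithelial-cell-like
phase objects, Poisson bacterial fields, sub-resolution point sources) and
a **forward renderer** (finite laser linewidth, camera shot/read noise and
quantization, ghost foci from extra cavity round trips), so every
reconstruction can be validated against known ground truth. It is aimed at
instrument builders and image-analysis researchers who want to explore
design trade-offs (reflectivity, linewidth, scan density) before touching
hardware.

## Worked example

```python
import numpy as np
from fpm import optics, phantoms, render, recon

cavity = optics.CavitySpec()   # 50 um channel, R = 0.68, water-like medium
line = optics.LaserLine()      # 515-519 nm scan, 35 steps, 0.29 nm linewidth

F = optics.coefficient_of_finesse(cavity.reflectivity)
N = optics.interference_order(cavity.medium_index, cavity.channel_height_um, 516.0)
print(f"coefficient of finesse  F = {F:.4f}")
print(f"interference order      N = {N}")
print(f"dOT resolution limit      = {optics.ot_resolution_limit(N, line.fwhm_nm):.2f} nm")

scene = phantoms.cell_scene(body_radius_um=60, body_delta_ot_nm=100.0,
                            attenuation=0.05, shape=(256, 256))
stack = render.render_stack(scene, cavity, line,
                            camera=render.CameraModel(seed=1))

roi = (0, 40, 0, 40)                       # sample-free corner
contrast, _ = recon.weber_contrast_stack(stack, roi=roi)
cmax = recon.max_contrast_map(contrast, stack.wavelengths_nm)
wfm = recon.wfm_baseline(stack, optics.free_spectral_range(515.0, 66.5))
c_wfm = recon.weber_contrast(wfm, recon.estimate_background(wfm, roi))
print(f"peak Weber contrast (resonant scan) = {cmax.values[128, 128]:.2f}")
print(f"peak Weber contrast (wide-field)    = {c_wfm[128, 128]:.3f}")
print(f"contrast enhancement                = {cmax.values[128,128]/c_wfm[128,128]:.0f}x")

rm = recon.resonance_map(stack)
otm = recon.delta_ot_map(recon.ot_map(rm, N), roi, wavelength_nm=517.0)
rec = recon.wrap_delta_ot(otm.delta_ot_um, 517.0)
print(f"background OT = {otm.background_ot_um:.4f} um (n_m * d = 66.5)")
print(f"recovered dOT at cell centre = {1e3*rec[128,128]:.1f} nm (truth 100)")
```

Output:

```
coefficient of finesse  F = 26.5625
interference order      N = 258
dOT resolution limit      = 37.41 nm
peak Weber contrast (resonant scan) = 12.73
peak Weber contrast (wide-field)    = 0.101
contrast enhancement                = 127x
background OT = 66.4998 um (n_m * d = 66.5)
recovered dOT at cell centre = 100.3 nm (truth 100)
```

Reading the numbers: the water-filled 50 μm channel runs at interference
order 258, so the 0.29 nm laser line limits the optical-thickness
resolution to 37.4 nm. A cell-like phase object only 100 nm thick in ΔOT —
invisible to a conventional microscope except through its 5% absorption
(Weber contrast 0.10) — reaches a Weber contrast of 12.7 at its resonant
wavelength, a two-orders-of-magnitude enhancement; the reconstructed ΔOT
at the cell centre agrees with the ground truth to a few nanometres.

## Command line

```sh
fpm simulate --scene cell --seed 1 --out run/
fpm reconstruct --stack run/stack --background-roi 0,40,0,40 --out run/maps
fpm count --stack run/stack
fpm characterize --zstack zstack.tif --z-range 0,200
fpm design-curves --out design.csv
fpm convert --stack run/stack --out run/tiff --format tiff
```

Each run snapshots its YAML configuration next to the outputs; all
randomness flows from the single configured seed, so reruns are
bit-reproducible.

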