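# epioct

Corneal **epi**thelial thickness profiling from anterior-segment **OCT**
B-scans: a reusable pipeline for boundary segmentation, Snell's-law
distortion correction, perpendicular thickness profiling along the
horizontal and vertical meridians, and test-retest repeatability
statistics — exercised end-to-end on physically forward-modelled synthetic
corneal phantoms.

## The problem

Spectral-domain OCT can image the whole cornea in a single B-scan, but two
systematic effects stand between the raw image and an epithelial thickness
map:

1. **Refraction distortion.** OCT records *optical* path length.  At the
   air–epithelium interface the probe beam bends (Snell's law) and slows
   (group index *n* = 1.389), so every echo below the front surface is
   displaced: its recorded depth is `z_front + n·s`, where `s` is the
   physical path along the refracted ray.  Uncorrected, the back boundary
   appears too deep and laterally sheared toward the periphery.
2. **Depth-dependent SNR.** Sensitivity rolls off with depth, so the
   peripheral cornea (deeper in the image because of corneal sagitta) is
   noisier, degrading boundary detection — and test-retest repeatability —
   from centre to limbus.

This package implements the full analysis: trace the air–epithelium
(front) and epithelium–Bowman (back) interfaces at sub-pixel precision,
undo the refraction distortion, measure the **perpendicular distance**
between the front surface and the corrected back surface, average it on an
apex-anchored 0.5-mm grid (±5 mm horizontal, ±4.5 mm vertical, left eyes
mirrored nasal↔temporal), and quantify agreement between repeated tests
with

- **CoR** = 2 × SD of the between-test differences (and CoR% = CoR / mean),
- **ICC(2,1)** — two-way random effects, absolute agreement, single
  measurement, from the two-way ANOVA mean squares,
- paired *t* tests, per grid location and per clinical zone.

Because no suitable public raw dataset exists, the `phantom` module is a
first-class component: it renders synthetic B-scans of a layered cornea
(spherical anterior surface, radially thickening epithelium — 52 µm at the
apex rising to 63/58/72 µm temporal-nasal/superior/inferior at 5 mm — with
an exact refraction forward model, speckle noise with depth roll-off,
superior eyelid occlusion on the vertical meridian, and test-retest
jitter), with ground truth attached to every scan.  The forward model and
the correction are exact inverses up to discretisation, which is the
central correctness property the test suite verifies.

## Worked example

```python
from epioct import (NoiseModel, PhantomSpec, ScanGeometry, SessionSpec,
                    render_bscan, profile_bscan, zonal_means)

spec = PhantomSpec(geometry=ScanGeometry().scaled(4))  # 512 x 1024 raster
scan = render_bscan(spec, SessionSpec(meridian="horizontal", eye="OD"), seed=7)
profile = profile_bscan(scan)   # segment -> dewarp -> thickness -> bin
for x, t, miss in zip(profile.positions_mm, profile.thickness_um, profile.missing):
    if x in (-5.0, -2.5, 0.0, 2.5, 5.0):
        print(f"x = {x:+.1f} mm : {t:5.1f} um")
z = zonal_means(profile)
print(f"zone means (um): central {z.central_um:.1f}, "
      f"paracentral {z.paracentral_um:.1f}, peripheral {z.peripheral_um:.1f}")
```

prints

```
x = -5.0 mm :  63.3 um
x = -2.5 mm :  53.4 um
x = +0.0 mm :  51.2 um
x = +2.5 mm :  53.1 um
x = +5.0 mm :  63.1 um
zone means (um): central 51.7, paracentral 52.6, peripheral 58.3
```

— a thin centre (~52 µm) thickening toward the limbus, recovered through
the full image pipeline from a noisy synthetic scan whose true field puts
63 µm at ±5 mm.  The zone names follow the clinical diameter convention
(central 0–3 mm, paracentral 3–6 mm, peripheral 6–10 mm).

The same pipeline is scriptable from the shell:

```bash
epioct simulate -o scans/ -n 21 --seed 1     # render a cohort (TIFF + JSON + manifest)
epioct profile  -i scans/ -o profiles/       # thickness profiles -> profiles.csv
epioct repeat   -i profiles/profiles.csv -o report/   # CoR / ICC / paired-t CSVs
```

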