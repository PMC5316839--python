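# cortex-patterns

Quantitative analysis of self-organizing cortical actin patterns.

During cell adhesion the cortical actin network of adherent cells
reorganizes through a sequence of self-organized patterns: **vortices**
(ring-like structures ~500 nm across with high rotational symmetry),
**stars** (asterisk-shaped patterns with few bundled arms spanning several
micrometres) and **asters** (smaller asterisks, under 3 µm, with many
single-fibre arms).  This package implements, as a tested and reusable
pipeline, the measurements used to characterize that process in
high-resolution microscopy data:

* **Orientation signatures** — per-pixel fibre orientation by the structure
  tensor (the Gaussian-windowed gradient outer product), with coherence
  weighting, and normalized angular histograms.  Read relative to the radial
  direction from its centre, a vortex shows two bell-shaped peaks at ±45°;
  stars show a few distinct peaks, asters a series of peaks, and random
  networks a flat distribution.
* **Pattern morphometrics and classification** — centre detection, the
  end-to-end diameter δ (mean arm-tip-to-opposing-arm-tip span through the
  core), ring-profile vortex diameters, and a rule-based
  vortex/star/aster/random classifier using the <3 µm aster size rule.
* **Mesh pore sizes** — normalize to the image maximum, threshold at 0.002,
  invert, fit each interior pore with its second-moment equivalent ellipse;
  the pore diameter ξ is twice the mean semi-axis, summarized by an
  exponential maximum-likelihood fit and compared across conditions as a
  ratio of means.
* **Nucleator track statistics** — per-track median distance σ from the
  pattern centre and dwell time τ, with censoring-aware exponential versus
  Gaussian dwell-model selection by AIC.  Uniform motion in a disk of radius
  R gives a population median σ = R/√2; immobilized molecules give σ = 0
  with τ pinned at the movie length.
* **FRAP turnover** — pre-bleach normalization, classic and iso-kymographs,
  least-squares front-velocity fits (v_growth = |contour slope| × pixel size
  / frame interval) and conversion to monomers per second through the
  2.7 nm actin monomer size.
* **AFM elasticity** — contact-point detection by a two-segment piecewise
  fit, indentation d = (z − z₀) − δ_cantilever, and Hertz fits
  (sphere: F = (4/3)·E/(1−ν²)·√R·d^{3/2}; four-sided pyramid:
  F = 0.7453·E/(1−ν²)·tanθ·d²) restricted to 100–500 nm depths, plus
  relative modulus changes (E − E_ctrl)/E_ctrl.
* **Synthetic data** — every stage has a generator with recorded ground
  truth (`cortex_patterns.synthgen`), so the whole pipeline is testable
  without microscope data.

## Worked example

```python
import numpy as np
from cortex_patterns import (histogram_peaks, orientation_histogram,
                             structure_tensor_field, monomer_rate)
from cortex_patterns.synthgen import gen_vortex, simulation_config

img, truth = gen_vortex(simulation_config(seed=1))   # 500-nm vortex
centre = truth.patterns[0].centre_px
field = structure_tensor_field(img)
rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
mask = (rr - centre[0])**2 + (cc - centre[1])**2 <= (450 / img.pixel_size_nm)**2
hist = orientation_histogram(field, mask=mask, convention="radial", centre=centre)
for angle, height in histogram_peaks(hist):
    print(f"peak at {angle:+.1f} deg (p = {height:.3f})")
print(f"60 nm/s regrowth = {monomer_rate(60.0):.1f} monomers/s")
```

prints

```
peak at +46.1 deg (p = 0.039)
peak at -45.5 deg (p = 0.037)
60 nm/s regrowth = 22.2 monomers/s
```

— the two spiral-chirality peaks of the vortex signature at ±45°, and the
monomer incorporation rate corresponding to a 60 nm/s filament regrowth
velocity (≈22 monomers added per second).

There is also a CLI for file-based runs:

```bash
cortex-patterns simulate --preset star_field --n-scenes 10 --seed 3 --out-dir scenes
cortex-patterns classify --image scenes --pixel-size-nm 29 --out records.csv
cortex-patterns afm --curve curve.csv --model pyramid --half-angle-deg 20 --out E.json
```

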