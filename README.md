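# pollenraman

Chemical mapping of single pollen grains from confocal Raman hyperspectral
images.

A Raman image of one grain is a grid of spectra — one per ~1 µm pixel over
the 400–3300 cm⁻¹ Raman-shift range. Stacked into a matrix
**D** (pixels × channels), the image is modelled as a non-negative bilinear
mixture

**D = C·Sᵀ + E**

where the rows of **S** are pure-component spectra (sporopollenin of the
exine wall, starch of the vegetative cell, proteins/lipids, the intine
polysaccharide mix, slide background) and **C** holds per-pixel
concentrations. The package implements the complete workflow used in
single-grain Raman studies of birch pollen:

1. **Preprocessing** — wavenumber calibration against a reference peak
   table, interpolation onto a common axis, rubberband (lower convex hull)
   fluorescence-background removal, robust cosmic-spike correction, area
   normalization over 400–3100 cm⁻¹, substrate/outlier removal by a
   correlation quality control (threshold 0.75), and Savitzky–Golay
   smoothing (order 2, window 9).
2. **Hierarchical cluster analysis (HCA)** — Ward linkage on the Pearson
   dissimilarity d = 1 − r over all retained pixels (jointly across many
   grains), cut at k = 5, giving false-color layer maps and cluster mean
   spectra.
3. **MCR-ALS unmixing** — multivariate curve resolution by alternating
   least squares with non-negativity on both **C** and **S**, initialized
   from the HCA cluster means; component spectra are kept unit-area so the
   concentrations read as area fractions.

Because raw single-grain Raman measurements are rarely published, the
package ships a first-class **phantom generator**: a layered birch-grain
model (sporopollenin exine with three protrusions, intine layers,
starch-rich core, discrete lipid bodies, weak slide background) rendered
through the full forward model — band-template spectra, smooth convex
fluorescence baseline, detector noise, sparse cosmic spikes — with exact
per-pixel ground truth. Every stage of the pipeline is validated against
that ground truth.

Intended users: spectroscopists and image analysts who want a tested,
scriptable reference implementation of this workflow, or a controllable
synthetic benchmark for their own unmixing methods.

## Worked example

```python
import numpy as np
import pollenraman as pr

img, truth, comps = pr.simulate_phantom(seed=1)
print(f"phantom: {img.width}x{img.height} px, {len(img.axis)} channels, "
      f"{len(truth.spikes)} cosmic spikes")

pre = pr.preprocess(img)                     # full default chain
print(f"preprocess: retained {int(pre.mask.sum())}/{pre.n_pixels} pixels")

hca = pr.hca_images(pre, k=5)                # joint HCA of retained pixels
print(f"HCA: cluster sizes {hca.counts.tolist()}")

res = pr.mcr_als(pre.retained_matrix(),      # non-negative unmixing
                 hca.mean_spectra, pre.axis)
print(f"MCR-ALS: {res.n_iter} iterations, lack of fit "
      f"{res.lof_percent:.2f} %, R^2 = {res.r_squared:.4f}")

nu = pre.axis.values
sel = (nu >= 400) & (nu <= 1800)
for region in ("exine", "core", "lipid_body"):
    m = truth.region_mask(region)[pre.mask]
    k = int(np.argmax(res.C[m].mean(axis=0)))
    peak = nu[sel][np.argmax(res.S[k][sel])]
    print(f"{region:>10s}: dominant component peaks at {peak:.0f} cm-1")
```

Output:

```
phantom: 40x40 px, 1351 channels, 71 cosmic spikes
preprocess: retained 716/1600 pixels
HCA: cluster sizes [202, 184, 168, 122, 40]
MCR-ALS: 500 iterations, lack of fit 6.10 %, R^2 = 0.9963
     exine: dominant component peaks at 1604 cm-1
      core: dominant component peaks at 482 cm-1
lipid_body: dominant component peaks at 1658 cm-1
```

The quality control keeps the 716 grain pixels and drops the slide; the
five clusters are the exine annulus, intine, core, a mixed boundary layer
and the lipid bodies; and the components dominating the exine, core and
lipid bodies peak at the sporopollenin (1604 cm⁻¹), starch (481 cm⁻¹,
nearest grid point 482 on the 2 cm⁻¹ axis) and amide-I/C=C (1657 cm⁻¹)
marker bands. A lack of fit of ~6 % against noisy, baseline-distorted data
corresponds to R² ≈ 0.996.

There is also a CLI:

```bash
pollenraman simulate --seed 1 --out sim/          # phantom + ground truth
pollenraman preprocess --in sim/phantom.csv --out pre.csv
pollenraman cluster --in pre.csv --k 5 --out hca/
pollenraman unmix --in pre.csv --k 5 --out mcr/
pollenraman run-all --seed 1 --out run/           # everything + figures
```

`run-all` writes every artifact (cluster maps, band-integral maps,
component spectra, concentration maps, per-grain coefficient tables,
figures) plus a `manifest.json` with SHA-256 checksums; identical config
and seed reproduce identical checksums.

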