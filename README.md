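# ftirct

FTIR micro-spectroscopy analysis of connective tissue in fish skeletal
muscle, built as a tested, reusable Python pipeline.

Connective tissue — the collagen/proteoglycan network that anchors muscle
fibers — largely determines filet quality in farmed fish such as Atlantic
cod: when it fails at the myofiber–myocommata attachments, filets gape.
Its two key components have distinct infrared signatures: **collagen
type I** dominates the amide I (1585–1720 cm⁻¹) and amide II
(1500–1586 cm⁻¹) protein bands, while the glycosaminoglycan
**chondroitin-4-sulfate (C-4-S)** has its strongest absorption in the
carbohydrate region (1140–985 cm⁻¹), with characteristic marker minima at
1134, 989 and 924 cm⁻¹. `ftirct` implements the full chemometric chain for
measuring and imaging these components in FTIR spectra and hyperspectral
images, for spectroscopists and fish-quality researchers:

* **Preprocessing** — Savitzky–Golay second derivatives (9-pt window,
  2nd-order polynomial), so bands appear as sharp minima and low-order
  baselines vanish, followed by basic extended multiplicative signal
  correction (EMSC): each spectrum *z* is decomposed by least squares as
  *z*(ν) = *a* + *d*₁ν̃ + *d*₂ν̃² + *b·m*(ν) + *e*(ν) against the
  dataset-mean reference *m*, and corrected to (*z* − *a* − *d*₁ν̃ −
  *d*₂ν̃²)/*b*.
* **Chemometrics** — region-restricted PCA (SVD on mean-centered spectra),
  second-derivative minima detection with sub-grid parabolic refinement,
  and assignment against the published collagen/C-4-S band table.
* **Imaging** — cosine-similarity segmentation of hyperspectral cubes into
  muscle vs connective tissue from user-selected patches, muscle-pixel
  discard, pixel-wise Pearson correlation images against the pure-component
  spectra, and diet-group comparison by superimposed histograms.
* **Synthetic data** — a generator producing pure-component, mixture,
  replicate-group and tissue-image data from Gaussian band models anchored
  to the published band positions, degraded by multiplicative scatter,
  polynomial baselines and additive noise (exactly the distortion family
  EMSC removes), with ground truth always attached.

## Worked example

Generate clean pure-component spectra on the 4000–750 cm⁻¹ instrument grid
(4 cm⁻¹ steps), run the full preprocessing chain, and read off the collagen
band positions:

```python
import numpy as np
import pandas as pd
import ftirct as ft

axis = ft.default_axis()                      # 4000 -> 752 cm^-1, 4 cm^-1 grid
coll = ft.generate_pure_spectrum(ft.collagen_model(), axis)
c4s = ft.generate_pure_spectrum(ft.c4s_model(), axis)

pure = ft.SpectrumSet(
    axis, np.stack([coll.intensity, c4s.intensity]),
    pd.DataFrame({"component": ["collagen_I", "C4S"]},
                 index=pd.Index(["coll", "c4s"], name="id")))

result = ft.preprocess_pipeline(pure, ft.SGParams(), region=(750, 4000))
peaks = ft.assign_peaks(ft.detect_minima(result.data.spectrum("coll"),
                                         region=(800, 1800)))
print(peaks[["wavenumber", "depth", "assignment"]].head(5).round(4).to_string())
```

```
   wavenumber   depth                                           assignment
0   1660.0000 -0.0066                           Amide I in collagen type I
1   1554.0000 -0.0053                          Amide II in collagen type I
2   1456.0000 -0.0030  CH2 asymmetric bending vibration in collagen type I
3   1338.0000 -0.0023          CH2 side chain vibration of collagen type I
4   1236.3888 -0.0023  Collagen amide III (C-N stretch, N-H bend, CH2 wag)
```

The deepest second-derivative minima of the corrected collagen spectrum
land on the published amide I (1660 cm⁻¹) and amide II (1554 cm⁻¹)
positions; depths are in second-derivative units (absorbance per cm⁻¹²),
negative because absorption bands are minima after twice differentiating.
Scanning preprocessed binary mixtures at the 50/50 and 90/10
collagen:C-4-S design for the three GAG marker minima:

```python
scan = ft.gag_marker_scan(mixtures_preprocessed)   # c4s_fraction in labels
print(scan.min_detected_fraction)                  # -> 0.1
```

shows the GAGs remain detectable down to a 10% C-4-S mass fraction.

## Command line

The same chain is scriptable end to end:

```sh
ftirct --outdir run simulate --seed 7          # synthetic study: spectra + 2 images
ftirct --outdir run preprocess --input run/groups.csv --region 920,1800
ftirct --outdir run pca --input run/corrected.csv --components 2
ftirct --outdir run segment --cube run/LS.env --patches patches.json
ftirct --outdir run map --cube run/LS.env --labels run/labels.csv \
       --pure pure.csv --component collagen_I
ftirct --outdir run report --ls ls_corr.csv --hs hs_corr.csv
```

Every subcommand writes a JSON manifest with the fully resolved parameters
and input checksums; `ftirct config` prints the merged configuration.

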