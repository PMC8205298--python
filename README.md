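# triq — threshold intensity quantization for mass spectrometry imaging

Mass spectrometry imaging (MSI) records a full mass spectrum per pixel of a
scanned surface; the *ion image* of a target m/z is the 2D map of its
intensity. Rendering that map requires quantizing continuous intensities
into *n* gray levels. The standard *zero-memory* quantizer spreads equal
bins over `[min(f), max(f)]` — and a handful of extreme-intensity pixels
("outliers"), ubiquitous in ambient ionization MSI, then squeeze virtually
the entire image into the lowest few levels.

**TrIQ** (threshold intensity quantization) restores contrast while keeping
the intensity scale linear. From the image histogram's cumulative
distribution it picks the threshold *T* as the upper edge of the first bin
whose CDF reaches a target probability *q* (default 0.98), then rebins
linearly with width

&nbsp;&nbsp;&nbsp;&nbsp;*w* = (*T* − *B*) / (*n* − 1),&nbsp;&nbsp;
*t<sub>k</sub>* = *B* + *k·w*,&nbsp;&nbsp;
*Q(f)* = 0 if *f* ≤ *t*₁, *k* if *t<sub>k</sub>* < *f* ≤ *t*<sub>*k*+1</sub>,
*n* − 1 if *f* > *t*<sub>*n*−1</sub>

so everything above *T* saturates into the top gray level. *B* is the image
minimum, or an analogously CDF-chosen *black level* that suppresses diffuse
background noise. *Global TrIQ* applies the highest per-image *T* of a
multi-slice set to every slice, putting them all on one color scale. Unlike
histogram equalization, the level→intensity relation stays linear, so color
bars remain quantitatively labeled.

The package also provides imzML reading and ion-image extraction
(m/z ± tolerance window sums), a 3×3 median filter, binary ROI masks
(non-zero / minimum-level / Otsu), RGB overlays, viridis PNG rendering with
intensity-unit color bars, a synthetic fixture generator with ground truth,
and a CLI. Quantizers follow the scikit-learn transformer protocol
(`fit` / `transform` / `get_params`), so they compose with sklearn
pipelines.

## Worked example

```python
import numpy as np
from triq import (SyntheticSpec, generate_ion_image, triq_quantize,
                  zero_memory_quantize, median_filter_3x3, mask_nonzero)

spec = SyntheticSpec(seed=7)          # 64x67 slice, 2% outliers, disk region
img, region = generate_ion_image(spec)
a = img.intensities
print("max intensity:", round(a.max(), 1), " pixels:", a.size)

raw = zero_memory_quantize(a, 256)    # naive min-max quantization
print("zero-memory: %.1f%% of pixels in the lowest 4 of 256 levels"
      % (100 * np.mean(raw.levels < 4)))

qr = triq_quantize(a, q=0.98, n=100)  # TrIQ with the default parameters
print("TrIQ q=0.98 n=100: T=%.1f  B=%.1f  w=%.2f"
      % (qr.threshold, qr.black_level, qr.bin_width))
print("pixels at/below T: %.1f%%" % (100 * np.mean(a <= qr.threshold)))

m = mask_nonzero(median_filter_3x3(triq_quantize(a, q=0.98, n=32)))
print("mask recovers %.1f%% of the seeded region"
      % (100 * np.mean(m.mask[region.mask])))
```

prints

```
max intensity: 69937.4  pixels: 4288
zero-memory: 70.9% of pixels in the lowest 4 of 256 levels
TrIQ q=0.98 n=100: T=20981.5  B=0.4  w=211.93
pixels at/below T: 98.0%
mask recovers 99.4% of the seeded region
```

The raw quantization wastes nearly the whole gray scale on a dozen outlier
pixels; TrIQ finds `T` such that 98% of pixels sit at or below it, spreads
them over equal bins of width `w`, and saturates the outliers into the top
level. The median-filtered non-zero mask then recovers the seeded sample
region almost completely.

The same pipeline from the shell:

```sh
triq synth img.tsv --seed 7
triq triq img.tsv levels.tsv --q 0.98 --levels 100 --png img.png
triq median levels.tsv filtered.tsv
triq mask filtered.tsv roi.tsv
```

Each command logs the computed `T`, `B` and `w` to stderr; the PNG's color
bar is labeled in original intensity units with the top tick marked `≥ T`.

For imzML data, start with
`triq extract run.imzML img.tsv --mz 885.55 --tol 0.3`.

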