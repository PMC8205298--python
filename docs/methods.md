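# Methods

## The quantization model

An ion image is a grid of non-negative analog intensities `f(x, y)` in
arbitrary detector units. Display requires mapping intensities to `n`
integer gray levels. All quantizers here are defined by *transition levels*
`t_1 < … < t_{n-1}` and the closed-upper-bin mapping

```
Q(f) = 0      if f <= t_1
       k      if t_k < f <= t_{k+1}
       n - 1  if f > t_{n-1}
```

A value equal to a transition level falls into the bin below it — a fixed
tie-break that makes every quantizer deterministic and order-preserving
(`f(a) <= f(b)` implies `Q(a) <= Q(b)`).

**Zero-memory** quantization uses `w = (max(f) - min(f)) / n` and
`t_k = min(f) + k·w`. The bin width is kept real-valued throughout: the
intensities are arbitrary-unit reals, and rounding `w` to an integer would
collapse low-intensity images onto a single level.

**TrIQ** replaces the upper anchor by a threshold `T` drawn from the
image's cumulative distribution. The intensity range is histogrammed into
`cdf_bins` equal bins (first bin closed at the minimum, interior bins
left-open/right-closed, out-of-range values clamped); `T` is the upper edge
of the *smallest* bin index whose cumulative fraction reaches the target
probability `q`. This resolution of "the bin whose CDF approximates q"
makes the coverage guarantee exact and one-sided: the fraction of pixels at
or below `T` is at least `q`, never below. A nearest-bin rule would leave
the direction of the error indeterminate. The scale is then rebuilt as
`w = (T - B) / (n - 1)`, `t_k = B + k·w`, so intensities above `T` saturate
into level `n - 1` while everything below is mapped linearly.

`cdf_bins` defaults to `n`: the threshold can only sit on a histogram edge,
so a finer search grid approximates `q` more closely. The two are
independently configurable, and images whose range is stretched by several
orders of magnitude benefit from `cdf_bins >> n` (a single extreme pixel
otherwise leaves `T` on a coarse early bin edge far above the bulk).

**Black level.** The lower anchor `B` defaults to `min(f)`. With
`q_black > 0` it is chosen by the mirrored CDF rule — the upper edge of the
smallest bin reaching cumulative fraction `q_black` — which zeroes at least
that fraction of pixels and suppresses diffuse background without reducing
color depth. The construction is symmetric with the `T` rule; the
alternative of reducing the gray-level count achieves a similar background
at the cost of depth. If `T <= B` the combination is rejected with guidance
to lower `q_black`.

**Global TrIQ.** For a set of slices the per-image thresholds are computed
first and the *maximum* becomes the shared `T`; the shared `B` is the
minimum over the per-image minima, so every image sits on one scale and a
given raw intensity receives the same gray level in every slice. Per-image
black levels are deliberately a single-image feature — a per-slice `B`
would break exactly the comparability that global mode exists for, so
`q_black > 0` raises in global mode.

**Histogram equalization** is included purely as the comparison baseline:
the image is zero-memory quantized to 256 levels, then remapped through the
normalized CDF `h(v) = round((cdf(v) - cdf_min) / (N - cdf_min) · (n-1))`.
On a uniform histogram this is the identity; on the skewed histograms MSI
produces it collapses many output levels (the occupied level count falls
well below `n`) and the level→intensity relation becomes nonlinear, which
is why its results carry `transition_levels = None` and are rendered
without intensity-unit tick labels.

**Degenerate inputs.** A constant image maps entirely to level 0 in every
quantizer — valid, not an error. Zero-intensity pixels (missing spectra)
are counted in histograms; they are real background.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `q` | 0.98 | fraction of pixels guaranteed at/below `T` |
| `n` (gray levels) | 100 | color depth of the rendered image |
| `cdf_bins` | `= n` | histogram resolution of the threshold search |
| `q_black` | 0 (off) | lower-tail fraction zeroed as background |
| m/z tolerance | ±0.3 | extraction window half-width (±0.1 for very high lateral-resolution AP-MALDI-style grids) |

## Ion-image extraction

Per pixel, all centroid intensities with m/z inside the closed window
`[mz - tol, mz + tol]` are **summed** (configurable to `max`). Summation is
common ion-image practice; the choice is explicit because either convention
is defensible. Continuous- and processed-mode imzML are both read as
centroid lists; peak picking is out of scope. The grid is row = y,
column = x, 1-based imzML coordinates, origin top-left; pixels without a
spectrum render as intensity 0.

## Post-processing

The 3×3 **median filter** computes the median over *in-bounds* neighbors
only (6 at edges, 4 at corners) rather than inventing padded border values,
and takes the lower median for even neighbor counts so output levels are
always levels present in the input. **Otsu** segmentation maximizes the
between-class variance `ω0·ω1·(μ0-μ1)²` over all gray-level cuts
(vectorized exhaustive search, smallest cut on ties; mask = level > cut);
it assumes a deeply bimodal histogram and is provided for comparison with
the TrIQ + median + non-zero-mask route. **Overlays** blend up to three
masks or level grids additively in linear RGB, each channel weighted by
`level / (n-1)` (1/0 for masks), clipped to [0, 1].

## Synthetic data

The generator emulates the three pathologies the quantizer targets: a
diffuse non-negative background (gamma law — Gaussian noise would produce
negative ion counts), a contiguous elevated sample region (disk or
rectangle, gamma intensities, by default ~40× the background so the sample
stands clearly above the noise floor, as tissue does in real slices), and a
configurable fraction of extreme outliers (uniform in a band an order of
magnitude above the region; regular pixels are capped just below the band
so the seeded outliers are exactly the ground-truth set). Defaults: a
64×67 grid, 2% outliers up to 7×10⁴ units — a heavy right skew under which
naive quantization packs most pixels into the lowest levels. Slice sets
reuse one layout with per-slice scale factors drawn from
`[1, 1 + scale_jitter]`.

Everything is deterministic given the seed. What the fixtures do *not*
emulate: realistic spectra (isotope patterns, peak shapes, chemical noise),
spatial intensity gradients, or correlated background structure — so
passing tests demonstrate the correctness of the quantization and
segmentation machinery, not detection performance on real tissue.

The miniature imzML writer emits processed-mode files with 32-bit floats
and explicit 1-based coordinates; round-trips through it are exact up to
float32 storage precision.

## Numerical choices

- All thresholds sit on histogram bin edges; comparisons use `searchsorted`
  with the same closed-upper-bin convention as the literal definition, so
  the vectorized mapping is bit-identical to a per-pixel loop.
- Transition levels are generated as `B + k·w` in one shot (not cumulative
  addition), keeping their spacing equal to `w` to ~1e-15 relative.
- The CDF uses exact integer counts divided by `N`; the `q = 1` edge case
  is clamped to the last bin to guard against float round-off.
- Operation counting (for the linear-complexity check) sums the array sizes
  each vectorized kernel touches, making the O(N)-per-image claim testable
  without wall-clock assertions. Problem sizes in the tests and the
  acceptance script (50×50 ops-oracle images, a 12-slice 64×67 global set,
  five doublings from 64×64) keep the whole suite in the seconds range
  while matching the grid sizes of real small-format MSI runs.

## Known limitations

- The threshold only lands on bin edges: with coarse `cdf_bins` and an
  extremely stretched range, `T` can sit far above the bulk of the data
  (raise `cdf_bins` in that case).
- Like any saturation method, TrIQ discards magnitude information above
  `T`; raw and processed images should be compared before interpretation.
- Otsu's method here operates on already-quantized levels; applying it to
  raw intensities is out of scope.
- The imzML reader trusts coordinates and centroids as stored; no
  recalibration, baseline correction or vendor-format support.
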