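# nirfuse

NDVI-weighted VIS–NIR image fusion and low-light enhancement for
greenhouse fruit imagery.

Berry crops are picked with the help of computer-vision systems, but
greenhouse light is uncontrolled: shaded canopy regions come out
underexposed, and dark ripe blackberries become nearly indistinguishable
from the background. `nirfuse` implements a fusion method for registered
visible/near-infrared image pairs that brightens exactly those regions,
guided by the vegetation index, plus the quality metrics and evaluation
harness needed to quantify the effect.

## Method

Given a registered pair — an RGB image *I* and a near-infrared plane
*N*, both normalised to [0, 1] — the pipeline computes:

1. **Vegetation index** (NDVI): `VI = (N − R) / (N + R)` with *R* the
   red channel; `VI > 0.2` marks vegetation, `VI ≈ 0` sky/soil. Its
   complement `VI′ = 1 − clip(VI, 0, 1)` weights non-vegetated regions.
2. **Complement** `I′ = 1 − I`: underexposed regions become haze-like,
   so a dark-channel-prior dehazing step acts as a low-light enhancer.
3. **Atmospheric light** `L`: per-channel maximum of *I* over the 0.1 %
   of pixels with the lowest `VI` — the brightest values among the
   least-vegetated (sky/tarpaulin) pixels.
4. **Dark channel and transmission**: `D = min_c I′_c / L_c`,
   `t = (1 − ω) · D` clamped to `[t_floor, 1]`.
5. **Enhancement**: `R_enh = L + (I′ − L) / t`, clipped and re-inverted.
6. **NIR term**: `FN_c = δ · N · D · I_c / (I_r + I_g + I_b)` — NIR
   energy distributed by the VIS color ratios, which preserves hue and
   saturation.
7. **Fusion**: with `w = t · VI′`,
   `F = clip(FN + I · (1 − w) + R_enh · w, 0, 1)`.

Defaults are `δ = 0.5`, `ω = 0.6`, `t_floor = 0.1`. Image quality is
measured with four standard fusion metrics: RMS contrast (0–255 scale),
256-bin Shannon entropy (bits, per channel averaged), CIELAB
colorfulness `σ_a + σ_b + 0.94·mean chroma`, and mean HSI saturation.
Images are split into underexposed vs. normal at mean CIELAB L = 40.

Because real registered greenhouse pairs are rarely shareable, the
package includes a synthetic scene generator (bright tarpaulin band,
shaded foliage with high NIR reflectance, drupelet-cluster fruits in
three ripeness stages, controllable exposure) with ground-truth masks
and center-based `{x, y, w, h, ripeness}` boxes, plus patch extraction
(224×224) and the usual augmentation set for downstream classifiers.

## Worked example

```sh
nirfuse synth --n 1 --seed 7 --exposure 0.2 --out demo
nirfuse fuse demo/scene_000_vis.png demo/scene_000_nir.png demo/fused.png
nirfuse metrics demo/scene_000_vis.png demo/fused.png --out demo/metrics.csv
cat demo/metrics.csv
```

```
contrast,entropy,colorfulness,saturation,image_id
13.358060763396802,4.297588845247344,12.88537588211397,0.5880850761419293,scene_000_vis.png
15.183125084490722,5.341531503192694,47.581077829313756,0.5880594893056295,fused.png
```

On this underexposed scene (exposure 0.2, mean CIELAB L ≈ 7, well below
the threshold of 40) fusion raises RMS contrast from 13.4 to 15.2 and
colorfulness from 12.9 to 47.6, while mean HSI saturation is unchanged
to four decimal places — the color-ratio form of the NIR term adds
brightness without shifting hue. `nirfuse evaluate --manifest
demo/manifest.csv --out eval` runs method comparisons over a whole
dataset and writes per-image metric tables plus Tukey HSD
multiple-comparison tables at α = 0.05.

The same functionality is available as a library:

```python
from nirfuse import SceneSpec, generate_scene, fuse, report

pair, truth = generate_scene(SceneSpec(seed=7, exposure=0.2))
result = fuse(pair)               # FusionResult with fused image + maps
print(report(result.fused))       # the four quality metrics
```

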