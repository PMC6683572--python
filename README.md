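# coverimg

Color-threshold pixel classification for plant image analysis. Every pixel
of a 24-bit raster is labeled **foreground** (within tolerance of one of up
to 10 sampled *include* colors), **ignored** (within tolerance of up to 10
*ignore* colors — netting, labels, blanked regions) or **background**, using
either an RGB or a YCbCr color-distance metric with one global tolerance.
From the counts `(C, I, B, N)` the tool reports:

- **coverage percent** `C·100/(N−I)` (identically `C·100/(C+B)`),
- **physical area** `C/(DPI/2.54)²` in cm², from the DPI embedded in the
  image file (or supplied with `--dpi`),
- **two-selection ratios** (e.g. senescent/total tissue) and their increase
  (Δ) between two imaging dates.

One selection, one tolerance and one metric are applied uniformly to the
whole image set, so per-image results are mutually comparable.

## Library overview

| Module | Contents |
|---|---|
| `coverimg.color_space` | `Color`, BT.601 YCbCr conversion, the two squared measures, `is_near` (strict `< tolerance²`) |
| `coverimg.selection` | `Selection` (≤10+≤10 channels), `add_channel`, `sample_pixel`, JSON `save_selection`/`load_selection` |
| `coverimg.raster_io` | `Raster` with DPI metadata, 24-bit BMP/PNG read-write, `crop`, `blank_region`, `blank_mask` |
| `coverimg.classify` | `classify_pixel` / vectorized `classify_image`, conflict policies, `render_mask_overlay` |
| `coverimg.coverage_metrics` | `coverage_percent`, `area_cm2`, `selection_ratio`, `senescence_delta` |
| `coverimg.fixtures` | seeded synthetic images with exact ground truth (calibration grids, blobs, two-phase plants, canopy plots) |
| `coverimg.cli` | batch runner + `coverimg` command |

```python
from coverimg import Selection, analyze_image, read_raster

img = read_raster("scan_001.bmp")                 # DPI read from the BMP header
sel = Selection(name="leaf", include=((52, 130, 60),),
                ignore=((255, 255, 255),), metric="rgb", tolerance=35)
res = analyze_image(img, sel)
print(res.coverage_pct, res.area_cm2, res.counts)
```

## CLI

```bash
# classify a whole set under one saved selection
coverimg classify scans/*.bmp --selection leaf.json --out results.csv

# override tolerance/metric, blank an artifact region in every image
coverimg classify scans/*.bmp --selection leaf.json --tolerance 40 \
    --blank "0,0,120,40,#F082AA" --out results.csv

# subset/total ratios, e.g. senescent vs whole plant
coverimg ratio photos/*.bmp --selection total.json \
    --subset-selection yellow.json --out ratios.csv

# paired early/late mode: appends the ratio increase (delta) per plant
coverimg ratio --selection total.json --subset-selection yellow.json \
    --pairs pairs.csv --out deltas.csv     # pairs.csv: plant,early_path,late_path

# synthetic test images + ground-truth JSON
coverimg fixtures --kind canopy_plot --seed 1 --out fixtures/ \
    --param cover_fraction=0.4

# counts and formula evaluation for one image
coverimg inspect scan_001.bmp --selection leaf.json
```

Selection files are small JSON documents
(`{"schema_version": 1, "name", "metric", "tolerance", "include", "ignore"}`).
The RGB metric counts brightness differences fully, so it typically needs
higher tolerances than YCbCr, which divides the squared luma difference by 9
and concentrates on hue.

## Conventions & edge cases

- Coordinates are 0-based, half-open, top-left origin.
- BMP DPI = pixels-per-meter × 0.0254; written as `round(dpi/0.0254)` (unset
  DPI is stored as 0). Round-trip error ≤ 0.0127 DPI.
- Anisotropic embedded resolution (>0.5 % relative difference) is an error
  unless `--dpi` is given; the horizontal axis is otherwise authoritative.
- A pixel within tolerance of both an include and an ignore channel is
  resolved by `--conflict {nearest,ignore-wins,include-wins}` (default
  `nearest`, ties → ignored).
- An image where every pixel is ignored yields a flagged undefined coverage
  (status `all-ignored`), never a silent zero and never a batch abort.
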