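# roctscan

A virtual robotic-OCT rig for large-area tissue imaging, plus the post-scan
reconstruction that turns pose-tagged B-scans into quantitative en-face maps.

The package simulates a free-flying, downward-looking OCT probe sweeping a
synthetic sample along planned scanlines. A closed-loop controller regulates
the probe altitude so the detected tissue surface stays at a fixed normalized
surface depth (NSD), keeping every B-scan in focus even on steep samples.
The recorded frames and poses then feed three en-face parameterizations:

- **DEPM** — depth-encoded map: absolute surface altitude (mm), pose-compensated.
- **ATCM** — attenuation map: per-A-scan extinction coefficient from a
  log-linear fit of the single-scattering decay `I(z) ∝ exp(-2 μ_t z)` in a
  near-surface window.
- **DIAM** — lumen-diameter map: per-slice lumen segmentation, morphological
  cleanup, centerline diameters, k×k grid averaging and bicubic upsampling.

Per-scanline maps are stitched by pose, averaging overlaps. A velocity-sweep
module emulates faster scanning by fractional-stride frame decimation and
scores map degradation with a structure-similarity metric.

## Modules

| module | contents |
|---|---|
| `roctscan.geometry` | poses, B-scans, pixel→base-frame transform, voxelization |
| `roctscan.scan_control` | scanline planning, entry poses, landing, NSD controller |
| `roctscan.oct_simulation` | virtual samples (letter phantoms, layered tissue, lumen fields) and the B-scan synthesizer |
| `roctscan.parameter_maps` | surface extraction, extinction fitting, DEPM/ATCM/DIAM, stitching |
| `roctscan.lumen_segmentation` | classical lumen segmenter (pluggable; external mask stacks supported), mask cleanup, diameter measurement |
| `roctscan.sweep_analysis` | frame-count arithmetic, decimation, quality curves |
| `roctscan.io` / `roctscan.cli` | acquisition/map readers-writers and the CLI |

## CLI

All commands read a YAML config. Minimal example:

```yaml
seed: 0
sample:
  kind: letter_phantom        # or layered_kidney
  footprint: [10.0, 10.0]
  letters: [{rect: [1.0, 3.5, 1.5, 2.0]}]
  extrusion_height: 0.4
plan: {x_st: 0.5, y_st: 2.5, z_st: 6.0, L: 3.0, W: 6.0, W_ol: 0.8, W_OCT: 3.2}
scan: {v_x: 0.6, fps: 20.0}
controller: {mu_ref: 0.75, K_p: 1.0, w_s: 0.5}
probe:
  width_px: 64
  height_px: 100
  alpha_res: {lateral: 0.05, axial: 0.02, elevational: 0.03}
```

```sh
roctscan plan     -c config.yaml              # scanline count + entry poses
roctscan simulate -c config.yaml -o truth/    # sample ground truth (TIFF + CSV)
roctscan scan  -c config.yaml -o acq/         # virtual scan -> images + poses
roctscan map   -i acq/ -o maps/ --kind depm   # or --kind atcm
roctscan diam  -i acq/ -o diam/               # lumen masks, measurements, DIAM
roctscan sweep -i acq/ -o sweep.csv --v0 0.6 --vmax 5.1 --step 0.5
```

Every `scan` run writes a `config_snapshot.yaml` and `run.log` next to its
outputs; identical config + seed reproduces bit-identical artifacts.

### Acquisition directory format

- `images.tif` — multi-page grayscale stack (float32/uint8/uint16), one page
  per frame; alternatively `frames/*.png`. Intensities are normalized to
  [0, 1] at load.
- `poses.csv` — columns `timestamp, r11..r33, tx, ty, tz` (row-major rotation,
  translation in mm), one row per frame; this file defines frame order/count.
- `meta.yaml` — `alpha_res` (lateral/axial/elevational mm per pixel),
  `width_px`, `height_px`, `scanline_lengths`.

Maps are written as float32 TIFF + `<name>_validity.tif` (uint8 mask) +
`<name>.yaml` sidecar (kind, units, resolution, origin).

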