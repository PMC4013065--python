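# rosettakit

Top-down rosette phenotyping in Python: segment photographs of young
*Arabidopsis* rosettes into calibrated binary masks, extract 20
two-dimensional shape descriptors, compute relative rosette area growth
rates, and run the discrimination statistics used to compare ecotypes
over time — longitudinal mixed-effects models with pairwise contrasts,
per-time-point scaled PCA and ReliefF feature ranking.  A synthetic
generator produces procedural rosette masks and effect-structured
descriptor tables with known ground truth so the whole pipeline is
testable without any photographs.

## Pipeline overview

| stage | module | what it does |
|---|---|---|
| segment | `rosettakit.segmentation` | nearest-neighbour colour classification, disc erosion/dilation cleanup, pot-region filter, px/mm calibration |
| extract | `rosettakit.descriptors` | 20 shape descriptors (areas, perimeters, hull metrics, principal-axis statistics, derived ratios) in physical units |
| growth | `rosettakit.growth` | relative area growth rate = difference of log areas per day, at interval mid-times |
| stats | `rosettakit.stats` | log-transform policy, Bonferroni outlier removal, random-intercept + AR(1) mixed models, Bonferroni-adjusted pairwise contrasts, scaled PCA, ReliefF |
| simulate | `rosettakit.synthetic` | procedural rosette masks and longitudinal descriptor tables with planted effects |

## CLI

Everything is reachable through the `rosette` command (each invocation
also writes a JSON run manifest next to its output):

```bash
# synthetic inputs
rosette simulate masks --n 5 --seed 0 --out-dir masks/
rosette simulate table --seed 1 --raw --out table.csv

# image -> mask -> descriptor row
rosette segment --image photo.png --fg-samples fg.csv --bg-samples bg.csv \
    --erode 1 --dilate 1 --pot 10,10,400,400 --px-per-mm 7.31 --out mask.png
rosette extract --mask mask.png --px-per-mm 7.31 --plant-id p1 \
    --ecotype Col-0 --das 17 --out table.csv

# growth rates and statistics
rosette growth --table table.csv --out rragr.csv
rosette stats lme --table table.csv --descriptor compactness --out lme.json
rosette stats tukey --table table.csv --descriptor area --factor ecotype --out tukey.csv
rosette stats pca --table table.csv --das 17 --out pca.json
rosette stats pca --table table.csv --subset perezperez --out pca7.json
rosette stats relieff --table table.csv --k 10 --seed 1 --out relieff.csv
```

Colour-sample files are CSVs of `R,G,B` rows.  Descriptor tables are
long-format CSVs with `plant_id`, `ecotype`, `das` and the 20
lower-case descriptor columns.

## Conventions worth knowing

* Masks are boolean grids, row-major, origin top-left, with a
  pixels-per-mm scale factor; lengths are reported in mm, areas in mm².
* Boundaries are Moore-traced pixel-centre contours; boundary length is
  the corner-cut (edge-midpoint) polygon length plus a half-pixel
  offset correction, accurate to ~1.5% on discs and rectangles.
* Convex-hull metrics use the corners of boundary pixels (the pixel
  *squares*), which guarantees `compactness = area / conhullarea <= 1`.
* The mixed model (random intercept per plant, AR(1) within-plant
  errors, quadratic time for the size-like descriptor group) is fitted
  by profiled REML implemented in `rosettakit.stats.lme`; the rho = 0
  case is cross-checked against statsmodels `MixedLM` in the tests.
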