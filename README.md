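# cmri-mapper

Desk-scale mapping of mangrove canopy and its change from multitemporal
multispectral imagery, built around the **Combined Mangrove Recognition
Index (CMRI)**:

```
CMRI = NDVI − NDWI = (NIR − Red)/(NIR + Red) − (NIR − SWIR)/(NIR + SWIR)
```

Dense, wet mangrove canopy scores high on both greenness and canopy
moisture, so its seasonal **maximum** CMRI separates mangrove from
terrestrial vegetation, bare ground and water, while the **shape** of its
bimonthly CMRI trajectory separates *Rhizophora mangle* (red mangrove,
fringing the tidal channels) from the other dominant mangrove species
(*Avicennia germinans* / *Laguncularia racemosa*, pooled because they are
spectrally inseparable in this setting).

The package is aimed at coastal remote-sensing practitioners who want the
full analysis chain as tested, reusable Python rather than a cloud
script:

1. **indices** — NDVI, SWIR-based NDWI and CMRI per pixel, with explicit
   validity masks (clouds and zero denominators are flagged, never zero).
2. **compositing** — scene-level cloud filter (strictly < 10% cover) and
   per-pixel maximum-value composites for the six calendar bimonths of
   each year, plus the annual maximum.
3. **classification** — mangrove extraction by thresholding the annual
   maximum CMRI (default 0.35, or an automatic Otsu split), then a
   Random-Forests ensemble (2000 trees) on the six bimonthly CMRI values
   to assign the two species groups.
4. **change_detection** — a per-pixel accumulated anomaly: deviations of
   the bimonthly mangrove indicator from the baseline year's annual mean,
   summed over all later periods. Clearance drifts to −6 per year, new
   colonization to +6, one-period phenological flickers stay at ±1 and
   are suppressed by a persistence threshold (default 4 periods).
5. **vectorize** — raster→polygon conversion (rook connectivity) and the
   0.2-ha minimum-mappable-area rule (exactly 20 pixels at 10 m; a patch
   of exactly 0.2 ha is retained).
6. **accuracy** — confusion matrix from validation points, overall /
   user's / producer's accuracies, commission and omission errors, and
   the kappa coefficient.
7. **synthetic** — a seeded scene generator with known ground truth
   (class geography, phenology profiles, cloud blobs, dated loss/gain
   patches) that stands in for the satellite archive in all tests.

## Worked example

`examples/` contains one short script per capability. The full pipeline
in one call (also available as `cmri demo` on the command line):

```python
from cmri import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=4, out_dir="scratch/example_change",
                                  shape=(128, 128), n_loss_patches=2,
                                  n_gain_patches=1, change_area_px=50))
```

which prints, via `examples/04_change_detection.py`:

```
injected: 100 px loss, 50 px gain (events dated 1 Jan 2020)
called:   1.00 ha loss, 0.50 ha gain (truth: 1.00 / 0.50 ha)

per-zone change accounting (totals are exact column sums):
    west: gain   0.50 ha, loss   0.50 ha
    east: gain   0.00 ha, loss   0.50 ha
   Total: gain   0.50 ha, loss   1.00 ha
```

The generator injected 1.00 ha of mangrove clearance and 0.50 ha of
colonization at the start of the final year; the accumulated-anomaly
statistic recovers both areas exactly at the default persistence
threshold, and the zonal table splits them between the two accounting
zones with totals that are exact column sums. The run directory holds
every intermediate product: bimonthly composites with coverage counts,
annual class maps, the anomaly and change rasters, filtered polygons,
and the accuracy report.

`examples/05_error_matrix.py` reproduces the published 480-point
validation assessment (overall accuracy 91.9%, kappa 0.84, R. mangle
commission 10% / omission 6%) from the matrix's printed marginals.

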