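# Methods

## The index and its variants

All stages operate on the Combined Mangrove Recognition Index,

    CMRI = (NIR − Red)/(NIR + Red) − (NIR − SWIR)/(NIR + SWIR),

a greenness term minus a wetness term, bounded in [−2, 2]. The wetness
term implemented by default is the SWIR-based normalized difference; the
original green-band NDWI, (Green − NIR)/(Green + NIR), is exposed as
`ndwi_variant="green"`. The two variants are *not* equivalent — under
the green variant, open water raises rather than lowers the index — and
which one an analysis intends is not always decidable from its printed
equation, so both are kept and the choice is logged. Whether "SWIR"
means the 1.6 µm or 2.2 µm band is a reader-level mapping decision: the
pipeline consumes whatever band the scene provides in its SWIR slot.

Zero denominators and cloud-masked pixels produce *invalid* pixels
(NaN + mask), never ±∞ or a silent 0, because the downstream maximum
composites must be able to ignore them.

## Compositing

Cloud handling is two-layered, mirroring operational practice: a scene
is discarded outright when its cloud-mask fraction is ≥ 10% (the filter
is strictly `<`), and on surviving scenes each cloud-masked pixel is
excluded from the per-pixel reduction. Composites are per-pixel maxima
over the six calendar bimonths (Jan–Feb … Nov–Dec; the period origin is
configurable) and carry a per-pixel coverage count; a composite pixel
is invalid iff no valid observation contributed. Partial years are
accepted — periods without any scene are flagged in
`missing_periods` — but a year with no scenes at all is an error. No
gap-filling, smoothing or harmonic fitting is applied.

## Mangrove extraction and species classification

Mangrove is separated from everything else by thresholding the annual
maximum CMRI. The threshold is deliberately a visible parameter: its
default of 0.35 sits halfway between the highest non-mangrove seasonal
maximum (≈ 0.2, dry-season-peaking terrestrial vegetation) and the
lowest mangrove one (≥ 0.5) in the synthetic study conditions, and an
automatic Otsu split of the annual-max histogram is available when no
calibrated value exists. The boundary convention is ≥.

Species-group separation rests on phenology: the feature vector is the
year's six bimonthly composite values, classified by a Random-Forests
ensemble of 2000 trees (seeded, out-of-bag accuracy logged). Pixels
with cloud gaps keep NaN in the missing periods — the forest's trees
route missing values rather than dropping the pixel, so a single cloudy
bimonth never erases a pixel's record. Species labels are emitted only
inside the mangrove mask; this is asserted on every product.

Per-period class maps gate the species label by that period's
composite: a pixel counts as mangrove in period t iff it belongs to the
annual mask *and* its period-t CMRI reaches the extraction threshold.
This produces a genuine bimonthly presence series (a pixel cleared in
June stops counting from July's period onward) while the species
assignment itself uses the full-year evidence. The annual product is a
majority vote over the six period labels; ties — possible with an even
number of periods — go to the class with the higher mean ensemble
probability for that pixel, which is deterministic and uses the same
phenological evidence as the vote.

## Accumulated-anomaly change detection

Let x_t ∈ {0, 1} be the bimonthly mangrove indicator and x̄ the mean of
x over the baseline year's periods. The statistic is

    A = Σ_{t after baseline} (x_t − x̄),

with invalid periods skipped and excluded from the period count n, so
|A| ≤ n always. A pixel behaving as in its baseline accumulates exactly
0; clearance of a baseline mangrove pixel accumulates −1 per period
(−6 over a full year); colonization +1. Loss is called at A ≤ −θ and
gain at A ≥ +θ with θ = 4 periods (≈ 8 months) by default: large enough
that a one-period flicker (|A| = 1) or a two-period seasonal excursion
can never be called, small enough that a mid-year clearance is caught
within the same year. A deviation-free alternative that accumulates
|x_t − x_{t−1}| (instability rather than signed change) is available
for sensitivity checks.

The signed-deviation form is one concrete reading of "differences
between each bimonthly classification and the annual average": taken
within a single year that sum is identically zero, so the baseline
year's mean is used as the reference, which preserves the intended
behavior (cumulative growth wherever cover genuinely changes) and
yields a sign for gain vs. loss.

## Vectorization and area accounting

Connected components use rook (4-) connectivity by default so diagonal
pixel chains do not inflate patch size; queen (8-) connectivity is a
switch. Component polygons are exact unions of pixel squares, so total
polygon area per class equals pixel count × pixel area before
filtering — this conservation is tested, not assumed. The minimum
mappable area is 0.2 ha, i.e. exactly 20 pixels of 10 m, boundary
inclusive: a 20-pixel patch stays, a 19-pixel patch is removed (and the
removed area logged). Areas are computed in the raster's projected CRS
with no geodesic correction; geographic (degree-unit) rasters are
rejected. Every summary table ends in a totals row that is exactly the
column sums. (The published per-state table this layout mirrors prints
a gain total of 208.8 ha against per-state gains summing to 188.8 ha;
this package's totals are always column sums, so that discrepancy is
documented here rather than reproduced.)

## Accuracy assessment

The error matrix is fixed as rows = reference, columns = mapped; for
class c, user's accuracy = diag/column total and producer's =
diag/row total, commission = 100 − user's, omission = 100 − producer's,
overall accuracy = 100·trace/n, and κ = (p_o − p_e)/(1 − p_e) with
p_e = Σ row·col/n². Because two-class matrices are nearly symmetric and
published tables sometimes swap the user's/producer's rows, reports
print both orientations. Metrics are reported at one decimal and at
integer percent. Validation points falling on non-mangrove or invalid
pixels are excluded with a logged count; the synthetic sampler draws
equal numbers per species group (240/240 by default) and only inside
truth patches of ≥ 4 pixels (≈ 400 m², the minimum footprint
interpretable on a validation photograph).

The published 480-point matrix used in tests and the acceptance script
is ingested from its printed *marginals* (row totals 230/250, diagonal
216/225, n = 480), because the printed off-diagonal cell (23) is
inconsistent with its own row total and with every derived metric; the
marginal-consistent cell (25) reproduces all seven published figures
exactly.

## The synthetic study conditions

The generator replaces the satellite archive with scenes whose only
physically meaningful quantity is the CMRI itself. Band synthesis
fixes Red and SWIR per class and solves the CMRI equation for NIR
(a quadratic with a closed-form root, polished by two Newton steps to
machine precision), so `compute_cmri` on a rendered scene recovers the
class's bimonthly profile mean plus zero-mean Gaussian noise exactly in
the sd → 0 limit. No atmospheric, BRDF or sensor physics, no orbit
geometry, and no band-resolution resampling are emulated — passing
tests demonstrate the *pipeline logic* (masking, compositing, feature
construction, thresholds, bookkeeping), not robustness to real
radiometric artifacts.

Fixed study conditions (chosen once, not tuned per run):

| parameter | default | rationale |
|---|---|---|
| landscape | 256×256 px at 10 m, quantile-cut smoothed Gaussian field | contiguous coast-like patches; class fractions exact to rounding |
| class fractions | water .30, R. mangle .20, other mangrove .20, terrestrial .20, bare .10 | mangrove-rich coastal strip |
| phenology means | mangroves in [0.55, 0.80] with opposed seasonal cycles; terrestrial ≤ 0.20; bare ≈ 0.09; water ≈ −0.62 | separable at the 0.35 threshold; the two mangrove 6-vectors are 0.36 apart (Bayes error ≈ 2·10⁻⁴ at sd 0.05) |
| noise sd | 0.05 (mangroves), 0.02–0.04 (others) | accuracy regime comparable to a ~90%-OA real assessment while keeping recovery checks meaningful |
| scenes | 5 per bimonth, cloud fraction ~ U(0, 0.12) as contiguous bright blobs | arid-coast cloud regime; the <10% filter removes ≈ 1/6 of scenes, leaving an empty bimonth with probability ≪ 1%, which raises a clear error |
| change events | 2 loss + 1 gain patches of 60 px, dated 1 Jan of the final year | whole-year persistence, so truth anomaly = ±6 |
| training / validation | 500 / 240 pixels per species group, truth-derived | mirrors an equal-proportion validation design |

The phenological trajectories are plausible fixtures for an arid-region
coast, not reconstructions of measured curves — no published curve
exists to reconstruct.

## Numerical and degenerate-input choices

Quadratic root selection in the band inversion always takes the smaller
positive root (the branch that exists for every attainable CMRI value);
sampled index values are clipped to the invertible range of the class's
band constants, a correction with probability < 10⁻³ under the default
profiles. Composite maxima are computed with −∞ sentinels so NaN never
propagates. The minimum-mappable filter compares areas with a 10⁻⁹ ha
slack against float rounding. Empty filter results warn rather than
raise; empty validation sets, single-class training sets, unsatisfiable
persistence thresholds and uncovered years raise with the offending
quantity named. All randomness flows from explicit seeds
(`numpy.random.default_rng`); reruns with the same config and seed are
byte-identical in their CSV outputs.

## Problem sizes

Default runs use a 256×256 landscape, two years of five scenes per
bimonth, a 2000-tree ensemble on 1000 training pixels, and 480
validation points; a full pipeline run completes in well under a minute
on one CPU. These sizes were chosen so the whole chain — including the
parameter-recovery checks — runs comfortably on a laptop; nothing in
the implementation assumes them.

## Known limitations

- The CMRI threshold (0.35) and the persistence threshold (4 periods)
  are calibrated on the synthetic conditions; real deployments should
  re-calibrate against reference sites or use the Otsu mode.
- Change is binary mangrove gain/loss; transitions between the two
  species groups are visible in the per-year class maps but are not
  called as change.
- The accuracy module implements the traditional matrix only — no
  area-weighted (Olofsson-style) estimators or accuracy variances.
- Scene ingestion expects the package's own TIFF layout (bands + mask +
  JSON-tagged georeferencing); external imagery must be converted to it.
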