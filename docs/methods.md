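# Methods

## Imaging model and what the generator emulates

The package analyses the standard three-channel high-content assay for
macrophage vacuolation: a nuclear dye identifies nucleated cells, a
whole-cell dye delineates the cell body and leaves vacuoles as dark holes
("negative staining"), and a phospholipid dye reports intracellular
phospholipid load.  Images are 16-bit single-plane rasters at a default
calibration of 0.325 µm/px, so a ~600 µm² macrophage spans ~85 px across a
1024×1024 field.

The synthetic generator renders each cell as a mildly eccentric ellipse
(aspect ratio uniform in [1.0, 1.2], random orientation) containing a
concentric nuclear ellipse and circular vacuoles.  All shapes are placed at
sub-pixel positions, which makes the *expected* rasterized pixel area equal
the analytic area (a pixel center is covered with probability equal to the
local area overlap); ground truth is recorded from the rasterized masks
themselves, so a noiseless render is exactly reproducible by pixel counting
and the truth tables agree with the rendered images to the pixel.

Channel intensities are piecewise-constant class means plus independent
Gaussian pixel noise within each class and an additive Gaussian read noise
over the frame, clipped to [0, 65535].  Defaults: background 2,000,
vacuole interior 8,000, stained cytoplasm 30,000, nucleus 22,000, read
noise SD 1,500.  These place the fixed vacuole-detection threshold of
19,000 more than 3σ from both the vacuole-interior and cytoplasm
populations, so detection of a planted vacuole is essentially
deterministic; presets are validated against exactly this separation
invariant.  The whole-cell dye is rendered across the entire cell footprint
(including over the nucleus), as whole-cell masks behave in projection; the
phospholipid dye is rendered uniformly over the cell at a
condition-dependent mean, so a cell's planted integrated signal is
(mean − background) × area.

### Vacuole placement

Vacuole radii are drawn Normal(µ, σ) (truncated at 1.3 px so every vacuole
survives the 4 px minimum-area filter) and placed largest-first by
rejection sampling on the pixel grid, with a one-pixel exclusion ring
around the nucleus and every placed vacuole, and a one-pixel erosion
inside the cell boundary.  The exclusion rings guarantee rasterized
vacuoles are mutually 8-disconnected and never touch the cell edge, so the
planted count is exactly the count of sub-threshold connected components.
When random sampling fails, placement falls back to an exhaustive scan of
all remaining integer-center pockets; only when no pocket exists is the
realized count reduced (placement saturation, recorded in the truth table
via both requested and realized counts).  The per-cell count is negative
binomial (dispersion k, default 60; `None` gives Poisson) with its mean
scaled by the cell's relative area — larger cells carry proportionally more
vacuoles, which keeps the vacuole-occupied fraction stable across the cell
size distribution and keeps small cells away from packing saturation.
Residual saturation loss at the untreated density (72 vacuoles covering 29%
of the cell) is ~2–3% of the count.

### Presets

Each (compound, concentration, recovery time) condition is a preset over:
cell area mean/SD (µm²), nucleus area fraction, vacuole count mean and
dispersion, vacuole radius mean/SD (µm), and the channel intensity means.
The vacuole radius is *derived*: given a target occupied fraction f, count
n and cell area A, the mean radius solves n·π(µ² + σ²) = f·A.  The shipped
registry encodes the study conditions:

| condition | cell area | vacuoles/cell | occupied fraction | phospholipid (net, ×baseline) |
|---|---|---|---|---|
| untreated R0/R24/R48 | 600/610/620 | 72/76/81 | 29/28/27% | 1× |
| amiodarone 5 µM R0 | 600 | 40 (=72/1.8) | 29% | 2.0× |
| amiodarone 10 µM R0 | 600 | 27.7 (=72/2.6) | 29% | 2.5× |
| amiodarone 10 µM R48 | 620 | 79 (recovered) | 27% | 2.9× |
| staurosporine 1 µM (all) | 72 (12%) | 9 | 9.8% | 1× |
| fluticasone 50 µM R0/R24/R48 | as untreated | as untreated | as untreated | 1×/2.6×/1.8× |
| salbutamol (both doses) | as untreated | as untreated | as untreated | 1× |

Two consequences of these baselines are worth stating explicitly. First,
with 72 vacuoles jointly covering 29% of the cell, the mean *single*
vacuole necessarily covers 29%/72 ≈ 0.40% of the cell area — any larger
per-vacuole share would be arithmetically incompatible with the count and
the total.  Second, the staurosporine preset's condensed nucleus
(18% of a 72 µm² cell ≈ 13 µm²) sets the scale for the segmentation QC
floors below.

Choices not pinned by the encoded study conditions: per-cell count
dispersion k = 60 (mild overdispersion beyond Poisson; the replicate-level
SEMs this produces are of the order seen in well-replicated HCS runs),
vacuole radius SD 0.08 µm, nucleus area fraction 0.12 (0.18 for the
apoptotic preset, whose nuclei condense while the cell shrinks faster),
untreated net phospholipid signal 3,000 grey/px.  Amiodarone intermediate
(R24) values interpolate between the acute effect and recovery; its acute
phospholipid elevation (2.0×/2.5×) reflects accumulation already under
exposure, rising slightly during wash-out to the measured 2.9× at R48.

### What the generator does *not* emulate

No optics PSF or focus blur, no photobleaching, no cell–cell contact or
confluence (cells are placed without overlap), no debris or staining
artifacts, no spatial intensity gradients, no 3D structure, and the
phospholipid stain is spatially uniform within the cell rather than
punctate.  Passing recovery tests therefore demonstrates that the
*measurement chain* is unbiased and correctly calibrated on images whose
ground truth is known — not that segmentation would survive heavily
confluent or artifact-laden real fields.

## Segmentation

Nuclei: Gaussian smoothing (σ = 1 px), Otsu threshold, hole filling,
minimum area 5 µm², distance-transform watershed to split touching nuclei
(peak separation ≈ radius of the smallest admissible nucleus).  Cells:
Otsu threshold of the smoothed cytoplasm channel, hole filling (so
vacuoles never perforate the mask), then marker-controlled watershed on the
negated distance transform with the nuclei as seeds; foreground without a
nucleus is discarded, giving a nucleus↔cell bijection.  Otsu is guarded by
a robust background floor (median + 6·1.4826·MAD of the smoothed image):
on a structure-free noise field Otsu would bisect the noise and flood the
frame; the guard returns an empty mask instead.  Thresholds are
configurable fixed-value overrides.

QC filter defaults: drop cells touching a 2 px border margin and cells
under 30 µm².  The floors are set well below the apoptotic population
(cell ≈ 72 ± 10 µm², nucleus ≈ 13 µm²): a filter tuned only to healthy
macrophages (hundreds of µm²) would silently delete the shrunken cells the
assay exists to count.  Ties at watershed boundaries follow the flooding
order of the underlying implementation; all area-based results carry
tolerances that absorb single-pixel boundary differences.

## Vacuole detection and measurement

Within each kept cell, candidate pixels are strictly below the grey
threshold (default 19,000), inside the cell mask and outside its nucleus
(the nuclear region is excluded so that a dim nuclear footprint can never
register as one giant vacuole).  8-connected components under 4 px are
rejected as noise; components touching the cell boundary are rejected as
background bleed-in rather than clipped, so segmentation-edge artifacts
cannot count as vacuoles.  Raw grey levels are used (no background
correction before thresholding).  Phospholipid content per cell is
Σ(channel − background) over the cell mask, background estimated as the
median of all non-cell pixels in the field, and the *integrated* total is
clipped at zero (per-pixel clipping would bias the sum upward);
`phospholipid_mean` is that total divided by the cell's pixel count.

A caveat on threshold monotonicity: the sub-threshold pixel set grows
monotonically with the threshold, but the boundary-discard rule can remove
a component wholesale once it grows into contact with the cell edge, so
total vacuole area is guaranteed monotone only for thresholds below the
stained-cytoplasm intensity — the regime the assay operates in, where the
cell rim stays super-threshold.

## Aggregation and statistics

Per-cell records are averaged per well; condition summaries report the
mean of well means with the SEM taken across independent experiments when
more than one is present (matching a "mean ± SEM of N independent
experiments" design) and across wells otherwise.  All inference runs on
well-level means — testing on individual cells would treat hundreds of
pseudo-replicates as independent.  Each feature gets a two-way ANOVA
(condition × recovery time, type-II, via ordinary least squares) and
two-sample t contrasts of every treated condition against untreated at the
matched time point, Bonferroni-corrected within the per-feature family of
all treated-vs-untreated contrasts; "significant" always means adjusted
p < 0.05.  Designs with fewer than two replicate wells in any cell are
rejected with the deficient cells named.  A built-in null simulation
(`simulate_null_type1`) verifies the contrast path rejects at the nominal
rate.

## Classification and reversibility

The decision list (order: pro_apoptotic → phospholipidosis →
lipid_accumulating → normal) is evaluated at every time point and the
highest-priority non-normal call wins; this lets a phenotype that only
appears after wash-out (the corticosteroid-style late phospholipid rise)
be detected while acute signatures dominate when present.  Thresholds
(2.5× area, 4× vacuole count, 2× and 1.5× phospholipid) live in
configuration; they transcribe the encoded effect sizes with roughly 2×
headroom, since the conditions of interest show 8× area and 2.6–8× count
changes.  The classifier is a pure function of the fold table, the stats
table and the thresholds.

Reversibility per feature: R = 1 − |recovered − baseline| /
|acute − baseline|, with baselines matched to each time point (the
untreated population itself drifts slightly over culture time), clamped to
[0, 1], hence invariant to affine rescaling of the feature.  Verdicts
combine R with the recovered-vs-baseline contrast: reversible
(non-significant and R ≥ 0.8), irreversible (significant and R < 0.2),
partial otherwise; features whose acute contrast was not significant are
not_applicable ("no acute effect" is operationalized by significance,
since exact equality of sample means never occurs).  The 0.8/0.2 cut-offs are a package construct — recovery claims in
this assay family rest on non-significance, with no published equivalence
margin — and are configurable at the API level.

## Determinism and problem sizes

Every stochastic step flows from one integer seed; plates derive one
independent RNG stream per (well, field) keyed by position, so outputs are
byte-identical across runs and invariant to analysis order.
`scripts/acceptance.py` uses desk-scaled plates — 3 simulated experiments
× 2 wells × 5 fields of 512×512 px at ~10 cells/field (~300 cells per
condition) — which holds the Monte-Carlo error of each reported mean near
1% while keeping a full run to a couple of minutes on one CPU; the test
suite uses the same generator at smaller sizes.

## Known limitations

- The vendor toolchain this measurement contract mirrors is closed; the
  package reproduces the *outputs* (nucleated-cell morphometry, negative-
  stain vacuole counts at a fixed 16-bit grey threshold), not the vendor's
  internal algorithms, and the 19,000 threshold presumes a 16-bit scale.
- The classifier covers exactly the four encoded signatures; intermediate
  phenotypes (e.g. a mild apoptotic response below the 2.5×/4× thresholds
  with a significant vacuole-fraction drop) fall through to `normal`.
- Phospholipid quantification is an intensity proxy; absolute grey·px
  values are only meaningful relative to a same-plate baseline, which is
  why fold changes are the reported unit.
- Realized vacuole counts can fall a few percent below the preset mean in
  the densest presets (placement saturation); truth tables record both
  requested and realized counts so the effect is measurable.
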