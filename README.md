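# foamquant

High-content image analysis of **foamy alveolar-macrophage phenotypes**:
per-cell vacuole morphometry and phospholipid quantification from
three-channel fluorescence images, rule-based phenotype classification, and
drug wash-out reversibility analysis — validated end-to-end against a
built-in synthetic image generator with per-cell ground truth.

## The problem

Inhaled-drug candidates are frequently abandoned when pre-clinical studies
show alveolar macrophages turning "foamy" — a highly vacuolated cytoplasm.
That single qualitative observation hides very different biology: a
phospholipidosis response (cationic amphiphilic drugs such as amiodarone
driving phospholipid accumulation), early apoptosis (e.g. staurosporine),
or a benign adaptive change that resolves once the stimulus is removed.
High-content imaging can tell these apart quantitatively: stain nuclei
(Hoechst-type dye), the whole cell body (cytoplasm mask dye) and
phospholipids (LipidTox-type dye), image each well at 40×, and measure
every cell.

`foamquant` implements that measurement chain for 16-bit, three-channel
field images:

1. **Segmentation** — nuclei by thresholding + distance-transform watershed;
   cells by marker-controlled watershed of the hole-filled cytoplasm
   foreground, seeded on nuclei, so only nucleated cells are measured.
2. **Vacuole detection by negative staining** — vacuoles are 8-connected
   components of cytoplasm-channel pixels *below* a fixed grey threshold
   (default **19,000**) inside the cell, excluding the nucleus; components
   smaller than 4 px or touching the cell boundary are rejected as noise.
3. **Per-cell features** — cell/nucleus area (µm²), vacuole count *N*,
   total vacuole area *A_v*, vacuole-occupied fraction *A_v / A_cell*, mean
   single-vacuole fraction, and background-subtracted integrated
   phospholipid intensity Σ(I − median background).
4. **Statistics** — per-well means (never per-cell pseudo-replication),
   two-way ANOVA (condition × recovery time) and Bonferroni-corrected
   treated-vs-untreated contrasts at α = 0.05.
5. **Phenotype calls** — a fixed decision list over fold changes:
   *pro_apoptotic* (cell area ↓ ≥2.5×, vacuoles ↓ ≥4×), *phospholipidosis*
   (vacuole count changed, occupied fraction unchanged, phospholipid
   ↑ ≥2×), *lipid_accumulating* (only phospholipid ↑ ≥1.5×), else *normal*.
6. **Reversibility** after 24/48 h wash-out — per feature,
   R = 1 − |recovered − baseline| / |acute − baseline| (clamped to [0, 1]),
   combined with the recovered-vs-baseline contrast: *reversible*
   (non-significant, R ≥ 0.8), *irreversible* (significant, R < 0.2),
   *partial*, or *not_applicable* when there was no acute effect.

Because no public image set exists for this assay, the package ships a
**synthetic plate generator** (`foamquant.synthgen`) whose presets encode
the published phenotype signatures — untreated macrophages with ~72
vacuoles/cell covering ~29% of a ~600 µm² cell; amiodarone's
fewer-but-larger vacuoles (1.8× / 2.6× fewer at 5 / 10 µM) with persistent
phospholipid accumulation (2.9× at 48 h wash-out); staurosporine's collapse
to 12% cell area with 9 vacuoles — and emits exact per-cell ground truth, so
every stage of the pipeline is testable without real data.

## Worked example

```python
from foamquant import (PlateLayout, simulate_and_analyze, compute_stats,
                       fold_changes, classify_all, reversibility)

conditions = ([("untreated", 0.0, r) for r in (0, 24, 48)]
              + [("amiodarone", 10.0, r) for r in (0, 24, 48)])
layout = PlateLayout.build(conditions, n_experiments=3,
                           wells_per_condition=3, fields_per_well=2)
records, summary = simulate_and_analyze(layout, rng_seed=7,
                                        cells_per_field=8, shape=(512, 512))

acute = records[(records.compound == "amiodarone") & (records.recovery_h == 0)]
base = records[(records.compound == "untreated") & (records.recovery_h == 0)]
print(f"untreated: {base.n_vacuoles.mean():.1f} vacuoles/cell, "
      f"{100*base.vacuole_area_fraction.mean():.1f}% of cell area")
print(f"amiodarone 10 uM (acute): {acute.n_vacuoles.mean():.1f} vacuoles/cell, "
      f"{100*acute.vacuole_area_fraction.mean():.1f}% of cell area")

stats = compute_stats(records)
folds = fold_changes(summary)
print(f"phenotype: {classify_all(folds, stats)[0].label}")
for _, r in reversibility(summary, stats, "amiodarone", 10.0,
                          recovered_at=48).iterrows():
    print(f"  {r.feature}: {r.verdict}")
```

prints

```
untreated: 69.3 vacuoles/cell, 28.5% of cell area
amiodarone 10 uM (acute): 26.8 vacuoles/cell, 28.2% of cell area
phenotype: phospholipidosis
  cell_area: not_applicable
  n_vacuoles: reversible
  vacuole_area_fraction: not_applicable
  phospholipid_total: irreversible
```

i.e. the drug leaves cell size and the vacuole-occupied fraction untouched
while cutting the vacuole count ~2.6× (fewer but larger vacuoles) and
accumulating phospholipid — the phospholipidosis signature; after 48 h
wash-out the morphometry has returned to baseline but the phospholipid has
not.

## Command line

```bash
foamquant generate --layout plate.yaml --seed 7 --out run/   # TIFFs + truth.csv
foamquant analyze  --images run/images --layout plate.yaml --out run/
foamquant classify --out run/                                # stats + report
foamquant all      --layout plate.yaml --seed 7 --out run/   # all of the above
```

`analyze` writes `cells.csv` (one row per kept cell) and `summary.csv`
(mean ± SEM per condition over replicate wells/experiments); `classify`
adds ANOVA/contrast tables, fold changes, phenotype calls with rule traces,
and a reversibility report.  Every run logs a provenance header (config
hash, seed, library versions) and per-field QC counts.

## Layout files

Plates are described in YAML: a list of wells with `compound`,
`concentration_uM`, `recovery_h` (0, 24 or 48 h of stimulus-free recovery
after a 24 h exposure), and `experiment` (independent replicate id), plus
`fields_per_well` (default 15 fields, ~500–1500 cells/well).  A plate with
treated wells must contain at least one untreated control well.
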