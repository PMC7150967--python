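import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from _oracle import flood_fill_vacuoles
from foamquant.segment import LabelMask, SegmentationResult, segment_field
from foamquant.synthgen import simulate_field
from foamquant.vacuoles import (
    VacuoleParams,
    aggregate,
    detect_vacuoles,
    measure_cell,
    measure_field,
)


def _square_cell_seg(size=20, ps=1.0):
    """A 10x10 cell with a 2x2 nucleus, as a ready-made segmentation."""
    cells = np.zeros((size, size), np.int32)
    cells[5:15, 5:15] = 1
    nuclei = np.zeros_like(cells)
    nuclei[6:8, 6:8] = 1
    return SegmentationResult(
        nuclei=LabelMask(nuclei, ps), cells=LabelMask(cells, ps), kept_labels=[1],
        qc_flags={1: ["kept"]},
    )


def test_uniformly_bright_cytoplasm_has_no_vacuoles():
    seg = _square_cell_seg()
    cyto = np.full((20, 20), 30_000, np.uint16)
    det = detect_vacuoles(cyto, seg)
    assert len(det.table) == 0


def test_shape_mismatch_is_an_error():
    seg = _square_cell_seg()
    with pytest.raises(ValueError, match="shape"):
        detect_vacuoles(np.zeros((10, 10), np.uint16), seg)


def test_boundary_touching_dark_component_is_discarded():
    seg = _square_cell_seg()
    cyto = np.full((20, 20), 30_000, np.uint16)
    cyto[5:8, 5:8] = 1_000  # dark patch in the cell corner -> touches outside
    cyto[10:12, 10:12] = 1_000  # interior dark patch -> a true vacuole
    det = detect_vacuoles(cyto, seg)
    assert len(det.table) == 1
    assert det.table["area_px"].iloc[0] == 4


def test_min_area_filter_drops_speckles():
    seg = _square_cell_seg()
    cyto = np.full((20, 20), 30_000, np.uint16)
    cyto[10, 10] = 1_000  # single-pixel speckle
    assert len(detect_vacuoles(cyto, seg, VacuoleParams(min_vacuole_area=4)).table) == 0
    assert len(detect_vacuoles(cyto, seg, VacuoleParams(min_vacuole_area=1)).table) == 1


def test_nucleus_region_is_excluded_from_the_search():
    seg = _square_cell_seg()
    cyto = np.full((20, 20), 30_000, np.uint16)
    cyto[6:8, 6:8] = 1_000  # dark nucleus footprint only
    assert len(detect_vacuoles(cyto, seg).table) == 0


def test_exact_fraction_arithmetic():
    """100-px cell with one 10-px vacuole at 1 µm/px -> fraction 0.10."""
    seg = _square_cell_seg(ps=1.0)
    cyto = np.full((20, 20), 30_000, np.uint16)
    cyto[10:12, 9:14] = 1_000  # 2x5 = 10 px
    det = detect_vacuoles(cyto, seg)
    phos = np.full((20, 20), 500, np.uint16)
    rec = measure_cell(1, seg, det, phos)
    assert rec.cell_area == pytest.approx(100.0)
    assert rec.vacuole_area_fraction == pytest.approx(0.10)
    assert rec.n_vacuoles == 1
    assert rec.mean_single_vacuole_fraction == pytest.approx(0.10)


def test_phospholipid_at_background_measures_zero():
    seg = _square_cell_seg()
    det = detect_vacuoles(np.full((20, 20), 30_000, np.uint16), seg)
    phos = np.full((20, 20), 2_000, np.uint16)
    rec = measure_cell(1, seg, det, phos)
    assert rec.phospholipid_total == 0.0
    assert rec.phospholipid_mean == 0.0


def test_measure_cell_unknown_label_raises():
    seg = _square_cell_seg()
    det = detect_vacuoles(np.full((20, 20), 30_000, np.uint16), seg)
    with pytest.raises(KeyError):
        measure_cell(7, seg, det, np.zeros((20, 20), np.uint16))


def test_pipeline_matches_flood_fill_oracle_on_noisy_field(small_preset):
    """Per-cell counts/areas equal an independent BFS flood fill exactly."""
    img, _ = simulate_field(small_preset, 4, 77, shape=(300, 300))
    seg = segment_field(img)
    det = detect_vacuoles(img.cytoplasm, seg)
    for lab in seg.kept_labels:
        oracle = flood_fill_vacuoles(
            img.cytoplasm, seg.cells.labels == lab, seg.nuclei.labels == lab
        )
        mine = sorted(det.table.loc[det.table["cell_label"] == lab, "area_px"])
        assert mine == oracle


@settings(
    max_examples=15,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
@given(seed=st.integers(0, 10_000))
def test_threshold_monotonicity(seed, small_preset):
    """Raising the grey threshold never decreases any cell's vacuole area.

    Holds for thresholds inside the assay's design band, i.e. below the
    stained cytoplasm intensity: the cell rim then stays super-threshold, so
    sub-threshold pixel sets grow monotonically without a component ever
    merging into the discarded boundary-touching class.
    """
    img, _ = simulate_field(small_preset, 2, seed, shape=(220, 220))
    seg = segment_field(img)
    for lab in seg.kept_labels:
        prev = -1.0
        for thr in (6_000, 12_000, 19_000, 21_000):
            det = detect_vacuoles(
                img.cytoplasm, seg, VacuoleParams(grey_threshold=thr, min_vacuole_area=1)
            )
            area = float(det.table.loc[det.table["cell_label"] == lab, "area_px"].sum())
            assert area >= prev
            prev = area


def test_record_invariants_on_synthetic_field(small_preset):
    img, _ = simulate_field(small_preset, 6, 13, shape=(300, 300))
    rec = measure_field(img, segment_field(img))
    assert ((rec["vacuole_area_fraction"] >= 0) & (rec["vacuole_area_fraction"] < 1)).all()
    np.testing.assert_allclose(
        rec["mean_single_vacuole_fraction"] * rec["n_vacuoles"],
        rec["vacuole_area_fraction"],
        atol=1e-12,
    )
    zero = rec["n_vacuoles"] == 0
    assert (rec.loc[zero, "vacuole_area_fraction"] == 0).all()


def _records(values_by_well):
    rows = []
    for (well, exp), vals in values_by_well.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "well": well, "experiment": exp, "compound": "untreated",
                    "concentration_uM": 0.0, "exposure_h": 24, "recovery_h": 0,
                    "cell_id": i, "cell_area": v, "nucleus_area": v / 10,
                    "n_vacuoles": 1, "total_vacuole_area": v / 5,
                    "vacuole_area_fraction": 0.2, "mean_single_vacuole_fraction": 0.2,
                    "phospholipid_total": v * 2, "phospholipid_mean": 2.0,
                }
            )
    return pd.DataFrame(rows)


class TestAggregate:
    def test_single_cell_single_well_sem_is_nan(self):
        summary = aggregate(_records({("A01", 1): [600.0]}))
        assert summary["cell_area_mean"].iloc[0] == 600.0
        assert np.isnan(summary["cell_area_sem"].iloc[0])

    def test_identical_replicate_wells_have_zero_sem(self):
        vals = [500.0, 700.0]
        summary = aggregate(
            _records({("A01", 1): vals, ("A02", 2): vals, ("A03", 3): vals})
        )
        assert summary["cell_area_mean"].iloc[0] == 600.0
        assert summary["cell_area_sem"].iloc[0] == 0.0
        assert summary["n_experiments"].iloc[0] == 3
        assert summary["n_cells"].iloc[0] == 6

    def test_sem_across_experiments_matches_closed_form(self):
        summary = aggregate(
            _records({("A01", 1): [500.0], ("A02", 2): [600.0], ("A03", 3): [700.0]})
        )
        expected = np.std([500.0, 600.0, 700.0], ddof=1) / np.sqrt(3)
        assert summary["cell_area_sem"].iloc[0] == pytest.approx(expected)

    def test_missing_metadata_is_an_error(self):
        with pytest.raises(ValueError, match="metadata"):
            aggregate(_records({("A01", 1): [1.0]}).drop(columns=["experiment"]))
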