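"""End-to-end analysis: fields -> per-cell records -> condition summaries."""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd

from .segment import SegmentationParams, SegmentationResult, segment_field
from .synthgen import FieldImage, PlateLayout, simulate_plate
from .vacuoles import VacuoleParams, aggregate, detect_vacuoles, measure_field

__all__ = ["analyze_field", "analyze_fields", "simulate_and_analyze"]

log = logging.getLogger("foamquant")


def analyze_field(
    img: FieldImage,
    seg_params: SegmentationParams | None = None,
    vac_params: VacuoleParams | None = None,
) -> tuple[pd.DataFrame, SegmentationResult]:
    """Segment one field, detect vacuoles, and measure every kept cell."""
    seg = segment_field(img, seg_params)
    det = detect_vacuoles(img.cytoplasm, seg, vac_params)
    records = measure_field(img, seg, det)
    n_dropped = len(seg.qc_flags) - len(seg.kept_labels)
    log.debug(
        "field %s/f%02d: %d cells kept, %d dropped by QC, %d vacuoles",
        img.well_id, img.field_index, len(seg.kept_labels), n_dropped,
        len(det.table),
    )
    return records, seg


def analyze_fields(
    fields: Iterable[FieldImage],
    seg_params: SegmentationParams | None = None,
    vac_params: VacuoleParams | None = None,
    layout: PlateLayout | None = None,
) -> pd.DataFrame:
    """Analyze many fields into one per-cell table (layout metadata merged)."""
    frames = []
    for img in fields:
        records, _ = analyze_field(img, seg_params, vac_params)
        frames.append(records)
    if not frames:
        raise ValueError("no fields found to analyze")
    df = pd.concat(frames, ignore_index=True)
    if layout is not None:
        df = df.merge(layout.to_frame().drop(columns=["fields_per_well"]),
                      on="well", how="left")
    return df


def simulate_and_analyze(
    layout: PlateLayout,
    rng_seed: int,
    preset_map: Mapping | None = None,
    cells_per_field: int = 35,
    shape: tuple[int, int] = (1024, 1024),
    seg_params: SegmentationParams | None = None,
    vac_params: VacuoleParams | None = None,
    with_truth: bool = False,
):
    """Simulate a plate in memory and analyze it field by field.

    Returns ``(records, summary)`` or ``(records, summary, truth)`` when
    ``with_truth`` is set; records carry the layout's condition metadata.
    """
    from .synthgen import truth_to_frame

    frames, truths = [], []
    meta = layout.to_frame().drop(columns=["fields_per_well"])
    for well, img, cells in simulate_plate(
        layout, rng_seed, preset_map, cells_per_field, shape
    ):
        records, _ = analyze_field(img, seg_params, vac_params)
        frames.append(records)
        if with_truth:
            truths.append(truth_to_frame(cells, well.well, img.field_index))
    records = pd.concat(frames, ignore_index=True).merge(meta, on="well", how="left")
    summary = aggregate(records)
    if with_truth:
        truth = pd.concat(truths, ignore_index=True).merge(meta, on="well", how="left")
        return records, summary, truth
    return records, summary
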