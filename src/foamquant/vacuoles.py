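"""Negative-stain vacuole detection and per-cell morphometry.

Vacuoles are 8-connected components of cytoplasm-channel pixels strictly
below a fixed grey threshold (default 19,000 on the 16-bit scale) inside a
cell's mask, excluding its nucleus.  Components smaller than a minimum pixel
area are treated as noise; components touching the cell boundary are treated
as background bleeding in rather than intracellular vacuoles and discarded.

Per-cell features: cell and nucleus area (µm²), vacuole count, total vacuole
area and its fraction of the cell area, the mean single-vacuole fraction
(mean over vacuoles of vacuole area / cell area), and background-subtracted
phospholipid intensity (integrated and per-pixel mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segment import SegmentationResult
from .synthgen import FieldImage

__all__ = [
    "VacuoleParams",
    "CellRecord",
    "VacuoleDetection",
    "detect_vacuoles",
    "measure_cell",
    "measure_field",
    "aggregate",
    "FEATURES",
]

_EIGHT = np.ones((3, 3), bool)

#: Per-cell feature columns carried through aggregation and statistics.
FEATURES = [
    "cell_area",
    "nucleus_area",
    "n_vacuoles",
    "total_vacuole_area",
    "vacuole_area_fraction",
    "mean_single_vacuole_fraction",
    "phospholipid_total",
    "phospholipid_mean",
]


@dataclass(frozen=True)
class VacuoleParams:
    """Detection parameters on the 16-bit grey scale."""

    grey_threshold: float = 19_000.0
    min_vacuole_area: int = 4  # px
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.grey_threshold < 65_535:
            raise ValueError("grey_threshold must lie in (0, 65535)")
        if self.min_vacuole_area < 1:
            raise ValueError("min_vacuole_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _structure(self) -> np.ndarray:
        return _EIGHT if self.connectivity == 8 else ndi.generate_binary_structure(2, 1)


@dataclass
class CellRecord:
    """Measured per-cell feature vector (areas in µm², intensity in grey)."""

    well: str
    field: int
    cell_id: int
    cell_area: float
    nucleus_area: float
    n_vacuoles: int
    total_vacuole_area: float
    vacuole_area_fraction: float
    mean_single_vacuole_fraction: float
    phospholipid_total: float
    phospholipid_mean: float


@dataclass
class VacuoleDetection:
    """Field-wide vacuole labels and their per-vacuole table."""

    labels: np.ndarray  # int32 raster; one positive id per vacuole
    table: pd.DataFrame  # columns: vacuole_id, cell_label, area_px


def detect_vacuoles(
    cytoplasm_channel: np.ndarray,
    seg: SegmentationResult,
    params: VacuoleParams | None = None,
) -> VacuoleDetection:
    """Detect vacuoles inside every kept cell of a segmentation."""
    params = params or VacuoleParams()
    cells = seg.cells.labels
    nuclei = seg.nuclei.labels
    if cytoplasm_channel.shape != cells.shape:
        raise ValueError("cytoplasm channel and cell mask shapes differ")

    out = np.zeros(cells.shape, np.int32)
    rows: list[dict] = []
    next_id = 0
    below = cytoplasm_channel < params.grey_threshold
    slices = ndi.find_objects(cells)
    for lab in seg.kept_labels:
        sl = slices[lab - 1]
        if sl is None:
            continue
        # pad the crop so boundary adjacency is evaluated correctly
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(sl, cells.shape)
        )
        cmask = cells[sl] == lab
        cand = below[sl] & cmask & (nuclei[sl] != lab)
        if not cand.any():
            continue
        comp, n = ndi.label(cand, structure=params._structure)
        if n == 0:
            continue
        touches_exterior = ndi.binary_dilation(~cmask, params._structure)
        ids = np.arange(1, n + 1)
        areas = ndi.sum_labels(np.ones_like(comp), comp, ids)
        touching = ndi.maximum(touches_exterior.astype(np.uint8), comp, ids)
        for cid, area, touch in zip(ids, areas, touching):
            if area < params.min_vacuole_area or touch:
                continue
            next_id += 1
            sel = comp == cid
            out[sl][sel] = next_id
            rows.append(
                {"vacuole_id": next_id, "cell_label": lab, "area_px": int(area)}
            )
    table = pd.DataFrame(rows, columns=["vacuole_id", "cell_label", "area_px"])
    return VacuoleDetection(labels=out, table=table)


def estimate_background(
    channel: np.ndarray, cells: np.ndarray
) -> float:
    """Field background level: median of the channel outside all cells."""
    outside = cells == 0
    if not outside.any():
        return 0.0
    return float(np.median(channel[outside]))


def measure_cell(
    cell_label: int,
    seg: SegmentationResult,
    detection: VacuoleDetection,
    phospholipid_channel: np.ndarray,
    background_estimate: float | None = None,
    well: str = "",
    field_index: int = 0,
) -> CellRecord:
    """Assemble the feature vector for one kept cell."""
    if cell_label not in seg.kept_labels:
        raise KeyError(f"cell label {cell_label} is not in the kept set")
    ps2 = seg.pixel_size**2
    cmask = seg.cells.labels == cell_label
    nmask = seg.nuclei.labels == cell_label
    if background_estimate is None:
        background_estimate = estimate_background(
            phospholipid_channel, seg.cells.labels
        )
    vac = detection.table
    mine = vac[vac["cell_label"] == cell_label]
    n_vac = len(mine)
    cell_area = float(cmask.sum()) * ps2
    total_vac = float(mine["area_px"].sum()) * ps2
    fraction = total_vac / cell_area if cell_area > 0 else 0.0
    single = (fraction / n_vac) if n_vac else 0.0
    net = phospholipid_channel[cmask].astype(np.float64) - background_estimate
    total_phos = max(float(net.sum()), 0.0)
    return CellRecord(
        well=well,
        field=field_index,
        cell_id=cell_label,
        cell_area=cell_area,
        nucleus_area=float(nmask.sum()) * ps2,
        n_vacuoles=n_vac,
        total_vacuole_area=total_vac,
        vacuole_area_fraction=fraction,
        mean_single_vacuole_fraction=single,
        phospholipid_total=total_phos,
        phospholipid_mean=total_phos / max(int(cmask.sum()), 1),
    )


def measure_field(
    img: FieldImage,
    seg: SegmentationResult,
    detection: VacuoleDetection | None = None,
    params: VacuoleParams | None = None,
) -> pd.DataFrame:
    """Per-cell measurement table for one field (one row per kept cell)."""
    if detection is None:
        detection = detect_vacuoles(img.cytoplasm, seg, params)
    bg = estimate_background(img.phospholipid, seg.cells.labels)
    ps2 = seg.pixel_size**2
    cells = seg.cells.labels
    nuclei = seg.nuclei.labels
    labels = seg.kept_labels
    if not labels:
        return pd.DataFrame(columns=["well", "field", "cell_id", *FEATURES])
    idx = np.asarray(labels)
    cell_px = ndi.sum_labels(np.ones_like(cells), cells, idx)
    nuc_px = ndi.sum_labels((nuclei > 0).astype(np.float64), cells, idx)
    phos_net = (
        ndi.sum_labels(img.phospholipid.astype(np.float64), cells, idx)
        - bg * cell_px
    )
    counts = np.zeros(len(idx))
    vac_px = np.zeros(len(idx))
    if len(detection.table):
        grp = detection.table.groupby("cell_label")["area_px"].agg(["count", "sum"])
        pos = {lab: i for i, lab in enumerate(labels)}
        for lab, row in grp.iterrows():
            counts[pos[int(lab)]] = row["count"]
            vac_px[pos[int(lab)]] = row["sum"]
    cell_area = cell_px * ps2
    total_vac = vac_px * ps2
    fraction = np.divide(total_vac, cell_area, out=np.zeros_like(total_vac), where=cell_area > 0)
    single = np.divide(fraction, counts, out=np.zeros_like(fraction), where=counts > 0)
    phos_total = np.clip(phos_net, 0.0, None)
    return pd.DataFrame(
        {
            "well": img.well_id,
            "field": img.field_index,
            "cell_id": idx,
            "cell_area": cell_area,
            "nucleus_area": nuc_px * ps2,
            "n_vacuoles": counts.astype(int),
            "total_vacuole_area": total_vac,
            "vacuole_area_fraction": fraction,
            "mean_single_vacuole_fraction": single,
            "phospholipid_total": phos_total,
            "phospholipid_mean": phos_total / np.maximum(cell_px, 1),
        }
    )


_META = ["compound", "concentration_uM", "exposure_h", "recovery_h"]


def aggregate(records: pd.DataFrame, layout=None) -> pd.DataFrame:
    """Condition summaries: well means, then mean ± SEM across replicates.

    ``records`` must carry the condition metadata columns (merged from the
    plate layout during analysis, or pass ``layout`` to merge here).  The SEM
    is taken across independent experiments when more than one is present
    (matching a "mean ± SEM of N independent experiments" design), otherwise
    across wells.  Conditions with zero cells yield a NaN row.
    """
    df = records.copy()
    if layout is not None and "compound" not in df.columns:
        df = df.merge(layout.to_frame(), on="well", how="left")
    missing = [c for c in _META + ["experiment", "well"] if c not in df.columns]
    if missing:
        raise ValueError(f"records lack metadata columns: {missing}")

    well_means = (
        df.groupby(_META + ["experiment", "well"], as_index=False)[FEATURES]
        .mean()
    )
    n_cells = df.groupby(_META, as_index=False).size().rename(columns={"size": "n_cells"})

    def _summarize(g: pd.DataFrame) -> pd.Series:
        out = {}
        n_exp = g["experiment"].nunique()
        exp_means = g.groupby("experiment")[FEATURES].mean()
        for f in FEATURES:
            out[f"{f}_mean"] = g[f].mean()
            if n_exp > 1:
                out[f"{f}_sem"] = float(exp_means[f].std(ddof=1) / np.sqrt(n_exp))
            elif len(g) > 1:
                out[f"{f}_sem"] = float(g[f].std(ddof=1) / np.sqrt(len(g)))
            else:
                out[f"{f}_sem"] = np.nan
        out["n_wells"] = len(g)
        out["n_experiments"] = n_exp
        return pd.Series(out)

    summary = (
        well_means.groupby(_META)
        .apply(_summarize, include_groups=False)
        .reset_index()
        .merge(n_cells, on=_META, how="left")
    )
    return summary
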