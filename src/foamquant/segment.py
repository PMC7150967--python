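"""Nucleus-seeded cell segmentation from the nuclear and cytoplasm channels.

The nuclear dye identifies nucleated cells; the whole-cell cytoplasm stain
delineates the cell body.  Nuclei are thresholded (Otsu by default, with a
robust background guard), split by a distance-transform watershed, and used
as seeds for a marker-controlled watershed over the thresholded cytoplasm
foreground.  Vacuoles appear as dark holes in the cytoplasm channel, so the
foreground is hole-filled before partitioning — a cell's mask is its full
footprint regardless of how vacuolated it is.  Foreground with no nucleus is
discarded, giving a nucleus-cell bijection on the kept labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import relabel_sequential, watershed

from .synthgen import DEFAULT_PIXEL_SIZE, FieldImage

__all__ = [
    "LabelMask",
    "SegmentationResult",
    "SegmentationParams",
    "segment_nuclei",
    "segment_cells",
    "filter_cells",
    "segment_field",
]

_EIGHT = np.ones((3, 3), bool)


@dataclass
class LabelMask:
    """Integer label raster (0 = background) with its pixel calibration."""

    labels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def areas_um2(self) -> dict[int, float]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): float(c) * self.pixel_size**2 for i, c in zip(ids, counts)}


@dataclass
class SegmentationResult:
    nuclei: LabelMask
    cells: LabelMask
    kept_labels: list[int] = field(default_factory=list)
    qc_flags: dict[int, list[str]] = field(default_factory=dict)

    @property
    def pixel_size(self) -> float:
        return self.cells.pixel_size


@dataclass
class SegmentationParams:
    """Tunable segmentation knobs (areas in µm², margins in px)."""

    pixel_size: float = DEFAULT_PIXEL_SIZE
    min_nucleus_area: float = 5.0
    min_cell_area: float = 30.0
    border_margin: int = 2
    smooth_sigma: float = 1.0
    nucleus_threshold: float | None = None  # None -> Otsu
    cell_threshold: float | None = None  # None -> Otsu


def _auto_threshold(smoothed: np.ndarray) -> float | None:
    """Otsu threshold with a robust guard against structure-free fields.

    On a field containing only background noise Otsu bisects the noise and
    floods the frame; requiring the threshold to also exceed the robust
    background level (median + 6 * 1.4826 * MAD) rejects that case.
    """
    lo, hi = float(smoothed.min()), float(smoothed.max())
    if hi - lo < 1e-9:
        return None
    otsu = float(threshold_otsu(smoothed))
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    guard = med + 6.0 * 1.4826 * mad
    thr = max(otsu, guard)
    if thr >= hi:
        return None
    return thr


def _foreground(raster, sigma, threshold):
    sm = gaussian(raster.astype(np.float64), sigma=sigma, preserve_range=True)
    thr = threshold if threshold is not None else _auto_threshold(sm)
    if thr is None:
        return np.zeros(raster.shape, bool)
    return sm > thr


def segment_nuclei(
    nuclear_channel: np.ndarray,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    min_nucleus_area: float = 5.0,
    smooth_sigma: float = 1.0,
    threshold: float | None = None,
) -> LabelMask:
    """Label nuclei; touching nuclei are split by a distance-transform watershed."""
    fg = _foreground(nuclear_channel, smooth_sigma, threshold)
    fg = ndi.binary_fill_holes(fg)
    min_px = max(1, int(round(min_nucleus_area / pixel_size**2)))
    lab, _ = ndi.label(fg, structure=_EIGHT)
    sizes = np.bincount(lab.ravel())
    small = np.flatnonzero(sizes < min_px)
    fg[np.isin(lab, small)] = False
    if not fg.any():
        return LabelMask(np.zeros(nuclear_channel.shape, np.int32), pixel_size)

    dist = ndi.distance_transform_edt(fg)
    # smooth the EDT so boundary-pixelation ripples along a nucleus' ridge
    # cannot seed spurious peaks that would split a single nucleus
    dist_s = ndi.gaussian_filter(dist, sigma=2.0)
    # minimum peak separation ~ radius of the smallest admissible nucleus
    min_dist = max(3, int(round(np.sqrt(min_px / np.pi))))
    peaks = peak_local_max(
        dist_s, min_distance=min_dist, labels=ndi.label(fg, structure=_EIGHT)[0],
        exclude_border=False,
    )
    markers = np.zeros(fg.shape, np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndi.label(markers > 0, structure=_EIGHT)
    lab = watershed(-dist, markers, mask=fg, connectivity=2)
    lab, _, _ = relabel_sequential(lab)
    return LabelMask(lab.astype(np.int32), pixel_size)


def segment_cells(
    cytoplasm_channel: np.ndarray,
    nuclei: LabelMask,
    smooth_sigma: float = 1.0,
    threshold: float | None = None,
) -> LabelMask:
    """Partition the hole-filled cytoplasm foreground among nucleus seeds.

    Vacuoles (negative-stain holes) are filled so they do not perforate the
    cell mask; foreground components containing no nucleus are dropped.
    Returned labels equal the seeding nucleus labels.
    """
    if cytoplasm_channel.shape != nuclei.labels.shape:
        raise ValueError("cytoplasm channel and nuclei mask shapes differ")
    fg = _foreground(cytoplasm_channel, smooth_sigma, threshold)
    fg = ndi.binary_fill_holes(fg)
    if nuclei.n_labels > 0 and not fg.any():
        raise ValueError("cytoplasm channel empty but nuclei are present")
    fg |= nuclei.labels > 0  # a nucleated cell always covers its nucleus
    dist = ndi.distance_transform_edt(fg)
    lab = watershed(-dist, nuclei.labels, mask=fg, connectivity=2)
    return LabelMask(lab.astype(np.int32), nuclei.pixel_size)


def filter_cells(
    nuclei: LabelMask,
    cells: LabelMask,
    min_cell_area: float = 30.0,
    border_margin: int = 2,
) -> SegmentationResult:
    """QC filter: drop border-touching and undersized cells, relabel 1..K.

    Returns a :class:`SegmentationResult` whose ``qc_flags`` records, per
    original label, why it was removed (``border``, ``undersized``,
    ``no_nucleus``) or ``kept``.
    """
    cl = cells.labels
    nl = nuclei.labels
    ps = cells.pixel_size
    h, w = cl.shape
    m = max(0, int(border_margin))
    border = np.zeros_like(cl, bool)
    if m > 0:
        border[:m, :] = border[-m:, :] = True
        border[:, :m] = border[:, -m:] = True
    else:
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True

    min_px = min_cell_area / ps**2
    qc: dict[int, list[str]] = {}
    keep: list[int] = []
    all_labels = np.unique(cl[cl > 0])
    border_labels = set(np.unique(cl[border & (cl > 0)]).tolist())
    sizes = np.bincount(cl.ravel(), minlength=int(cl.max()) + 1)
    nucleated = set(np.unique(cl[(nl > 0) & (cl > 0)]).tolist())
    for lab in all_labels:
        lab = int(lab)
        flags = []
        if lab in border_labels:
            flags.append("border")
        if sizes[lab] < min_px:
            flags.append("undersized")
        if lab not in nucleated:
            flags.append("no_nucleus")
        qc[lab] = flags or ["kept"]
        if not flags:
            keep.append(lab)

    mapping = {old: new for new, old in enumerate(sorted(keep), start=1)}
    lut = np.zeros(int(max(cl.max(), nl.max())) + 1, np.int32)
    for old, new in mapping.items():
        lut[old] = new
    new_cells = lut[cl]
    new_nuclei = lut[nl]
    # clip defensively: a nucleus pixel must lie inside its own cell
    new_nuclei[new_nuclei != new_cells] = 0
    return SegmentationResult(
        nuclei=LabelMask(new_nuclei.astype(np.int32), ps),
        cells=LabelMask(new_cells.astype(np.int32), ps),
        kept_labels=sorted(mapping.values()),
        qc_flags=qc,
    )


def segment_field(
    img: FieldImage, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Full per-field segmentation: nuclei -> cells -> QC filter."""
    p = params or SegmentationParams()
    ps = img.pixel_size or p.pixel_size
    nuclei = segment_nuclei(
        img.nuclear, pixel_size=ps, min_nucleus_area=p.min_nucleus_area,
        smooth_sigma=p.smooth_sigma, threshold=p.nucleus_threshold,
    )
    cells = segment_cells(
        img.cytoplasm, nuclei, smooth_sigma=p.smooth_sigma, threshold=p.cell_threshold
    )
    return filter_cells(
        nuclei, cells, min_cell_area=p.min_cell_area, border_margin=p.border_margin
    )
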