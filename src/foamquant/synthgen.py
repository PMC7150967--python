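"""Synthetic three-channel field images of macrophage populations.

Cells are rendered as mildly eccentric ellipses containing a nuclear ellipse
and a set of circular vacuoles planted strictly inside the cytoplasm (the
cell minus its nucleus).  The cytoplasm dye stains the whole cell body;
vacuoles appear as dark holes in that channel ("negative staining"), the
nuclear dye stains nuclei only, and the phospholipid dye stains the whole
cell at a condition-dependent level.  All shapes are rasterized at sub-pixel
positions so expected pixel areas equal the analytic areas, and the ground
truth recorded per cell is taken from the rasterized masks themselves — so a
noiseless render is exactly reproducible by pixel counting.

Vacuoles are placed by rejection sampling on the pixel grid with a one-pixel
exclusion zone around the nucleus and previously placed vacuoles and a
two-pixel zone inside the cell boundary, which guarantees that rasterized
vacuoles are mutually 8-disconnected and never touch the cell edge.  When a
cell is too crowded to accept its sampled vacuole count the realized count is
reduced and recorded as truth (placement saturation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage.draw import ellipse as _draw_ellipse

from .presets import DEFAULT_PRESETS, GeneratorPreset, condition_key, get_preset

__all__ = [
    "CellTruth",
    "FieldImage",
    "WellSpec",
    "PlateLayout",
    "sample_cell_population",
    "render_field",
    "simulate_field",
    "simulate_plate",
    "generate_plate",
    "truth_masks",
    "truth_to_frame",
    "DEFAULT_PIXEL_SIZE",
]

#: Default pixel calibration (µm / px): a 600 µm² cell spans ~85 px across.
DEFAULT_PIXEL_SIZE = 0.325

_EIGHT = np.ones((3, 3), bool)


@dataclass
class CellTruth:
    """Ground truth for one synthetic cell.

    Areas are µm² derived from the rasterized masks; ``phospholipid_total``
    is the planted background-subtracted integrated intensity in grey·px.
    """

    cell_id: int
    centroid: tuple[float, float]  # (row, col) in field pixels
    cell_area: float
    nucleus_area: float
    n_vacuoles: int
    vacuole_areas: list[float]
    vacuole_area_fraction: float
    phospholipid_total: float
    n_vacuoles_requested: int = 0
    # Local raster stamps (origin set at field placement time); these let the
    # test suite rebuild exact truth label masks for oracle comparisons.
    cell_mask: np.ndarray | None = field(default=None, repr=False)
    nucleus_mask: np.ndarray | None = field(default=None, repr=False)
    vacuole_labels: np.ndarray | None = field(default=None, repr=False)
    origin: tuple[int, int] | None = field(default=None, repr=False)


@dataclass
class FieldImage:
    """One imaging field: three co-registered 16-bit channels."""

    nuclear: np.ndarray
    cytoplasm: np.ndarray
    phospholipid: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    well_id: str = ""
    field_index: int = 0

    def __post_init__(self) -> None:
        shapes = {self.nuclear.shape, self.cytoplasm.shape, self.phospholipid.shape}
        if len(shapes) != 1:
            raise ValueError(f"channels must share dimensions, got {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclear.shape

    def channels(self) -> dict[str, np.ndarray]:
        return {"nuc": self.nuclear, "cyto": self.cytoplasm, "phos": self.phospholipid}


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

_VALID_RECOVERY = (0, 24, 48)


@dataclass(frozen=True)
class WellSpec:
    well: str
    compound: str
    concentration_uM: float
    recovery_h: int
    experiment: int = 1
    exposure_h: int = 24

    @property
    def condition(self) -> tuple:
        return condition_key(self.compound, self.concentration_uM, self.recovery_h)


@dataclass
class PlateLayout:
    """Mapping of wells to conditions for one simulated plate."""

    wells: list[WellSpec]
    fields_per_well: int = 15

    def __post_init__(self) -> None:
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")
        seen = set()
        for w in self.wells:
            if w.recovery_h not in _VALID_RECOVERY:
                raise ValueError(
                    f"well {w.well}: recovery_h must be one of {_VALID_RECOVERY}"
                )
            if w.well in seen:
                raise ValueError(f"duplicate well id {w.well}")
            seen.add(w.well)
        treated = any(w.compound.lower() != "untreated" for w in self.wells)
        control = any(w.compound.lower() == "untreated" for w in self.wells)
        if treated and not control:
            raise ValueError("a plate with treated wells needs >=1 untreated control well")

    def conditions(self) -> list[tuple]:
        return sorted({w.condition for w in self.wells})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(w) for w in self.wells]).assign(
            fields_per_well=self.fields_per_well
        )

    def to_yaml(self, path) -> None:
        doc = {
            "fields_per_well": self.fields_per_well,
            "wells": [dataclasses.asdict(w) for w in self.wells],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        doc = yaml.safe_load(Path(path).read_text())
        wells = [WellSpec(**w) for w in doc["wells"]]
        return cls(wells=wells, fields_per_well=int(doc.get("fields_per_well", 15)))

    @classmethod
    def build(
        cls,
        conditions: Sequence[tuple[str, float, int]],
        n_experiments: int = 3,
        wells_per_condition: int = 6,
        fields_per_well: int = 15,
    ) -> "PlateLayout":
        """Factorial layout: every condition replicated in every experiment.

        ``wells_per_condition`` is the total across experiments and must be a
        multiple of ``n_experiments``.
        """
        if wells_per_condition % n_experiments:
            raise ValueError("wells_per_condition must divide evenly among experiments")
        per_exp = wells_per_condition // n_experiments
        wells = []
        idx = 0
        for compound, conc, rec in conditions:
            for exp in range(1, n_experiments + 1):
                for _ in range(per_exp):
                    row = chr(ord("A") + idx // 12)
                    col = idx % 12 + 1
                    wells.append(
                        WellSpec(
                            well=f"{row}{col:02d}",
                            compound=compound,
                            concentration_uM=float(conc),
                            recovery_h=int(rec),
                            experiment=exp,
                        )
                    )
                    idx += 1
        return cls(wells=wells, fields_per_well=fields_per_well)


def demo_layout(fields_per_well: int = 3) -> PlateLayout:
    """Tiny two-condition layout used by the CLI demo and smoke tests."""
    return PlateLayout.build(
        [("untreated", 0.0, 0), ("staurosporine", 1.0, 0)],
        n_experiments=3,
        wells_per_condition=3,
        fields_per_well=fields_per_well,
    )


# ---------------------------------------------------------------------------
# cell sampling
# ---------------------------------------------------------------------------


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_count(
    preset: GeneratorPreset, rng: np.random.Generator, area_ratio: float = 1.0
) -> int:
    """Per-cell vacuole count; the mean scales with relative cell area.

    Larger cells carry proportionally more vacuoles, which keeps the
    vacuole-occupied fraction stable across the cell-size distribution.
    """
    mu = preset.vacuole_count_mean * area_ratio
    if mu <= 0:
        return 0
    k = preset.vacuole_count_dispersion
    if k is None:
        return int(rng.poisson(mu))
    return int(rng.negative_binomial(k, k / (k + mu)))


def _ellipse_mask(shape, center, r_major, r_minor, rotation) -> np.ndarray:
    rr, cc = _draw_ellipse(
        center[0], center[1], r_major, r_minor, shape=shape, rotation=rotation
    )
    mask = np.zeros(shape, bool)
    mask[rr, cc] = True
    return mask


def _disk_struct(r: float) -> np.ndarray:
    n = int(np.ceil(r))
    dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
    return dy * dy + dx * dx <= r * r


def _place_vacuoles(
    cytoplasm_allowed: np.ndarray,
    radii_px: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 40,
) -> tuple[np.ndarray, list[int]]:
    """Sample non-touching disks inside the allowed region.

    Random candidate centers (with sub-pixel jitter, keeping the expected
    rasterized area at pi r^2) are tried first; once a cell is crowded the
    placement falls back to an exhaustive scan for any remaining pocket, so
    the realized count only drops below the sampled count when placement is
    geometrically impossible.  Returns an int32 label raster and the placed
    pixel areas; larger vacuoles are placed first.
    """
    labels = np.zeros(cytoplasm_allowed.shape, np.int32)
    blocked = ~cytoplasm_allowed
    h, w = labels.shape
    areas: list[int] = []
    nbr = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 0), (0, 1), (1, -1), (1, 0), (1, 1)]
    vid = 0
    for r in sorted(radii_px, reverse=True):
        n = int(np.ceil(r + 0.5))
        dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
        dy, dx = dy.ravel(), dx.ravel()
        free = np.flatnonzero(~blocked)
        ys = xs = None
        if free.size:
            picks = free[rng.integers(free.size, size=max_attempts)]
            jit = rng.uniform(-0.5, 0.5, size=(max_attempts, 2))
            for pick, (u, v) in zip(picks, jit):
                iy, ix = int(pick // w), int(pick % w)
                inside = (dy - u) ** 2 + (dx - v) ** 2 <= r * r
                py, px = iy + dy[inside], ix + dx[inside]
                if (py < 0).any() or (px < 0).any() or (py >= h).any() or (px >= w).any():
                    continue
                if blocked[py, px].any():
                    continue
                ys, xs = py, px
                break
        if ys is None:
            # exhaustive: integer centers where the whole disk is unblocked
            valid = ~ndi.binary_dilation(blocked, _disk_struct(r))
            valid[: n + 1, :] = valid[-n - 1 :, :] = False
            valid[:, : n + 1] = valid[:, -n - 1 :] = False
            cands = np.flatnonzero(valid)
            if cands.size == 0:
                continue  # geometrically impossible: realized count drops
            pick = cands[rng.integers(cands.size)]
            iy, ix = int(pick // w), int(pick % w)
            inside = dy * dy + dx * dx <= r * r
            ys, xs = iy + dy[inside], ix + dx[inside]
        vid += 1
        labels[ys, xs] = vid
        for ddy, ddx in nbr:
            blocked[np.clip(ys + ddy, 0, h - 1), np.clip(xs + ddx, 0, w - 1)] = True
        areas.append(int(ys.size))
    return labels, areas


def sample_cell_population(
    preset: GeneratorPreset,
    n_cells: int,
    rng_seed,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    max_attempts: int = 40,
) -> list[CellTruth]:
    """Sample ``n_cells`` cells with planted vacuoles from a preset.

    Each cell is built as a local raster stamp (cell / nucleus / vacuole
    masks); the recorded truth areas are pixel counts converted to µm², so
    they match what a pixel-exact measurement of a noiseless render returns.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    preset.validate()
    rng = _as_rng(rng_seed)
    ps2 = pixel_size**2
    cells: list[CellTruth] = []
    for cid in range(n_cells):
        area_um = -1.0
        while area_um <= max(1.0, 4 * ps2):
            area_um = rng.normal(preset.cell_area_mean, preset.cell_area_sd)
        area_px = area_um / ps2
        aspect = rng.uniform(1.0, 1.2)
        theta = rng.uniform(0, np.pi)
        r0 = np.sqrt(area_px / np.pi)
        a, b = r0 * aspect, r0 / aspect
        pad = int(np.ceil(a)) + 4
        shape = (2 * pad + 1, 2 * pad + 1)
        center = (pad + rng.uniform(-0.5, 0.5), pad + rng.uniform(-0.5, 0.5))
        cell_mask = _ellipse_mask(shape, center, a, b, theta)

        nuc_area_px = preset.nucleus_area_fraction * area_px
        rn = np.sqrt(nuc_area_px / np.pi)
        na, nb = rn * aspect, rn / aspect
        # keep the nucleus inside the cell: offset bounded by the margin
        max_off = max(0.0, (b - nb) * 0.4)
        off = rng.uniform(-max_off, max_off, size=2)
        nucleus_mask = _ellipse_mask(
            shape, (center[0] + off[0], center[1] + off[1]), na, nb, theta
        )
        nucleus_mask &= cell_mask

        n_req = _draw_count(preset, rng, area_um / preset.cell_area_mean)
        if n_req > 0:
            radii_um = rng.normal(
                preset.vacuole_radius_mean, preset.vacuole_radius_sd, size=n_req
            )
            radii_px = np.maximum(radii_um / pixel_size, 1.3)
            allowed = ndi.binary_erosion(cell_mask, _EIGHT)
            allowed &= ~ndi.binary_dilation(nucleus_mask, _EIGHT)
            vac_labels, vac_areas_px = _place_vacuoles(
                allowed, radii_px, rng, max_attempts=max_attempts
            )
        else:
            vac_labels = np.zeros(shape, np.int32)
            vac_areas_px = []

        cell_area = cell_mask.sum() * ps2
        vac_areas = [n * ps2 for n in vac_areas_px]
        cells.append(
            CellTruth(
                cell_id=cid + 1,
                centroid=(float(center[0]), float(center[1])),
                cell_area=cell_area,
                nucleus_area=nucleus_mask.sum() * ps2,
                n_vacuoles=len(vac_areas),
                vacuole_areas=vac_areas,
                vacuole_area_fraction=float(sum(vac_areas) / cell_area),
                phospholipid_total=float(
                    (preset.phospholipid_intensity_mean - preset.background_mean)
                    * cell_mask.sum()
                ),
                n_vacuoles_requested=n_req,
                cell_mask=cell_mask,
                nucleus_mask=nucleus_mask,
                vacuole_labels=vac_labels,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


class FieldPlacementError(RuntimeError):
    """Cells could not be placed without overlap."""


def render_field(
    cells: Sequence[CellTruth],
    preset: GeneratorPreset,
    rng_seed,
    shape: tuple[int, int] = (1024, 1024),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    border_margin: int = 6,
    max_attempts: int = 400,
    well_id: str = "",
    field_index: int = 0,
) -> FieldImage:
    """Place cell stamps in a field without overlap and paint the channels.

    Mutates each :class:`CellTruth` with its field ``origin`` and field-frame
    ``centroid``.  Raises :class:`FieldPlacementError` when a stamp cannot be
    placed (use a larger field or fewer cells).
    """
    rng = _as_rng(rng_seed)
    h, w = shape
    occupancy = np.zeros(shape, bool)
    cyto = np.full(shape, preset.background_mean, np.float64)
    nuc = np.full(shape, preset.background_mean, np.float64)
    phos = np.full(shape, preset.background_mean, np.float64)

    for truth in cells:
        stamp = truth.cell_mask
        if stamp is None:
            raise ValueError("CellTruth has no raster stamp; use sample_cell_population")
        sh, sw = stamp.shape
        dilated = ndi.binary_dilation(stamp, _EIGHT, iterations=2)
        lo_y, hi_y = border_margin, h - border_margin - sh
        lo_x, hi_x = border_margin, w - border_margin - sw
        if hi_y <= lo_y or hi_x <= lo_x:
            raise FieldPlacementError(
                f"cell stamp {sh}x{sw} does not fit a {h}x{w} field; "
                "use a larger field or smaller cells"
            )
        for attempt in range(max_attempts):
            oy = int(rng.integers(lo_y, hi_y))
            ox = int(rng.integers(lo_x, hi_x))
            region = occupancy[oy : oy + sh, ox : ox + sw]
            if not (region & dilated).any():
                break
        else:
            raise FieldPlacementError(
                f"could not place {len(cells)} cells in a {h}x{w} field; "
                "use a larger field or fewer cells per field"
            )
        occupancy[oy : oy + sh, ox : ox + sw] |= dilated
        truth.origin = (oy, ox)
        truth.centroid = (truth.centroid[0] + oy, truth.centroid[1] + ox)

        sl = np.s_[oy : oy + sh, ox : ox + sw]
        cmask, nmask, vlab = truth.cell_mask, truth.nucleus_mask, truth.vacuole_labels
        n_cell = int(cmask.sum())
        cyto[sl][cmask] = preset.cytoplasm_intensity_mean + rng.normal(
            0, preset.cytoplasm_intensity_sd, n_cell
        ) if preset.cytoplasm_intensity_sd else preset.cytoplasm_intensity_mean
        vmask = vlab > 0
        nv = int(vmask.sum())
        if nv:
            cyto[sl][vmask] = preset.vacuole_interior_intensity_mean + (
                rng.normal(0, preset.vacuole_interior_intensity_sd, nv)
                if preset.vacuole_interior_intensity_sd
                else 0.0
            )
        nn = int(nmask.sum())
        if nn:
            nuc[sl][nmask] = preset.nucleus_intensity_mean + (
                rng.normal(0, preset.nucleus_intensity_sd, nn)
                if preset.nucleus_intensity_sd
                else 0.0
            )
        phos[sl][cmask] = preset.phospholipid_intensity_mean + (
            rng.normal(0, preset.phospholipid_intensity_sd, n_cell)
            if preset.phospholipid_intensity_sd
            else 0.0
        )

    if preset.noise_sd:
        for arr in (cyto, nuc, phos):
            arr += rng.normal(0, preset.noise_sd, shape)
    to16 = lambda a: np.clip(np.rint(a), 0, 65_535).astype(np.uint16)
    return FieldImage(
        nuclear=to16(nuc),
        cytoplasm=to16(cyto),
        phospholipid=to16(phos),
        pixel_size=pixel_size,
        well_id=well_id,
        field_index=field_index,
    )


def truth_masks(
    cells: Sequence[CellTruth], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rebuild field-frame truth label rasters (cells, nuclei, vacuoles)."""
    cell_lab = np.zeros(shape, np.int32)
    nuc_lab = np.zeros(shape, np.int32)
    vac_lab = np.zeros(shape, np.int32)
    vmax = 0
    for t in cells:
        if t.origin is None:
            raise ValueError("cells were not rendered into a field yet")
        oy, ox = t.origin
        sh, sw = t.cell_mask.shape
        sl = np.s_[oy : oy + sh, ox : ox + sw]
        cell_lab[sl][t.cell_mask] = t.cell_id
        nuc_lab[sl][t.nucleus_mask] = t.cell_id
        vv = t.vacuole_labels
        vac_lab[sl][vv > 0] = vv[vv > 0] + vmax
        vmax = vac_lab.max()
    return cell_lab, nuc_lab, vac_lab


def truth_to_frame(
    cells: Sequence[CellTruth], well_id: str = "", field_index: int = 0
) -> pd.DataFrame:
    """Flatten truths to a table (one row per cell; vacuole areas summed)."""
    rows = []
    for t in cells:
        rows.append(
            {
                "well": well_id,
                "field": field_index,
                "cell_id": t.cell_id,
                "centroid_y": t.centroid[0],
                "centroid_x": t.centroid[1],
                "cell_area": t.cell_area,
                "nucleus_area": t.nucleus_area,
                "n_vacuoles": t.n_vacuoles,
                "n_vacuoles_requested": t.n_vacuoles_requested,
                "total_vacuole_area": float(sum(t.vacuole_areas)),
                "vacuole_area_fraction": t.vacuole_area_fraction,
                "phospholipid_total": t.phospholipid_total,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------


def _field_rng(seed: int, well_idx: int, field_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), well_idx, field_idx]))


def simulate_field(
    preset: GeneratorPreset,
    n_cells: int,
    rng_seed,
    shape: tuple[int, int] = (1024, 1024),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    well_id: str = "",
    field_index: int = 0,
) -> tuple[FieldImage, list[CellTruth]]:
    """Sample a population and render it into one field (single RNG stream)."""
    rng = _as_rng(rng_seed)
    cells = sample_cell_population(preset, n_cells, rng, pixel_size=pixel_size)
    img = render_field(
        cells, preset, rng, shape=shape, pixel_size=pixel_size,
        well_id=well_id, field_index=field_index,
    )
    return img, cells


def _resolve_presets(layout: PlateLayout, preset_map) -> dict:
    source = dict(DEFAULT_PRESETS) if preset_map is None else dict(preset_map)
    resolved, missing = {}, []
    for cond in layout.conditions():
        if cond in source:
            resolved[cond] = get_preset(source[cond])
        else:
            missing.append(cond)
    if missing:
        raise KeyError(
            "no preset for condition(s): "
            + ", ".join(f"{c[0]} {c[1]:g} uM R{c[2]}" for c in missing)
        )
    return resolved


def simulate_plate(
    layout: PlateLayout,
    rng_seed: int,
    preset_map: Mapping | None = None,
    cells_per_field: int = 35,
    shape: tuple[int, int] = (1024, 1024),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> Iterator[tuple[WellSpec, FieldImage, list[CellTruth]]]:
    """Yield (well, field image, truths) for every field of a plate.

    Deterministic given ``rng_seed``: each (well, field) gets an independent
    RNG stream keyed by its position in the layout.
    """
    presets = _resolve_presets(layout, preset_map)
    for wi, well in enumerate(layout.wells):
        preset = presets[well.condition]
        for fi in range(layout.fields_per_well):
            rng = _field_rng(rng_seed, wi, fi)
            img, cells = simulate_field(
                preset, cells_per_field, rng, shape=shape,
                pixel_size=pixel_size, well_id=well.well, field_index=fi,
            )
            yield well, img, cells


def generate_plate(
    layout: PlateLayout,
    out_dir,
    rng_seed: int,
    preset_map: Mapping | None = None,
    cells_per_field: int = 35,
    shape: tuple[int, int] = (1024, 1024),
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    multipage: bool = False,
) -> pd.DataFrame:
    """Write a plate of field TIFFs plus a ground-truth CSV; return the truth table."""
    from .io import write_field  # local import: io depends on FieldImage

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for well, img, cells in simulate_plate(
        layout, rng_seed, preset_map, cells_per_field, shape, pixel_size
    ):
        write_field(img, out, multipage=multipage)
        frames.append(truth_to_frame(cells, well.well, img.field_index))
    truth = pd.concat(frames, ignore_index=True)
    truth.to_csv(out / "truth.csv", index=False)
    layout.to_yaml(out / "layout.yaml")
    return truth
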