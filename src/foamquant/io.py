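"""File I/O: field TIFFs, plate discovery, and the CSV table contracts.

Field images are written either as one 16-bit TIFF per channel, named
``<well>_f<NN>_<channel>.tif`` with channel in {nuc, cyto, phos}, or as one
3-page TIFF per field named ``<well>_f<NN>.tif`` (page order nuc, cyto,
phos).  Discovery auto-detects which convention a directory uses.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthgen import DEFAULT_PIXEL_SIZE, FieldImage

__all__ = [
    "CHANNEL_NAMES",
    "write_field",
    "read_field",
    "discover_fields",
    "iter_plate",
]

CHANNEL_NAMES = ("nuc", "cyto", "phos")

_PER_CHANNEL = re.compile(r"^(?P<well>[A-Za-z0-9]+)_f(?P<field>\d+)_(?P<ch>nuc|cyto|phos)\.tiff?$")
_MULTIPAGE = re.compile(r"^(?P<well>[A-Za-z0-9]+)_f(?P<field>\d+)\.tiff?$")


def write_field(img: FieldImage, out_dir, multipage: bool = False) -> list[Path]:
    """Write one field's channels to TIFF; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{img.well_id}_f{img.field_index:02d}"
    if multipage:
        path = out / f"{stem}.tif"
        stack = np.stack([img.nuclear, img.cytoplasm, img.phospholipid])
        tifffile.imwrite(path, stack)
        return [path]
    paths = []
    for name, raster in img.channels().items():
        path = out / f"{stem}_{name}.tif"
        tifffile.imwrite(path, raster)
        paths.append(path)
    return paths


def read_field(
    paths, well_id: str, field_index: int, pixel_size: float = DEFAULT_PIXEL_SIZE
) -> FieldImage:
    """Read a field from one multipage TIFF path or a {channel: path} dict."""
    if isinstance(paths, (str, Path)):
        stack = tifffile.imread(paths)
        if stack.ndim != 3 or stack.shape[0] != 3:
            raise ValueError(f"{paths}: expected a 3-page TIFF, got shape {stack.shape}")
        nuc, cyto, phos = stack
    else:
        nuc = tifffile.imread(paths["nuc"])
        cyto = tifffile.imread(paths["cyto"])
        phos = tifffile.imread(paths["phos"])
    return FieldImage(
        nuclear=nuc, cytoplasm=cyto, phospholipid=phos,
        pixel_size=pixel_size, well_id=well_id, field_index=field_index,
    )


def discover_fields(image_dir) -> list[dict]:
    """List the fields in a directory (either naming convention).

    Returns sorted entries ``{"well", "field", "paths"}`` where ``paths`` is
    a channel dict or a single multipage path.  Raises if no fields are
    found or a field is missing channels.
    """
    image_dir = Path(image_dir)
    per_channel: dict[tuple, dict] = {}
    multipage: dict[tuple, Path] = {}
    for p in sorted(image_dir.glob("*.tif*")):
        m = _PER_CHANNEL.match(p.name)
        if m:
            key = (m["well"], int(m["field"]))
            per_channel.setdefault(key, {})[m["ch"]] = p
            continue
        m = _MULTIPAGE.match(p.name)
        if m:
            multipage[(m["well"], int(m["field"]))] = p
    if not per_channel and not multipage:
        raise FileNotFoundError(f"no fields found in {image_dir}")
    entries = []
    for key, chans in per_channel.items():
        missing = set(CHANNEL_NAMES) - set(chans)
        if missing:
            raise FileNotFoundError(
                f"field {key[0]}_f{key[1]:02d}: missing channel file(s) {sorted(missing)}"
            )
        entries.append({"well": key[0], "field": key[1], "paths": chans})
    for key, path in multipage.items():
        if key in per_channel:
            continue
        entries.append({"well": key[0], "field": key[1], "paths": path})
    return sorted(entries, key=lambda e: (e["well"], e["field"]))


def iter_plate(image_dir, pixel_size: float = DEFAULT_PIXEL_SIZE):
    """Yield :class:`FieldImage` for every field discovered in a directory."""
    for entry in discover_fields(image_dir):
        yield read_field(entry["paths"], entry["well"], entry["field"], pixel_size)
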