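"""File I/O: 16-bit TIFF images, CSV tables, and run manifests.

Conventions: pixel coordinates are row-major and 0-based everywhere; TIFF
round-trips preserve 16-bit values exactly (one page per channel, aggregate
channel first); CSV numeric values are written with full repr precision.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .field import CHANNEL_ORDER, ImageField

__all__ = [
    "write_image", "read_image",
    "write_table", "read_table",
    "sha256_of", "write_manifest",
]


def write_image(field: ImageField, path: str | Path) -> Path:
    """Write a field as a multi-page 16-bit grayscale TIFF (aggregate page
    first, organelle second)."""
    path = Path(path)
    pages = [np.asarray(field.channels[name]).astype(np.uint16)
             for name in field.channel_names()]
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack",
                     metadata={"channels": field.channel_names(),
                               "field_id": field.field_id})
    return path


def read_image(path: str | Path, channel_names: list[str] | None = None,
               ) -> ImageField:
    """Read a single- or multi-page TIFF back into an ImageField, preserving
    channel order."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    names = channel_names or meta.get("channels") or list(CHANNEL_ORDER[: len(data)])
    if len(names) != len(data):
        raise ValueError(f"{path}: {len(data)} pages but {len(names)} channel names")
    channels = {name: page for name, page in zip(names, data)}
    return ImageField(channels, provenance=str(path),
                      field_id=str(meta.get("field_id", path.stem)))


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """CSV with full-precision floats and stable column order."""
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path, required_columns: list[str] | None = None,
               ) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> Path:
    """Atomic JSON write (temp file + rename)."""
    path = Path(path)
    tmp = path.with_suffix(".tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    os.replace(tmp, path)
    return path
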