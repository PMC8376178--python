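"""File formats and pluggable annotation ingestion.

Canonical on-disk conventions: float32 TIFF for analysis images, 8-bit
PNG for display crops, CSV for point tables, JSON for reports.  Point
coordinates are 0-based (x = column, y = row), pixel centers at
integers.

Annotation tables from any crowdsourcing service are mapped onto the
canonical ``worker_id, image_id, x, y`` schema by a *dialect* — a named
column mapping registered with :func:`register_dialect`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigError, SchemaError
from .records import ANNOTATION_COLUMNS, AnnotationSet
from .spotimage import to_display_uint8

logger = logging.getLogger(__name__)

# dialect name -> {canonical column: source column}
_DIALECTS: dict[str, dict[str, str]] = {
    "quantius": {"worker_id": "worker_id", "image_id": "image_id", "x": "x", "y": "y"},
}


def register_dialect(name: str, column_map: dict[str, str]) -> None:
    """Register an ingestion dialect mapping canonical -> source columns."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in column_map]
    if missing:
        raise ConfigError(f"dialect {name!r} does not map canonical columns {missing}")
    _DIALECTS[name] = dict(column_map)


def ingest_annotations(
    path,
    dialect: str = "quantius",
    image_width: float | None = None,
    image_height: float | None = None,
    image_id: str | None = None,
) -> AnnotationSet:
    """Read an annotation CSV into the canonical schema.

    Rows with non-numeric or (when image dimensions are given)
    out-of-range coordinates are dropped and counted in the log.  Extra
    columns are ignored.
    """
    if dialect not in _DIALECTS:
        raise ConfigError(f"unknown annotation dialect {dialect!r}; known: {sorted(_DIALECTS)}")
    colmap = _DIALECTS[dialect]
    raw = pd.read_csv(path)
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = pd.DataFrame({canon: raw[src] for canon, src in colmap.items()})
    n0 = len(df)
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    df = df.dropna(subset=["x", "y"])
    if image_width is not None:
        df = df[(df["x"] >= 0) & (df["x"] < image_width)]
    if image_height is not None:
        df = df[(df["y"] >= 0) & (df["y"] < image_height)]
    dropped = n0 - len(df)
    if dropped:
        logger.info("%s: dropped %d/%d rows with invalid coordinates", path, dropped, n0)
    df = df.reset_index(drop=True)
    if image_id is None:
        ids = df["image_id"].unique()
        image_id = str(ids[0]) if len(ids) else "img0"
    df["worker_id"] = df["worker_id"].astype(str)
    df["image_id"] = df["image_id"].astype(str)
    return AnnotationSet(image_id=image_id, df=df[ANNOTATION_COLUMNS])


def read_image(path) -> np.ndarray:
    """Read a TIFF/PNG image as float; multi-page TIFF becomes a z-stack."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luminance
            arr = arr[..., :3].mean(axis=-1)
    return np.asarray(arr, dtype=float)


def write_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_png(path, image: np.ndarray, scale: float = 1.0, order: int = 1) -> None:
    """Display-normalised 8-bit PNG (percentile clip [0.1, 99.9]).

    ``scale`` > 1 upscales by interpolation before export (``order`` 1 =
    bilinear, 0 = nearest neighbor), as crops are shown enlarged at the
    annotation interface.
    """
    image = np.asarray(image, dtype=float)
    if scale != 1.0:
        from skimage.transform import resize

        shape = (round(image.shape[0] * scale), round(image.shape[1] * scale))
        image = resize(image, shape, order=order, preserve_range=True, anti_aliasing=False)
    iio.imwrite(path, to_display_uint8(image))


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return vars(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_consensus_csv(path, points, image_id: str = "img0") -> None:
    pd.DataFrame(
        {
            "image_id": image_id,
            "x": [p.x for p in points],
            "y": [p.y for p in points],
            "n_support": [p.n_support for p in points],
            "origin": [p.origin for p in points],
        }
    ).to_csv(path, index=False)


def write_crop_manifest(path, crops) -> None:
    pd.DataFrame(
        [
            {
                "crop_id": c.crop_id,
                "parent_id": c.parent_id,
                "x0": c.x0,
                "y0": c.y0,
                "width": c.width,
                "height": c.height,
                "scale": c.scale,
                "depth": c.depth,
                "flag": c.flag,
            }
            for c in crops
        ]
    ).to_csv(path, index=False)
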