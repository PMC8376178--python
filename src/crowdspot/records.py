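"""Core in-memory containers.

Images are plain 2-D numpy arrays of finite, non-negative intensities with
``image[row, col]`` indexing; all point coordinates in this package are
``(x, y)`` = (column, row), 0-based, pixel centers at integer coordinates,
x increasing rightward and y increasing downward.  Point tables travel as
pandas DataFrames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SpotRecord:
    """A single ground-truth or detected fluorescent spot.

    Parameters
    ----------
    x, y:
        Sub-pixel center (column, row) in the host image frame.
    sigma:
        Width of the isotropic Gaussian intensity profile, in pixels.
    amplitude:
        Peak intensity above the local background.
    snr:
        Amplitude divided by the robust local background standard
        deviation; ``nan`` when unknown (e.g. raw detector output).
    """

    x: float
    y: float
    sigma: float
    amplitude: float = math.nan
    snr: float = math.nan

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def spots_to_frame(spots: list[SpotRecord]) -> pd.DataFrame:
    """Tabulate spots as ``spot_id,x,y,sigma,amplitude,snr``."""
    return pd.DataFrame(
        {
            "spot_id": np.arange(len(spots)),
            "x": [s.x for s in spots],
            "y": [s.y for s in spots],
            "sigma": [s.sigma for s in spots],
            "amplitude": [s.amplitude for s in spots],
            "snr": [s.snr for s in spots],
        }
    )


def frame_to_spots(df: pd.DataFrame) -> list[SpotRecord]:
    return [
        SpotRecord(
            x=float(r.x),
            y=float(r.y),
            sigma=float(getattr(r, "sigma", 1.0)),
            amplitude=float(getattr(r, "amplitude", math.nan)),
            snr=float(getattr(r, "snr", math.nan)),
        )
        for r in df.itertuples(index=False)
    ]


def spot_coords(spots) -> np.ndarray:
    """(n, 2) array of (x, y) coordinates from SpotRecords or raw pairs."""
    if len(spots) == 0:
        return np.empty((0, 2), dtype=float)
    first = spots[0]
    if isinstance(first, SpotRecord):
        return np.array([[s.x, s.y] for s in spots], dtype=float)
    return np.asarray(spots, dtype=float).reshape(len(spots), 2)


ANNOTATION_COLUMNS = ["worker_id", "image_id", "x", "y"]


@dataclass
class AnnotationSet:
    """Point clicks for one image collected from redundant annotators.

    ``df`` holds one row per click with columns
    ``worker_id, image_id, x, y`` (extra columns are carried along).
    """

    image_id: str
    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ANNOTATION_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_workers(self) -> int:
        return int(self.df["worker_id"].nunique())

    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "annotation_id", np.arange(len(out)))
        out.to_csv(path, index=False)
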