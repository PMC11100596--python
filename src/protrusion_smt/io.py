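"""Movie container and TIFF / CSV input-output.

Movies are single-channel 2-D time lapses stored as (frame, row, col)
float arrays with physical calibration attached.  On disk they are
ImageJ-compatible multi-page uint16 TIFFs (pixel size in um, frame
interval in s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass
class Movie:
    """Calibrated 2-D+time intensity stack.

    ``data`` has shape (n_frames, height, width); NaN marks pixels that
    left the field of view after drift correction.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D, got shape {self.data.shape}")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def copy_with(self, data: np.ndarray) -> "Movie":
        return replace(self, data=data)


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write an ImageJ-compatible uint16 multi-page TIFF.

    Raises ``ValueError`` when finite intensities exceed the uint16 range;
    NaN sentinel pixels are stored as 0.
    """
    data = np.asarray(movie.data, dtype=float)
    finite = data[np.isfinite(data)]
    if finite.size and (finite.max() > 65535 or finite.min() < 0):
        raise ValueError(
            "movie intensities outside the uint16 range [0, 65535]; "
            "rescale or lower camera gain before writing"
        )
    out = np.nan_to_num(data, nan=0.0).round().astype(np.uint16)
    tifffile.imwrite(
        str(path),
        out,
        imagej=True,
        resolution=(1e3 / movie.pixel_size_nm, 1e3 / movie.pixel_size_nm),
        metadata={
            "unit": "um",
            "finterval": movie.frame_interval_s,
            "axes": "TYX",
        },
    )


def read_movie(
    path: str | Path,
    pixel_size_nm: float | None = None,
    frame_interval_s: float | None = None,
) -> Movie:
    """Read a multi-page TIFF; calibration from ImageJ tags unless given."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        if data.ndim == 2:
            data = data[None]
        ij = tif.imagej_metadata or {}
        if frame_interval_s is None:
            frame_interval_s = float(ij.get("finterval", 1.0))
        if pixel_size_nm is None:
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            if res is not None and res.value[0] > 0:
                # pixels per um -> nm per pixel
                pixel_size_nm = 1e3 * res.value[1] / res.value[0]
            else:
                pixel_size_nm = 1.0
    return Movie(
        data=data.astype(np.float64),
        pixel_size_nm=pixel_size_nm,
        frame_interval_s=frame_interval_s,
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
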