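"""File I/O: TIFF movies with axis metadata, label stacks, CSV tables,
and structured-text (YAML) configuration files.

CSV dialect is comma-separated UTF-8 with a ``.`` decimal and a fixed
header row, so outputs are bit-exact comparable across runs and languages.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .movie import Movie

__all__ = [
    "write_movie",
    "read_movie",
    "write_labels",
    "read_labels",
    "write_ground_truth",
    "TRACKS_COLUMNS",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_config",
    "read_config",
]

TRACKS_COLUMNS = [
    "track_id",
    "frame",
    "time_s",
    "nucleus_label",
    "x_um",
    "y_um",
    "z_um",
    "area_um2",
    "sf",
    "circularity",
    "min_feret_um",
    "max_feret_um",
    "gap",
]

GROUND_TRUTH_COLUMNS = [
    "frame",
    "nucleus_id",
    "x_px",
    "y_px",
    "z_px",
    "semi_major_px",
    "semi_minor_px",
    "sf_true",
    "squeezing",
]


def write_movie(movie: Movie, path) -> None:
    """Write a movie as multi-page TIFF with TZYX axis metadata."""
    tifffile.imwrite(
        path,
        movie.data,
        metadata={
            "axes": "TZYX",
            "pixel_size_um": movie.pixel_size_um,
            "frame_interval_s": movie.frame_interval_s,
        },
    )


def read_movie(path, pixel_size_um: float | None = None,
               frame_interval_s: float | None = None) -> Movie:
    """Read a TZYX TIFF movie; metadata overridable from arguments."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 3:  # single z-slice stack stored as TYX
        data = data[:, None, :, :]
    ps = pixel_size_um if pixel_size_um is not None else float(
        meta.get("pixel_size_um", 1.0))
    fi = frame_interval_s if frame_interval_s is not None else float(
        meta.get("frame_interval_s", 1.0))
    return Movie(data=data, pixel_size_um=ps, frame_interval_s=fi,
                 name=Path(path).stem)


def write_labels(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(path)


def write_ground_truth(truth, path) -> None:
    truth.table.to_csv(path, index=False, columns=GROUND_TRUTH_COLUMNS)


def write_tracks_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=TRACKS_COLUMNS)


def read_tracks_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)
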