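"""Movie, spot and track I/O.

Movies travel as multi-page TIFF plus a plain-text sidecar
(``<name>.meta.txt``) holding the physical calibration; loading without the
sidecar (or explicit calibration) is a hard error — units are never
silently assumed.  Tabular outputs are CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidParameterError
from .detection import Spot
from .synthetic import GroundTruth, Movie
from .tracking import Trajectory

__all__ = [
    "save_movie",
    "load_movie",
    "spots_to_dataframe",
    "spots_from_dataframe",
    "tracks_to_dataframe",
    "save_ground_truth",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.txt")


def save_movie(movie: Movie, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.stack.astype(np.float32),
                     photometric="minisblack")
    _sidecar(path).write_text(
        f"pixel_size_um = {movie.pixel_size}\n"
        f"frame_interval_s = {movie.frame_interval}\n"
        f"channel = {movie.channel_label}\n"
    )


def load_movie(
    path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> Movie:
    """Read a multi-page TIFF; calibration from sidecar unless given.

    Raises if the calibration cannot be determined or the file is unreadable.
    """
    path = Path(path)
    try:
        stack = tifffile.imread(path).astype(float)
    except Exception as exc:
        raise InvalidParameterError(f"cannot read TIFF {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    channel = "A"
    meta = _sidecar(path)
    if meta.exists():
        for raw in meta.read_text().splitlines():
            if "=" not in raw:
                continue
            key, val = (s.strip() for s in raw.split("=", 1))
            if key == "pixel_size_um" and pixel_size is None:
                pixel_size = float(val)
            elif key == "frame_interval_s" and frame_interval is None:
                frame_interval = float(val)
            elif key == "channel":
                channel = val
    if pixel_size is None or frame_interval is None:
        raise InvalidParameterError(
            f"missing calibration for {path}: supply pixel_size/frame_interval "
            f"or a {meta.name} sidecar"
        )
    return Movie(stack, pixel_size, frame_interval, channel_label=channel)


def spots_to_dataframe(spots: list[Spot]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.frame, s.x, s.y, s.intensity, s.sigma, s.background, s.snr)
         for s in spots],
        columns=["frame", "x_px", "y_px", "intensity", "sigma_px",
                 "background", "snr"],
    )


def spots_from_dataframe(df: pd.DataFrame) -> list[Spot]:
    return [
        Spot(frame=int(r.frame), x=float(r.x_px), y=float(r.y_px),
             intensity=float(r.intensity), sigma=float(r.sigma_px),
             background=float(r.background), snr=float(r.snr))
        for r in df.itertuples()
    ]


def tracks_to_dataframe(tracks: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for k in range(t.n_points):
            rows.append((t.track_id, int(t.frames[k]), t.x[k], t.y[k],
                         t.intensity[k], t.censored_start, t.censored_end))
    return pd.DataFrame(
        rows, columns=["track_id", "frame", "x_px", "y_px", "intensity",
                       "censored_start", "censored_end"],
    )


def save_ground_truth(gt: GroundTruth, path) -> None:
    gt.to_dataframe().to_csv(path, index=False)
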