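"""Standard-format readers and writers for pipeline artifacts.

Movies travel as multi-page TIFF, trial tables and per-neuron tables as
CSV, response tensors as HDF5 (dataset ``responses``) with a long-format
CSV fallback, ROI sets as a 16-bit label-image TIFF plus a JSON sidecar,
and ground truth / summaries as JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import MovieStack, RoiSet


def save_movie(movie: MovieStack, path: str | Path) -> None:
    tifffile.imwrite(path, movie.frames.astype(np.float32), metadata={"frame_rate": movie.frame_rate})


def load_movie(path: str | Path, frame_rate: float = 8.0) -> MovieStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return MovieStack(frames=np.asarray(frames, dtype=float), frame_rate=frame_rate)


def save_roiset(rois: RoiSet, tiff_path: str | Path, json_path: str | Path) -> None:
    tifffile.imwrite(tiff_path, rois.label_image.astype(np.uint16))
    rois.to_json(json_path)


def load_roiset(json_path: str | Path) -> RoiSet:
    return RoiSet.from_json(json_path)


def save_shifts(shifts: list[tuple[int, int]], path: str | Path) -> None:
    pd.DataFrame(shifts, columns=["dy", "dx"]).to_csv(path, index_label="frame")


def load_shifts(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    return [(int(r.dy), int(r.dx)) for r in df.itertuples()]
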