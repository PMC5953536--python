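"""Shared data containers for the population-sparseness imaging pipeline.

The pipeline moves data through three canonical shapes:

* :class:`MovieStack` — a T x H x W fluorescence movie plus its frame rate.
* :class:`TrialTable` — one row per stimulus presentation, with the blank
  (OFF) and stimulus (ON) frame windows as 0-based half-open ranges.
* :class:`ResponseTensor` — trial x stimulus x neuron dF/F0 responses, the
  stacked per-trial response matrices that all statistics operate on.
* :class:`RoiSet` — labelled cell-body pixel sets plus per-ROI neuropil
  annuli used for trace extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRIAL_TABLE_COLUMNS = ("trial", "stimulus", "off_start", "off_end", "on_start", "on_end")


@dataclass
class MovieStack:
    """A fluorescence movie: ``frames`` is T x H x W, values finite."""

    frames: np.ndarray
    frame_rate: float = 8.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class TrialTable:
    """Per-presentation stimulus identity and OFF/ON frame windows.

    Frame windows are 0-based half-open ``[start, end)`` ranges; the OFF
    (blank) window precedes the ON (stimulus) window within each trial.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        t = self.table
        bad = t[(t.off_end <= t.off_start) | (t.on_end <= t.on_start)]
        if len(bad):
            raise ValueError("empty or inverted frame window in trial table")
        overlap = t[t.on_start < t.off_end]
        if len(overlap):
            raise ValueError("OFF window must precede and not overlap the ON window")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def stimuli(self) -> np.ndarray:
        return np.unique(self.table["stimulus"].to_numpy())

    @property
    def n_frames_required(self) -> int:
        return int(self.table[["off_end", "on_end"]].to_numpy().max())

    def rows_for_stimulus(self, stimulus) -> pd.DataFrame:
        rows = self.table[self.table["stimulus"] == stimulus]
        if len(rows) == 0:
            raise KeyError(f"stimulus {stimulus!r} not present in trial table")
        return rows


@dataclass
class RoiSet:
    """Cell-body ROIs and their neuropil annuli on an H x W plane.

    ``rois[i]`` and ``neuropil[i]`` are (k, 2) integer arrays of (row, col)
    pixel coordinates.  ROI pixel sets are pairwise disjoint, and every
    annulus excludes all ROI pixels.
    """

    rois: list[np.ndarray]
    neuropil: list[np.ndarray]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for i, px in enumerate(self.rois):
            px = np.asarray(px, dtype=int)
            if px.size == 0:
                raise ValueError(f"ROI {i} is empty")
            self.rois[i] = px
            pts = set(map(tuple, px))
            if seen & pts:
                raise ValueError("ROI pixel sets are not pairwise disjoint")
            seen |= pts
        self.neuropil = [np.asarray(a, dtype=int) for a in self.neuropil]

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def label_image(self) -> np.ndarray:
        """H x W int image, 0 = background, i+1 = pixels of ROI i."""
        lab = np.zeros(self.shape, dtype=np.uint16)
        for i, px in enumerate(self.rois):
            lab[px[:, 0], px[:, 1]] = i + 1
        return lab

    def to_json(self, path: str | Path) -> None:
        obj = {
            "shape": list(self.shape),
            "rois": [px.tolist() for px in self.rois],
            "neuropil": [px.tolist() for px in self.neuropil],
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSet":
        obj = json.loads(Path(path).read_text())
        return cls(
            rois=[np.asarray(p, dtype=int).reshape(-1, 2) for p in obj["rois"]],
            neuropil=[np.asarray(p, dtype=int).reshape(-1, 2) for p in obj["neuropil"]],
            shape=tuple(obj["shape"]),
        )


@dataclass
class ResponseTensor:
    """Trial x stimulus x neuron dF/F0 responses.

    ``values[t, s, n]`` is the response of neuron ``n`` to stimulus ``s`` on
    trial (repeat) ``t``; one trial slice is the S x N response matrix of a
    full pass through the stimulus set.
    """

    values: np.ndarray
    stimulus_ids: np.ndarray | None = None
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be trials x stimuli x neurons")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response tensor contains non-finite values")
        if self.stimulus_ids is None:
            self.stimulus_ids = np.arange(self.n_stimuli)
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.n_neurons)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        self.neuron_ids = np.asarray(self.neuron_ids)
        if len(self.stimulus_ids) != self.n_stimuli or len(self.neuron_ids) != self.n_neurons:
            raise ValueError("id tables inconsistent with tensor dimensions")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[2]

    def trial_mean(self) -> np.ndarray:
        """S x N mean response across trials."""
        return self.values.mean(axis=0)

    # ---- I/O ---------------------------------------------------------------

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("responses", data=self.values)
            f.create_dataset("stimulus_ids", data=np.asarray(self.stimulus_ids))
            f.create_dataset("neuron_ids", data=np.asarray(self.neuron_ids))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "ResponseTensor":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                values=f["responses"][...],
                stimulus_ids=f["stimulus_ids"][...] if "stimulus_ids" in f else None,
                neuron_ids=f["neuron_ids"][...] if "neuron_ids" in f else None,
            )

    def to_long_csv(self, path: str | Path) -> None:
        r, s, n = np.meshgrid(
            np.arange(self.n_trials), self.stimulus_ids, self.neuron_ids, indexing="ij"
        )
        pd.DataFrame(
            {
                "trial": r.ravel(),
                "stimulus": s.ravel(),
                "neuron": n.ravel(),
                "dff": self.values.ravel(),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "ResponseTensor":
        df = pd.read_csv(path)
        trials = np.unique(df["trial"])
        stims = np.unique(df["stimulus"])
        neurons = np.unique(df["neuron"])
        piv = df.pivot_table(index=["trial", "stimulus"], columns="neuron", values="dff")
        vals = piv.to_numpy().reshape(len(trials), len(stims), len(neurons))
        return cls(values=vals, stimulus_ids=stims, neuron_ids=neurons)
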