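"""Ground-truth simulator for sparse population responses and small movies.

Emulates the statistical structure the downstream analysis assumes: a large
stimulus set (natural images), ~1000 simultaneously imaged neurons, and very
sparse strong tuning — each stimulus strongly drives only a fraction of a
percent of the population, while most neurons are strongly driven by at
least one stimulus.  All outputs are deterministic functions of their seed.

Desk-scale defaults are S=200 stimuli x N=200 neurons x 3 trials with one
strong responder per stimulus (0.5% of the population); the full recorded
scale (2250 x ~1000) is available by passing the sizes explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import MovieStack, ResponseTensor, TrialTable, TRIAL_TABLE_COLUMNS
import pandas as pd

# Desk-scale study conditions used throughout the analysis scripts.
DEFAULT_S = 200
DEFAULT_N = 200
DEFAULT_K_STRONG = 1
DEFAULT_AMP_STRONG = 1.0
DEFAULT_WEAK_SCALE = 0.05
DEFAULT_NOISE_SD = 0.1
DEFAULT_N_TRIALS = 3


@dataclass
class TuningMatrix:
    """Noiseless S x N stimulus-by-neuron tuning in dF/F0 units.

    Each stimulus row has exactly ``k_strong`` entries at or above
    ``amp_strong`` (the planted strong responders); the remaining entries are
    weak half-normal background responses scaled by ``weak_scale``.
    """

    values: np.ndarray
    k_strong: int
    amp_strong: float
    weak_scale: float
    strong_neurons: np.ndarray = field(default=None)  # S x k_strong neuron indices

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted structure."""

    tuning: TuningMatrix
    noise_sd: float
    seed: int
    planted_shifts: list[tuple[int, int]] | None = None
    planted_rois: list[np.ndarray] | None = None
    neuropil_level: float = 0.0

    def to_json(self, path: str | Path) -> None:
        obj = {
            "k_strong": self.tuning.k_strong,
            "amp_strong": self.tuning.amp_strong,
            "weak_scale": self.tuning.weak_scale,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "neuropil_level": self.neuropil_level,
            "tuning": self.tuning.values.tolist(),
            "strong_neurons": self.tuning.strong_neurons.tolist(),
            "planted_shifts": [list(s) for s in self.planted_shifts]
            if self.planted_shifts is not None
            else None,
            "planted_rois": [r.tolist() for r in self.planted_rois]
            if self.planted_rois is not None
            else None,
        }
        Path(path).write_text(json.dumps(obj))


def _balanced_strong_assignment(S: int, N: int, k_strong: int, rng: np.random.Generator) -> np.ndarray:
    """Assign k_strong strong-responder neurons to each stimulus, balanced.

    Neurons are dealt from a shuffled pool in which each neuron appears as
    evenly as possible (ceil(k*S/N) times), so that when k*S >= N every
    neuron is a strong responder for at least one stimulus — matching the
    observation that most recorded cells respond strongly to at least one
    image.  Within-stimulus duplicates are repaired by random swaps.
    """
    total = S * k_strong
    full_rounds, rem = divmod(total, N)
    pool = np.concatenate(
        [np.tile(np.arange(N), full_rounds), rng.choice(N, size=rem, replace=False)]
    )
    pool = rng.permutation(pool)
    assign = pool.reshape(S, k_strong)
    # repair duplicate neurons within a stimulus row by swapping across rows
    for _ in range(1000):
        dup_rows = [s for s in range(S) if len(set(assign[s])) < k_strong]
        if not dup_rows:
            break
        for s in dup_rows:
            seen: set[int] = set()
            for j in range(k_strong):
                if assign[s, j] in seen:
                    s2 = int(rng.integers(S))
                    j2 = int(rng.integers(k_strong))
                    assign[s, j], assign[s2, j2] = assign[s2, j2], assign[s, j]
                else:
                    seen.add(int(assign[s, j]))
    else:  # pragma: no cover - k_strong close to N can frustrate the repair
        for s in range(S):
            if len(set(assign[s])) < k_strong:
                assign[s] = rng.choice(N, size=k_strong, replace=False)
    return assign


def generate_tuning_matrix(
    S: int = DEFAULT_S,
    N: int = DEFAULT_N,
    k_strong: int = DEFAULT_K_STRONG,
    amp_strong: float = DEFAULT_AMP_STRONG,
    weak_scale: float = DEFAULT_WEAK_SCALE,
    seed: int = 0,
) -> TuningMatrix:
    """Build a sparse non-negative tuning matrix with planted strong responders.

    Per stimulus, ``k_strong`` neurons receive an amplitude drawn uniformly
    in [amp_strong, 1.1*amp_strong]; all other entries are half-normal with
    scale ``weak_scale``.
    """
    if not 1 <= k_strong <= N:
        raise ValueError(f"k_strong must be in [1, N]; got {k_strong} with N={N}")
    if amp_strong <= 0:
        raise ValueError("amp_strong must be positive")
    if weak_scale < 0:
        raise ValueError("weak_scale must be non-negative")
    rng = np.random.default_rng(seed)
    values = weak_scale * np.abs(rng.standard_normal((S, N)))
    strong = _balanced_strong_assignment(S, N, k_strong, rng)
    amps = amp_strong * (1.0 + 0.1 * rng.random((S, k_strong)))
    rows = np.repeat(np.arange(S), k_strong)
    values[rows, strong.ravel()] = amps.ravel()
    return TuningMatrix(
        values=values,
        k_strong=k_strong,
        amp_strong=amp_strong,
        weak_scale=weak_scale,
        strong_neurons=strong,
    )


def generate_response_tensor(
    tuning: TuningMatrix,
    n_trials: int = DEFAULT_N_TRIALS,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    floor_at_zero: bool = True,
) -> tuple[ResponseTensor, GroundTruth]:
    """Add i.i.d. Gaussian trial noise to the tuning matrix per trial.

    With ``floor_at_zero`` (default) responses are clipped at 0 after adding
    noise, keeping the tensor non-negative like dF/F0 responses; disable it
    for analyses that rely on unbiased trial means.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    vals = tuning.values[None, :, :] + noise_sd * rng.standard_normal(
        (n_trials, tuning.n_stimuli, tuning.n_neurons)
    )
    if floor_at_zero:
        vals = np.maximum(vals, 0.0)
    tensor = ResponseTensor(values=vals)
    return tensor, GroundTruth(tuning=tuning, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# movie synthesis
# ---------------------------------------------------------------------------


@dataclass
class MovieLayout:
    """Geometry and intensity parameters for a synthetic imaging plane.

    ROIs are discs of radius ``roi_radius`` placed on a regular grid with at
    least ``margin`` pixels between any ROI pixel and the frame border
    (margin must exceed the largest planted shift plus the neuropil annulus
    extent for registration and extraction to be exact).
    """

    height: int = 128
    width: int = 128
    roi_radius: float = 3.5
    margin: int = 16
    spacing: int = 24
    f0: float = 100.0
    frame_noise_sd: float = 0.0
    frame_rate: float = 8.0


def plant_rois(n_rois: int, layout: MovieLayout) -> list[np.ndarray]:
    """Place ``n_rois`` disc ROIs on a grid; returns (k, 2) pixel arrays."""
    ys = np.arange(layout.margin, layout.height - layout.margin, layout.spacing)
    xs = np.arange(layout.margin, layout.width - layout.margin, layout.spacing)
    centers = [(y, x) for y in ys for x in xs]
    if n_rois > len(centers):
        raise ValueError(
            f"cannot place {n_rois} ROIs on a {len(centers)}-site grid; "
            "shrink spacing/margin or the ROI count"
        )
    yy, xx = np.mgrid[0 : layout.height, 0 : layout.width]
    rois = []
    for cy, cx in centers[:n_rois]:
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= layout.roi_radius**2
        rois.append(np.argwhere(mask))
    return rois


def plant_shifts(
    n_frames: int, max_shift: int, n_reference: int, seed: int = 0
) -> list[tuple[int, int]]:
    """Per-frame integer (dy, dx) jitter: zero during the initial reference
    epoch (the frames later averaged into the registration template), then
    i.i.d. uniform in [-max_shift, max_shift]."""
    rng = np.random.default_rng(seed)
    shifts = [(0, 0)] * min(n_reference, n_frames)
    for _ in range(n_frames - len(shifts)):
        shifts.append((int(rng.integers(-max_shift, max_shift + 1)),
                       int(rng.integers(-max_shift, max_shift + 1))))
    return shifts


def make_trial_table(
    stimuli: np.ndarray | int,
    n_trials: int,
    off_frames: int = 8,
    on_frames: int = 8,
) -> TrialTable:
    """Sequential trial table: each presentation is OFF (blank) then ON.

    Mirrors the recording protocol of a 1 s blank followed by a 1 s stimulus
    at 8 frames/s.  Trials are laid out stimulus-major within each repeat.
    """
    if isinstance(stimuli, (int, np.integer)):
        stimuli = np.arange(stimuli)
    rows = []
    frame = 0
    for t in range(n_trials):
        for s in stimuli:
            rows.append(
                dict(
                    trial=t,
                    stimulus=int(s),
                    off_start=frame,
                    off_end=frame + off_frames,
                    on_start=frame + off_frames,
                    on_end=frame + off_frames + on_frames,
                )
            )
            frame += off_frames + on_frames
    return TrialTable(pd.DataFrame(rows, columns=list(TRIAL_TABLE_COLUMNS)))


def _translate(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    h, w = img.shape
    ys, ye = max(dy, 0), min(h + dy, h)
    xs, xe = max(dx, 0), min(w + dx, w)
    out[ys:ye, xs:xe] = img[ys - dy : ye - dy, xs - dx : xe - dx]
    return out


def generate_movie(
    ground_truth: GroundTruth,
    layout: MovieLayout,
    trial_table: TrialTable,
    neuropil_index: float = 0.7,
) -> MovieStack:
    """Render a movie whose extracted dF/F0 equals the planted responses.

    Pixel model per frame: background pixels carry the neuropil field
    ``n(t)`` (a slowly varying non-negative trace at ``neuropil_level``);
    pixels of ROI i carry ``f0 * (1 + dff_target)`` plus ``r * n(t)``
    contamination, where the dF/F0 target during a trial's ON window is that
    trial's planted response and 0 during OFF.  Subtracting ``r`` times the
    annulus trace therefore recovers the uncontaminated somatic signal
    exactly.  Optional per-frame translations and Gaussian pixel noise are
    applied last.
    """
    rois = ground_truth.planted_rois
    if rois is None:
        raise ValueError("ground truth has no planted ROIs")
    n_rois = len(rois)
    h, w = layout.height, layout.width
    # overlapping or out-of-bounds ROIs are a layout error
    occ = np.zeros((h, w), dtype=int)
    for px in rois:
        if px[:, 0].min() < 0 or px[:, 1].min() < 0 or px[:, 0].max() >= h or px[:, 1].max() >= w:
            raise ValueError("planted ROI extends outside the frame")
        occ[px[:, 0], px[:, 1]] += 1
    if occ.max() > 1:
        raise ValueError("planted ROIs overlap")

    tensor, _ = generate_response_tensor(
        ground_truth.tuning,
        n_trials=int(trial_table.table["trial"].max()) + 1,
        noise_sd=ground_truth.noise_sd,
        seed=ground_truth.seed,
    )
    if tensor.n_neurons < n_rois:
        raise ValueError("tuning matrix has fewer neurons than planted ROIs")

    n_frames = trial_table.n_frames_required
    shifts = ground_truth.planted_shifts or [(0, 0)] * n_frames
    if len(shifts) < n_frames:
        raise ValueError("planted shift list shorter than the movie")
    rng = np.random.default_rng(ground_truth.seed + 1)

    # slowly varying neuropil field, strictly positive when level > 0
    if ground_truth.neuropil_level > 0:
        walk = np.cumsum(rng.standard_normal(n_frames)) * 0.02
        neuropil_trace = ground_truth.neuropil_level * (1.0 + 0.2 * np.sin(walk))
    else:
        neuropil_trace = np.zeros(n_frames)

    stim_index = {s: i for i, s in enumerate(np.unique(trial_table.table["stimulus"]))}
    # per-frame dF/F0 target for every ROI (0 outside ON windows)
    dff = np.zeros((n_frames, n_rois))
    for row in trial_table.table.itertuples():
        si = stim_index[row.stimulus]
        dff[row.on_start : row.on_end, :] = tensor.values[row.trial, si, :n_rois]

    frames = np.empty((n_frames, h, w))
    r = neuropil_index
    for t in range(n_frames):
        scene = np.full((h, w), neuropil_trace[t])
        for i, px in enumerate(rois):
            scene[px[:, 0], px[:, 1]] = layout.f0 * (1.0 + dff[t, i]) + r * neuropil_trace[t]
        dy, dx = shifts[t]
        frame = _translate(scene, dy, dx, fill=neuropil_trace[t])
        if layout.frame_noise_sd > 0:
            frame = frame + layout.frame_noise_sd * rng.standard_normal((h, w))
        frames[t] = frame
    return MovieStack(frames=frames, frame_rate=layout.frame_rate)
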