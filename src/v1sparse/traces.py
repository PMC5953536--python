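"""Fluorescence trace extraction and dF/F0 computation.

Converts a (registered) movie plus an ROI set into the trial x stimulus x
neuron response tensor.  The somatic trace of each ROI is the per-frame mean
over its pixels; neuropil contamination is removed by subtracting
``r`` (default 0.7) times the mean trace of the surrounding annulus; the
response on each trial is (F - F0) / F0 with F0 the mean corrected
fluorescence over the trial's blank (OFF) window and F the mean over the
stimulus (ON) window.
"""

from __future__ import annotations

import numpy as np

from .core import MovieStack, ResponseTensor, RoiSet, TrialTable

DEFAULT_NEUROPIL_INDEX = 0.7


def extract_traces(movie: MovieStack, rois: RoiSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI somatic and neuropil traces, each (n_rois, T).

    ``F[i, t]`` is the mean over ROI i's pixels of frame t; ``F_np[i, t]``
    the mean over its neuropil annulus (zero if the annulus is empty).
    """
    h, w = movie.shape
    n = len(rois)
    T = movie.n_frames
    F = np.empty((n, T))
    F_np = np.zeros((n, T))
    flat = movie.frames.reshape(T, h * w)
    for i, px in enumerate(rois.rois):
        if px.size == 0:
            raise ValueError(f"ROI {i} is empty")
        if px[:, 0].max() >= h or px[:, 1].max() >= w:
            raise ValueError(f"ROI {i} extends outside the movie frame")
        F[i] = flat[:, px[:, 0] * w + px[:, 1]].mean(axis=1)
        ann = rois.neuropil[i]
        if ann.size:
            F_np[i] = flat[:, ann[:, 0] * w + ann[:, 1]].mean(axis=1)
    return F, F_np


def neuropil_correct(
    F: np.ndarray, F_np: np.ndarray, r: float = DEFAULT_NEUROPIL_INDEX
) -> np.ndarray:
    """Remove neuropil contamination: corrected = F - r * F_np."""
    F = np.asarray(F, dtype=float)
    F_np = np.asarray(F_np, dtype=float)
    if F.shape != F_np.shape:
        raise ValueError("somatic and neuropil traces must have the same shape")
    if not 0 <= r <= 1:
        raise ValueError("neuropil index r must be in [0, 1]")
    return F - r * F_np


def compute_dff(trace: np.ndarray, trial_table: TrialTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trial dF/F0 responses for one neuron's corrected trace.

    For every row of the trial table, F0 is the mean of the trace over the
    OFF window and F the mean over the ON window; the response is
    (F - F0) / F0.  Returns (responses, trial ids, stimulus ids) aligned to
    the table rows.  A non-positive baseline aborts with the trial named,
    rather than propagating NaNs into the sparseness counts.
    """
    trace = np.asarray(trace, dtype=float)
    t = trial_table.table
    if t[["off_end", "on_end"]].to_numpy().max() > len(trace):
        raise ValueError("trial windows extend beyond the trace")
    responses = np.empty(len(t))
    for k, row in enumerate(t.itertuples()):
        f0 = trace[row.off_start : row.off_end].mean()
        if f0 <= 0:
            raise ValueError(
                f"degenerate baseline F0={f0:.4g} in trial {row.trial}, "
                f"stimulus {row.stimulus}"
            )
        f = trace[row.on_start : row.on_end].mean()
        responses[k] = (f - f0) / f0
    return responses, t["trial"].to_numpy(), t["stimulus"].to_numpy()


def responses_from_movie(
    movie: MovieStack,
    rois: RoiSet,
    trial_table: TrialTable,
    r: float = DEFAULT_NEUROPIL_INDEX,
) -> ResponseTensor:
    """Full extraction: movie + ROIs -> trial x stimulus x neuron tensor.

    Every stimulus must appear once per trial id (a complete repeat design).
    """
    F, F_np = extract_traces(movie, rois)
    corrected = neuropil_correct(F, F_np, r=r)
    t = trial_table.table
    trials = np.unique(t["trial"])
    stims = np.unique(t["stimulus"])
    counts = t.groupby(["trial", "stimulus"]).size()
    if len(counts) != len(trials) * len(stims) or (counts != 1).any():
        raise ValueError("trial table is not a complete trial x stimulus design")
    trial_pos = {v: i for i, v in enumerate(trials)}
    stim_pos = {v: i for i, v in enumerate(stims)}
    vals = np.empty((len(trials), len(stims), len(rois)))
    for i in range(len(rois)):
        resp, tr, st = compute_dff(corrected[i], trial_table)
        for v, a, b in zip(resp, tr, st):
            vals[trial_pos[a], stim_pos[b], i] = v
    return ResponseTensor(values=vals, stimulus_ids=stims, neuron_ids=np.arange(len(rois)))
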