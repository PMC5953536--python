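"""Nearest-centroid stimulus decoding with response thresholding.

The decoder treats each trial's S x N response matrix as S population
vectors and asks, for every held-out trial vector, which stimulus's centroid
(the element-wise mean of the *other* trials' matrices) is closest in
Euclidean distance — an S-way classification task whose chance accuracy is
1/S.  Cross-validation is leave-one-trial-out over the R trials (3-fold for
the canonical 3-repeat design), and the reported accuracy is the mean of the
per-trial accuracies.

The thresholding experiments measure how much of the decodable information
lives in the largest responses: ``top_only`` keeps only the largest p% of
responses (pooled over trials, stimuli and neurons) and zeroes the rest;
``top_excluded`` zeroes exactly those largest p% and keeps the rest.  In
``relative`` mode the ranking is by response divided by the neuron's own
peak (max trial-mean over stimuli) instead of raw magnitude.  Thresholding
is applied to the whole tensor before the cross-validation split, so train
and test see the same transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import ResponseTensor
from .sparseness import neuron_peaks

#: Percentage grid at which the thresholded decoding curves are evaluated.
DEFAULT_PERCENTAGES = (
    [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
    + [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
    + [20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0]
)


@dataclass
class CentroidModel:
    """Per-stimulus centroids C (S x N) trained with one trial held out."""

    C: np.ndarray
    held_out_trial: int


def train_centroids(tensor: ResponseTensor, held_out_trial: int) -> CentroidModel:
    """Element-wise mean of all trials except ``held_out_trial``."""
    if tensor.n_trials < 2:
        raise ValueError("cross-validation needs at least two trials")
    if not 0 <= held_out_trial < tensor.n_trials:
        raise ValueError("held_out_trial out of range")
    keep = [t for t in range(tensor.n_trials) if t != held_out_trial]
    return CentroidModel(C=tensor.values[keep].mean(axis=0), held_out_trial=held_out_trial)


def predict(x: np.ndarray, model: CentroidModel) -> int:
    """Index of the centroid row closest to ``x`` in Euclidean distance.

    Ties are broken toward the smallest stimulus index (deterministic).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.C.shape[1],):
        raise ValueError("query vector length does not match the centroids")
    d = np.linalg.norm(model.C - x[None, :], axis=1)
    return int(np.argmin(d))


def predict_batch(X: np.ndarray, model: CentroidModel) -> np.ndarray:
    """Vectorized :func:`predict` for an S x N matrix of query rows."""
    d = cdist(np.asarray(X, dtype=float), model.C)
    return d.argmin(axis=1)


def cross_validated_accuracy(tensor: ResponseTensor) -> float:
    """Leave-one-trial-out decoding accuracy, averaged over trials.

    For each trial t: train centroids on the other trials, classify every
    stimulus row of trial t, score the fraction of correct stimulus indices;
    return the mean of the per-trial accuracies.
    """
    accs = []
    truth = np.arange(tensor.n_stimuli)
    for t in range(tensor.n_trials):
        model = train_centroids(tensor, t)
        pred = predict_batch(tensor.values[t], model)
        accs.append(float((pred == truth).mean()))
    return float(np.mean(accs))


def _n_kept(p: float, total: int) -> int:
    """Number of pooled entries in the 'top p%', robust to float round-off."""
    q = p * total / 100.0
    return int(round(q)) if abs(q - round(q)) < 1e-6 else int(np.ceil(q))


def threshold_responses(
    tensor: ResponseTensor,
    p: float,
    keep: str = "top_only",
    mode: str = "absolute",
) -> ResponseTensor:
    """Keep or zero the largest p% of responses, pooled over the tensor.

    ``mode='absolute'`` ranks the raw R*S*N values jointly; ``'relative'``
    ranks each value divided by its neuron's peak (max trial-mean response;
    neurons with a non-positive peak are never ranked into the top);
    ``'relative_per_neuron'`` is the alternative reading of a peak-relative
    threshold, selecting the top p% of each neuron's own R*S entries.  Ties
    at the cut are resolved by a stable order (neuron, then stimulus, then
    trial) so that exactly the computed number of entries is kept and the
    kept sets of ``top_only(p)`` and ``top_excluded(p)`` are exact
    complements.
    """
    if not 0 <= p <= 100:
        raise ValueError("p must be a percentage in [0, 100]")
    if keep not in ("top_only", "top_excluded"):
        raise ValueError("keep must be 'top_only' or 'top_excluded'")
    if mode not in ("absolute", "relative", "relative_per_neuron"):
        raise ValueError("mode must be 'absolute', 'relative' or 'relative_per_neuron'")
    vals = tensor.values
    if mode == "relative_per_neuron":
        return _threshold_per_neuron(tensor, p, keep)
    if mode == "absolute":
        key = vals
    else:
        peaks, valid = neuron_peaks(tensor)
        safe = np.where(valid, peaks, 1.0)
        key = vals / safe[None, None, :]
        key = np.where(valid[None, None, :], key, -np.inf)
    # stable tie order: neuron, then stimulus, then trial -> put the highest
    # priority axis slowest-varying in the flattened key
    key_flat = np.ascontiguousarray(np.transpose(key, (2, 1, 0))).ravel()
    vals_flat = np.ascontiguousarray(np.transpose(vals, (2, 1, 0))).ravel()
    order = np.argsort(-key_flat, kind="stable")
    m = _n_kept(p, key_flat.size)
    top = order[:m]
    if keep == "top_only":
        out_flat = np.zeros_like(vals_flat)
        out_flat[top] = vals_flat[top]
    else:
        out_flat = vals_flat.copy()
        out_flat[top] = 0.0
    out = np.transpose(out_flat.reshape(tensor.n_neurons, tensor.n_stimuli, tensor.n_trials), (2, 1, 0))
    return ResponseTensor(
        values=out.copy(), stimulus_ids=tensor.stimulus_ids, neuron_ids=tensor.neuron_ids
    )


def _threshold_per_neuron(tensor: ResponseTensor, p: float, keep: str) -> ResponseTensor:
    """Per-neuron variant: keep/zero the top p% of each neuron's entries."""
    vals = tensor.values
    R, S, N = vals.shape
    m = _n_kept(p, R * S)
    out = vals.copy() if keep == "top_excluded" else np.zeros_like(vals)
    for i in range(N):
        flat = np.ascontiguousarray(vals[:, :, i].T).ravel()  # stimulus-major ties
        top = np.argsort(-flat, kind="stable")[:m]
        if keep == "top_only":
            sel = np.zeros_like(flat)
            sel[top] = flat[top]
        else:
            sel = flat.copy()
            sel[top] = 0.0
        out[:, :, i] = sel.reshape(S, R).T
    return ResponseTensor(
        values=out, stimulus_ids=tensor.stimulus_ids, neuron_ids=tensor.neuron_ids
    )


@dataclass
class DecodingCurve:
    """Accuracy as a function of the top-response percentage for one mode."""

    keep: str
    mode: str
    percentages: list[float]
    accuracy: list[float]
    full_accuracy: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "keep": self.keep,
                "mode": self.mode,
                "percentage": self.percentages,
                "accuracy": self.accuracy,
                "full_accuracy": self.full_accuracy,
            }
        )


def decoding_curve(
    tensor: ResponseTensor,
    percentages: list[float] | None = None,
    keep: str = "top_only",
    mode: str = "absolute",
) -> DecodingCurve:
    """Evaluate cross-validated accuracy after thresholding at each p.

    The full-data accuracy is also computed as the reference ("achievable")
    performance; ``top_only`` at p = 100 and ``top_excluded`` at p = 0
    reproduce it exactly since the tensor is untouched.
    """
    if percentages is None:
        percentages = list(DEFAULT_PERCENTAGES)
    if any(p < 0 or p > 100 for p in percentages):
        raise ValueError("percentages must lie in [0, 100]")
    full = cross_validated_accuracy(tensor)
    accs = [
        cross_validated_accuracy(threshold_responses(tensor, p, keep=keep, mode=mode))
        for p in percentages
    ]
    return DecodingCurve(
        keep=keep, mode=mode, percentages=list(percentages), accuracy=accs, full_accuracy=full
    )
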