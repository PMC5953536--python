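"""Half-maximum sparseness statistics for population response tensors.

The central statistic is deliberately simple: a neuron "responds strongly"
to a stimulus when its trial-mean response exceeds half of that neuron's own
peak (its maximum trial-mean response over the whole stimulus set).

* population sparseness of a stimulus — the fraction of neurons strongly
  driven by it (a peaked population response distribution gives a small
  fraction);
* life-time sparseness of a neuron — the fraction of stimuli that drive it
  strongly (the half-height width of its tuning curve, as a fraction).

Because the threshold is relative to each neuron's own peak, both measures
are invariant to rescaling any single neuron's responses, and they are far
less sensitive to baseline offsets and weak-response nonlinearity of calcium
signals than moment-based sparseness indices, which are provided here only
for comparison (:func:`classic_sparseness`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ResponseTensor

DEFAULT_THRESH_FRAC = 0.5


def neuron_peaks(tensor: ResponseTensor) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron peak (max over stimuli of the trial-mean response).

    Returns ``(peaks, valid)`` where ``valid`` flags neurons with a strictly
    positive peak; the rest are excluded from sparseness counts downstream
    (a non-positive peak makes the half-max threshold meaningless).
    """
    means = tensor.trial_mean()  # S x N
    peaks = means.max(axis=0)
    return peaks, peaks > 0


def _above_half_max(tensor: ResponseTensor, thresh_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean S x N matrix of strong responses, plus the valid-neuron mask."""
    if not 0 < thresh_frac < 1:
        raise ValueError("thresh_frac must be in (0, 1)")
    peaks, valid = neuron_peaks(tensor)
    means = tensor.trial_mean()
    strong = means > thresh_frac * peaks[None, :]
    strong[:, ~valid] = False
    return strong, valid


def population_sparseness(
    tensor: ResponseTensor, thresh_frac: float = DEFAULT_THRESH_FRAC
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stimulus count and fraction of neurons above half their own peak.

    The count for stimulus s is over valid neurons whose trial-mean response
    to s strictly exceeds ``thresh_frac`` times their own peak; the fraction
    divides by the number of valid neurons.
    """
    strong, valid = _above_half_max(tensor, thresh_frac)
    counts = strong.sum(axis=1)
    return counts, counts / max(int(valid.sum()), 1)


def lifetime_sparseness(
    tensor: ResponseTensor, thresh_frac: float = DEFAULT_THRESH_FRAC
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron count and fraction of stimuli above half the neuron's peak.

    Invalid (non-positive-peak) neurons get count 0 and fraction NaN.
    """
    strong, valid = _above_half_max(tensor, thresh_frac)
    counts = strong.sum(axis=0)
    frac = counts / tensor.n_stimuli
    frac = np.where(valid, frac, np.nan)
    return counts, frac


def classic_sparseness(responses: np.ndarray) -> float:
    """Moment-based (Treves–Rolls / Vinje–Gallant style) sparseness of one
    response vector: with a = (sum r / n)^2 / (sum r^2 / n), returns
    (1 - a) / (1 - 1/n), in [0, 1] (1 = one-hot, 0 = flat).

    Negative responses are floored at 0 for this measure only; an all-zero
    vector has no defined value and returns NaN.
    """
    r = np.maximum(np.asarray(responses, dtype=float), 0.0)
    n = r.size
    if n < 2:
        raise ValueError("need at least two responses")
    sq = (r**2).sum()
    if sq == 0:
        return float("nan")
    a = (r.sum() / n) ** 2 / (sq / n)
    return float((1 - a) / (1 - 1 / n))


@dataclass
class SparsenessSummary:
    """All half-max sparseness outputs for one response tensor."""

    per_stimulus_counts: np.ndarray
    per_stimulus_fraction: np.ndarray
    per_neuron_counts: np.ndarray
    per_neuron_fraction: np.ndarray
    neuron_peaks: np.ndarray
    valid_neurons: np.ndarray
    mean_population_sparseness: float
    mean_lifetime_sparseness: float
    n_excluded_neurons: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mean_population_sparseness": self.mean_population_sparseness,
                    "mean_lifetime_sparseness": self.mean_lifetime_sparseness,
                    "mean_population_count": float(self.per_stimulus_counts.mean()),
                    "mean_lifetime_count": float(
                        self.per_neuron_counts[self.valid_neurons].mean()
                    ),
                    "n_excluded_neurons": self.n_excluded_neurons,
                }
            )
        )

    def histograms(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Integer-count histograms (population and life-time sparseness)."""
        pop = pd.Series(self.per_stimulus_counts).value_counts().sort_index()
        life = pd.Series(self.per_neuron_counts[self.valid_neurons]).value_counts().sort_index()
        return (
            pop.rename_axis("n_neurons_above_half_max").reset_index(name="n_stimuli"),
            life.rename_axis("n_stimuli_above_half_max").reset_index(name="n_neurons"),
        )


def sparseness_summary(
    tensor: ResponseTensor, thresh_frac: float = DEFAULT_THRESH_FRAC
) -> SparsenessSummary:
    """Compute all half-max sparseness statistics for a tensor."""
    peaks, valid = neuron_peaks(tensor)
    pop_counts, pop_frac = population_sparseness(tensor, thresh_frac)
    life_counts, life_frac = lifetime_sparseness(tensor, thresh_frac)
    return SparsenessSummary(
        per_stimulus_counts=pop_counts,
        per_stimulus_fraction=pop_frac,
        per_neuron_counts=life_counts,
        per_neuron_fraction=life_frac,
        neuron_peaks=peaks,
        valid_neurons=valid,
        mean_population_sparseness=float(pop_frac.mean()),
        mean_lifetime_sparseness=float(np.nanmean(life_frac)) if valid.any() else float("nan"),
        n_excluded_neurons=int((~valid).sum()),
    )
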