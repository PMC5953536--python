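"""Trial-to-trial reliability of sparse strong responses via shuffle ROC.

For each neuron, stimuli whose trial-mean response exceeds half the neuron's
maximum mean response form the ON class; the rest are OFF.  The AUC of an
ROC separating single-trial ON responses from OFF responses is close to 1
when the strong responses repeat across trials.  The null hypothesis —
strong responses are one-off events, not stimulus-locked — is tested by
shuffling the pooled single-trial responses across (trial, stimulus) slots;
each shuffle recomputes the per-stimulus means, the half-max threshold, the
ON/OFF classes and the AUC, and the p-value is the fraction of shuffles
whose AUC reaches the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import ResponseTensor

DEFAULT_N_SHUFFLES = 1000


def classify_on_off(mean_responses: np.ndarray, thresh_frac: float = 0.5) -> np.ndarray:
    """Boolean ON mask: mean response > thresh_frac * max mean response.

    The peak stimulus is always ON; with all means equal, every stimulus is
    ON (every value exceeds half of itself when positive).
    """
    means = np.asarray(mean_responses, dtype=float)
    if means.size < 2:
        raise ValueError("need at least two stimuli")
    return means > thresh_frac * means.max()


def auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-sum AUC: P(random ON value > random OFF value), ties count 1/2."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_on = int(labels.sum())
    n_off = labels.size - n_on
    if n_on == 0 or n_off == 0:
        raise ValueError("both classes must be non-empty to define an AUC")
    ranks = rankdata(values)
    return float((ranks[labels].sum() - n_on * (n_on + 1) / 2) / (n_on * n_off))


@dataclass
class ReliabilityResult:
    observed_auc: float
    shuffle_aucs: np.ndarray
    p_value: float
    on_class: np.ndarray  # boolean per-stimulus mask
    n_shuffles: int


def shuffle_test(
    trial_responses: np.ndarray,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    thresh_frac: float = 0.5,
    seed: int = 0,
    plus_one: bool = True,
) -> ReliabilityResult:
    """Shuffle-ROC reliability test for one neuron's R x S trial responses.

    Shuffling permutes the pooled R*S single-trial responses jointly across
    all (trial, stimulus) slots; per shuffle the per-stimulus means, the
    half-max threshold, the ON/OFF classes and the AUC are all recomputed.
    Shuffle AUCs reaching the observed AUC (>=) count against significance.
    With ``plus_one`` (default) the p-value is (1 + hits) / (1 + n_shuffles),
    which can never be exactly zero; the plain fraction hits / n_shuffles is
    available with ``plus_one=False``.

    A shuffle (or the observed data) with an empty OFF class — all stimuli
    above half-max, as happens when all responses are equal — has no defined
    ROC; such shuffles are scored AUC = 0.5, and fully degenerate observed
    data returns p = 1 with a warning.
    """
    x = np.asarray(trial_responses, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("trial_responses must be R x S with R >= 2")
    R, S = x.shape
    rng = np.random.default_rng(seed)
    pooled = x.ravel()  # slot order: trial-major, (r, s)

    def _auc_from(on_mask: np.ndarray, ranks_rs: np.ndarray) -> float:
        n_on = R * int(on_mask.sum())
        n_off = R * S - n_on
        if n_on == 0 or n_off == 0:
            return 0.5
        ranks_on = ranks_rs.reshape(R, S)[:, on_mask].sum()
        return (ranks_on - n_on * (n_on + 1) / 2) / (n_on * n_off)

    ranks = rankdata(pooled)
    means = x.mean(axis=0)
    degenerate = np.allclose(x, x.flat[0])
    on_obs = classify_on_off(means, thresh_frac)
    auc_obs = _auc_from(on_obs, ranks)

    if degenerate:
        warnings.warn("all responses equal; reliability test is undefined (p = 1)")
        return ReliabilityResult(
            observed_auc=0.5,
            shuffle_aucs=np.full(n_shuffles, 0.5),
            p_value=1.0,
            on_class=on_obs,
            n_shuffles=n_shuffles,
        )

    # vectorized shuffles: permute pooled values (and their ranks) per shuffle
    perms = np.argsort(rng.random((n_shuffles, R * S)), axis=1)
    shuf_vals = pooled[perms].reshape(n_shuffles, R, S)
    shuf_means = shuf_vals.mean(axis=1)
    thr = thresh_frac * shuf_means.max(axis=1)
    on = shuf_means > thr[:, None]  # n_shuffles x S
    n_on = R * on.sum(axis=1)
    n_off = R * S - n_on
    shuf_ranks = ranks[perms].reshape(n_shuffles, R, S)
    rank_sums = (shuf_ranks * on[:, None, :]).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        shuffle_aucs = (rank_sums - n_on * (n_on + 1) / 2) / (n_on * n_off)
    shuffle_aucs = np.where((n_on == 0) | (n_off == 0), 0.5, shuffle_aucs)

    hits = int((shuffle_aucs >= auc_obs - 1e-12).sum())
    p = (1 + hits) / (1 + n_shuffles) if plus_one else hits / n_shuffles
    return ReliabilityResult(
        observed_auc=float(auc_obs),
        shuffle_aucs=shuffle_aucs,
        p_value=float(p),
        on_class=on_obs,
        n_shuffles=n_shuffles,
    )


def population_reliability(
    tensor: ResponseTensor,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    thresh_frac: float = 0.5,
    seed: int = 0,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, float]:
    """Run the shuffle test on every neuron of a tensor.

    Returns a per-neuron table (neuron, auc, p_value, n_on) and the fraction
    of neurons significant at ``alpha`` — the population's reliability.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(tensor.n_neurons):
        res = shuffle_test(
            tensor.values[:, :, i],
            n_shuffles=n_shuffles,
            thresh_frac=thresh_frac,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            dict(
                neuron=int(tensor.neuron_ids[i]),
                auc=res.observed_auc,
                p_value=res.p_value,
                n_on=int(res.on_class.sum()),
            )
        )
    df = pd.DataFrame(rows)
    return df, float((df["p_value"] < alpha).mean())
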