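"""Independent brute-force oracles used to cross-check the implementation.

Every function here is written as a naive loop (or direct formula) and
never calls the package's own vectorized code paths.
"""

from __future__ import annotations

import numpy as np


def peaks_oracle(values: np.ndarray) -> np.ndarray:
    """Per-neuron max over stimuli of the trial-mean response, double loop."""
    R, S, N = values.shape
    peaks = np.empty(N)
    for n in range(N):
        best = -np.inf
        for s in range(S):
            m = sum(values[r, s, n] for r in range(R)) / R
            best = max(best, m)
        peaks[n] = best
    return peaks


def population_counts_oracle(values: np.ndarray, thresh_frac: float = 0.5) -> np.ndarray:
    """Per-stimulus count of neurons above thresh_frac of their own peak."""
    R, S, N = values.shape
    peaks = peaks_oracle(values)
    counts = np.zeros(S, dtype=int)
    for s in range(S):
        for n in range(N):
            if peaks[n] <= 0:
                continue
            m = sum(values[r, s, n] for r in range(R)) / R
            if m > thresh_frac * peaks[n]:
                counts[s] += 1
    return counts


def lifetime_counts_oracle(values: np.ndarray, thresh_frac: float = 0.5) -> np.ndarray:
    """Per-neuron count of stimuli above thresh_frac of the neuron's peak."""
    R, S, N = values.shape
    peaks = peaks_oracle(values)
    counts = np.zeros(N, dtype=int)
    for n in range(N):
        if peaks[n] <= 0:
            continue
        for s in range(S):
            m = sum(values[r, s, n] for r in range(R)) / R
            if m > thresh_frac * peaks[n]:
                counts[n] += 1
    return counts


def auc_oracle(values: np.ndarray, labels: np.ndarray) -> float:
    """P(ON > OFF) by exhaustive pair enumeration, ties counting 1/2."""
    on = [v for v, l in zip(values, labels) if l]
    off = [v for v, l in zip(values, labels) if not l]
    wins = 0.0
    for a in on:
        for b in off:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(on) * len(off))


def centroid_oracle(values: np.ndarray, held_out: int) -> np.ndarray:
    """Per-entry loop mean over all trials except held_out."""
    R, S, N = values.shape
    C = np.zeros((S, N))
    for s in range(S):
        for n in range(N):
            acc = 0.0
            for r in range(R):
                if r != held_out:
                    acc += values[r, s, n]
            C[s, n] = acc / (R - 1)
    return C


def predict_oracle(x: np.ndarray, C: np.ndarray) -> int:
    """Exhaustive Euclidean argmin with first-wins tie break."""
    best, best_d = 0, np.inf
    for s in range(C.shape[0]):
        d = float(np.sqrt(((C[s] - x) ** 2).sum()))
        if d < best_d:
            best, best_d = s, d
    return best


def cv_accuracy_oracle(values: np.ndarray) -> float:
    """End-to-end leave-one-trial-out nearest-centroid accuracy, all loops."""
    R, S, N = values.shape
    accs = []
    for t in range(R):
        C = centroid_oracle(values, t)
        correct = sum(predict_oracle(values[t, s], C) == s for s in range(S))
        accs.append(correct / S)
    return float(np.mean(accs))


def top_only_oracle(values: np.ndarray, p: float) -> np.ndarray:
    """Keep the top-p% pooled entries by sort-and-count (distinct values)."""
    flat = values.ravel()
    total = flat.size
    q = p * total / 100.0
    m = int(round(q)) if abs(q - round(q)) < 1e-6 else int(np.ceil(q))
    if m == 0:
        return np.zeros_like(values)
    cutoff = np.sort(flat)[::-1][m - 1]
    out = np.where(values >= cutoff, values, 0.0)
    return out


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """The discrete Gaussian kernel scipy.ndimage uses (normalized, truncated)."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur_oracle(image: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Direct separable convolution with reflect padding, explicit loops."""
    k = gaussian_kernel_1d(sigma, truncate)
    r = (len(k) - 1) // 2
    # scipy.ndimage's "reflect" boundary duplicates the edge sample,
    # i.e. numpy's "symmetric" padding
    padded = np.pad(image, r, mode="symmetric")
    h, w = image.shape
    tmp = np.zeros((h, w + 2 * r))
    for i in range(h):
        for j in range(w + 2 * r):
            tmp[i, j] = sum(padded[i + r + kk, j] * k[kk + r] for kk in range(-r, r + 1))
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = sum(tmp[i, j + kk + r] * k[kk + r] for kk in range(-r, r + 1))
    return out


def register_shift_oracle(frame: np.ndarray, template: np.ndarray, max_shift: int) -> tuple[int, int]:
    """Exhaustive search over the shift grid maximizing the Pearson
    correlation of the overlapping region."""
    h, w = frame.shape
    best, best_c = (0, 0), -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            ys, ye = max(dy, 0), min(h + dy, h)
            xs, xe = max(dx, 0), min(w + dx, w)
            f = frame[ys:ye, xs:xe].ravel()
            t = template[ys - dy : ye - dy, xs - dx : xe - dx].ravel()
            if f.std() == 0 or t.std() == 0:
                continue
            c = np.corrcoef(f, t)[0, 1]
            if c > best_c:
                best, best_c = (dy, dx), c
    return best


def iou(px_a: np.ndarray, px_b: np.ndarray) -> float:
    a = set(map(tuple, np.asarray(px_a).tolist()))
    b = set(map(tuple, np.asarray(px_b).tolist()))
    return len(a & b) / len(a | b)
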