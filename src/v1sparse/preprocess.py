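"""Movie preprocessing: rigid registration, differential images, ROI detection.

Cell bodies in densely labelled superficial cortex are often too dim at rest
to segment anatomically, so ROIs are found functionally: for each stimulus,
average the stimulus-ON frames and subtract the average of the preceding
blank (OFF) frames; band-pass the differential image with a difference of
Gaussians; and keep connected pixel groups larger than ``min_pixels`` whose
values exceed the image mean by ``z_thresh`` standard deviations.  The
band-pass is used only for ROI identification — all response measurements
downstream read the raw movie.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.morphology import disk

from .core import MovieStack, RoiSet, TrialTable


def build_template(movie: MovieStack, n_frames: int = 1000) -> np.ndarray:
    """Registration template: pixel-wise mean of the first ``n_frames`` frames."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    n = min(n_frames, movie.n_frames)
    return movie.frames[:n].mean(axis=0)


def register_frames(
    movie: MovieStack, template: np.ndarray, max_shift: int = 8
) -> tuple[MovieStack, list[tuple[int, int]]]:
    """Rigid translation correction by normalized cross-correlation.

    For each frame, searches integer shifts within ±``max_shift`` for the
    translation maximizing the normalized cross-correlation with the
    template, then translates the frame back; vacated edge pixels are filled
    from the template so differential images stay unbiased at the borders.

    Returns the corrected movie and the detected per-frame (dy, dx) shifts
    (positive dy/dx = frame content displaced down/right relative to the
    template).
    """
    h, w = movie.shape
    if max_shift >= min(h, w) // 2:
        raise ValueError("max_shift too large for the frame size")
    template = np.asarray(template, dtype=float)
    out = np.empty_like(movie.frames)
    shifts: list[tuple[int, int]] = []
    m = max_shift
    for t, frame in enumerate(movie.frames):
        if frame.std() == 0:
            warnings.warn(f"frame {t} has zero variance; assuming no shift")
            dy = dx = 0
        else:
            padded = np.pad(frame, m, mode="edge")
            ncc = match_template(padded, template)
            i, j = np.unravel_index(np.argmax(ncc), ncc.shape)
            dy, dx = int(i) - m, int(j) - m
        shifts.append((dy, dx))
        corrected = template.copy()
        ys, ye = max(dy, 0), min(h + dy, h)
        xs, xe = max(dx, 0), min(w + dx, w)
        corrected[ys - dy : ye - dy, xs - dx : xe - dx] = frame[ys:ye, xs:xe]
        out[t] = corrected
    return MovieStack(frames=out, frame_rate=movie.frame_rate), shifts


def differential_image(movie: MovieStack, trial_table: TrialTable, stimulus) -> np.ndarray:
    """Mean ON frame minus mean OFF frame over all trials of one stimulus."""
    rows = trial_table.rows_for_stimulus(stimulus)
    on_idx = np.concatenate([np.arange(r.on_start, r.on_end) for r in rows.itertuples()])
    off_idx = np.concatenate([np.arange(r.off_start, r.off_end) for r in rows.itertuples()])
    if on_idx.max() >= movie.n_frames or off_idx.max() >= movie.n_frames:
        raise ValueError("trial windows extend beyond the movie")
    return movie.frames[on_idx].mean(axis=0) - movie.frames[off_idx].mean(axis=0)


def bandpass_filter(
    image: np.ndarray, low_size: float = 5.0, high_size: float = 50.0
) -> np.ndarray:
    """Difference-of-Gaussians band-pass: blur at sigma=low minus sigma=high.

    Removes both pixel noise (scales below ``low_size``) and slow background
    (scales above ``high_size``); a constant image maps to zero.
    """
    if low_size <= 0 or high_size <= 0:
        raise ValueError("filter sizes must be positive")
    if low_size >= high_size:
        raise ValueError("low_size must be smaller than high_size")
    image = np.asarray(image, dtype=float)
    return ndimage.gaussian_filter(image, low_size) - ndimage.gaussian_filter(image, high_size)


def _components(mask: np.ndarray, connectivity: int) -> list[np.ndarray]:
    structure = np.ones((3, 3), bool) if connectivity == 8 else None
    lab, n = ndimage.label(mask, structure=structure)
    return [np.argwhere(lab == i) for i in range(1, n + 1)]


def _neuropil_annuli(
    roi_masks: list[np.ndarray], shape: tuple[int, int], gap: int, width: int
) -> list[np.ndarray]:
    any_roi = np.zeros(shape, bool)
    masks = []
    for px in roi_masks:
        mask = np.zeros(shape, bool)
        mask[px[:, 0], px[:, 1]] = True
        masks.append(mask)
        any_roi |= mask
    annuli = []
    for mask in masks:
        inner = ndimage.binary_dilation(mask, structure=disk(gap))
        outer = ndimage.binary_dilation(mask, structure=disk(gap + width))
        annuli.append(np.argwhere(outer & ~inner & ~any_roi))
    return annuli


def detect_rois(
    diff_images: list[np.ndarray],
    z_thresh: float = 3.0,
    min_pixels: int = 25,
    low_size: float = 5.0,
    high_size: float = 50.0,
    connectivity: int = 8,
    merge_overlap: float = 0.5,
    annulus_gap: int = 2,
    annulus_width: int = 4,
) -> RoiSet:
    """Segment active-cell ROIs from a set of differential images.

    Per image: band-pass, threshold at mean + ``z_thresh``·std (statistics
    over that image's pixels), take connected components (8-connectivity by
    default) with more than ``min_pixels`` pixels whose mean value exceeds
    the threshold.  Components from different images are merged (union) when
    their overlap exceeds ``merge_overlap`` of the smaller component;
    remaining overlaps are resolved by assigning contested pixels to the
    larger ROI so the final pixel sets are disjoint.  A neuropil annulus
    (``annulus_width`` px wide, starting ``annulus_gap`` px out, excluding
    all ROI pixels) is attached to each ROI.
    """
    if len(diff_images) == 0:
        raise ValueError("need at least one differential image")
    shape = np.asarray(diff_images[0]).shape
    comps: list[set[tuple[int, int]]] = []
    for img in diff_images:
        img = np.asarray(img, dtype=float)
        if img.shape != shape:
            raise ValueError("differential images must share a shape")
        f = bandpass_filter(img, low_size, high_size)
        thr = f.mean() + z_thresh * f.std()
        for px in _components(f > thr, connectivity):
            if len(px) > min_pixels and f[px[:, 0], px[:, 1]].mean() > thr:
                comps.append(set(map(tuple, px.tolist())))

    # merge detections of the same cell across differential images
    merged: list[set[tuple[int, int]]] = []
    for comp in comps:
        target = None
        for existing in merged:
            ov = len(comp & existing)
            if ov > merge_overlap * min(len(comp), len(existing)):
                target = existing
                break
        if target is None:
            merged.append(set(comp))
        else:
            target |= comp

    # repeat merging until stable (unions can create new overlaps)
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                ov = len(merged[i] & merged[j])
                if ov and ov > merge_overlap * min(len(merged[i]), len(merged[j])):
                    merged[i] |= merged[j]
                    del merged[j]
                    changed = True
                    break
            if changed:
                break

    # enforce disjointness: contested pixels go to the larger ROI
    merged.sort(key=len, reverse=True)
    taken: set[tuple[int, int]] = set()
    rois: list[np.ndarray] = []
    for comp in merged:
        comp = comp - taken
        if len(comp) > min_pixels:
            taken |= comp
            rois.append(np.array(sorted(comp)))

    annuli = _neuropil_annuli(rois, shape, annulus_gap, annulus_width)
    return RoiSet(rois=rois, neuropil=annuli, shape=tuple(shape))
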