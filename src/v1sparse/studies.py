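"""Canned desk-scale experiments reproducing the analysis end to end.

Each function builds its own synthetic inputs at the stated problem size,
runs the relevant pipeline stages, and returns plain-dict measurements.
They are the single source for both the acceptance checks and the analysis
drivers, so the reported numbers always come from the same code path as the
library itself.
"""

from __future__ import annotations

import numpy as np

from . import preprocess as pp
from . import reliability as rel
from . import sparseness as sp
from . import synthetic as syn
from . import traces as tr
from .core import ResponseTensor, RoiSet
from .decoding import cross_validated_accuracy, threshold_responses

# band-pass scales for the desk-scale synthetic movies: planted somata span
# ~37 px (r = 3.5), an order of magnitude smaller than real cell bodies at
# recording resolution, so the filter scales shrink in proportion
MOVIE_LOW_SIZE = 1.0
MOVIE_HIGH_SIZE = 20.0


def desk_scale_tensor(seed: int, noise_sd: float = syn.DEFAULT_NOISE_SD):
    """The default study conditions: S=200, N=200, k_strong=1, 3 trials."""
    tuning = syn.generate_tuning_matrix(seed=seed)
    tensor, truth = syn.generate_response_tensor(tuning, noise_sd=noise_sd, seed=seed + 1)
    return tensor, truth


def chance_decoding_study(seed: int, S: int = 2250, N: int = 50, n_trials: int = 3) -> dict:
    """Nearest-centroid accuracy on stimulus-independent responses.

    With i.i.d. responses carrying no stimulus information, the S-way
    decoder performs at chance, 1/S (0.044% for the full 2250-image set).
    """
    rng = np.random.default_rng(seed)
    tensor = ResponseTensor(values=np.abs(rng.standard_normal((n_trials, S, N))))
    acc = cross_validated_accuracy(tensor)
    p = 1.0 / S
    se = float(np.sqrt(p * (1 - p) / (n_trials * S)))
    return {"accuracy": acc, "chance": p, "binomial_se": se, "n_tests": n_trials * S}


def sparseness_recovery_study(seed: int) -> dict:
    """Noise-free closure: generator -> sparseness statistics.

    With noise_sd = 0 the half-max population sparseness must equal
    k_strong/N for every stimulus and the per-neuron lifetime counts must
    match the planted strong-responder assignment exactly.
    """
    tuning = syn.generate_tuning_matrix(seed=seed)
    tensor, _ = syn.generate_response_tensor(tuning, noise_sd=0.0, seed=seed + 1)
    pop_counts, pop_frac = sp.population_sparseness(tensor)
    life_counts, _ = sp.lifetime_sparseness(tensor)
    true_life = np.bincount(tuning.strong_neurons.ravel(), minlength=tuning.n_neurons)
    return {
        "population_counts": pop_counts,
        "population_fraction": pop_frac,
        "expected_fraction": tuning.k_strong / tuning.n_neurons,
        "lifetime_counts": life_counts,
        "true_lifetime_counts": true_life,
        "lifetime_exact": bool((life_counts == true_life).all()),
    }


def sparseness_study(seed: int) -> dict:
    """Half-max sparseness under the default (noisy) study conditions."""
    tensor, _ = desk_scale_tensor(seed)
    s = sp.sparseness_summary(tensor)
    return {
        "mean_population_fraction": s.mean_population_sparseness,
        "mean_population_count": float(s.per_stimulus_counts.mean()),
        "mean_lifetime_fraction": s.mean_lifetime_sparseness,
        "n_neurons": tensor.n_neurons,
        "n_stimuli": tensor.n_stimuli,
    }


def reliability_calibration_study(
    seed: int, n_null: int = 2000, S: int = 50, R: int = 3, n_shuffles: int = 1000
) -> dict:
    """Type-I error of the shuffle-ROC test on exchangeable null neurons."""
    rng = np.random.default_rng(seed)
    ps = np.empty(n_null)
    for i in range(n_null):
        x = rng.standard_normal((R, S))
        ps[i] = rel.shuffle_test(x, n_shuffles=n_shuffles, seed=int(rng.integers(2**31))).p_value
    return {"type1_rate": float((ps < 0.01).mean()), "n_null": n_null, "p_values": ps}


def tuned_reliability_study(
    seed: int, n_replicates: int = 200, S: int = 200, R: int = 3, n_shuffles: int = 1000
) -> dict:
    """Shuffle-ROC significance rate for strongly tuned synthetic neurons.

    Each replicate neuron follows the default generator's single-neuron
    statistics: one strong stimulus near 1.0 dF/F0, weak half-normal
    background, moderate trial noise.
    """
    rng = np.random.default_rng(seed)
    sig = 0
    for _ in range(n_replicates):
        tuning = syn.DEFAULT_WEAK_SCALE * np.abs(rng.standard_normal(S))
        tuning[rng.integers(S)] = syn.DEFAULT_AMP_STRONG * (1 + 0.1 * rng.random())
        x = tuning[None, :] + syn.DEFAULT_NOISE_SD * rng.standard_normal((R, S))
        x = np.maximum(x, 0.0)
        res = rel.shuffle_test(x, n_shuffles=n_shuffles, seed=int(rng.integers(2**31)))
        sig += res.p_value <= 0.01
    return {"fraction_significant": sig / n_replicates, "n_replicates": n_replicates}


def decoding_study(seed: int, percentages=(0.5, 1.0, 2.0, 5.0)) -> dict:
    """Full vs thresholded decoding accuracy at desk scale."""
    tensor, _ = desk_scale_tensor(seed)
    full = cross_validated_accuracy(tensor)
    top_only = {
        p: cross_validated_accuracy(threshold_responses(tensor, p, "top_only"))
        for p in percentages
    }
    top_excluded = {
        p: cross_validated_accuracy(threshold_responses(tensor, p, "top_excluded"))
        for p in percentages
    }
    return {
        "full_accuracy": full,
        "top_only": top_only,
        "top_excluded": top_excluded,
        "n_stimuli": tensor.n_stimuli,
    }


def imaging_closure_study(
    seed: int,
    n_stimuli: int = 50,
    n_trials: int = 4,
    n_rois: int = 16,
    max_shift: int = 4,
    template_frames: int = 1000,
) -> dict:
    """Noise-free movie round trip at 128 x 128 with 200 trials.

    Plants disc ROIs, per-frame translations (zero during the template
    epoch) and neuropil contamination, then runs registration, ROI
    detection and dF/F0 extraction and scores recovery of every planted
    quantity.
    """
    layout = syn.MovieLayout(height=128, width=128, margin=16, spacing=24)
    rois = syn.plant_rois(n_rois, layout)
    tuning = syn.generate_tuning_matrix(n_stimuli, n_rois, 1, seed=seed)
    trials = syn.make_trial_table(n_stimuli, n_trials)
    shifts = syn.plant_shifts(
        trials.n_frames_required, max_shift, n_reference=template_frames, seed=seed + 1
    )
    truth = syn.GroundTruth(
        tuning=tuning,
        noise_sd=0.0,
        seed=seed,
        planted_shifts=shifts,
        planted_rois=rois,
        neuropil_level=5.0,
    )
    movie = syn.generate_movie(truth, layout, trials)

    template = pp.build_template(movie, template_frames)
    registered, found = pp.register_frames(movie, template, max_shift=max_shift)
    shift_exact = np.mean([a == b for a, b in zip(found, shifts)])

    diffs = [pp.differential_image(registered, trials, s) for s in trials.stimuli]
    detected = pp.detect_rois(diffs, low_size=MOVIE_LOW_SIZE, high_size=MOVIE_HIGH_SIZE)

    def _iou(a, b):
        sa = set(map(tuple, a.tolist()))
        sb = set(map(tuple, b.tolist()))
        return len(sa & sb) / len(sa | sb)

    ious = [max((_iou(p, d) for d in detected.rois), default=0.0) for p in rois]
    matched = {
        int(np.argmax([_iou(p, d) for p in rois])) for d in detected.rois
    }
    false_positives = sum(
        1 for d in detected.rois if max(_iou(p, d) for p in rois) <= 0.5
    )

    planted_set = RoiSet(
        rois=[r.copy() for r in rois],
        neuropil=pp._neuropil_annuli(rois, (layout.height, layout.width), 2, 4),
        shape=(layout.height, layout.width),
    )
    tensor = tr.responses_from_movie(registered, planted_set, trials)
    planted, _ = syn.generate_response_tensor(tuning, n_trials, 0.0, seed=seed)
    denom = np.maximum(np.abs(planted.values), 1e-3)
    rel_err = float((np.abs(tensor.values - planted.values) / denom).max())

    return {
        "n_trials": len(trials.table),
        "shift_exact_rate": float(shift_exact),
        "n_planted": n_rois,
        "n_detected": len(detected),
        "min_iou": float(min(ious)),
        "n_matched": len(matched),
        "false_positives": int(false_positives),
        "max_relative_extraction_error": rel_err,
    }
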