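import numpy as np
import pytest

from v1sparse import synthetic as syn
from v1sparse.core import ResponseTensor, RoiSet
from v1sparse.preprocess import _neuropil_annuli


@pytest.fixture(scope="session")
def desk_tensor():
    """Desk-scale study conditions: S=200, N=200, one strong responder per
    stimulus, moderate trial noise, 3 trials."""
    tuning = syn.generate_tuning_matrix(seed=11)
    tensor, truth = syn.generate_response_tensor(tuning, seed=12)
    return tensor, truth


@pytest.fixture(scope="session")
def small_movie_bundle():
    """A 96x96 noiseless movie with 9 planted disc ROIs, 12 stimuli x 3
    trials, planted shifts (zero in the template epoch) and neuropil
    contamination — small enough for unit tests, rich enough to exercise
    registration, detection and extraction."""
    layout = syn.MovieLayout(height=96, width=96, margin=14, spacing=22)
    rois = syn.plant_rois(9, layout)
    tuning = syn.generate_tuning_matrix(12, 9, 1, 1.0, 0.05, seed=3)
    trials = syn.make_trial_table(12, 3)
    shifts = syn.plant_shifts(trials.n_frames_required, 3, n_reference=64, seed=4)
    truth = syn.GroundTruth(
        tuning=tuning,
        noise_sd=0.0,
        seed=3,
        planted_shifts=shifts,
        planted_rois=rois,
        neuropil_level=5.0,
    )
    movie = syn.generate_movie(truth, layout, trials)
    planted_roiset = RoiSet(
        rois=[r.copy() for r in rois],
        neuropil=_neuropil_annuli(rois, (96, 96), 2, 4),
        shape=(96, 96),
    )
    return dict(
        layout=layout,
        truth=truth,
        trials=trials,
        movie=movie,
        planted_roiset=planted_roiset,
        template_frames=64,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_tensor(rng, R=3, S=8, N=6, nonneg=True):
    vals = rng.standard_normal((R, S, N))
    if nonneg:
        vals = np.abs(vals)
    return ResponseTensor(values=vals)
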