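import numpy as np
import pytest

from v1sparse import preprocess as pp
from v1sparse.core import MovieStack
from v1sparse.synthetic import _translate
from oracles import gaussian_blur_oracle, iou, register_shift_oracle


def _movie(frames, rate=8.0):
    return MovieStack(frames=np.asarray(frames, dtype=float), frame_rate=rate)


class TestTemplate:
    def test_constant_movie(self):
        m = _movie(np.full((5, 8, 8), 3.0))
        assert (pp.build_template(m, 3) == 3.0).all()

    def test_mean_arithmetic(self):
        m = _movie(np.stack([np.zeros((4, 4)), np.full((4, 4), 2.0)]))
        assert (pp.build_template(m, 2) == 1.0).all()

    def test_matches_naive_pixel_mean(self, rng):
        frames = rng.random((10, 6, 7))
        m = _movie(frames)
        naive = np.zeros((6, 7))
        for i in range(6):
            for j in range(7):
                naive[i, j] = sum(frames[t, i, j] for t in range(10)) / 10
        assert pp.build_template(m, 10) == pytest.approx(naive)

    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError):
            pp.build_template(_movie(np.zeros((2, 4, 4))), 0)


class TestRegistration:
    @staticmethod
    def _scene(rng, h=64, w=64):
        # smooth random scene with structure at the 3-px scale
        from scipy.ndimage import gaussian_filter

        return gaussian_filter(rng.random((h, w)), 3) * 100

    def test_identity_frame(self, rng):
        scene = self._scene(rng)
        movie = _movie(scene[None])
        _, shifts = pp.register_frames(movie, scene, max_shift=5)
        assert shifts == [(0, 0)]

    def test_planted_shift_recovered_exactly(self, rng):
        scene = self._scene(rng)
        frame = _translate(scene, 3, -2, fill=float(scene.mean()))
        _, shifts = pp.register_frames(_movie(frame[None]), scene, max_shift=5)
        assert shifts == [(3, -2)]

    def test_noisy_shift_within_one_pixel_of_oracle(self, rng):
        scene = self._scene(rng)
        for planted in [(2, 4), (-3, 1), (0, -4)]:
            frame = _translate(scene, *planted, fill=float(scene.mean()))
            frame = frame + rng.standard_normal(frame.shape) * 1.0
            _, shifts = pp.register_frames(_movie(frame[None]), scene, max_shift=5)
            oracle = register_shift_oracle(frame, scene, 5)
            assert abs(shifts[0][0] - planted[0]) <= 1
            assert abs(shifts[0][1] - planted[1]) <= 1
            assert abs(shifts[0][0] - oracle[0]) <= 1
            assert abs(shifts[0][1] - oracle[1]) <= 1

    def test_registration_idempotent(self, rng):
        scene = self._scene(rng)
        frames = np.stack(
            [_translate(scene, dy, dx, fill=float(scene.mean())) for dy, dx in [(2, 1), (-1, 3), (0, 0)]]
        )
        registered, _ = pp.register_frames(_movie(frames), scene, max_shift=5)
        _, again = pp.register_frames(registered, scene, max_shift=5)
        assert again == [(0, 0)] * 3

    def test_constant_frame_warns_zero_shift(self):
        scene = np.zeros((16, 16))
        with pytest.warns(UserWarning, match="zero variance"):
            _, shifts = pp.register_frames(_movie(scene[None]), scene + 1, max_shift=3)
        assert shifts == [(0, 0)]


class TestDifferentialImage:
    def test_self_subtraction_is_zero(self, small_movie_bundle):
        b = small_movie_bundle
        frames = np.tile(b["movie"].frames[:1], (b["trials"].n_frames_required, 1, 1))
        d = pp.differential_image(_movie(frames), b["trials"], 0)
        assert np.abs(d).max() == 0.0

    def test_planted_amplitude(self, small_movie_bundle):
        # noiseless movie without shifts: diff equals f0*dff on ROI pixels
        from v1sparse import synthetic as syn

        b = small_movie_bundle
        truth = b["truth"]
        no_shift = syn.GroundTruth(
            tuning=truth.tuning, noise_sd=0.0, seed=truth.seed,
            planted_rois=truth.planted_rois, neuropil_level=0.0,
        )
        movie = syn.generate_movie(no_shift, b["layout"], b["trials"])
        s = int(b["trials"].stimuli[0])
        d = pp.differential_image(movie, b["trials"], s)
        roi = truth.planted_rois[0]
        expected = b["layout"].f0 * truth.tuning.values[s, 0]
        assert d[roi[:, 0], roi[:, 1]] == pytest.approx(expected, abs=1e-9)

    def test_two_trial_mean(self):
        # amplitudes A and 3A across two trials average to 2A
        frames = np.zeros((8, 4, 4))
        frames[2:4] = 1.0  # trial 0 ON: A = 1
        frames[6:8] = 3.0  # trial 1 ON: 3A
        import pandas as pd

        from v1sparse.core import TrialTable

        tt = TrialTable(pd.DataFrame(
            dict(trial=[0, 1], stimulus=[7, 7],
                 off_start=[0, 4], off_end=[2, 6], on_start=[2, 6], on_end=[4, 8])
        ))
        d = pp.differential_image(_movie(frames), tt, 7)
        assert d == pytest.approx(np.full((4, 4), 2.0))

    def test_unknown_stimulus(self, small_movie_bundle):
        b = small_movie_bundle
        with pytest.raises(KeyError):
            pp.differential_image(b["movie"], b["trials"], 999)


class TestBandpass:
    def test_constant_maps_to_zero(self):
        out = pp.bandpass_filter(np.full((32, 32), 7.0), 2, 8)
        assert np.abs(out).max() < 1e-12

    def test_impulse_sums_to_zero(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        out = pp.bandpass_filter(img, 2, 8)
        assert abs(out.sum()) < 1e-9

    def test_matches_direct_convolution(self, rng):
        img = rng.random((16, 16))
        out = pp.bandpass_filter(img, 1.5, 3.0)
        expected = gaussian_blur_oracle(img, 1.5) - gaussian_blur_oracle(img, 3.0)
        assert out == pytest.approx(expected, abs=1e-10)

    def test_bad_sizes_rejected(self):
        img = np.zeros((8, 8))
        with pytest.raises(ValueError):
            pp.bandpass_filter(img, 0, 5)
        with pytest.raises(ValueError):
            pp.bandpass_filter(img, 5, 5)


def _blob_image(rng, shape=(96, 96), center=(48, 48), radius=3.5, amp=30.0, noise=1.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    img = rng.standard_normal(shape) * noise
    img[mask] += amp
    return img, np.argwhere(mask)


class TestDetectRois:
    # desk-scale filter sizes: the synthetic cells span ~37 px (r = 3.5), an
    # order of magnitude smaller than real somata at recording resolution,
    # so the band-pass scales shrink accordingly
    LOW, HIGH = 1.0, 20.0

    def test_pure_noise_yields_no_rois(self, rng):
        # false-positive rate of >25-px components above mean + 3 std is
        # essentially zero on white-noise differential images
        images = [rng.standard_normal((96, 96)) for _ in range(10)]
        rs = pp.detect_rois(images, low_size=self.LOW, high_size=self.HIGH)
        assert len(rs) == 0

    def test_planted_blob_recovered(self, rng):
        img, mask = _blob_image(rng)
        rs = pp.detect_rois([img], low_size=self.LOW, high_size=self.HIGH)
        assert len(rs) == 1
        assert iou(rs.rois[0], mask) > 0.5

    def test_small_blob_rejected(self, rng):
        # a 10-pixel blob is below the >25-pixel size rule however bright
        img, mask = _blob_image(rng, radius=1.7, amp=50.0)
        assert len(mask) < 25
        rs = pp.detect_rois([img], low_size=self.LOW, high_size=self.HIGH)
        assert len(rs) == 0

    def test_offset_invariance(self, rng):
        img, _ = _blob_image(rng)
        a = pp.detect_rois([img], low_size=self.LOW, high_size=self.HIGH)
        b = pp.detect_rois([img + 1000.0], low_size=self.LOW, high_size=self.HIGH)
        assert len(a) == len(b) == 1
        assert (a.rois[0] == b.rois[0]).all()

    def test_merged_across_images_and_disjoint(self, rng):
        img1, mask = _blob_image(rng)
        img2, _ = _blob_image(rng)  # same cell, second differential image
        img3, mask3 = _blob_image(rng, center=(20, 70))
        rs = pp.detect_rois([img1, img2, img3], low_size=self.LOW, high_size=self.HIGH)
        assert len(rs) == 2
        # pairwise disjoint pixels and annuli excluding ROI pixels
        all_px = [set(map(tuple, r.tolist())) for r in rs.rois]
        assert not (all_px[0] & all_px[1])
        roi_union = all_px[0] | all_px[1]
        for ann in rs.neuropil:
            assert not (set(map(tuple, ann.tolist())) & roi_union)

    def test_empty_image_list_rejected(self):
        with pytest.raises(ValueError):
            pp.detect_rois([])

    def test_full_movie_recovery(self, small_movie_bundle):
        # noiseless synthetic movie: every planted ROI recovered (IoU > 0.5),
        # no false positives, all sets above the size floor
        b = small_movie_bundle
        template = pp.build_template(b["movie"], b["template_frames"])
        registered, shifts = pp.register_frames(b["movie"], template, max_shift=4)
        assert shifts == b["truth"].planted_shifts[: b["movie"].n_frames]
        diffs = [pp.differential_image(registered, b["trials"], s) for s in b["trials"].stimuli]
        rs = pp.detect_rois(diffs, low_size=self.LOW, high_size=self.HIGH)
        assert len(rs) == len(b["truth"].planted_rois)
        for planted in b["truth"].planted_rois:
            assert max(iou(planted, r) for r in rs.rois) > 0.5
        assert all(len(r) > 25 for r in rs.rois)
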