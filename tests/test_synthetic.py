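"""Stimulus generators, encoding model and run-level simulator."""

import numpy as np
import pytest
from scipy import stats

from fmri2img.preprocess import PreprocParams, average_blocks
from fmri2img.synthetic import (BlockDesign, EncodingModel, DEFAULT_COLORS,
                                generate_natural_like,
                                render_artificial_shapes, render_letters,
                                simulate_responses, simulate_run_timeseries)


@pytest.mark.parametrize("n_colors,n_shapes", [(8, 5), (1, 1), (3, 2)])
def test_shape_set_is_full_factorial_and_distinct(n_colors, n_shapes):
    colors = dict(list(DEFAULT_COLORS.items())[:n_colors])
    shapes = ("square", "circle", "triangle", "cross", "diamond")[:n_shapes]
    imgs, attrs = render_artificial_shapes(colors, shapes, canvas_size=16)
    assert len(imgs) == n_colors * n_shapes
    assert len(attrs) == len(imgs)
    # brute-force pairwise pixel comparison: all images distinct
    for i in range(len(imgs)):
        for j in range(i + 1, len(imgs)):
            assert not np.array_equal(imgs[i], imgs[j])
    # determinism
    imgs2, _ = render_artificial_shapes(colors, shapes, canvas_size=16)
    for a, b in zip(imgs, imgs2):
        np.testing.assert_array_equal(a, b)


def test_shape_rendering_rejects_bad_config():
    with pytest.raises(ValueError):
        render_artificial_shapes({}, ("square",))
    with pytest.raises(ValueError):
        render_artificial_shapes(DEFAULT_COLORS, ())
    with pytest.raises(ValueError):
        render_artificial_shapes(canvas_size=8)


def test_letter_rendering():
    imgs = render_letters(canvas_size=32)
    assert len(imgs) == 10
    a1, a2 = render_letters(["A", "A"], 32)
    np.testing.assert_array_equal(a1, a2)
    assert render_letters([], 32) == []
    with pytest.raises(ValueError):
        render_letters(["4"])
    # black glyph on white ground
    a = render_letters(["T"], 32)[0]
    assert a.max() == 1.0 and a.min() == 0.0


def test_natural_like_seeding_and_variability():
    a = generate_natural_like(5, 32, seed=1)
    b = generate_natural_like(5, 32, seed=1)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    assert generate_natural_like(0, 32, seed=1) == []
    c = generate_natural_like(2, 32, seed=2)
    # different seeds: images differ in at least 1% of pixels
    frac = np.mean(np.abs(a[0] - c[0]) > 1e-6)
    assert frac > 0.01


def test_trial_responses_statistics():
    model = EncodingModel(32, 16, feature_size=8, noise_sd=0.5, seed=3)
    img = generate_natural_like(1, 16, seed=4)[0]
    clean = model.respond(img)

    same = simulate_responses(
        EncodingModel(32, 16, feature_size=8, noise_sd=0.0, seed=3), img, 5)
    assert np.ptp(same, axis=0).max() == 0.0  # noiseless -> identical trials

    trials = simulate_responses(model, img, 10_000, seed=9)
    se = 0.5 / np.sqrt(10_000)
    assert np.all(np.abs(trials.mean(axis=0) - clean) < 4 * se)

    # variance of the n-trial average scales ~ 1/n (law of iid averaging)
    reps = np.stack([simulate_responses(model, img, 16, seed=100 + r)
                     for r in range(400)])
    v1 = reps[:, 0, :].var(axis=0).mean()
    v4 = reps[:, :4, :].mean(axis=1).var(axis=0).mean()
    v16 = reps.mean(axis=1).var(axis=0).mean()
    assert v1 / v4 == pytest.approx(4.0, rel=0.25)
    assert v1 / v16 == pytest.approx(16.0, rel=0.25)


def test_random_conv_feature_map():
    model = EncodingModel(16, 16, feature_map="random_conv", seed=0)
    img = generate_natural_like(1, 16, seed=0)[0]
    r1, r2 = model.respond(img), model.respond(img)
    np.testing.assert_array_equal(r1, r2)
    with pytest.raises(ValueError):
        model.respond(np.zeros((8, 8, 3)))


class TestRunSimulator:
    def _model(self, noise=0.0):
        return EncodingModel(24, 16, feature_size=8, noise_sd=noise, seed=5)

    def _stimuli(self, n=6):
        imgs = generate_natural_like(n, 16, seed=6)
        return imgs, [f"s{i}" for i in range(n)]

    def test_clean_blocks_equal_noiseless_responses(self):
        model = self._model()
        imgs, ids = self._stimuli()
        run = simulate_run_timeseries(model, imgs, ids, drift_slope=0.0,
                                      motion_amp=0.0, spike_rate=0.0,
                                      noise_sd=0.0, baseline=0.0)
        params = PreprocParams(block_seconds=8.0, shift_seconds=4.0)
        got = dict(average_blocks(run, params))
        for sid, resp in zip(ids, run.extras["responses"]):
            np.testing.assert_allclose(got[sid], resp, atol=1e-12)

    def test_injected_drift_recovered_by_ols(self):
        model = self._model()
        imgs, ids = self._stimuli(3)
        run = simulate_run_timeseries(model, imgs, ids, drift_slope=0.05,
                                      motion_amp=0.0, spike_rate=0.0,
                                      noise_sd=0.0)
        t = np.arange(run.data.shape[0])
        x = np.column_stack([np.ones_like(t), t])
        slopes = np.linalg.lstsq(x, run.data, rcond=None)[0][1]
        # stimulus blocks perturb the fit slightly; drift dominates
        assert np.median(slopes) == pytest.approx(0.05, abs=0.01)

    def test_spike_count_in_binomial_99_interval(self):
        model = self._model()
        imgs, ids = self._stimuli(40)  # long run
        run = simulate_run_timeseries(model, imgs, ids, spike_rate=0.01,
                                      noise_sd=0.0, seed=12)
        n = run.data.size
        k = int(run.extras["spike_mask"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.01)
        assert lo <= k <= hi

    def test_overlapping_blocks_rejected(self):
        from fmri2img.preprocess import RunTimeSeries
        with pytest.raises(ValueError, match="overlap"):
            RunTimeSeries(np.zeros((50, 4)), (0, 5),
                          [(10, 6, "a"), (12, 4, "b")], np.zeros((50, 6)))

    def test_seeded_determinism(self):
        model = self._model(noise=0.3)
        imgs, ids = self._stimuli()
        r1 = simulate_run_timeseries(model, imgs, ids, spike_rate=0.01, seed=7)
        r2 = simulate_run_timeseries(model, imgs, ids, spike_rate=0.01, seed=7)
        np.testing.assert_array_equal(r1.data, r2.data)
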