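"""Sample-preparation chain: each stage against an independent oracle."""

import numpy as np
import pytest

from fmri2img.preprocess import (PreprocParams, RunTimeSeries, apply_zscore,
                                 average_blocks, average_trials_and_rescale,
                                 despike, fit_voxel_stats, load_run_h5,
                                 normalize_to_rest, preprocess_run,
                                 regress_nuisance, save_run_h5)


def _run(data, motion=None, rest=(0, 8), blocks=(), tr=2.0):
    t = data.shape[0]
    if motion is None:
        motion = np.zeros((t, 6))
    return RunTimeSeries(data, rest, list(blocks), motion, tr)


class TestNuisanceRegression:
    def test_pure_ramp_reduces_to_baseline(self):
        # linear trend removed; the voxel baseline (run mean) is retained
        t = 60
        ramp = 5.0 + 0.3 * np.arange(t)
        run = _run(np.tile(ramp[:, None], (1, 3)))
        out = regress_nuisance(run).data
        np.testing.assert_allclose(out, ramp.mean(), atol=1e-8)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        t, d = 80, 5
        motion = rng.normal(size=(t, 6))
        motion -= motion.mean(axis=0)
        data = 100 + rng.normal(size=(t, d)) \
            + np.arange(t)[:, None] * rng.normal(size=d) \
            + motion @ rng.normal(size=(6, d))
        run = _run(data, motion)
        out = regress_nuisance(run).data
        design = np.column_stack([np.ones(t), np.linspace(-1, 1, t), motion])
        beta = np.linalg.lstsq(design, data, rcond=None)[0]
        expected = data - design[:, 1:] @ beta[1:]
        np.testing.assert_allclose(out, expected, atol=1e-8)
        # demeaned residuals orthogonal to every design column
        centered = out - out.mean(axis=0)
        assert np.abs(design.T @ centered).max() < 1e-6

    def test_rank_deficient_design_raises(self):
        t = 40
        motion = np.zeros((t, 6))
        motion[:, 0] = np.linspace(-1, 1, t)  # duplicates the trend column
        with pytest.raises(np.linalg.LinAlgError):
            regress_nuisance(_run(np.random.default_rng(1).normal(size=(t, 2)),
                                  motion))


class TestRestNormalization:
    def test_stated_convention(self):
        data = np.full((20, 2), 100.0)
        data[10:, 0] = 110.0  # +10 percent
        out = normalize_to_rest(_run(data, rest=(0, 10))).data
        assert out[0, 0] == 0.0
        assert out[15, 0] == pytest.approx(10.0)

    def test_matches_per_voxel_loop(self):
        rng = np.random.default_rng(2)
        data = 50 + rng.random((30, 7))
        run = _run(data, rest=(0, 6))
        out = normalize_to_rest(run).data
        for v in range(7):
            m = data[:6, v].mean()
            np.testing.assert_allclose(out[:, v], 100 * (data[:, v] / m - 1))

    def test_zero_rest_mean_flags_voxel(self):
        data = np.ones((20, 3))
        data[:, 1] = 0.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            normalize_to_rest(_run(data, rest=(0, 5)))


class TestDespike:
    def test_clips_only_extremes(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(200, 4))
        spiked = data.copy()
        mu, sd = data[:, 0].mean(), data[:, 0].std()
        run_clean = despike(_run(data), k=3.0)
        # series already within bounds -> unchanged where no extremes
        inside = np.abs(data - data.mean(0)) <= 3 * data.std(0)
        np.testing.assert_array_equal(run_clean.data[inside], data[inside])

        spiked[50, 0] = mu + 10 * sd
        out = despike(_run(spiked), k=3.0).data
        mu2, sd2 = spiked[:, 0].mean(), spiked[:, 0].std()
        assert out[50, 0] == pytest.approx(mu2 + 3 * sd2)

    def test_idempotent_with_fixed_bounds(self):
        rng = np.random.default_rng(4)
        data = rng.standard_t(df=3, size=(300, 5))
        mu, sd = data.mean(axis=0), data.std(axis=0)
        once = despike(_run(data), k=3.0).data
        again = np.clip(once, mu - 3 * sd, mu + 3 * sd)
        np.testing.assert_array_equal(once, again)

    def test_positive_k_required(self):
        with pytest.raises(ValueError):
            despike(_run(np.ones((20, 2))), k=0.0)


class TestBlockAveraging:
    def test_window_arithmetic(self):
        # tr=2 s, 8 s block, 4 s shift -> 4 volumes starting 2 after onset
        t, d = 40, 3
        data = np.arange(t, dtype=float)[:, None] * np.ones((1, d))
        run = _run(data, blocks=[(10, 4, "a")], tr=2.0)
        out = average_blocks(run, PreprocParams(block_seconds=8, shift_seconds=4))
        (sid, vec), = out
        assert sid == "a"
        np.testing.assert_allclose(vec, np.mean([12, 13, 14, 15]))

    def test_constant_series(self):
        run = _run(np.full((30, 2), 7.0), blocks=[(5, 4, "a"), (15, 4, "b")])
        for _sid, vec in average_blocks(run, PreprocParams()):
            np.testing.assert_allclose(vec, 7.0)

    def test_window_beyond_run_raises(self):
        run = _run(np.zeros((12, 2)), blocks=[(8, 4, "late")])
        with pytest.raises(ValueError, match="late"):
            average_blocks(run, PreprocParams())


class TestZScoring:
    def test_train_stats_definition(self):
        x = np.array([[0.0, 4.0], [2.0, 8.0]])
        stats = fit_voxel_stats(x)
        np.testing.assert_allclose(stats.mean, [1.0, 6.0])
        z = apply_zscore(x, stats)
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.abs(z.std(axis=0) - 1).max() < 1e-10

    def test_affine_inverse_recovers_input(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2.0, 3.0, size=(50, 6))
        stats = fit_voxel_stats(x)
        z = apply_zscore(x, stats)
        np.testing.assert_allclose(z * stats.sd + stats.mean, x, atol=1e-12)
        np.testing.assert_allclose(apply_zscore(stats.mean[None], stats), 0.0)
        np.testing.assert_allclose(
            apply_zscore((stats.mean + stats.sd)[None], stats), 1.0)

    def test_heldout_offset_survives(self):
        rng = np.random.default_rng(6)
        train = rng.normal(size=(100, 4))
        stats = fit_voxel_stats(train)
        test = rng.normal(size=(100, 4)) + 2.0  # shifted held-out set
        z = apply_zscore(test, stats)
        assert z.mean() > 1.0  # train stats do not recenter the test set

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_voxel_stats(np.ones((5, 3)))  # zero variance
        stats = fit_voxel_stats(np.random.default_rng(7).normal(size=(10, 4)))
        with pytest.raises(ValueError):
            apply_zscore(np.zeros((2, 5)), stats)


class TestTrialAveraging:
    def test_modes(self):
        v = np.ones((4, 3)) * 2.0
        np.testing.assert_allclose(average_trials_and_rescale(v, "sqrt_n"), 4.0)
        np.testing.assert_allclose(average_trials_and_rescale(v, "n"), 8.0)
        one = np.array([[1.0, 2.0]])
        np.testing.assert_allclose(average_trials_and_rescale(one, "sqrt_n"),
                                   one[0])
        np.testing.assert_allclose(average_trials_and_rescale(one, "n"), one[0])
        with pytest.raises(ValueError):
            average_trials_and_rescale(np.empty((0, 3)))

    def test_sqrt_n_preserves_noise_scale(self):
        # Monte Carlo: variance of the rescaled average ~ single-trial variance
        rng = np.random.default_rng(8)
        out = np.array([average_trials_and_rescale(
            rng.normal(size=(4, 1)), "sqrt_n")[0] for _ in range(10_000)])
        assert out.var() == pytest.approx(1.0, rel=0.1)


def test_run_container_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    run = _run(rng.normal(size=(30, 5)), motion=rng.normal(size=(30, 6)),
               blocks=[(10, 4, "a"), (20, 4, "b")])
    p = str(tmp_path / "run.h5")
    save_run_h5(run, p)
    back = load_run_h5(p)
    np.testing.assert_array_equal(back.data, run.data)
    np.testing.assert_array_equal(back.motion, run.motion)
    assert back.blocks == run.blocks
    assert back.rest_window == run.rest_window
    with pytest.raises(ValueError, match="data"):
        import h5py
        q = str(tmp_path / "bad.h5")
        with h5py.File(q, "w") as f:
            f.create_dataset("blocks", data=np.zeros(1))
        load_run_h5(q)
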