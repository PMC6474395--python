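"""Similarity metrics, identification protocol, RV coefficient, ablations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmri2img.evaluation import (ablation_winning_percentages,
                                 enumerate_trials, flatten_pearson,
                                 modified_rv, reconstruct,
                                 rv_permutation_test, score_trials, ssim_rgb,
                                 subsample_trials, winning_percentage)
from fmri2img.synthetic import render_artificial_shapes


def _loop_pearson(a, b):
    x = a.ravel()
    y = b.ravel()
    mx, my = x.mean(), y.mean()
    num = sxx = syy = 0.0
    for i in range(x.size):
        num += (x[i] - mx) * (y[i] - my)
        sxx += (x[i] - mx) ** 2
        syy += (y[i] - my) ** 2
    return num / np.sqrt(sxx * syy)


class TestPearson:
    def test_extremes(self):
        a = np.random.default_rng(0).random((8, 8, 3))
        assert flatten_pearson(a, a) == pytest.approx(1.0)
        neg = -(a - a.mean())
        assert flatten_pearson(a, neg + 0.5) == pytest.approx(-1.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.random((6, 6, 3)), rng.random((6, 6, 3))
            assert flatten_pearson(a, b) == pytest.approx(
                _loop_pearson(a, b), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            flatten_pearson(np.full((8, 8, 3), 0.3),
                            np.random.default_rng(2).random((8, 8, 3)))


class TestSSIM:
    def test_identical_is_one(self):
        a = np.random.default_rng(3).random((16, 16, 3))
        assert ssim_rgb(a, a) == pytest.approx(1.0)

    def test_luminance_offset_penalized(self):
        a = np.full((16, 16, 3), 0.2)
        b = np.full((16, 16, 3), 0.8)
        assert ssim_rgb(a, b) < 0.5

    def test_matches_reference_implementation(self):
        from skimage.metrics import structural_similarity as sk_ssim
        rng = np.random.default_rng(4)
        a, b = rng.random((16, 16, 3)), rng.random((16, 16, 3))
        ref = np.mean([sk_ssim(a[..., c], b[..., c], gaussian_weights=True,
                               sigma=1.5, use_sample_covariance=False,
                               data_range=1.0) for c in range(3)])
        assert ssim_rgb(a, b) == pytest.approx(ref, abs=1e-6)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ssim_rgb(np.zeros((8, 8, 3)), np.zeros((8, 8, 3)))


class TestTrialEnumeration:
    def _images(self, n, seed=5):
        rng = np.random.default_rng(seed)
        return {f"s{i}": rng.random((12, 12, 3)) for i in range(n)}

    def test_all_lures_per_reconstruction(self):
        imgs = self._images(50)
        trials = enumerate_trials(imgs, imgs)
        assert len(trials) == 50 * 49
        by_recon = {}
        for t in trials:
            by_recon.setdefault(t.recon_id, set()).add(t.lure_id)
        assert all(len(v) == 49 for v in by_recon.values())

    def test_two_images_one_trial_each(self):
        imgs = self._images(2)
        assert len(enumerate_trials(imgs, imgs)) == 2

    def test_shape_and_color_restrictions(self):
        imgs, attrs = render_artificial_shapes(canvas_size=16)
        ids = [f"sh{i}" for i in range(len(imgs))]
        m = dict(zip(ids, imgs))
        a = dict(zip(ids, attrs))
        shape_trials = enumerate_trials(m, m, a, restrict="shape")
        color_trials = enumerate_trials(m, m, a, restrict="color")
        assert len(shape_trials) == 40 * 4   # same color, other 4 shapes
        assert len(color_trials) == 40 * 7   # same shape, other 7 colors
        for t in shape_trials:
            assert a[t.true_id]["color_id"] == a[t.lure_id]["color_id"]
            assert a[t.true_id]["shape_id"] != a[t.lure_id]["shape_id"]

    def test_subsampling_fixed_across_calls(self):
        imgs = self._images(50)
        trials = enumerate_trials(imgs, imgs)
        s1 = subsample_trials(trials, 10, seed=9)
        s2 = subsample_trials(trials, 10, seed=9)
        assert len(s1) == 500
        assert [(t.recon_id, t.lure_id) for t in s1] == \
               [(t.recon_id, t.lure_id) for t in s2]
        all_of_them = subsample_trials(trials, 49, seed=1)
        assert len(all_of_them) == len(trials)
        with pytest.raises(ValueError):
            subsample_trials(trials, 50, seed=0)


class TestScoring:
    def test_perfect_reconstructions_score_100(self):
        rng = np.random.default_rng(6)
        imgs = {f"s{i}": rng.random((12, 12, 3)) for i in range(10)}
        trials = enumerate_trials(imgs, imgs)
        rep = score_trials(trials, imgs, imgs, "pearson")
        assert rep.mean == 100.0
        assert all(v == 100.0 for v in rep.per_recon.values())

    def test_hand_built_ordering(self):
        base = np.zeros((12, 12, 3))
        base[2:6, 2:6] = 1.0
        other = np.zeros((12, 12, 3))
        other[6:10, 6:10] = 1.0
        trues = {"a": base, "b": other}
        recons = {"a": base * 0.9 + 0.05, "b": base.copy()}  # b's recon wrong
        rep = score_trials(enumerate_trials(recons, trues), recons, trues,
                           "pearson")
        assert rep.per_recon["a"] == 100.0
        assert rep.per_recon["b"] == 0.0
        assert rep.mean == 50.0


class TestModifiedRV:
    def _loop_rv(self, x, y):
        x = x - x.mean(axis=0)
        y = y - y.mean(axis=0)
        sx = x @ x.T
        sy = y @ y.T
        num = aa = bb = 0.0
        n = x.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                num += sx[i, j] * sy[i, j]
                aa += sx[i, j] ** 2
                bb += sy[i, j] ** 2
        return num / np.sqrt(aa * bb)

    def test_identity_and_loop_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(6, 10))
        assert modified_rv(x, x) == pytest.approx(1.0)
        for _ in range(10):
            a, b = rng.normal(size=(5, 7)), rng.normal(size=(5, 7))
            assert modified_rv(a, b) == pytest.approx(
                self._loop_rv(a, b), abs=1e-12)

    def test_two_samples_give_sign(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            a, b = rng.normal(size=(2, 9)), rng.normal(size=(2, 9))
            assert abs(modified_rv(a, b)) == pytest.approx(1.0)

    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 50.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
        assert modified_rv(a, b) == pytest.approx(modified_rv(b, a), abs=1e-12)
        assert modified_rv(scale * a, b) == pytest.approx(
            modified_rv(a, b), abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            modified_rv(np.zeros((4, 5)), np.ones((4, 5)))


class TestPermutationTest:
    def test_strong_signal_small_p(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(20, 15))
        res = rv_permutation_test(x, x, n_perm=999, seed=0)
        assert res.p_value <= 0.01
        assert res.rv == pytest.approx(1.0)

    def test_single_permutation_p_values(self):
        rng = np.random.default_rng(10)
        ps = set()
        for s in range(20):
            x = rng.normal(size=(5, 6))
            y = rng.normal(size=(5, 6))
            ps.add(rv_permutation_test(x, y, n_perm=1, seed=s).p_value)
        assert ps <= {0.5, 1.0}

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = [rv_permutation_test(rng.normal(size=(8, 6)),
                                  rng.normal(size=(8, 6)),
                                  n_perm=39, seed=s).p_value
              for s in range(60)]
        assert 0.2 < np.mean(ps) < 0.8  # crude uniformity check under the null


class TestWinningPercentage:
    def test_degenerate_and_tie_policies(self):
        assert winning_percentage([1.0] * 10) == (100.0, 0.0)
        assert winning_percentage([0.5] * 10) == (50.0, 50.0)
        pa, pb = winning_percentage([1.0, 0.0, 0.5, 1.0])
        assert pa + pb == pytest.approx(100.0)

    def test_six_pairs_for_four_conditions(self):
        rng = np.random.default_rng(12)
        trues = {f"s{i}": rng.random((12, 12, 3)) for i in range(5)}
        conds = {name: {k: rng.random((12, 12, 3)) for k in trues}
                 for name in ("full", "-L_img", "-L_feat", "-L_adv")}
        wp = ablation_winning_percentages(conds, trues)
        assert len(wp) == 6
        for pa, pb in wp.values():
            assert pa + pb == pytest.approx(100.0)

    def test_identical_reconstructions_split_even(self):
        rng = np.random.default_rng(13)
        trues = {f"s{i}": rng.random((12, 12, 3)) for i in range(4)}
        same = {k: rng.random((12, 12, 3)) for k in trues}
        wp = ablation_winning_percentages({"a": same, "b": dict(same)}, trues)
        assert wp[("a", "b")] == (50.0, 50.0)


def test_reconstruct_composes_average_and_generator():
    """With identical trials, the sqrt_n-rescaled input is sqrt(n) * v, so
    the output equals a direct generator call on that scaled vector."""
    from conftest import tiny_gen_spec
    from fmri2img.models import build_generator

    gen = build_generator(tiny_gen_spec(64, np.float64),
                          np.random.default_rng(3))
    v = np.random.default_rng(4).normal(size=64)
    trials = np.tile(v, (4, 1))
    out = reconstruct(gen, trials, mode="sqrt_n")
    direct = gen.forward((2.0 * v)[None])[0].transpose(1, 2, 0)
    np.testing.assert_allclose(out, np.clip(direct, 0, 1), atol=1e-12)
    single = reconstruct(gen, v[None], mode="n")
    np.testing.assert_allclose(
        single, np.clip(gen.forward(v[None])[0].transpose(1, 2, 0), 0, 1))
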