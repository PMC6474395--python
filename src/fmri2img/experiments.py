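"""Study assembly and desk-scale experiment drivers.

``build_study`` wires the synthetic stimulus generators and the
encoding model into z-scored train/test :class:`PairedDataset` splits
with the emulated study's trial structure.  The ``run_toy_*`` drivers
are the scaled-down analogs of the headline experiments — end-to-end
reconstruction, the dataset-size sweep and the loss ablation — sized to
run on one CPU in minutes; docs/methods.md records the problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import PairedDataset, StimulusRecord, make_training_pairs
from .evaluation import (enumerate_trials, modified_rv, reconstruct,
                         rv_permutation_test, score_trials, subsample_trials)
from .models import (LossWeights, toy_comparator_spec, toy_discriminator_spec,
                     toy_generator_spec)
from .preprocess import apply_zscore, fit_voxel_stats
from .synthetic import (DEFAULT_LETTERS, EncodingModel, generate_natural_like,
                        render_artificial_shapes, render_letters,
                        simulate_responses, simulate_run_timeseries)
from .training import TrainConfig, run_ablation, run_size_sweep, train

__all__ = [
    "StudyConfig", "Study", "build_study",
    "toy_study_config", "toy_train_config",
    "run_preprocessing_recovery",
    "run_toy_recovery", "run_toy_size_sweep", "run_toy_ablation",
]


@dataclass
class StudyConfig:
    """Geometry of the simulated study.

    The defaults reproduce the emulated experiment's structure: 1,200
    training images x 5 presentations, 50 natural test images x 24
    trials, 8 x 5 artificial shapes x 20 trials, 10 letters x 12 trials.
    """
    n_train_images: int = 1200
    n_train_trials: int = 5
    n_test_natural: int = 50
    n_test_trials: int = 24
    shape_trials: int = 20
    letter_trials: int = 12
    include_shapes: bool = True
    include_letters: bool = True
    canvas_size: int = 32
    n_voxels: int = 256
    feature_map: str = "downsample_gray"
    feature_size: int = 16
    noise_sd: float = 0.6
    seed: int = 0


@dataclass
class Study:
    train: PairedDataset
    test_sets: dict                       # stimulus_type -> PairedDataset
    encoding: EncodingModel
    stats: object                         # training VoxelStats
    config: StudyConfig


def _dataset(records, model, n_trials, rng, split, stimulus_type):
    trials = {
        rec.stimulus_id: simulate_responses(
            model, rec.image, n_trials, seed=int(rng.integers(2 ** 31)))
        for rec in records
    }
    return make_training_pairs(records, trials, split, stimulus_type)


def build_study(cfg: StudyConfig) -> Study:
    """Simulate the full study and z-score it from training statistics.

    Train and test stimuli (and their category labels) are disjoint by
    construction; all voxel vectors are normalized per voxel with the
    training mean/SD, test vectors reusing the training statistics.
    """
    rng = np.random.default_rng(cfg.seed)
    model = EncodingModel(cfg.n_voxels, cfg.canvas_size, cfg.feature_map,
                          cfg.feature_size, cfg.noise_sd,
                          seed=int(rng.integers(2 ** 31)))

    img_seed = int(rng.integers(2 ** 31))
    n_total = cfg.n_train_images + cfg.n_test_natural
    naturals = generate_natural_like(n_total, cfg.canvas_size, seed=img_seed)
    train_recs = [
        StimulusRecord(f"train{i:05d}", im, f"traincat{i:05d}")
        for i, im in enumerate(naturals[:cfg.n_train_images])]
    test_recs = [
        StimulusRecord(f"test{i:04d}", im, f"testcat{i:04d}")
        for i, im in enumerate(naturals[cfg.n_train_images:])]

    train = _dataset(train_recs, model, cfg.n_train_trials, rng,
                     "train", "natural")
    test_sets = {
        "natural": _dataset(test_recs, model, cfg.n_test_trials, rng,
                            "test", "natural")}

    if cfg.include_shapes:
        imgs, attrs = render_artificial_shapes(canvas_size=cfg.canvas_size)
        recs = [StimulusRecord(
            f"shape_{a['color_id']}_{a['shape_id']}", im,
            f"shapecat_{a['color_id']}_{a['shape_id']}", a)
            for im, a in zip(imgs, attrs)]
        test_sets["shapes"] = _dataset(recs, model, cfg.shape_trials, rng,
                                       "test", "shapes")
    if cfg.include_letters:
        recs = [StimulusRecord(f"letter_{l}", im, f"lettercat_{l}")
                for l, im in zip(DEFAULT_LETTERS,
                                 render_letters(canvas_size=cfg.canvas_size))]
        test_sets["letters"] = _dataset(recs, model, cfg.letter_trials, rng,
                                        "test", "letters")

    stats = fit_voxel_stats(train.voxels)
    train = replace_voxels(train, apply_zscore(train.voxels, stats))
    test_sets = {k: replace_voxels(ds, apply_zscore(ds.voxels, stats))
                 for k, ds in test_sets.items()}
    return Study(train, test_sets, model, stats, cfg)


def replace_voxels(ds: PairedDataset, voxels: np.ndarray) -> PairedDataset:
    return PairedDataset(voxels, ds.stimulus_ids, ds.trial_indices, ds.images,
                         ds.categories, ds.stim_attrs, ds.split,
                         ds.stimulus_type)


# ---------------------------------------------------------------------------
# toy presets

def toy_study_config(seed: int = 0, n_train_images: int = 64,
                     n_test: int = 20, noise_sd: float = 0.0) -> StudyConfig:
    """Desk-scale study: 64 training images x 5 trials at 32 x 32, D=256
    voxels, 20 held-out natural-like test images, noiseless encoding."""
    return StudyConfig(
        n_train_images=n_train_images, n_train_trials=5,
        n_test_natural=n_test, n_test_trials=1,
        include_shapes=False, include_letters=False,
        canvas_size=32, n_voxels=256, noise_sd=noise_sd, seed=seed)


def toy_train_config(seed: int = 0, iterations: int = 1200,
                     batch_size: int = 32,
                     weights: LossWeights | None = None) -> TrainConfig:
    """CPU-scale schedule: identity crop at 32 x 32, Adam lr 2e-3.

    The learning rate is 10x the study-scale default because the toy
    nets are orders of magnitude smaller and the budget is a few
    thousand iterations rather than 500,000.
    """
    return TrainConfig(
        batch_size=batch_size, max_iterations=iterations,
        learning_rate=2e-3, resize_to=32, crop_to=32,
        weights=weights or LossWeights(), seed=seed)


# ---------------------------------------------------------------------------
# drivers

def _evaluate_generator(gen, study: Study, which: str = "natural",
                        metric: str = "pearson", rescale_mode: str = "sqrt_n",
                        per_image: int | None = None, trial_seed: int = 0):
    test = study.test_sets[which]
    recons = {sid: reconstruct(gen, test.trials_for(sid), rescale_mode)
              for sid in test.unique_stimulus_ids()}
    trues = {sid: test.images[sid] for sid in recons}
    trials = enumerate_trials(recons, trues)
    if per_image is not None:
        trials = subsample_trials(trials, per_image, seed=trial_seed)
    report = score_trials(trials, recons, trues, metric)
    return report, recons, trues


def run_preprocessing_recovery(seed: int = 0, n_stimuli: int = 20,
                               n_repeats: int = 12, n_voxels: int = 64,
                               noise_sd: float = 0.1) -> dict:
    """Preparation-chain recovery on a simulated run with known components.

    One long run presents ``n_stimuli`` stimuli ``n_repeats`` times each
    (randomized order) with linear drift, motion-correlated components,
    sparse large spikes and thermal noise.  The full chain (nuisance
    regression -> rest normalization -> despiking -> shifted block
    averaging -> trial averaging) is then compared against the encoding
    model's noiseless responses after per-voxel z-scoring.
    """
    from .preprocess import (average_blocks, despike, normalize_to_rest,
                             PreprocParams, regress_nuisance)

    model = EncodingModel(n_voxels, 16, feature_size=8, noise_sd=noise_sd,
                          seed=seed)
    model.weight_matrix *= 10.0   # percent-signal-scale responses
    imgs = generate_natural_like(n_stimuli, 16, seed=seed + 1)
    ids = [f"s{i:02d}" for i in range(n_stimuli)]
    rng = np.random.default_rng(seed + 2)
    order = np.concatenate([rng.permutation(n_stimuli)
                            for _ in range(n_repeats)])
    run = simulate_run_timeseries(
        model, [imgs[i] for i in order], [ids[i] for i in order],
        drift_slope=0.03, motion_amp=0.5, spike_rate=0.003,
        spike_amplitude=20.0, seed=seed + 3)

    normalized = normalize_to_rest(regress_nuisance(run))
    clipped = despike(normalized, 3.0)
    by_stim = {}
    for sid, vec in average_blocks(clipped, PreprocParams()):
        by_stim.setdefault(sid, []).append(vec)
    got = np.stack([np.mean(by_stim[s], axis=0) for s in ids])
    true = np.stack([model.respond(im) for im in imgs])
    gz = apply_zscore(got, fit_voxel_stats(got))
    tz = apply_zscore(true, fit_voxel_stats(true))
    corr = float(np.corrcoef(gz.ravel(), tz.ravel())[0, 1])
    changed = np.abs(clipped.data - normalized.data) > 1e-9
    return {
        "pattern_correlation": corr,
        "n_entries": int(got.size),
        "spikes_injected": int(run.extras["spike_mask"].sum()),
        "spikes_clipped": bool(changed[run.extras["spike_mask"]].all()),
        "run": run,
    }


def run_toy_recovery(seed: int = 0, iterations: int = 1200,
                     batch_size: int = 32, n_perm: int = 199) -> dict:
    """End-to-end scaled-down reconstruction experiment.

    Builds the noiseless toy study, trains the toy model with the full
    three-term objective, reconstructs the 20 held-out test images and
    reports pairwise identification accuracy (Pearson and SSIM) plus
    the modified RV coefficient with its permutation p-value.
    """
    study = build_study(toy_study_config(seed))
    gen, state = train(study.train, toy_train_config(seed, iterations,
                                                     batch_size))
    rep_p, recons, trues = _evaluate_generator(gen, study, metric="pearson")
    rep_s, _, _ = _evaluate_generator(gen, study, metric="ssim")

    ids = sorted(recons)
    x = np.stack([recons[i].ravel() for i in ids])
    y = np.stack([trues[i].ravel() for i in ids])
    rv = rv_permutation_test(x, y, n_perm=n_perm, seed=seed)
    return {
        "pearson": rep_p, "ssim": rep_s,
        "rv": rv.rv, "rv_p": rv.p_value,
        "state": state, "generator": gen, "study": study,
        "recons": recons, "trues": trues,
    }


def run_toy_size_sweep(seed: int = 0, sizes_images=(20, 40, 80),
                       epochs: int = 60, batch_size: int = 32,
                       per_image: int = 10) -> dict:
    """Scaled-down dataset-size sweep over nested subsets.

    Trains one model per subset size (in images; x5 trials gives the
    sample counts) on a shared seed and scores each on the identical
    seeded subsample of pairwise trials (``per_image`` lures per test
    image, fixed across conditions).
    """
    study = build_study(toy_study_config(seed, n_train_images=max(sizes_images)))
    per = study.config.n_train_trials
    cfg = toy_train_config(seed)
    models = run_size_sweep(study.train, [m * per for m in sizes_images],
                            cfg, epochs=epochs, batch_size=batch_size)
    accs = {}
    for m_imgs in sizes_images:
        gen, _ = models[m_imgs * per]
        rep, _, _ = _evaluate_generator(
            gen, study, metric="pearson", per_image=per_image,
            trial_seed=seed)
        accs[m_imgs] = rep.mean
    return {"accuracy_by_size": accs, "study": study, "models": models}


def run_toy_ablation(seed: int = 0, iterations: int = 400,
                     batch_size: int = 32) -> dict:
    """Scaled-down loss ablation: full model and one term removed at a
    time, compared by objective winning percentages over all 6 pairs."""
    from .evaluation import ablation_winning_percentages

    study = build_study(toy_study_config(seed))
    cfg = toy_train_config(seed, iterations, batch_size)
    models = run_ablation(study.train, cfg)
    test = study.test_sets["natural"]
    trues = {sid: test.images[sid] for sid in test.unique_stimulus_ids()}
    recons = {name: {sid: reconstruct(gen, test.trials_for(sid))
                     for sid in trues}
              for name, (gen, _st) in models.items()}
    wp = ablation_winning_percentages(recons, trues, metric="pearson")
    return {"winning_percentages": wp, "models": models, "study": study}
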