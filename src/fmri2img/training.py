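"""Adversarial training loop with loss weighting, gating and jittering.

Each iteration draws a seeded mini-batch, jitter-crops the target images
(resize to ``resize_to``, random ``crop_to`` window — emulating ~1
degree of fixational eye movement on a 12 degree display), computes the
three-term generator objective and the discriminator objective on the
same forward passes, then applies a discriminator Adam step (if the
gate allows) followed by a generator Adam step.

Gating: the discriminator update is skipped whenever
``l_discr / l_adv < threshold`` (strictly below; default 0.1), and the
ratio is re-evaluated every iteration, so the discriminator resumes as
soon as the ratio recovers.  This prevents the discriminator from
overpowering the generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .data import PairedDataset, subset_by_size
from .images import resize_image
from .models import (
    EPS, Comparator, ComparatorSpec, DiscriminatorSpec, GeneratorSpec,
    LossBreakdown, LossWeights, adversarial_loss, build_comparator,
    build_discriminator, build_generator, discriminator_loss, image_loss,
    total_loss, toy_comparator_spec, toy_discriminator_spec,
    toy_generator_spec,
)

__all__ = [
    "TrainConfig", "TrainState", "jitter_crop", "gate_discriminator",
    "train", "run_size_sweep", "run_ablation",
    "save_checkpoint", "load_checkpoint",
]

LOG_FIELDS = ("l_img", "l_feat", "l_adv", "l_discr", "discriminator_active")


@dataclass
class TrainConfig:
    """Optimizer and schedule constants.

    Defaults are the study-scale values (batch 64, 500,000 iterations,
    Adam with beta1 = 0.9, beta2 = 0.999, lr = 2e-4, gate threshold 0.1,
    resize 248 / crop 227); toy runs override ``max_iterations``,
    ``resize_to`` and ``crop_to``.
    """
    batch_size: int = 64
    max_iterations: int = 500_000
    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    lr_decay: bool = False          # linear decay to 0 over max_iterations
    gating_threshold: float = 0.1
    resize_to: int = 248
    crop_to: int = 227
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0

    def __post_init__(self):
        if self.crop_to > self.resize_to:
            raise ValueError("crop_to must be <= resize_to")
        if min(self.batch_size, self.max_iterations) <= 0 or self.learning_rate <= 0:
            raise ValueError("batch size, iterations and learning rate must be positive")


@dataclass
class TrainState:
    generator: nn.Sequential
    discriminator: nn.Sequential
    comparator: Comparator
    gen_opt: nn.Adam
    disc_opt: nn.Adam
    config: TrainConfig
    iteration: int = 0
    log: list = field(default_factory=list)   # one LossBreakdown-like dict per iter
    rng: np.random.Generator = None
    diverged: bool = False
    gen_spec: GeneratorSpec = None
    disc_spec: DiscriminatorSpec = None
    comp_spec: ComparatorSpec = None


def jitter_crop(image: np.ndarray, resize_to: int, crop_to: int,
                rng: np.random.Generator) -> np.ndarray:
    """Resize then crop a random ``crop_to`` square window.

    Offsets are uniform on {0, ..., resize_to - crop_to} in each axis;
    ``crop_to == resize_to`` is the deterministic identity crop.
    """
    if crop_to > resize_to:
        raise ValueError("crop window larger than resized image")
    img = resize_image(image, resize_to)
    r = resize_to - crop_to
    oy, ox = (int(rng.integers(0, r + 1)), int(rng.integers(0, r + 1))) if r else (0, 0)
    return img[oy:oy + crop_to, ox:ox + crop_to]


def gate_discriminator(l_discr: float, l_adv: float,
                       threshold: float = 0.1) -> bool:
    """True (active) unless the discriminator/adversarial loss ratio is
    strictly below the threshold.  A zero adversarial loss is a
    degenerate case: the discriminator stays active."""
    if l_adv <= 0:
        return True
    return not (l_discr / l_adv < threshold)


# ---------------------------------------------------------------------------

def _prepare_arrays(ds: PairedDataset, config: TrainConfig, dtype):
    """Voxels (n, D) and resized target images (n, 3, R, R), stored once."""
    vox = ds.voxels.astype(dtype)
    order = ds.unique_stimulus_ids()
    resized = {s: resize_image(ds.images[s], config.resize_to).transpose(2, 0, 1)
               for s in order}
    imgs = np.stack([resized[s] for s in ds.stimulus_ids]).astype(dtype)
    return vox, imgs


def _crop_batch(imgs: np.ndarray, crop: int, offsets: np.ndarray) -> np.ndarray:
    out = np.empty((imgs.shape[0], imgs.shape[1], crop, crop), dtype=imgs.dtype)
    for i, (oy, ox) in enumerate(offsets):
        out[i] = imgs[i, :, oy:oy + crop, ox:ox + crop]
    return out


def _softmax_grad_real(logits: np.ndarray, target_real: bool) -> np.ndarray:
    """d/dlogits of -sum log p(target class), target 0 = real, 1 = fake."""
    p = nn.softmax(logits.astype(np.float64))
    onehot = np.zeros_like(p)
    onehot[:, 0 if target_real else 1] = 1.0
    return (p - onehot).astype(logits.dtype)


def train(ds: PairedDataset, config: TrainConfig,
          gen_spec: GeneratorSpec | None = None,
          disc_spec: DiscriminatorSpec | None = None,
          comp_spec: ComparatorSpec | None = None,
          state: TrainState | None = None,
          extra_iterations: int | None = None):
    """Adversarial training; returns ``(generator, TrainState)``.

    Deterministic given ``config.seed`` and fixed thread configuration.
    Resume by passing a previous ``state`` (seeded RNG state travels in
    checkpoints).  Non-finite losses abort with ``state.diverged`` set
    and the last finite parameters kept.
    """
    if ds.n_samples == 0:
        raise ValueError("training dataset is empty")
    if state is None:
        master = np.random.default_rng(config.seed)
        init_rng = np.random.default_rng(master.integers(2 ** 31))
        gen_spec = gen_spec or toy_generator_spec(ds.voxel_dim, config.crop_to)
        disc_spec = disc_spec or toy_discriminator_spec()
        comp_spec = comp_spec or toy_comparator_spec()
        if gen_spec.input_dim != ds.voxel_dim:
            raise ValueError(
                f"generator input dim {gen_spec.input_dim} != dataset D={ds.voxel_dim}")
        gen = build_generator(gen_spec, init_rng)
        disc = build_discriminator(disc_spec, init_rng)
        comp = build_comparator(comp_spec)
        state = TrainState(
            generator=gen, discriminator=disc, comparator=comp,
            gen_opt=nn.Adam(gen.params(), config.learning_rate,
                            config.beta1, config.beta2),
            disc_opt=nn.Adam(disc.params(), config.learning_rate,
                             config.beta1, config.beta2),
            config=config, rng=np.random.default_rng(master.integers(2 ** 31)),
            gen_spec=gen_spec, disc_spec=disc_spec, comp_spec=comp_spec)
    gen, disc, comp = state.generator, state.discriminator, state.comparator
    rng = state.rng
    w = config.weights
    dtype = gen.params()[0].data.dtype

    vox, imgs = _prepare_arrays(ds, config, dtype)
    n = vox.shape[0]
    r = config.resize_to - config.crop_to

    target_iter = state.iteration + extra_iterations if extra_iterations \
        else config.max_iterations
    adv_on = w.lambda_adv > 0

    while state.iteration < target_iter:
        if n >= config.batch_size:
            idx = rng.permutation(n)[:config.batch_size]
        else:
            idx = rng.integers(0, n, size=config.batch_size)
        offsets = rng.integers(0, r + 1, size=(len(idx), 2))
        x = _crop_batch(imgs[idx], config.crop_to, offsets)
        v = vox[idx]

        g = gen.forward(v)

        # pixel term
        diff = g - x
        l_img = float(np.sum(diff.astype(np.float64) ** 2))
        grad_g = (2.0 * w.lambda_img) * diff

        # feature term (frozen comparator; backprop to its input only).
        # recon pass runs last so the cached activations match the backprop
        feat_x = comp.features(x)
        feat_g = comp.features(g)
        fdiff = feat_g - feat_x
        l_feat = float(np.sum(fdiff.astype(np.float64) ** 2))
        if w.lambda_feat > 0:
            grad_g += w.lambda_feat * comp.backprop_to_input(2.0 * fdiff)

        if adv_on:
            logits_g = disc.forward(g)
            p_g = nn.softmax(logits_g.astype(np.float64))[:, 0]
            l_adv = adversarial_loss(p_g)
            grad_adv_in = disc.backward(
                _softmax_grad_real(logits_g, target_real=True))
            disc.zero_grad()  # adversarial grads belong to the generator only
            grad_g += w.lambda_adv * grad_adv_in

            logits_x = disc.forward(x)
            p_x = nn.softmax(logits_x.astype(np.float64))[:, 0]
            l_discr = discriminator_loss(p_x, p_g)
        else:
            l_adv = 0.0
            l_discr = float("nan")

        l_tot = w.lambda_img * l_img + w.lambda_feat * l_feat + w.lambda_adv * l_adv
        if not np.isfinite(l_tot):
            state.diverged = True
            break

        active = adv_on and gate_discriminator(
            l_discr, l_adv, config.gating_threshold)

        if config.lr_decay:
            frac = 1.0 - state.iteration / config.max_iterations
            state.gen_opt.lr = config.learning_rate * max(frac, 1e-3)
            state.disc_opt.lr = state.gen_opt.lr

        # discriminator step first (on the freshest losses), then generator
        if active:
            disc.zero_grad()
            # real pass: cached activations are from logits_x above
            disc.backward(_softmax_grad_real(logits_x, target_real=True))
            disc.forward(g)  # re-cache the recon pass (detached from gen)
            disc.backward(_softmax_grad_real(logits_g, target_real=False))
            state.disc_opt.step()

        gen.zero_grad()
        gen.backward(grad_g)
        state.gen_opt.step()

        state.log.append({
            "l_img": l_img, "l_feat": l_feat, "l_adv": l_adv,
            "l_discr": l_discr, "discriminator_active": bool(active),
        })
        state.iteration += 1

    return gen, state


# ---------------------------------------------------------------------------
# experiment drivers

def run_size_sweep(ds: PairedDataset, sizes, config: TrainConfig,
                   epochs: int = 1000, batch_size: int = 60,
                   gen_spec=None, disc_spec=None, comp_spec=None):
    """One model per nested training subset, epoch-based schedule.

    ``sizes`` are sample counts (multiples of the trials-per-image);
    each condition trains for ``epochs`` passes at ``batch_size``
    (defaults follow the size-analysis schedule: 1,000 epochs, batch
    60), sharing the seed across conditions.
    """
    out = {}
    for m in sizes:
        sub = subset_by_size(ds, m)
        iters = max(1, int(np.ceil(epochs * sub.n_samples / batch_size)))
        cfg = replace(config, batch_size=batch_size, max_iterations=iters)
        gen, st = train(sub, cfg, gen_spec, disc_spec, comp_spec)
        out[m] = (gen, st)
    return out


ABLATIONS = ("full", "-L_img", "-L_feat", "-L_adv")


def run_ablation(ds: PairedDataset, config: TrainConfig,
                 gen_spec=None, disc_spec=None, comp_spec=None):
    """Four trainings: full objective and one loss term removed at a time.

    Removing a term sets its lambda to 0; without the adversarial term
    the discriminator is never built into the update path (its updates
    are skipped entirely).
    """
    out = {}
    for name in ABLATIONS:
        w = LossWeights(
            lambda_img=0.0 if name == "-L_img" else config.weights.lambda_img,
            lambda_feat=0.0 if name == "-L_feat" else config.weights.lambda_feat,
            lambda_adv=0.0 if name == "-L_adv" else config.weights.lambda_adv)
        cfg = replace(config, weights=w)
        gen, st = train(ds, cfg, gen_spec, disc_spec, comp_spec)
        out[name] = (gen, st)
    return out


# ---------------------------------------------------------------------------
# checkpointing

def save_checkpoint(state: TrainState, path: str) -> None:
    """Single-file archive: parameters, optimizer moments, log, RNG state."""
    arrays = {}
    for name, net in (("gen", state.generator), ("disc", state.discriminator)):
        for i, a in enumerate(net.state_arrays()):
            arrays[f"{name}_p{i}"] = a
    for name, opt in (("gopt", state.gen_opt), ("dopt", state.disc_opt)):
        for i, a in enumerate(opt.state_arrays()):
            arrays[f"{name}_s{i}"] = a
    from dataclasses import asdict

    from .models import spec_to_dict
    meta = {
        "version": 1,
        "iteration": state.iteration,
        "rng_state": state.rng.bit_generator.state,
        "log": state.log,
        "diverged": state.diverged,
        "config": {**asdict(state.config),
                   "weights": asdict(state.config.weights)},
        "specs": {
            "gen": spec_to_dict(state.gen_spec) if state.gen_spec else None,
            "disc": spec_to_dict(state.disc_spec) if state.disc_spec else None,
            "comp": spec_to_dict(state.comp_spec) if state.comp_spec else None,
        },
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str, state: TrainState) -> TrainState:
    """Restore parameters/optimizer/log/RNG into a freshly built state."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        if meta.get("version") != 1:
            raise ValueError("unsupported checkpoint version")
        for name, net in (("gen", state.generator), ("disc", state.discriminator)):
            arrays = []
            i = 0
            while f"{name}_p{i}" in z:
                arrays.append(z[f"{name}_p{i}"])
                i += 1
            net.load_state_arrays(arrays)
        for name, opt in (("gopt", state.gen_opt), ("dopt", state.disc_opt)):
            arrays = []
            i = 0
            while f"{name}_s{i}" in z:
                arrays.append(z[f"{name}_s{i}"])
                i += 1
            opt.load_state_arrays(arrays)
    state.iteration = meta["iteration"]
    state.log = meta["log"]
    state.diverged = meta["diverged"]
    state.rng = np.random.default_rng()
    state.rng.bit_generator.state = meta["rng_state"]
    return state


def load_checkpoint_standalone(path: str) -> TrainState:
    """Rebuild a full TrainState (nets + optimizers) from a checkpoint
    written by :func:`save_checkpoint` with specs included."""
    from .models import spec_from_dict
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
    specs = meta.get("specs") or {}
    if not specs.get("gen"):
        raise ValueError("checkpoint does not carry network specs")
    gen_spec = spec_from_dict(specs["gen"])
    disc_spec = spec_from_dict(specs["disc"])
    comp_spec = spec_from_dict(specs["comp"])
    cfg_d = dict(meta["config"])
    cfg_d["weights"] = LossWeights(**cfg_d["weights"])
    config = TrainConfig(**cfg_d)
    rng = np.random.default_rng(0)
    gen = build_generator(gen_spec, rng)
    disc = build_discriminator(disc_spec, rng)
    comp = build_comparator(comp_spec)
    state = TrainState(
        generator=gen, discriminator=disc, comparator=comp,
        gen_opt=nn.Adam(gen.params(), config.learning_rate,
                        config.beta1, config.beta2),
        disc_opt=nn.Adam(disc.params(), config.learning_rate,
                         config.beta1, config.beta2),
        config=config, rng=np.random.default_rng(0),
        gen_spec=gen_spec, disc_spec=disc_spec, comp_spec=comp_spec)
    return load_checkpoint(path, state)
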