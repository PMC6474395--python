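"""Generator, discriminator and comparator networks, and the training losses.

The generator maps a length-D voxel vector through fully connected
layers to a spatial seed and then through a stack of up-convolutions to
an RGB image.  The discriminator is a convolutional two-way classifier
(real stimulus vs reconstruction) ending in global average pooling and
fully connected layers with a softmax pair.  The comparator is a frozen
convolutional feature extractor; the feature (perceptual) loss is the
summed squared distance between its tap-layer activations for the
reconstruction and the target.

Loss conventions follow the printed objective: sums (not means) over the
batch,

    L = lambda_img * sum_i ||G(v_i) - x_i||^2
      + lambda_feat * sum_i ||C(G(v_i)) - C(x_i)||^2
      + lambda_adv * (-sum_i log D(G(v_i)))

with defaults lambda_img = 2e6, lambda_feat = 0.01, lambda_adv = 100,
and the discriminator objective

    L_discr = -sum_i [log D(x_i) + log(1 - D(G(v_i)))].

Probabilities are clamped to [eps, 1 - eps] (eps = 1e-7) before logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "EPS", "LossWeights", "LossBreakdown",
    "GeneratorSpec", "DiscriminatorSpec", "ComparatorSpec",
    "build_generator", "build_discriminator", "build_comparator",
    "Comparator",
    "image_loss", "feature_loss", "adversarial_loss", "discriminator_loss",
    "total_loss",
    "toy_generator_spec", "toy_discriminator_spec", "toy_comparator_spec",
    "study_scale_generator_spec", "study_scale_discriminator_spec",
]

EPS = 1e-7


@dataclass
class LossWeights:
    lambda_img: float = 2e6
    lambda_feat: float = 0.01
    lambda_adv: float = 100.0

    def __post_init__(self):
        if min(self.lambda_img, self.lambda_feat, self.lambda_adv) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    l_img: float
    l_feat: float
    l_adv: float
    l_total: float
    l_discr: float


# ---------------------------------------------------------------------------
# specs

@dataclass
class GeneratorSpec:
    """Voxel vector -> image network.

    ``upconv`` entries are ``(out_channels, kernel, stride, pad)``.  The
    study-scale preset keeps three fully connected and six up-convolution
    layers; the toy preset (two FC + three upconvs, 32 x 32 output) is a
    deliberately smaller configuration for CPU-scale runs.
    """
    input_dim: int
    fc_widths: list
    seed_channels: int
    seed_size: int
    upconv: list
    output_size: int
    dtype: type = np.float32

    def achieved_size(self) -> int:
        s = self.seed_size
        for _c, k, st, p in self.upconv:
            s = nn.convt_out_size(s, k, st, p)
        return s


@dataclass
class DiscriminatorSpec:
    """Image -> (p_real, p_fake) classifier; conv stack, global average
    pooling, fully connected head ending in a 2-way softmax."""
    conv: list                 # (out_channels, kernel, stride, pad)
    fc_widths: list            # hidden widths; a final width-2 layer is implied
    in_channels: int = 3
    dtype: type = np.float32


@dataclass
class ComparatorSpec:
    """Frozen feature extractor defining the perceptual metric space.

    ``weights_source`` is ``("random_fixed", seed)`` — a fixed-seed
    random convolutional net (random features define a valid metric
    space for toy-scale work) — or ``("external_file", path)`` pointing
    at an ``.npz`` of conv weights for use with real pretrained filters.
    ``tap_layer`` indexes the convolution to read features from
    (negative = from the end); ``tap_post_activation`` selects post- vs
    pre-nonlinearity activations.
    """
    conv: list = field(default_factory=lambda: [(16, 5, 2, 2), (32, 5, 2, 2)])
    tap_layer: int = -1
    tap_post_activation: bool = True
    weights_source: tuple = ("random_fixed", 0)
    in_channels: int = 3
    dtype: type = np.float32


# ---------------------------------------------------------------------------
# builders

def build_generator(spec: GeneratorSpec, rng=None) -> nn.Sequential:
    """MSRA-initialized generator; validates the upconv geometry."""
    achieved = spec.achieved_size()
    if achieved != spec.output_size:
        raise ValueError(
            f"upconv stack produces {achieved}x{achieved}, spec demands "
            f"{spec.output_size}x{spec.output_size}; adjust kernels/strides")
    rng = rng or np.random.default_rng(0)
    layers = []
    d = spec.input_dim
    for w in spec.fc_widths:
        layers += [nn.Dense(d, w, rng, spec.dtype), nn.ReLU()]
        d = w
    seed_dim = spec.seed_channels * spec.seed_size ** 2
    layers += [nn.Dense(d, seed_dim, rng, spec.dtype), nn.ReLU(),
               nn.Reshape((spec.seed_channels, spec.seed_size, spec.seed_size))]
    c = spec.seed_channels
    for i, (c_out, k, st, p) in enumerate(spec.upconv):
        layers.append(nn.ConvTranspose2d(c, c_out, k, st, p, rng, spec.dtype))
        if i < len(spec.upconv) - 1:
            layers.append(nn.LeakyReLU(0.2))
        c = c_out
    return nn.Sequential(layers)


def build_discriminator(spec: DiscriminatorSpec, rng=None) -> nn.Sequential:
    rng = rng or np.random.default_rng(1)
    layers = []
    c = spec.in_channels
    for c_out, k, st, p in spec.conv:
        layers += [nn.Conv2d(c, c_out, k, st, p, rng, spec.dtype),
                   nn.LeakyReLU(0.2)]
        c = c_out
    layers.append(nn.GlobalAvgPool())
    d = c
    for w in spec.fc_widths:
        layers += [nn.Dense(d, w, rng, spec.dtype), nn.LeakyReLU(0.2)]
        d = w
    layers.append(nn.Dense(d, 2, rng, spec.dtype))  # logits; softmax in loss
    return nn.Sequential(layers)


class Comparator:
    """Frozen conv feature extractor with a configurable tap layer."""

    def __init__(self, spec: ComparatorSpec):
        self.spec = spec
        kind, src = spec.weights_source
        if kind == "random_fixed":
            rng = np.random.default_rng(int(src))
            weights = None
        elif kind == "external_file":
            rng = np.random.default_rng(0)
            weights = np.load(src)
        else:
            raise ValueError(f"unknown weights_source kind {kind!r}")
        layers = []
        c = spec.in_channels
        for i, (c_out, k, st, p) in enumerate(spec.conv):
            conv = nn.Conv2d(c, c_out, k, st, p, rng, spec.dtype)
            if weights is not None:
                conv.w.data = weights[f"conv{i}_w"].astype(spec.dtype)
                conv.b.data = weights[f"conv{i}_b"].astype(spec.dtype)
            layers += [conv, nn.ReLU()]
            c = c_out
        self.net = nn.Sequential(layers)
        tap = spec.tap_layer % len(spec.conv)
        # index into the flat [conv, relu, conv, relu, ...] layer list
        self._stop = 2 * tap + (2 if spec.tap_post_activation else 1)

    def features(self, images: np.ndarray) -> np.ndarray:
        """Tap-layer activations for an (N, 3, H, W) batch."""
        return self.net.forward_to(images, self._stop)

    def backprop_to_input(self, g_feat: np.ndarray) -> np.ndarray:
        """Input-space gradient of a functional of the tap activations.

        The comparator is frozen: its parameter grads are discarded.
        """
        gx = self.net.backward(g_feat, start=self._stop)
        self.net.zero_grad()
        return gx

    def state_arrays(self):
        return self.net.state_arrays()


def build_comparator(spec: ComparatorSpec) -> Comparator:
    return Comparator(spec)


# ---------------------------------------------------------------------------
# losses (batch arrays are NCHW)

def image_loss(recon: np.ndarray, target: np.ndarray) -> float:
    """Sum of squared pixel differences over the batch."""
    if recon.shape != target.shape:
        raise ValueError(f"shape mismatch {recon.shape} vs {target.shape}")
    d = recon - target
    return float(np.sum(d * d))


def feature_loss(recon: np.ndarray, target: np.ndarray,
                 comparator: Comparator) -> float:
    """Sum of squared differences of comparator tap activations."""
    d = comparator.features(recon) - comparator.features(target)
    return float(np.sum(d * d))


def discriminator_probs(discriminator: nn.Sequential,
                        images: np.ndarray) -> np.ndarray:
    """P(real) per image, from the discriminator's softmax pair."""
    logits = discriminator.forward(images)
    return nn.softmax(logits.astype(np.float64))[:, 0]


def adversarial_loss(p_real: np.ndarray) -> float:
    """-sum_i log D(G(v_i)), with D clamped to [eps, 1 - eps]."""
    p = np.clip(np.asarray(p_real, dtype=np.float64), EPS, 1.0 - EPS)
    return float(-np.sum(np.log(p)))


def discriminator_loss(p_real_on_real: np.ndarray,
                       p_real_on_recon: np.ndarray) -> float:
    """-sum_i [log D(x_i) + log(1 - D(G(v_i)))]."""
    pr = np.clip(np.asarray(p_real_on_real, dtype=np.float64), EPS, 1.0 - EPS)
    pg = np.clip(np.asarray(p_real_on_recon, dtype=np.float64), EPS, 1.0 - EPS)
    return float(-np.sum(np.log(pr) + np.log(1.0 - pg)))


def total_loss(l_img: float, l_feat: float, l_adv: float,
               weights: LossWeights, l_discr: float = float("nan")) -> LossBreakdown:
    total = (weights.lambda_img * l_img + weights.lambda_feat * l_feat
             + weights.lambda_adv * l_adv)
    return LossBreakdown(l_img, l_feat, l_adv, total, l_discr)


# ---------------------------------------------------------------------------
# presets

def spec_to_dict(spec) -> dict:
    """JSON-able form of a network spec (dtype encoded by name)."""
    from dataclasses import asdict
    d = asdict(spec)
    d["dtype"] = np.dtype(spec.dtype).name
    d["kind"] = type(spec).__name__
    return d


def spec_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("kind")
    d["dtype"] = {"float32": np.float32, "float64": np.float64}[d["dtype"]]
    cls = {"GeneratorSpec": GeneratorSpec,
           "DiscriminatorSpec": DiscriminatorSpec,
           "ComparatorSpec": ComparatorSpec}[kind]
    for k in ("upconv", "conv"):
        if k in d and d[k] is not None:
            d[k] = [tuple(e) for e in d[k]]
    if "weights_source" in d:
        d["weights_source"] = tuple(d["weights_source"])
    return cls(**d)


def toy_generator_spec(input_dim: int, output_size: int = 32,
                       dtype=np.float32) -> GeneratorSpec:
    """CPU-scale generator: 2 FC + 3 upconvs to a 32 x 32 image."""
    if output_size % 8:
        raise ValueError("toy output_size must be a multiple of 8")
    return GeneratorSpec(
        input_dim=input_dim,
        fc_widths=[256],
        seed_channels=64, seed_size=output_size // 8,
        upconv=[(32, 4, 2, 1), (16, 4, 2, 1), (3, 4, 2, 1)],
        output_size=output_size, dtype=dtype)


def toy_discriminator_spec(dtype=np.float32) -> DiscriminatorSpec:
    return DiscriminatorSpec(
        conv=[(16, 4, 2, 1), (32, 4, 2, 1), (64, 4, 2, 1)],
        fc_widths=[32], dtype=dtype)


def toy_comparator_spec(seed: int = 0, dtype=np.float32) -> ComparatorSpec:
    return ComparatorSpec(weights_source=("random_fixed", seed), dtype=dtype)


def study_scale_generator_spec(input_dim: int) -> GeneratorSpec:
    """Faithful geometry: 3 FC + 6 upconvs reaching a 227 x 227 image.

    Channel widths follow the reference up-convolutional generator this
    model adapts; exact kernel/stride bookkeeping is chosen so the stack
    lands on 227 exactly (4 -> 7 -> 14 -> 28 -> 56 -> 113 -> 227).
    """
    return GeneratorSpec(
        input_dim=input_dim,
        fc_widths=[4096, 4096],
        seed_channels=256, seed_size=4,
        upconv=[(256, 3, 2, 1), (128, 4, 2, 1), (64, 4, 2, 1),
                (32, 4, 2, 1), (16, 3, 2, 0), (3, 3, 2, 0)],
        output_size=227)


def study_scale_discriminator_spec() -> DiscriminatorSpec:
    """Five conv layers, average pooling, two fully connected layers."""
    return DiscriminatorSpec(
        conv=[(32, 7, 4, 3), (64, 5, 2, 2), (128, 3, 2, 1),
              (256, 3, 2, 1), (256, 3, 2, 1)],
        fc_widths=[512])
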