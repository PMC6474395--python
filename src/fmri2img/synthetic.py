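"""Synthetic visual-perception study: stimuli, encoding model, responses.

Emulates the structure of a block-design fMRI image-perception dataset —
natural-image training stimuli presented repeatedly, plus artificial
shapes (a color x shape factorial set) and alphabet letters as
generalization test sets — via a ground-truth linear encoding model
mapping image features to voxel responses.  Everything is deterministic
given its seed, so every downstream stage (preprocessing, training,
evaluation) is testable without any real recording.

Default study geometry mirrors the emulated experiment: 1,200 training
images x 5 presentations (6,000 samples), 50 natural test images x 24
trials, 40 shapes (8 colors x 5 shapes) x 20 trials, 10 letters x 12
trials.  The toy presets in :mod:`fmri2img.experiments` scale this down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import nn
from .images import as_float_image, downsample_mean, rgb_to_gray

__all__ = [
    "DEFAULT_COLORS", "DEFAULT_SHAPES", "DEFAULT_LETTERS",
    "render_artificial_shapes", "render_letters", "generate_natural_like",
    "EncodingModel", "simulate_responses",
    "BlockDesign", "simulate_run_timeseries",
]


# ---------------------------------------------------------------------------
# artificial shapes

DEFAULT_COLORS = {
    "red": (0.9, 0.1, 0.1),
    "green": (0.1, 0.8, 0.1),
    "blue": (0.15, 0.25, 0.9),
    "yellow": (0.95, 0.9, 0.1),
    "cyan": (0.1, 0.85, 0.85),
    "magenta": (0.9, 0.15, 0.9),
    "orange": (0.95, 0.55, 0.1),
    "white": (0.95, 0.95, 0.95),
}

DEFAULT_SHAPES = ("square", "circle", "triangle", "cross", "diamond")

_BACKGROUND = 0.5  # uniform mid-gray ground for the figure


def _shape_mask(shape: str, n: int) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    r = n * 0.32
    y, x = yy - c, xx - c
    if shape == "square":
        return (np.abs(y) <= r) & (np.abs(x) <= r)
    if shape == "circle":
        return y ** 2 + x ** 2 <= r ** 2
    if shape == "triangle":
        return (y >= -r) & (np.abs(x) <= (y + r) * 0.6)
    if shape == "cross":
        w = r * 0.4
        return ((np.abs(x) <= w) & (np.abs(y) <= r)) | \
               ((np.abs(y) <= w) & (np.abs(x) <= r))
    if shape == "diamond":
        return np.abs(y) + np.abs(x) <= r * 1.3
    raise ValueError(f"unknown shape glyph {shape!r}")


def render_shape(shape: str, color, canvas_size: int) -> np.ndarray:
    """One foreground glyph of the given color on a uniform background."""
    if canvas_size < 16:
        raise ValueError("canvas_size must be >= 16")
    img = np.full((canvas_size, canvas_size, 3), _BACKGROUND)
    mask = _shape_mask(shape, canvas_size)
    img[mask] = np.asarray(color, dtype=np.float64)
    return img


def render_artificial_shapes(colors=None, shapes=None, canvas_size: int = 32):
    """Full factorial color x shape stimulus set.

    Returns ``(images, attrs)`` where ``attrs[i]`` carries the
    ``color_id`` / ``shape_id`` labels used by the shape- and
    color-restricted identification analyses.
    """
    colors = DEFAULT_COLORS if colors is None else colors
    shapes = DEFAULT_SHAPES if shapes is None else tuple(shapes)
    if not colors or not shapes:
        raise ValueError("color and shape palettes must be non-empty")
    images, attrs = [], []
    for color_id, rgb in colors.items():
        for shape_id in shapes:
            images.append(render_shape(shape_id, rgb, canvas_size))
            attrs.append({"color_id": color_id, "shape_id": shape_id})
    return images, attrs


# ---------------------------------------------------------------------------
# letters: packaged 5x7 bitmap glyphs (no system-font dependency)

_FONT_5x7 = {
    "A": ("01110", "10001", "10001", "11111", "10001", "10001", "10001"),
    "B": ("11110", "10001", "10001", "11110", "10001", "10001", "11110"),
    "C": ("01110", "10001", "10000", "10000", "10000", "10001", "01110"),
    "D": ("11110", "10001", "10001", "10001", "10001", "10001", "11110"),
    "E": ("11111", "10000", "10000", "11110", "10000", "10000", "11111"),
    "F": ("11111", "10000", "10000", "11110", "10000", "10000", "10000"),
    "G": ("01110", "10001", "10000", "10111", "10001", "10001", "01111"),
    "H": ("10001", "10001", "10001", "11111", "10001", "10001", "10001"),
    "I": ("01110", "00100", "00100", "00100", "00100", "00100", "01110"),
    "J": ("00111", "00010", "00010", "00010", "00010", "10010", "01100"),
    "K": ("10001", "10010", "10100", "11000", "10100", "10010", "10001"),
    "L": ("10000", "10000", "10000", "10000", "10000", "10000", "11111"),
    "M": ("10001", "11011", "10101", "10101", "10001", "10001", "10001"),
    "N": ("10001", "11001", "10101", "10011", "10001", "10001", "10001"),
    "O": ("01110", "10001", "10001", "10001", "10001", "10001", "01110"),
    "P": ("11110", "10001", "10001", "11110", "10000", "10000", "10000"),
    "Q": ("01110", "10001", "10001", "10001", "10101", "10010", "01101"),
    "R": ("11110", "10001", "10001", "11110", "10100", "10010", "10001"),
    "S": ("01111", "10000", "10000", "01110", "00001", "00001", "11110"),
    "T": ("11111", "00100", "00100", "00100", "00100", "00100", "00100"),
    "U": ("10001", "10001", "10001", "10001", "10001", "10001", "01110"),
    "V": ("10001", "10001", "10001", "10001", "10001", "01010", "00100"),
    "W": ("10001", "10001", "10001", "10101", "10101", "11011", "10001"),
    "X": ("10001", "10001", "01010", "00100", "01010", "10001", "10001"),
    "Y": ("10001", "10001", "01010", "00100", "00100", "00100", "00100"),
    "Z": ("11111", "00001", "00010", "00100", "01000", "10000", "11111"),
}

DEFAULT_LETTERS = ("A", "C", "E", "H", "K", "N", "O", "R", "S", "T")


def render_letter(letter: str, canvas_size: int = 32) -> np.ndarray:
    """Black letter glyph on a white background."""
    if letter not in _FONT_5x7:
        raise ValueError(f"letter must be one of A-Z, got {letter!r}")
    glyph = np.array([[c == "1" for c in row] for row in _FONT_5x7[letter]])
    scale = max(1, int(canvas_size * 0.7) // 7)
    big = np.kron(glyph, np.ones((scale, scale), dtype=bool))
    img = np.ones((canvas_size, canvas_size, 3))
    y0 = (canvas_size - big.shape[0]) // 2
    x0 = (canvas_size - big.shape[1]) // 2
    img[y0:y0 + big.shape[0], x0:x0 + big.shape[1]][big] = 0.0
    return img


def render_letters(letters=DEFAULT_LETTERS, canvas_size: int = 32):
    return [render_letter(l, canvas_size) for l in letters]


# ---------------------------------------------------------------------------
# natural-like textures

def generate_natural_like(n: int, canvas_size: int = 32, seed: int = 0):
    """Smooth random textures with broadband spatial structure.

    Each image is a sum of two Gaussian-smoothed white-noise fields (a
    coarse and a finer scale) shared across channels, plus a weaker
    per-channel chromatic field; min-max normalized into [0.02, 0.98].
    This yields the fast-decaying spatial spectrum of natural scenes
    without attempting photorealism.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        coarse = gaussian_filter(rng.normal(size=(canvas_size, canvas_size)),
                                 canvas_size / 8.0, mode="wrap")
        fine = gaussian_filter(rng.normal(size=(canvas_size, canvas_size)),
                               canvas_size / 24.0, mode="wrap")
        lum = coarse + 0.45 * fine
        img = np.empty((canvas_size, canvas_size, 3))
        for c in range(3):
            chroma = gaussian_filter(
                rng.normal(size=(canvas_size, canvas_size)),
                canvas_size / 8.0, mode="wrap")
            img[..., c] = lum + 0.35 * chroma
        lo, hi = img.min(), img.max()
        img = 0.02 + 0.96 * (img - lo) / (hi - lo)
        out.append(img)
    return out


# ---------------------------------------------------------------------------
# encoding model

class EncodingModel:
    """Ground-truth image -> voxel map: ``v = W f(x) (+ noise)``.

    ``feature_map`` is either ``"downsample_gray"`` (grayscale pixels
    block-averaged to ``feature_size**2``; the default, which keeps toy
    reconstruction identifiable) or ``"random_conv"`` (one fixed-seed
    random convolution layer with half-wave rectification, a harder
    nonlinear map).
    """

    def __init__(self, n_voxels: int, canvas_size: int,
                 feature_map: str = "downsample_gray", feature_size: int = 16,
                 noise_sd: float = 0.6, seed: int = 0):
        self.n_voxels = int(n_voxels)
        self.canvas_size = int(canvas_size)
        self.feature_map = feature_map
        self.feature_size = int(feature_size)
        self.noise_sd = float(noise_sd)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        if feature_map == "downsample_gray":
            self.n_features = self.feature_size ** 2
        elif feature_map == "random_conv":
            self._conv_w = rng.normal(
                0.0, 0.3, size=(8, 3, 5, 5))
            side = nn.conv_out_size(canvas_size, 5, 4, 2)
            self.n_features = 8 * side * side
        else:
            raise ValueError(f"unknown feature_map {feature_map!r}")
        self.weight_matrix = rng.normal(
            0.0, 1.0 / np.sqrt(self.n_features),
            size=(self.n_voxels, self.n_features))

    def features(self, image: np.ndarray) -> np.ndarray:
        img = as_float_image(image)
        if img.shape[0] != self.canvas_size or img.shape[1] != self.canvas_size:
            raise ValueError(
                f"image side {img.shape[:2]} does not match model canvas "
                f"{self.canvas_size}")
        if self.feature_map == "downsample_gray":
            # centered intensities: responses are signal deviations, not
            # offsets proportional to overall image brightness
            f = downsample_mean(rgb_to_gray(img), self.feature_size).ravel()
            return f - 0.5
        x = img.transpose(2, 0, 1)[None]
        y = nn.conv_fwd(x, self._conv_w, stride=4, pad=2)
        return np.maximum(y, 0.0).ravel()

    def respond(self, image: np.ndarray) -> np.ndarray:
        """Noiseless voxel response vector for one stimulus."""
        return self.weight_matrix @ self.features(image)


def simulate_responses(model: EncodingModel, image: np.ndarray,
                       n_trials: int, seed: int = 0) -> np.ndarray:
    """``n_trials`` x D trial responses: noiseless response + iid Gaussian noise."""
    clean = model.respond(image)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, model.noise_sd, size=(n_trials, model.n_voxels)) \
        if model.noise_sd > 0 else np.zeros((n_trials, model.n_voxels))
    return clean[None, :] + noise


# ---------------------------------------------------------------------------
# run-level time series

@dataclass
class BlockDesign:
    """Block/rest layout of one run, in volumes."""
    rest_volumes: int = 12          # initial rest (24 s at TR = 2 s)
    block_volumes: int = 4          # stimulus block (8 s at TR = 2 s)
    gap_volumes: int = 2            # inter-block rest
    delay_volumes: int = 2          # hemodynamic response delay (4 s)
    tr_seconds: float = 2.0

    def layout(self, n_stimuli: int):
        onsets = []
        t = self.rest_volumes
        for _ in range(n_stimuli):
            onsets.append(t)
            t += self.block_volumes + self.gap_volumes
        total = t + self.delay_volumes + 2
        return onsets, total


def simulate_run_timeseries(model: EncodingModel, stimuli, stimulus_ids,
                            design: BlockDesign | None = None,
                            baseline: float = 100.0,
                            drift_slope: float = 0.02,
                            motion_amp: float = 0.5,
                            spike_rate: float = 0.0,
                            spike_amplitude: float = 10.0,
                            noise_sd: float | None = None,
                            seed: int = 0):
    """Generate one run of voxel time series around the encoding model.

    Additively composes, per voxel: a rest baseline, delayed block-wise
    noiseless responses, a linear drift, components correlated with six
    smooth motion regressors, sparse large spikes, and iid Gaussian
    noise.  Returns a :class:`fmri2img.preprocess.RunTimeSeries` whose
    ``extras`` dict retains every ground-truth component so tests can
    check what the preprocessing chain recovers.
    """
    from .preprocess import RunTimeSeries  # local import to avoid cycle

    design = design or BlockDesign()
    rng = np.random.default_rng(seed)
    d = model.n_voxels
    onsets, t_total = design.layout(len(stimuli))

    responses = np.stack([model.respond(im) for im in stimuli])
    signal = np.zeros((t_total, d))
    blocks = []
    for onset, stim_id, resp in zip(onsets, stimulus_ids, responses):
        a = onset + design.delay_volumes
        signal[a:a + design.block_volumes] += resp[None, :]
        blocks.append((onset, design.block_volumes, stim_id))

    tt = np.arange(t_total)
    drift = drift_slope * tt[:, None] * np.ones((1, d))

    motion = np.cumsum(rng.normal(size=(t_total, 6)), axis=0)
    motion = gaussian_filter(motion, (4.0, 0.0))
    motion -= motion.mean(axis=0)
    sd = motion.std(axis=0)
    motion /= np.where(sd > 0, sd, 1.0)
    motion_coef = rng.normal(0.0, motion_amp, size=(6, d))
    motion_part = motion @ motion_coef

    spike_mask = rng.random(size=(t_total, d)) < spike_rate
    spike_sign = np.where(rng.random(size=(t_total, d)) < 0.5, -1.0, 1.0)
    spikes = spike_mask * spike_sign * spike_amplitude

    nsd = model.noise_sd if noise_sd is None else noise_sd
    noise = rng.normal(0.0, nsd, size=(t_total, d)) if nsd > 0 else 0.0

    data = baseline + signal + drift + motion_part + spikes + noise
    return RunTimeSeries(
        data=data,
        rest_window=(0, design.rest_volumes),
        blocks=blocks,
        motion=motion,
        tr_seconds=design.tr_seconds,
        extras={
            "responses": responses,
            "stimulus_ids": list(stimulus_ids),
            "spike_mask": spike_mask,
            "drift": drift,
            "motion_part": motion_part,
            "baseline": baseline,
            "delay_volumes": design.delay_volumes,
        },
    )
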