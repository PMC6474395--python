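"""fMRI sample preparation: from run-level time series to model-ready vectors.

The chain, in order: nuisance regression (linear trend + six motion
parameters), normalization to the initial rest-period baseline (percent
signal change), despiking (clipping beyond +-k SD per run), block
averaging with a hemodynamic shift, per-voxel z-scoring from training
statistics, and trial averaging with amplitude rescaling for test data.

Nuisance regression removes the fitted trend/motion contributions but
retains each voxel's baseline (the fitted intercept): the subsequent
rest normalization divides by the rest-window mean, which is only
meaningful with the baseline in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RunTimeSeries", "VoxelStats", "PreprocParams",
    "regress_nuisance", "normalize_to_rest", "despike", "average_blocks",
    "fit_voxel_stats", "apply_zscore", "average_trials_and_rescale",
    "preprocess_run", "save_run_h5", "load_run_h5",
]


@dataclass
class RunTimeSeries:
    """One run: T x D voxel amplitudes plus design metadata.

    ``blocks`` is a list of ``(onset_volume, duration_volumes,
    stimulus_id)``; ``rest_window`` is a half-open volume range.
    """
    data: np.ndarray
    rest_window: tuple
    blocks: list
    motion: np.ndarray
    tr_seconds: float = 2.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        t = self.data.shape[0]
        if not (0 <= self.rest_window[0] < self.rest_window[1] <= t):
            raise ValueError(f"rest window {self.rest_window} outside run of {t} volumes")
        spans = sorted((o, o + dur) for o, dur, _ in self.blocks)
        for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping blocks at volumes {a1} < {b0}")
        for a, b in spans:
            if a < 0 or b > t:
                raise ValueError(f"block [{a}, {b}) outside run of {t} volumes")
        if self.motion is not None and self.motion.shape[0] != t:
            raise ValueError("motion regressors must have one row per volume")

    def replace_data(self, data: np.ndarray) -> "RunTimeSeries":
        return RunTimeSeries(data, self.rest_window, self.blocks,
                             self.motion, self.tr_seconds, self.extras)


@dataclass
class VoxelStats:
    """Per-voxel mean and SD, computed on training samples only."""
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        bad = np.flatnonzero(self.sd <= 0)
        if bad.size:
            raise ValueError(f"zero-variance voxels: {bad[:20].tolist()}")


@dataclass
class PreprocParams:
    despike_k: float = 3.0
    shift_seconds: float = 4.0        # hemodynamic delay compensation
    block_seconds: float = 8.0        # 8 s training blocks / 12 s test blocks
    rescale_mode: str = "sqrt_n"      # {"sqrt_n", "n"}

    def __post_init__(self):
        if self.despike_k <= 0:
            raise ValueError("despike_k must be positive")
        if self.rescale_mode not in ("sqrt_n", "n"):
            raise ValueError(f"unknown rescale_mode {self.rescale_mode!r}")

    def shift_volumes(self, tr: float) -> int:
        return _as_volumes(self.shift_seconds, tr, "shift_seconds")

    def block_volumes(self, tr: float) -> int:
        return _as_volumes(self.block_seconds, tr, "block_seconds")


def _as_volumes(seconds: float, tr: float, name: str) -> int:
    v = seconds / tr
    if abs(v - round(v)) > 1e-9 or v < 0:
        raise ValueError(f"{name}={seconds} is not a non-negative multiple of TR={tr}")
    return int(round(v))


# ---------------------------------------------------------------------------

def regress_nuisance(run: RunTimeSeries) -> RunTimeSeries:
    """Remove a linear trend and six motion components from each voxel.

    Per-voxel OLS of amplitude on [intercept, linear trend, motion x 6];
    the trend and motion contributions are subtracted while the fitted
    intercept (the voxel baseline) is kept, so the output minus its
    intercept is orthogonal to every design column.
    """
    if run.motion is None:
        raise ValueError("motion regressors required for nuisance regression")
    t, d = run.data.shape
    # motion columns that carry no signal (e.g. a motionless phantom run)
    # are dropped rather than treated as a rank defect
    live = np.flatnonzero(run.motion.std(axis=0) > 1e-12)
    design = np.column_stack([
        np.ones(t),
        np.linspace(-1.0, 1.0, t),
        run.motion[:, live],
    ])
    if t <= design.shape[1] + 2:
        raise ValueError("run too short for nuisance regression")
    beta, _, rank, _ = np.linalg.lstsq(design, run.data, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient nuisance design (rank {rank} < {design.shape[1]}); "
            "check for constant or duplicated motion regressors")
    cleaned = run.data - design[:, 1:] @ beta[1:]
    return run.replace_data(cleaned)


def normalize_to_rest(run: RunTimeSeries) -> RunTimeSeries:
    """Express each voxel as percent change from its initial-rest mean."""
    a, b = run.rest_window
    rest_mean = run.data[a:b].mean(axis=0)
    bad = np.flatnonzero(np.abs(rest_mean) < 1e-12)
    if bad.size:
        raise ValueError(f"zero rest-window mean for voxels {bad[:20].tolist()}")
    return run.replace_data(100.0 * (run.data / rest_mean - 1.0))


def despike(run: RunTimeSeries, k: float = 3.0) -> RunTimeSeries:
    """Clip values beyond mean +- k SD per voxel (single pass).

    The statistics are computed once on the input; clipping to those
    fixed bounds is idempotent.
    """
    if k <= 0:
        raise ValueError("despike threshold k must be positive")
    mu = run.data.mean(axis=0)
    sd = run.data.std(axis=0)
    lo, hi = mu - k * sd, mu + k * sd
    return run.replace_data(np.clip(run.data, lo, hi))


def average_blocks(run: RunTimeSeries, params: PreprocParams):
    """One voxel vector per stimulus block.

    Averages the volumes in ``[onset + shift, onset + shift + block)``
    where shift and block length are converted from seconds via the TR
    (e.g. a 4 s shift and 8 s block at TR = 2 s -> start 2 volumes after
    onset, average 4 volumes).
    """
    shift = params.shift_volumes(run.tr_seconds)
    nvol = params.block_volumes(run.tr_seconds)
    t = run.data.shape[0]
    out = []
    for onset, _dur, stim_id in run.blocks:
        a = onset + shift
        if a + nvol > t:
            raise ValueError(
                f"shifted window [{a}, {a + nvol}) for stimulus {stim_id!r} "
                f"exceeds run length {t}")
        out.append((stim_id, run.data[a:a + nvol].mean(axis=0)))
    return out


def fit_voxel_stats(train_vectors) -> VoxelStats:
    """Per-voxel mean/SD over training samples (ddof=0)."""
    x = np.asarray(train_vectors, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 training vectors")
    return VoxelStats(mean=x.mean(axis=0), sd=x.std(axis=0))


def apply_zscore(vectors, stats: VoxelStats) -> np.ndarray:
    x = np.asarray(vectors, dtype=np.float64)
    if x.shape[-1] != stats.mean.shape[0]:
        raise ValueError(
            f"vector length {x.shape[-1]} does not match stats ({stats.mean.shape[0]})")
    return (x - stats.mean) / stats.sd


def average_trials_and_rescale(trials, mode: str = "sqrt_n") -> np.ndarray:
    """Trial-average repeated presentations and restore amplitude scale.

    Averaging n iid-noise trials shrinks the noise SD by sqrt(n); the
    default ``sqrt_n`` mode multiplies the average by sqrt(n) so the
    test input matches the scale the z-scoring established on
    single-trial training data.  ``n`` mode multiplies by n instead.
    """
    x = np.asarray(trials, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] == 0:
        raise ValueError("no trials to average")
    n = x.shape[0]
    factor = {"sqrt_n": np.sqrt(n), "n": float(n)}[mode]
    return x.mean(axis=0) * factor


def save_run_h5(run: RunTimeSeries, path: str) -> None:
    """Run container: datasets ``data`` (T x D), ``motion`` (T x 6) and a
    structured ``blocks`` table; attributes ``tr_seconds``, rest window."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=run.data)
        if run.motion is not None:
            f.create_dataset("motion", data=run.motion)
        block_dt = np.dtype([("onset", "i8"), ("duration", "i8"),
                             ("stimulus_id", h5py.string_dtype("utf-8"))])
        table = np.array([(o, d, s) for o, d, s in run.blocks], dtype=block_dt)
        f.create_dataset("blocks", data=table)
        f.attrs["tr_seconds"] = run.tr_seconds
        f.attrs["rest_start"], f.attrs["rest_end"] = run.rest_window


def load_run_h5(path: str) -> RunTimeSeries:
    import h5py
    with h5py.File(path, "r") as f:
        for name in ("data", "blocks"):
            if name not in f:
                raise ValueError(f"malformed run container: missing {name!r}")
        data = f["data"][()]
        motion = f["motion"][()] if "motion" in f else None
        blocks = [(int(b["onset"]), int(b["duration"]),
                   b["stimulus_id"].decode() if isinstance(b["stimulus_id"], bytes)
                   else str(b["stimulus_id"]))
                  for b in f["blocks"][()]]
        tr = float(f.attrs["tr_seconds"])
        rest = (int(f.attrs["rest_start"]), int(f.attrs["rest_end"]))
    return RunTimeSeries(data, rest, blocks, motion, tr)


def preprocess_run(run: RunTimeSeries, params: PreprocParams | None = None):
    """Full per-run chain: nuisance -> rest-normalize -> despike -> blocks."""
    params = params or PreprocParams()
    run = regress_nuisance(run)
    run = normalize_to_rest(run)
    run = despike(run, params.despike_k)
    return average_blocks(run, params)
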