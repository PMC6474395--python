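"""Reconstruction and quantitative assessment.

Implements the pairwise identification protocol (one reconstruction vs
the true stimulus and a lure of the same stimulus type; accuracy =
percent of trials selecting the true stimulus, chance 50%), flattened
Pearson and RGB-averaged SSIM similarity metrics, the shape/color
restricted comparisons, seeded trial subsampling for the dataset-size
sweep, the modified RV coefficient with its permutation baseline, and
winning percentages for the loss-ablation comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .images import as_float_image
from .preprocess import average_trials_and_rescale

__all__ = [
    "ComparisonTrial", "AccuracyReport", "RVResult",
    "reconstruct", "flatten_pearson", "ssim_rgb",
    "enumerate_trials", "score_trials", "subsample_trials",
    "modified_rv", "rv_permutation_test", "winning_percentage",
    "ablation_winning_percentages",
]


# ---------------------------------------------------------------------------
# reconstruction

def reconstruct(generator, trials, mode: str = "sqrt_n") -> np.ndarray:
    """Trial-average + rescale the test vectors, run the generator, clip.

    ``trials`` is (n_trials, D) of z-scored test vectors; returns an
    (h, w, 3) image in [0, 1].
    """
    v = average_trials_and_rescale(trials, mode)
    dtype = generator.params()[0].data.dtype
    out = generator.forward(v[None].astype(dtype))[0]
    return np.clip(out.transpose(1, 2, 0).astype(np.float64), 0.0, 1.0)


# ---------------------------------------------------------------------------
# similarity metrics

def flatten_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of channel-concatenated pixel vectors."""
    x = as_float_image(a).ravel()
    y = as_float_image(b).ravel()
    if x.shape != y.shape:
        raise ValueError("image shapes differ")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.sqrt(xc @ xc), np.sqrt(yc @ yc)
    if nx < 1e-12 or ny < 1e-12:
        raise ValueError("zero-variance image in Pearson comparison")
    return float((xc @ yc) / (nx * ny))


_SSIM_TRUNCATE = (11 - 1) / 2 / 1.5  # 11-tap Gaussian window at sigma 1.5


def _ssim_plane(x: np.ndarray, y: np.ndarray, sigma: float,
                c1: float, c2: float) -> float:
    f = dict(sigma=sigma, truncate=_SSIM_TRUNCATE, mode="reflect")
    mx = gaussian_filter(x, **f)
    my = gaussian_filter(y, **f)
    mxx = gaussian_filter(x * x, **f)
    myy = gaussian_filter(y * y, **f)
    mxy = gaussian_filter(x * y, **f)
    vx = mxx - mx * mx
    vy = myy - my * my
    cxy = mxy - mx * my
    s = ((2 * mx * my + c1) * (2 * cxy + c2)) / \
        ((mx * mx + my * my + c1) * (vx + vy + c2))
    pad = int(_SSIM_TRUNCATE * sigma + 0.5)  # ignore filter-edge artifacts
    return float(s[pad:-pad, pad:-pad].mean())


def ssim_rgb(a: np.ndarray, b: np.ndarray, data_range: float = 1.0,
             sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Structural similarity per RGB channel, averaged over channels.

    Gaussian-weighted 11 x 11 local statistics with the standard
    constants C1 = (k1 L)^2, C2 = (k2 L)^2 (Wang et al.).
    """
    x = as_float_image(a)
    y = as_float_image(b)
    if x.shape != y.shape:
        raise ValueError("image shapes differ")
    if min(x.shape[0], x.shape[1]) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    return float(np.mean([_ssim_plane(x[..., c], y[..., c], sigma, c1, c2)
                          for c in range(3)]))


_METRICS = {"pearson": flatten_pearson, "ssim": ssim_rgb}


# ---------------------------------------------------------------------------
# pairwise identification

@dataclass
class ComparisonTrial:
    recon_id: str
    true_id: str
    lure_id: str

    def __post_init__(self):
        if self.lure_id == self.true_id:
            raise ValueError("lure must differ from the true stimulus")


@dataclass
class AccuracyReport:
    per_recon: dict            # recon_id -> percent correct
    mean: float                # percent
    ci95: tuple                # (lo, hi) percent
    n_samples: int
    metric: str
    n_trials: int
    n_correct: float           # ties counted 0.5


@dataclass
class RVResult:
    rv: float
    null_distribution: np.ndarray
    p_value: float


def enumerate_trials(recons: dict, trues: dict, attrs: dict | None = None,
                     restrict: str | None = None):
    """All pairwise trials: each reconstruction vs every eligible lure.

    With ``restrict="shape"`` lures share the reconstruction's
    ``color_id`` and differ in ``shape_id`` (shape identification at
    fixed color); ``restrict="color"`` is the converse.  Reconstructions
    with no eligible lure are excluded.
    """
    if set(recons) != set(trues):
        raise ValueError("reconstruction and stimulus id sets differ")
    ids = sorted(recons)
    trials = []
    for rid in ids:
        for lid in ids:
            if lid == rid:
                continue
            if restrict is not None:
                a, b = attrs[rid], attrs[lid]
                if restrict == "shape":
                    if a["color_id"] != b["color_id"] or a["shape_id"] == b["shape_id"]:
                        continue
                elif restrict == "color":
                    if a["shape_id"] != b["shape_id"] or a["color_id"] == b["color_id"]:
                        continue
                else:
                    raise ValueError(f"unknown restriction {restrict!r}")
            trials.append(ComparisonTrial(rid, rid, lid))
    return trials


def subsample_trials(trials, per_image: int, seed: int = 0):
    """Seeded selection of ``per_image`` lures per reconstruction.

    The same seed yields the same selection, so conditions compared in
    the size sweep share identical trial sets (e.g. 50 test images x 10
    lures = 500 fixed trials).
    """
    by_recon = {}
    for t in trials:
        by_recon.setdefault(t.recon_id, []).append(t)
    rng = np.random.default_rng(seed)
    out = []
    for rid in sorted(by_recon):
        pool = by_recon[rid]
        if per_image > len(pool):
            raise ValueError(
                f"per_image={per_image} exceeds the {len(pool)} available "
                f"lures for {rid!r}")
        pick = rng.choice(len(pool), size=per_image, replace=False)
        out.extend(pool[i] for i in sorted(pick))
    return out


def score_trials(trials, recons: dict, trues: dict,
                 metric: str = "pearson") -> AccuracyReport:
    """Select the candidate more similar to the reconstruction per trial.

    Ties earn 0.5 credit.  Per-reconstruction accuracy is the percent of
    its trials selecting the true stimulus; the mean accuracy carries a
    normal-approximation 95% CI across reconstructions.
    """
    if not trials:
        raise ValueError("no trials to score")
    mfun = _METRICS[metric]
    sim_cache = {}

    def sim(rid, cid):
        key = (rid, cid)
        if key not in sim_cache:
            sim_cache[key] = mfun(recons[rid], trues[cid])
        return sim_cache[key]

    credit = {}
    total_correct = 0.0
    n_used = 0
    for t in trials:
        try:
            st = sim(t.recon_id, t.true_id)
            sl = sim(t.recon_id, t.lure_id)
        except ValueError:
            continue  # degenerate image; trial dropped
        c = 1.0 if st > sl else (0.5 if st == sl else 0.0)
        credit.setdefault(t.recon_id, []).append(c)
        total_correct += c
        n_used += 1
    if n_used == 0:
        raise ValueError("all trials failed the similarity metric")
    per = {rid: 100.0 * float(np.mean(cs)) for rid, cs in credit.items()}
    accs = np.array(list(per.values()))
    mean = float(accs.mean())
    se = float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
    return AccuracyReport(per_recon=per, mean=mean,
                          ci95=(mean - 1.96 * se, mean + 1.96 * se),
                          n_samples=len(accs), metric=metric,
                          n_trials=n_used, n_correct=total_correct)


# ---------------------------------------------------------------------------
# modified RV coefficient

def _rv_cross_products(m: np.ndarray) -> np.ndarray:
    mc = m - m.mean(axis=0, keepdims=True)
    s = mc @ mc.T
    np.fill_diagonal(s, 0.0)
    return s


def modified_rv(x: np.ndarray, y: np.ndarray) -> float:
    """Modified RV coefficient (Smilde et al.) between two n x p matrices.

    Columns are mean-centered; the diagonals of the n x n cross-product
    matrices are zeroed before taking their matrix correlation, removing
    the self-similarity inflation of the plain RV coefficient.  Rows are
    test samples, columns pixels.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape[0] != y.shape[0]:
        raise ValueError("row (sample) counts differ")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    sx = _rv_cross_products(x)
    sy = _rv_cross_products(y)
    nx = np.linalg.norm(sx)
    ny = np.linalg.norm(sy)
    if nx == 0 or ny == 0:
        raise ValueError("degenerate (all-zero) cross-product matrix")
    return float(np.sum(sx * sy) / (nx * ny))


def rv_permutation_test(x: np.ndarray, y: np.ndarray, n_perm: int = 999,
                        seed: int = 0) -> RVResult:
    """Permutation baseline: RV over row-shuffled x vs fixed y.

    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rv = modified_rv(x, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = modified_rv(x[rng.permutation(x.shape[0])], y)
    p = (1.0 + np.sum(null >= rv)) / (1.0 + n_perm)
    return RVResult(rv=rv, null_distribution=null, p_value=float(p))


# ---------------------------------------------------------------------------
# winning percentage (ablation comparisons)

def winning_percentage(a_wins) -> tuple:
    """Percent of trials each condition wins; ties split 50/50.

    ``a_wins`` holds per-trial outcomes: 1.0 (A wins), 0.0 (B wins) or
    0.5 (tie).  Returns ``(percent_a, percent_b)`` summing to 100.
    """
    a = np.asarray(list(a_wins), dtype=np.float64)
    if a.size == 0:
        raise ValueError("no trials")
    pa = 100.0 * a.mean()
    return (float(pa), float(100.0 - pa))


def ablation_winning_percentages(recons_by_condition: dict, trues: dict,
                                 metric: str = "pearson") -> dict:
    """All pairwise condition comparisons (6 pairs for 4 conditions).

    For each stimulus, the condition whose reconstruction is more
    similar to the true image (by the metric) wins the trial.
    """
    mfun = _METRICS[metric]
    sims = {cond: {sid: mfun(r[sid], trues[sid]) for sid in trues}
            for cond, r in recons_by_condition.items()}
    out = {}
    for ca, cb in itertools.combinations(sorted(recons_by_condition), 2):
        wins = []
        for sid in sorted(trues):
            da, db = sims[ca][sid], sims[cb][sid]
            wins.append(1.0 if da > db else (0.5 if da == db else 0.0))
        out[(ca, cb)] = winning_percentage(wins)
    return out
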