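"""Paired (image, voxel-vector) dataset container, persistence, integrity.

On disk a split is one HDF5 file (voxel matrix plus per-sample metadata
and JSON-encoded stimulus attributes) with a sibling ``<stem>_images/``
directory of 8-bit PNGs keyed by stimulus id, keeping stimuli
human-inspectable.  Sample order is the stored order; shuffling belongs
to the (seeded) trainer.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field

import h5py
import numpy as np

from .images import load_png, save_png

__all__ = [
    "StimulusRecord", "PairedDataset", "IntegrityReport",
    "save_dataset", "load_dataset",
    "make_training_pairs", "subset_by_size", "check_integrity",
]

_ID_RE = re.compile(r"^[A-Za-z0-9_\-.]+$")


@dataclass
class StimulusRecord:
    stimulus_id: str
    image: np.ndarray
    category_id: str
    attrs: dict = field(default_factory=dict)  # e.g. color_id / shape_id


@dataclass
class PairedDataset:
    """Aligned samples: one row of ``voxels`` per (stimulus, presentation)."""
    voxels: np.ndarray                 # (n_samples, D)
    stimulus_ids: list                 # len n_samples
    trial_indices: np.ndarray          # (n_samples,)
    images: dict                       # stimulus_id -> (h, w, 3) float image
    categories: dict                   # stimulus_id -> category_id
    stim_attrs: dict = field(default_factory=dict)
    split: str = "train"               # {"train", "test"}
    stimulus_type: str = "natural"     # {"natural", "shapes", "letters"}

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.trial_indices = np.asarray(self.trial_indices, dtype=np.int64)
        n = self.voxels.shape[0]
        if len(self.stimulus_ids) != n or self.trial_indices.shape[0] != n:
            raise ValueError("sample metadata length mismatch")
        keys = list(zip(self.stimulus_ids, self.trial_indices.tolist()))
        if len(set(keys)) != n:
            raise ValueError("(stimulus_id, trial_index) keys are not unique")
        missing = [s for s in set(self.stimulus_ids) if s not in self.images]
        if missing:
            raise ValueError(f"stimulus ids without an image: {sorted(missing)[:10]}")
        for sid in self.images:
            if not _ID_RE.match(sid):
                raise ValueError(f"stimulus id {sid!r} is not filesystem-safe")

    @property
    def n_samples(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_dim(self) -> int:
        return self.voxels.shape[1]

    def unique_stimulus_ids(self):
        """Stimulus ids in stable first-appearance order."""
        seen, out = set(), []
        for s in self.stimulus_ids:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out

    def trials_for(self, stimulus_id: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.stimulus_ids) if s == stimulus_id]
        return self.voxels[idx]


def _images_dir(path: str) -> str:
    stem = path[:-3] if path.endswith(".h5") else path
    return stem + "_images"


def save_dataset(ds: PairedDataset, path: str) -> None:
    if not path.endswith(".h5"):
        path = path + ".h5"
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("voxels", data=ds.voxels)
        f.create_dataset("stimulus_ids",
                         data=np.array(ds.stimulus_ids, dtype=object),
                         dtype=h5py.string_dtype("utf-8"))
        f.create_dataset("trial_indices", data=ds.trial_indices)
        f.attrs["split"] = ds.split
        f.attrs["stimulus_type"] = ds.stimulus_type
        f.attrs["voxel_dim"] = ds.voxel_dim
        f.attrs["categories"] = json.dumps(ds.categories)
        f.attrs["stim_attrs"] = json.dumps(ds.stim_attrs)
        f.attrs["format_version"] = 1
    img_dir = _images_dir(path)
    os.makedirs(img_dir, exist_ok=True)
    for sid, img in ds.images.items():
        save_png(img, os.path.join(img_dir, f"{sid}.png"))


def load_dataset(path: str) -> PairedDataset:
    if not path.endswith(".h5"):
        path = path + ".h5"
    with h5py.File(path, "r") as f:
        for name in ("voxels", "stimulus_ids", "trial_indices"):
            if name not in f:
                raise ValueError(f"malformed dataset container: missing dataset {name!r}")
        for attr in ("split", "stimulus_type", "voxel_dim", "categories"):
            if attr not in f.attrs:
                raise ValueError(f"malformed dataset container: missing attribute {attr!r}")
        voxels = f["voxels"][()]
        if voxels.ndim != 2 or voxels.shape[1] != int(f.attrs["voxel_dim"]):
            raise ValueError(
                f"voxel_dim header ({int(f.attrs['voxel_dim'])}) does not match "
                f"data shape {voxels.shape}")
        stimulus_ids = [s.decode() if isinstance(s, bytes) else str(s)
                        for s in f["stimulus_ids"][()]]
        trial_indices = f["trial_indices"][()]
        categories = json.loads(f.attrs["categories"])
        stim_attrs = json.loads(f.attrs.get("stim_attrs", "{}"))
        split = str(f.attrs["split"])
        stimulus_type = str(f.attrs["stimulus_type"])
    img_dir = _images_dir(path)
    images = {}
    for sid in set(stimulus_ids):
        p = os.path.join(img_dir, f"{sid}.png")
        if not os.path.exists(p):
            raise ValueError(f"malformed dataset container: missing image for {sid!r}")
        images[sid] = load_png(p)
    return PairedDataset(voxels, stimulus_ids, trial_indices, images,
                         categories, stim_attrs, split, stimulus_type)


def make_training_pairs(records, trials, split="train",
                        stimulus_type="natural") -> PairedDataset:
    """Expand per-stimulus trial lists: one sample per presentation.

    ``trials`` maps stimulus_id -> (n_trials, D) array.  With 1,200
    stimuli x 5 presentations this yields the full 6,000-sample
    training set.
    """
    voxels, sids, tidx = [], [], []
    images, categories, stim_attrs = {}, {}, {}
    for rec in records:
        tr = np.atleast_2d(np.asarray(trials[rec.stimulus_id]))
        if tr.shape[0] == 0:
            raise ValueError(f"stimulus {rec.stimulus_id!r} has no trials")
        for j in range(tr.shape[0]):
            voxels.append(tr[j])
            sids.append(rec.stimulus_id)
            tidx.append(j)
        images[rec.stimulus_id] = rec.image
        categories[rec.stimulus_id] = rec.category_id
        if rec.attrs:
            stim_attrs[rec.stimulus_id] = dict(rec.attrs)
    return PairedDataset(np.asarray(voxels), sids, np.asarray(tidx),
                         images, categories, stim_attrs, split, stimulus_type)


def subset_by_size(ds: PairedDataset, m: int) -> PairedDataset:
    """First ``m / trials_per_image`` stimuli (stable order), all trials.

    Subsets are nested by construction: subset(m1) is contained in
    subset(m2) whenever m1 <= m2.
    """
    order = ds.unique_stimulus_ids()
    per = ds.n_samples // len(order)
    if per * len(order) != ds.n_samples:
        raise ValueError("subset_by_size requires a uniform trial count per stimulus")
    if m % per != 0:
        raise ValueError(f"m={m} is not divisible by trials-per-image ({per})")
    if m > ds.n_samples:
        raise ValueError(f"m={m} exceeds dataset size {ds.n_samples}")
    keep = set(order[:m // per])
    idx = [i for i, s in enumerate(ds.stimulus_ids) if s in keep]
    return PairedDataset(
        ds.voxels[idx], [ds.stimulus_ids[i] for i in idx],
        ds.trial_indices[idx],
        {s: ds.images[s] for s in keep},
        {s: ds.categories[s] for s in keep},
        {s: v for s, v in ds.stim_attrs.items() if s in keep},
        ds.split, ds.stimulus_type)


@dataclass
class IntegrityReport:
    passed: bool
    violations: list

    def __bool__(self):
        return self.passed


def check_integrity(train: PairedDataset, test: PairedDataset) -> IntegrityReport:
    """Cross-split checks: disjoint categories, consistent D, unique keys."""
    violations = []
    shared = set(train.categories.values()) & set(test.categories.values())
    if shared:
        violations.append(f"categories shared across splits: {sorted(shared)}")
    if train.voxel_dim != test.voxel_dim:
        violations.append(
            f"voxel dimension mismatch: train D={train.voxel_dim}, "
            f"test D={test.voxel_dim}")
    for name, ds in (("train", train), ("test", test)):
        keys = list(zip(ds.stimulus_ids, ds.trial_indices.tolist()))
        if len(set(keys)) != len(keys):  # pragma: no cover - blocked by ctor
            violations.append(f"duplicate sample keys in {name} split")
    return IntegrityReport(passed=not violations, violations=violations)
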