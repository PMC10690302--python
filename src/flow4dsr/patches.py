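"""Patch extraction, augmentation and model-wise dataset splitting.

Training operates on co-registered patch pairs: a 12^3 low-resolution input
block (3 velocity components + magnitude) and the 24^3 noise-free
high-resolution target.  Patches are kept only if the HR reference contains
at least 5% non-stationary voxels (fluid voxels carrying flow), data are
augmented by rigid 90/180/270-degree rotations, and samples are partitioned
model-wise 6:2:2 so no phantom contributes to more than one split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .synthesis import VelocityVolume, make_pair

__all__ = [
    "PatchPair",
    "PatchDataset",
    "extract_patches",
    "augment_rotations",
    "split_by_model",
    "build_dataset",
    "nonstationary_fraction",
]

STATIONARY_SPEED_CMS = 1e-6  # below this a fluid voxel counts as stationary


@dataclass
class PatchPair:
    """Co-registered LR input / HR target blocks (HR = 2x LR per axis)."""

    lr_patch: np.ndarray  # (3, s, s, s) velocities, cm/s
    lr_mag: np.ndarray  # (s, s, s)
    hr_patch: np.ndarray  # (3, 2s, 2s, 2s) velocities, cm/s
    hr_mask: np.ndarray  # (2s, 2s, 2s) bool
    compartment: str
    sample_id: str
    frame: int
    venc_cms: float

    def __post_init__(self) -> None:
        s = self.lr_patch.shape[1:]
        if self.hr_patch.shape[1:] != tuple(2 * n for n in s):
            raise ValueError("HR block must be 2x the LR block per axis")


def nonstationary_fraction(hr_velocity, hr_mask) -> float:
    """Fraction of voxels that are fluid and carry non-negligible flow."""
    speed = np.sqrt((np.asarray(hr_velocity, dtype=np.float64) ** 2).sum(axis=0))
    return float((hr_mask & (speed > STATIONARY_SPEED_CMS)).mean())


def extract_patches(
    hr: VelocityVolume,
    lr: VelocityVolume,
    lr_patch_size: int = 12,
    min_nonstationary: float = 0.05,
    stride: int | None = None,
) -> list[PatchPair]:
    """Tile the LR grid and keep patches passing the 5% non-stationary rule.

    The filter is evaluated on the co-located noise-free HR reference, so it
    is independent of the LR noise realization.
    """
    if stride is None:
        stride = lr_patch_size
    s = lr_patch_size
    shape = lr.grid_shape
    if any(n < s for n in shape):
        warnings.warn("volume smaller than patch size; no patches extracted")
        return []
    out = []
    starts = [range(0, n - s + 1, stride) for n in shape]
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                hr_sl = (
                    slice(2 * i, 2 * i + 2 * s),
                    slice(2 * j, 2 * j + 2 * s),
                    slice(2 * k, 2 * k + 2 * s),
                )
                hr_vel = hr.velocity[(slice(None),) + hr_sl]
                hr_mask = hr.fluid_mask[hr_sl]
                if nonstationary_fraction(hr_vel, hr_mask) < min_nonstationary:
                    continue
                lr_sl = (
                    slice(i, i + s),
                    slice(j, j + s),
                    slice(k, k + s),
                )
                out.append(
                    PatchPair(
                        lr_patch=np.ascontiguousarray(
                            lr.velocity[(slice(None),) + lr_sl]
                        ),
                        lr_mag=np.ascontiguousarray(lr.magnitude[lr_sl]),
                        hr_patch=np.ascontiguousarray(hr_vel),
                        hr_mask=np.ascontiguousarray(hr_mask),
                        compartment=hr.compartment,
                        sample_id=hr.sample_id,
                        frame=hr.frame_index,
                        venc_cms=lr.venc_cms,
                    )
                )
    return out


_AXES_PLANES = {0: (1, 2), 1: (2, 0), 2: (0, 1)}  # rotation plane per axis


def _rotate_field(field: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Rotate the voxel lattice of a (...,x,y,z) array by k*90 deg."""
    a, b = _AXES_PLANES[axis]
    nd = field.ndim
    return np.rot90(field, k, axes=(nd - 3 + a, nd - 3 + b))


def _rotate_vectors(vec: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Apply the k*90-degree rotation matrix about ``axis`` to components."""
    a, b = _AXES_PLANES[axis]
    out = vec.copy()
    for _ in range(k % 4):
        va, vb = out[a].copy(), out[b].copy()
        out[a] = -vb
        out[b] = va
    return out


def rotate_patch(patch: PatchPair, k: int, axis: int = 2) -> PatchPair:
    """Rigid rotation of both lattice and velocity vectors by k*90 deg."""
    return replace(
        patch,
        lr_patch=np.ascontiguousarray(
            _rotate_vectors(_rotate_field(patch.lr_patch, k, axis), k, axis)
        ),
        lr_mag=np.ascontiguousarray(_rotate_field(patch.lr_mag, k, axis)),
        hr_patch=np.ascontiguousarray(
            _rotate_vectors(_rotate_field(patch.hr_patch, k, axis), k, axis)
        ),
        hr_mask=np.ascontiguousarray(_rotate_field(patch.hr_mask, k, axis)),
    )


def augment_rotations(patch: PatchPair, axis: int = 2) -> list[PatchPair]:
    """Identity plus 90/180/270-degree rotations about one axis.

    Both the voxel lattice and the velocity vectors rotate, so the speed
    field is preserved voxelwise and directional bias is avoided.
    """
    if len(set(patch.lr_mag.shape)) != 1:
        raise ValueError("rotation augmentation requires cubic patches")
    return [rotate_patch(patch, k, axis) for k in range(4)]


def split_by_model(
    samples_or_ids,
    ratios: tuple[int, int, int] = (6, 2, 2),
    seed: int = 0,
) -> tuple[set, set, set]:
    """Partition sample ids (not patches) into train/val/test per compartment.

    Accepts FlowSamples or ``(sample_id, compartment)`` tuples.  Largest-
    remainder allocation of the ratio within each compartment; with a single
    id in a compartment everything goes to train (with a warning).
    """
    items = []
    for s in samples_or_ids:
        if isinstance(s, tuple):
            items.append(s)
        else:
            items.append((s.sample_id, s.compartment))
    by_comp: dict[str, list[str]] = {}
    for sid, comp in items:
        by_comp.setdefault(comp, []).append(sid)
    rng = np.random.default_rng(seed)
    total = sum(ratios)
    train, val, test = set(), set(), set()
    for comp in sorted(by_comp):
        ids = sorted(set(by_comp[comp]))
        if len(ids) == 1:
            warnings.warn(
                f"single sample in compartment {comp!r}: assigned to train"
            )
            train.update(ids)
            continue
        rng.shuffle(ids)
        n = len(ids)
        exact = [n * r / total for r in ratios]
        counts = [int(np.floor(e)) for e in exact]
        remainders = [e - c for e, c in zip(exact, counts)]
        while sum(counts) < n:
            i = int(np.argmax(remainders))
            counts[i] += 1
            remainders[i] = -1
        if counts[0] == 0:  # training must not be empty
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[0] += 1
        train.update(ids[: counts[0]])
        val.update(ids[counts[0] : counts[0] + counts[1]])
        test.update(ids[counts[0] + counts[1] :])
    return train, val, test


class PatchDataset:
    """In-memory patch dataset with train/val/test splits.

    Thin container over stacked numpy arrays; persisted to HDF5 through
    :mod:`flow4dsr.io`.
    """

    SPLITS = ("train", "val", "test")

    def __init__(self) -> None:
        self.patches: dict[str, list[PatchPair]] = {s: [] for s in self.SPLITS}
        self.manifest: dict = {}

    def add(self, split: str, patches) -> None:
        self.patches[split].extend(patches)

    def counts(self) -> dict[str, dict[str, int]]:
        """Per-split, per-compartment patch counts."""
        out = {}
        for split in self.SPLITS:
            comp_counts: dict[str, int] = {}
            for p in self.patches[split]:
                comp_counts[p.compartment] = comp_counts.get(p.compartment, 0) + 1
            out[split] = comp_counts
        return out

    def n(self, split: str) -> int:
        return len(self.patches[split])

    def stacked(self, split: str):
        """Return (lr_input (N,4,s,s,s), hr_target (N,3,2s,..), hr_mask,
        venc (N,), compartments (N,)) with velocities normalized by VENC."""
        ps = self.patches[split]
        if not ps:
            raise ValueError(f"split {split!r} is empty")
        venc = np.array([p.venc_cms for p in ps])
        lr = np.stack(
            [
                np.concatenate(
                    [p.lr_patch / p.venc_cms, p.lr_mag[None]], axis=0
                )
                for p in ps
            ]
        ).astype(np.float32)
        hr = np.stack([p.hr_patch / p.venc_cms for p in ps]).astype(np.float32)
        mask = np.stack([p.hr_mask for p in ps])
        comps = np.array([p.compartment for p in ps])
        return lr, hr, mask, venc, comps


def build_dataset(
    samples,
    seed: int = 0,
    hr_spacing_mm: float | None = None,
    snr_db_range: tuple[float, float] = (12.0, 20.0),
    lr_patch_size: int = 12,
    min_nonstationary: float = 0.05,
    stride: int | None = None,
    ratios: tuple[int, int, int] = (6, 2, 2),
    augment: bool = True,
    path=None,
) -> PatchDataset:
    """End-to-end dataset builder: pairs -> filter -> split -> augment.

    Rotation augmentation (x4 about z) is applied to the training split
    only.  The SNR of each (sample, frame) pair is drawn uniformly from
    ``snr_db_range`` — heterogeneous noise as with frame-wise VENC
    adjustment.  A manifest with per-compartment counts is recorded; if
    ``path`` is given the dataset is written to HDF5.
    """
    rng = np.random.default_rng(seed)
    train_ids, val_ids, test_ids = split_by_model(samples, ratios, seed=seed)
    ds = PatchDataset()
    for sample in samples:
        if sample.sample_id in train_ids:
            split = "train"
        elif sample.sample_id in val_ids:
            split = "val"
        else:
            split = "test"
        for frame in range(sample.n_frames):
            if sample.max_speed(frame) <= 0:
                continue
            snr = float(rng.uniform(*snr_db_range))
            pair_seed = int(rng.integers(0, 2**31 - 1))
            hr, lr = make_pair(
                sample, frame, hr_spacing_mm, snr_db=snr, seed=pair_seed
            )
            patches = extract_patches(
                hr, lr, lr_patch_size, min_nonstationary, stride
            )
            if split == "train" and augment:
                patches = [
                    q for p in patches for q in augment_rotations(p, axis=2)
                ]
            ds.add(split, patches)
    ds.manifest = {
        "schema_version": "1",
        "counts": ds.counts(),
        "splits": {
            "train": sorted(train_ids),
            "val": sorted(val_ids),
            "test": sorted(test_ids),
        },
        "synthesis": {
            "snr_db_range": list(snr_db_range),
            "factor": 2,
            "venc_rule": "1.2x frame peak speed, rounded up to 10 cm/s",
            "lr_patch_size": lr_patch_size,
            "min_nonstationary": min_nonstationary,
            "augment": augment,
        },
        "seed": seed,
    }
    if path is not None:
        from .io import write_patch_dataset

        write_patch_dataset(ds, path)
        with open(str(path) + ".manifest.json", "w") as fh:
            json.dump(ds.manifest, fh, indent=2)
    return ds
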