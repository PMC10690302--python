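"""HDF5 / NIfTI persistence for volumes and patch datasets.

Conventions: axis order (x, y, z), 0-based voxel indices, voxel-center
sampling; velocities stored as float32 cm/s, masks as uint8; metric
computations run in float64 in memory.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .patches import PatchDataset, PatchPair
from .synthesis import VelocityVolume

SCHEMA_VERSION = "1"

__all__ = [
    "write_volume",
    "read_volume",
    "write_patch_dataset",
    "read_patch_dataset",
    "export_nifti",
    "import_nifti",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised when an HDF5 file does not match the expected layout."""


def write_volume(vol: VelocityVolume, path, group: str | None = None) -> None:
    """Write a VelocityVolume to HDF5 (datasets u/v/w/mag/mask + attrs)."""
    with h5py.File(path, "a") as fh:
        g = fh.require_group(group) if group else fh
        for key in ("u", "v", "w", "mag", "mask"):
            if key in g:
                del g[key]
        for key, arr in zip("uvw", vol.velocity):
            g.create_dataset(key, data=arr.astype(np.float32))
        g.create_dataset("mag", data=vol.magnitude.astype(np.float32))
        g.create_dataset("mask", data=vol.fluid_mask.astype(np.uint8))
        g.attrs["schema_version"] = SCHEMA_VERSION
        g.attrs["spacing_mm"] = vol.spacing_mm
        g.attrs["venc_cms"] = vol.venc_cms
        g.attrs["frame_index"] = vol.frame_index
        g.attrs["compartment"] = vol.compartment
        g.attrs["sample_id"] = vol.sample_id
        g.attrs["snr_db"] = np.nan if vol.snr_db is None else vol.snr_db


def read_volume(path, group: str | None = None) -> VelocityVolume:
    with h5py.File(path, "r") as fh:
        g = fh[group] if group else fh
        missing = [k for k in ("u", "v", "w", "mag", "mask") if k not in g]
        if missing or "schema_version" not in g.attrs:
            raise SchemaError(
                f"not a flow4dsr volume (schema v{SCHEMA_VERSION}); "
                f"missing {missing}"
            )
        vel = np.stack([g[k][...] for k in "uvw"])
        snr = float(g.attrs["snr_db"])
        return VelocityVolume(
            velocity=vel,
            magnitude=g["mag"][...],
            fluid_mask=g["mask"][...].astype(bool),
            spacing_mm=float(g.attrs["spacing_mm"]),
            venc_cms=float(g.attrs["venc_cms"]),
            frame_index=int(g.attrs["frame_index"]),
            snr_db=None if np.isnan(snr) else snr,
            compartment=str(g.attrs["compartment"]),
            sample_id=str(g.attrs["sample_id"]),
        )


_PATCH_KEYS = ("lr_u", "lr_v", "lr_w", "lr_mag",
               "hr_u", "hr_v", "hr_w", "hr_mask")


def write_patch_dataset(ds: PatchDataset, path) -> None:
    """Persist a PatchDataset: groups /train /val /test, one dataset per
    field (N x 12^3 LR, N x 24^3 HR), per-patch metadata arrays."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        for split in ds.SPLITS:
            g = fh.create_group(split)
            ps = ds.patches[split]
            if not ps:
                g.attrs["empty"] = True
                continue
            lr = np.stack([p.lr_patch for p in ps]).astype(np.float32)
            hr = np.stack([p.hr_patch for p in ps]).astype(np.float32)
            arrays = {
                "lr_u": lr[:, 0], "lr_v": lr[:, 1], "lr_w": lr[:, 2],
                "lr_mag": np.stack([p.lr_mag for p in ps]).astype(np.float32),
                "hr_u": hr[:, 0], "hr_v": hr[:, 1], "hr_w": hr[:, 2],
                "hr_mask": np.stack([p.hr_mask for p in ps]).astype(np.uint8),
            }
            for key, arr in arrays.items():
                g.create_dataset(key, data=arr)
            g.create_dataset(
                "compartment",
                data=np.array([p.compartment for p in ps], dtype="S16"),
            )
            g.create_dataset(
                "sample_id",
                data=np.array([p.sample_id for p in ps], dtype="S32"),
            )
            g.create_dataset("frame", data=np.array([p.frame for p in ps]))
            g.create_dataset(
                "venc_cms", data=np.array([p.venc_cms for p in ps])
            )


def read_patch_dataset(path) -> PatchDataset:
    ds = PatchDataset()
    with h5py.File(path, "r") as fh:
        if "schema_version" not in fh.attrs:
            raise SchemaError("missing schema_version attribute")
        for split in ds.SPLITS:
            if split not in fh:
                raise SchemaError(f"missing split group /{split}")
            g = fh[split]
            if g.attrs.get("empty", False):
                continue
            missing = [k for k in _PATCH_KEYS if k not in g]
            if missing:
                raise SchemaError(f"split /{split} missing datasets {missing}")
            n = g["lr_u"].shape[0]
            lr = np.stack([g[k][...] for k in ("lr_u", "lr_v", "lr_w")], axis=1)
            hr = np.stack([g[k][...] for k in ("hr_u", "hr_v", "hr_w")], axis=1)
            comps = [c.decode() for c in g["compartment"][...]]
            sids = [s.decode() for s in g["sample_id"][...]]
            for i in range(n):
                ds.patches[split].append(
                    PatchPair(
                        lr_patch=lr[i],
                        lr_mag=g["lr_mag"][i],
                        hr_patch=hr[i],
                        hr_mask=g["hr_mask"][i].astype(bool),
                        compartment=comps[i],
                        sample_id=sids[i],
                        frame=int(g["frame"][i]),
                        venc_cms=float(g["venc_cms"][i]),
                    )
                )
    return ds


def export_nifti(vol: VelocityVolume, path_prefix) -> list[Path]:
    """Write vx/vy/vz/mag as NIfTI-1 (spacing in the header, float32 cm/s)
    plus the fluid mask as a uint8 companion."""
    import nibabel as nib

    affine = np.diag([vol.spacing_mm, vol.spacing_mm, vol.spacing_mm, 1.0])
    prefix = Path(path_prefix)
    out = []
    fields = {
        "vx": vol.velocity[0], "vy": vol.velocity[1], "vz": vol.velocity[2],
        "mag": vol.magnitude,
    }
    for name, arr in fields.items():
        p = prefix.parent / f"{prefix.name}_{name}.nii"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), p)
        out.append(p)
    p = prefix.parent / f"{prefix.name}_mask.nii"
    nib.save(nib.Nifti1Image(vol.fluid_mask.astype(np.uint8), affine), p)
    out.append(p)
    return out


def import_nifti(path_prefix, venc_cms: float,
                 frame_index: int = 0) -> VelocityVolume:
    """Re-assemble a VelocityVolume from an :func:`export_nifti` file set."""
    import nibabel as nib

    prefix = Path(path_prefix)

    def load(name):
        img = nib.load(prefix.parent / f"{prefix.name}_{name}.nii")
        return np.asarray(img.dataobj), img

    vx, img = load("vx")
    vy, _ = load("vy")
    vz, _ = load("vz")
    mag, _ = load("mag")
    mask, _ = load("mask")
    spacing = float(img.header.get_zooms()[0])
    return VelocityVolume(
        velocity=np.stack([vx, vy, vz]).astype(np.float64),
        magnitude=mag.astype(np.float64),
        fluid_mask=mask.astype(bool),
        spacing_mm=spacing,
        venc_cms=venc_cms,
        frame_index=frame_index,
    )
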