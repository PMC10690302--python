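"""Synthetic phase-contrast MRI generation from velocity fields.

Velocity fields are encoded into per-component complex signals
(``s_c = magnitude * exp(i*pi*v_c/VENC)``), optionally corrupted by
zero-mean complex Gaussian noise, and downsampled by central k-space
cropping — producing paired noise-free high-resolution / noisy
low-resolution volumes at a 1:2 resolution factor, the training substrate
for the super-resolution networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "VelocityVolume",
    "ComplexImageSet",
    "voxelize",
    "encode_complex",
    "decode_velocity",
    "add_complex_noise",
    "kspace_downsample",
    "make_pair",
    "default_venc",
]

MAG_FLUID = 1.0
MAG_BACKGROUND = 0.05
MAG_THRESHOLD = 0.5  # fluid/background magnitude decision level


@dataclass
class VelocityVolume:
    """One time frame's voxelized velocity data plus MR metadata."""

    velocity: np.ndarray  # (3, nx, ny, nz), cm/s
    magnitude: np.ndarray  # (nx, ny, nz), arbitrary units, >= 0
    fluid_mask: np.ndarray  # (nx, ny, nz), bool
    spacing_mm: float
    venc_cms: float
    frame_index: int = 0
    snr_db: float | None = None  # None = noise-free
    compartment: str = "aortic"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity)
        self.magnitude = np.asarray(self.magnitude)
        self.fluid_mask = np.asarray(self.fluid_mask, dtype=bool)
        if self.velocity.shape[0] != 3:
            raise ValueError("velocity must have 3 components first")
        if self.velocity.shape[1:] != self.magnitude.shape:
            raise ValueError("velocity and magnitude grids differ")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if self.venc_cms <= 0:
            raise ValueError("VENC must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape

    def max_component_speed(self) -> float:
        return float(np.abs(self.velocity).max())


@dataclass
class ComplexImageSet:
    """Per-velocity-component complex volumes (the simulated MR signal)."""

    signals: np.ndarray  # (3, nx, ny, nz), complex
    venc_cms: float
    spacing_mm: float

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.complex128)
        if self.signals.shape[0] != 3:
            raise ValueError("expected 3 component signals")


def _resample(field: np.ndarray, out_shape, zoom: float) -> np.ndarray:
    """Linear voxel-center resampling onto a coarser grid.

    Output voxel i sits at source coordinate (i + 0.5)*zoom - 0.5.
    """
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * zoom - 0.5 for n in out_shape], indexing="ij"
    )
    return ndimage.map_coordinates(
        field, np.array(coords), order=1, mode="nearest"
    )


def voxelize(sample, frame: int, spacing_mm: float | None = None) -> VelocityVolume:
    """Sample one frame of a :class:`~flow4dsr.phantoms.FlowSample` onto a
    uniform image grid at ``spacing_mm`` (>= native; coarsening only).

    The magnitude image is generated from the fluid segmentation
    (``MAG_FLUID`` inside, ``MAG_BACKGROUND`` outside); velocities outside
    the resampled mask are zeroed.  Noise-free.
    """
    if spacing_mm is None:
        spacing_mm = sample.spacing_mm
    if spacing_mm < sample.spacing_mm - 1e-9:
        raise ValueError("target spacing finer than source grid")
    vel_src = sample.velocity[frame].astype(np.float64)
    if abs(spacing_mm - sample.spacing_mm) < 1e-9:
        mask = sample.fluid_mask.copy()
        vel = vel_src.copy()
    else:
        zoom = spacing_mm / sample.spacing_mm
        out_shape = tuple(
            max(int(np.floor(n / zoom)), 1) for n in sample.grid_shape
        )
        mask = _resample(sample.fluid_mask.astype(np.float64), out_shape, zoom) >= 0.5
        vel = np.stack([_resample(c, out_shape, zoom) for c in vel_src])
        vel *= mask  # keep the non-fluid region strictly stationary
    magnitude = np.where(mask, MAG_FLUID, MAG_BACKGROUND)
    return VelocityVolume(
        velocity=vel,
        magnitude=magnitude,
        fluid_mask=mask,
        spacing_mm=spacing_mm,
        venc_cms=max(default_venc(np.abs(vel).max()), 10.0),
        frame_index=frame,
        snr_db=None,
        compartment=sample.compartment,
        sample_id=sample.sample_id,
    )


def default_venc(max_speed_cms: float) -> float:
    """Frame-wise VENC rule: 1.2x the peak speed, rounded up to 10 cm/s.

    Keeps VENC above the maximum velocity (no aliasing) while varying it
    across the cardiac cycle, so the velocity-to-noise ratio varies between
    frames exactly as a clinical per-frame VENC adjustment would.
    """
    return float(np.ceil(1.2 * max_speed_cms / 10.0) * 10.0)


def encode_complex(vol: VelocityVolume) -> ComplexImageSet:
    """Phase-contrast encoding: ``s_c = magnitude * exp(i*pi*v_c/VENC)``."""
    if vol.max_component_speed() >= vol.venc_cms:
        raise ValueError("velocity exceeds VENC: encoding would alias")
    phase = np.pi * vol.velocity.astype(np.float64) / vol.venc_cms
    signals = vol.magnitude[None] * np.exp(1j * phase)
    return ComplexImageSet(signals, vol.venc_cms, vol.spacing_mm)


def decode_velocity(
    cset: ComplexImageSet,
    magnitude_threshold: float = MAG_THRESHOLD,
    frame_index: int = 0,
    snr_db: float | None = None,
    compartment: str = "aortic",
    sample_id: str = "",
) -> VelocityVolume:
    """Inverse of :func:`encode_complex`: ``v_c = VENC * arg(s_c) / pi``.

    The magnitude image is the component-mean ``|s_c|``; the fluid mask is a
    magnitude threshold (zero-signal voxels decode to zero velocity).
    """
    velocity = cset.venc_cms * np.angle(cset.signals) / np.pi
    magnitude = np.abs(cset.signals).mean(axis=0)
    mask = magnitude > magnitude_threshold
    return VelocityVolume(
        velocity=velocity,
        magnitude=magnitude,
        fluid_mask=mask,
        spacing_mm=cset.spacing_mm,
        venc_cms=cset.venc_cms,
        frame_index=frame_index,
        snr_db=snr_db,
        compartment=compartment,
        sample_id=sample_id,
    )


def add_complex_noise(
    cset: ComplexImageSet, snr_db: float | None, seed
) -> ComplexImageSet:
    """Add zero-mean Gaussian noise to real and imaginary channels.

    sigma is set from the requested SNR against the mean fluid-region
    magnitude: ``mean(|s| in fluid) / sigma = 10**(snr_db/20)``.  The fluid
    region is identified by magnitude thresholding.  ``snr_db=None`` is the
    noise-free identity.
    """
    if snr_db is None:
        return ComplexImageSet(
            cset.signals.copy(), cset.venc_cms, cset.spacing_mm
        )
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite (or None for noise-free)")
    mag = np.abs(cset.signals).mean(axis=0)
    fluid = mag > MAG_THRESHOLD
    ref = mag[fluid].mean() if fluid.any() else mag.mean()
    sigma = ref / 10 ** (snr_db / 20.0)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, cset.signals.shape) + 1j * rng.normal(
        0.0, sigma, cset.signals.shape
    )
    return ComplexImageSet(
        cset.signals + noise, cset.venc_cms, cset.spacing_mm
    )


def kspace_downsample(cset: ComplexImageSet, factor: int = 2) -> ComplexImageSet:
    """Lower resolution by central k-space cropping.

    Each component signal is Fourier transformed (zero frequency at the
    array center), the central ``(N/factor)`` block is retained per axis,
    and the result inverse transformed.  Amplitudes are rescaled by
    ``1/factor**3`` so a constant image maps to the same constant; output
    spacing is ``factor`` times the input spacing.  Odd dimensions are
    edge-padded (on the high side) to the next multiple of ``factor``.
    """
    signals = cset.signals
    shape = signals.shape[1:]
    pad = [(0, (-n) % factor) for n in shape]
    if any(p[1] for p in pad):
        signals = np.stack(
            [np.pad(s, pad, mode="edge") for s in signals]
        )
        shape = signals.shape[1:]
    out = []
    crop = tuple(
        slice(n // 2 - (n // factor) // 2, n // 2 + (n // factor + 1) // 2)
        for n in shape
    )
    for s in signals:
        k = np.fft.fftshift(np.fft.fftn(s))
        k_lo = k[crop]
        out.append(np.fft.ifftn(np.fft.ifftshift(k_lo)) / factor**3)
    return ComplexImageSet(
        np.stack(out), cset.venc_cms, cset.spacing_mm * factor
    )


def _even_crop(vol: VelocityVolume) -> VelocityVolume:
    """Trim trailing slices so every dimension is even (clean 1:2 pairing)."""
    sl = tuple(slice(0, n - n % 2) for n in vol.grid_shape)
    if all(s.stop == n for s, n in zip(sl, vol.grid_shape)):
        return vol
    return replace(
        vol,
        velocity=vol.velocity[(slice(None),) + sl],
        magnitude=vol.magnitude[sl],
        fluid_mask=vol.fluid_mask[sl],
    )


def make_pair(
    sample,
    frame: int,
    hr_spacing_mm: float | None = None,
    venc_cms: float | None = None,
    snr_db: float | None = 15.0,
    seed=0,
) -> tuple[VelocityVolume, VelocityVolume]:
    """Build one HR/LR training pair for a frame of a flow sample.

    HR is the noise-free voxelized frame; LR is obtained by complex
    encoding, complex Gaussian noise, k-space truncation by 2, and phase
    decoding.  Returns ``(hr, lr)`` with ``lr.spacing == 2 * hr.spacing``.
    """
    hr = _even_crop(voxelize(sample, frame, hr_spacing_mm))
    max_speed = hr.max_component_speed()
    if venc_cms is None:
        venc_cms = max(default_venc(max_speed), 10.0)
    if venc_cms <= max_speed:
        raise ValueError("VENC must exceed the frame's maximum velocity")
    hr = replace(hr, venc_cms=venc_cms)
    cset = encode_complex(hr)
    cset = add_complex_noise(cset, snr_db, seed)
    cset = kspace_downsample(cset, factor=2)
    lr = decode_velocity(
        cset,
        frame_index=frame,
        snr_db=snr_db,
        compartment=sample.compartment,
        sample_id=sample.sample_id,
    )
    if any(2 * nl != nh for nl, nh in zip(lr.grid_shape, hr.grid_shape)):
        warnings.warn("LR grid is not exactly half the HR grid")
    return hr, lr
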