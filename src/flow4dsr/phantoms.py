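"""Analytic, time-resolved flow phantoms per cardiovascular compartment.

Each generator returns a :class:`FlowSample`: a velocity field (cm/s) on a
uniform isotropic grid over a cardiac-cycle's worth of time frames, plus a
static fluid mask.  The phantoms are closed-form laminar profiles with
flux-consistent rescaling — deterministic, desk-scale stand-ins for
patient-specific CFD, with deliberately disparate velocity scales across
compartments (slow small-calibre cerebrovascular flow up to fast aortic
jets, plus a two-lumen "dissection" geometry held out from training).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

COMPARTMENTS = ("cardiac", "aortic", "cerebro", "dissection")

__all__ = [
    "COMPARTMENTS",
    "FlowSample",
    "poiseuille_tube",
    "stenotic_tube",
    "cardiac_chamber",
    "dissection_tube",
    "apply_waveform",
    "compartment_suite",
    "systolic_waveform",
]


@dataclass
class FlowSample:
    """A time-resolved velocity field on a uniform grid: one 'model'.

    Attributes
    ----------
    velocity : ndarray, shape (n_frames, 3, nx, ny, nz), cm/s
        Cartesian velocity components per frame; zero outside ``fluid_mask``.
    fluid_mask : ndarray of bool, shape (nx, ny, nz)
        Static blood-pool mask (rigid vessel during synthesis).
    waveform : ndarray, shape (n_frames,)
        Dimensionless per-frame scale factors relative to the base field.
    """

    sample_id: str
    compartment: str
    spacing_mm: float
    velocity: np.ndarray
    fluid_mask: np.ndarray
    waveform: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.velocity.ndim == 4:  # single frame given as (3, nx, ny, nz)
            self.velocity = self.velocity[None]
        if self.waveform is None:
            self.waveform = np.ones(self.velocity.shape[0])
        self.velocity = np.asarray(self.velocity, dtype=np.float32)
        self.fluid_mask = np.asarray(self.fluid_mask, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        if self.velocity.shape[1] != 3:
            raise ValueError("velocity must have 3 components")
        if self.velocity.shape[2:] != self.fluid_mask.shape:
            raise ValueError("velocity grid and mask shape mismatch")
        if np.any(self.velocity[:, :, ~self.fluid_mask] != 0):
            raise ValueError("velocity must vanish outside the fluid mask")
        peak = float(np.abs(self.velocity).max())
        if not np.isfinite(peak) or peak <= 0:
            raise ValueError("max speed must be finite and positive")
        frac = self.fluid_mask.mean()
        if not (0.01 <= frac <= 0.60):
            raise ValueError(
                f"fluid mask covers {frac:.1%} of voxels; vessel-like "
                "geometry requires 1%-60%"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.fluid_mask.shape

    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    def max_speed(self, frame: int | None = None) -> float:
        """Peak speed (cm/s), overall or for one frame."""
        v = self.velocity if frame is None else self.velocity[frame]
        axis = 1 if frame is None else 0
        return float(np.sqrt((v.astype(np.float64) ** 2).sum(axis=axis)).max())


MIN_GRID = 24  # so LR halves still fit a 12^3 inference patch
MAX_GRID = 64  # desk-scale bound: full pipelines run on one CPU


def _tube_grid(radius_mm, length_mm, spacing_mm, axis, margin_vox=3):
    """Voxel-center coordinate grids for a tube along ``axis``."""
    r_vox = radius_mm / spacing_mm
    n_cross = max(int(np.ceil(2 * r_vox)) + 2 * margin_vox, MIN_GRID)
    n_axis = min(
        max(int(round(length_mm / spacing_mm)), MIN_GRID), MAX_GRID
    )
    shape = [n_cross, n_cross, n_cross]
    shape[axis] = n_axis
    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    cross_axes = [a for a in range(3) if a != axis]
    c0 = (shape[cross_axes[0]] - 1) / 2.0
    c1 = (shape[cross_axes[1]] - 1) / 2.0
    r = np.sqrt(
        (coords[cross_axes[0]] - c0) ** 2 + (coords[cross_axes[1]] - c1) ** 2
    ) * spacing_mm
    return tuple(shape), coords[axis], r


def poiseuille_tube(
    radius_mm: float,
    length_mm: float,
    peak_velocity_cms: float,
    spacing_mm: float,
    axis: int = 2,
    sample_id: str = "poiseuille",
    compartment: str = "aortic",
) -> FlowSample:
    """Straight rigid tube with a parabolic (Hagen–Poiseuille) axial profile.

    v(r) = v_peak * (1 - (r/R)^2) inside the lumen, zero outside (no slip).
    """
    if radius_mm < 2 * spacing_mm:
        raise ValueError(
            "under-resolved geometry: radius must be >= 2 * spacing"
        )
    if peak_velocity_cms <= 0:
        raise ValueError("peak velocity must be positive")
    shape, _, r = _tube_grid(radius_mm, length_mm, spacing_mm, axis)
    mask = r < radius_mm
    v_ax = np.where(mask, peak_velocity_cms * (1 - (r / radius_mm) ** 2), 0.0)
    vel = np.zeros((3,) + shape, dtype=np.float32)
    vel[axis] = v_ax
    return FlowSample(sample_id, compartment, spacing_mm, vel, mask)


def stenotic_tube(
    radius_mm: float,
    stenosis_fraction: float,
    peak_velocity_cms: float,
    spacing_mm: float,
    length_mm: float | None = None,
    axis: int = 2,
    sample_id: str = "stenotic",
    compartment: str = "aortic",
) -> FlowSample:
    """Tube with a smooth axisymmetric Gaussian narrowing (jet phantom).

    The lumen radius tapers to ``(1 - stenosis_fraction) * R`` at the throat.
    The axial parabolic profile is rescaled slice-by-slice so the discrete
    volumetric flux through every cross-section equals the inlet flux
    (continuity), which makes the throat velocity exceed the inlet peak.
    """
    if not 0 <= stenosis_fraction < 1:
        raise ValueError("stenosis_fraction must be in [0, 1)")
    if radius_mm * (1 - stenosis_fraction) < 2 * spacing_mm:
        raise ValueError(
            "under-resolved geometry: throat radius must be >= 2 * spacing"
        )
    if length_mm is None:
        length_mm = 8 * radius_mm
    shape, ax_idx, r = _tube_grid(radius_mm, length_mm, spacing_mm, axis)
    n_axis = shape[axis]
    z = ax_idx * spacing_mm
    z0 = (n_axis - 1) * spacing_mm / 2.0
    sigma = length_mm / 8.0
    r_local = radius_mm * (
        1 - stenosis_fraction * np.exp(-((z - z0) ** 2) / (2 * sigma**2))
    )
    mask = r < r_local
    v_ax = np.where(mask, peak_velocity_cms * (1 - (r / r_local) ** 2), 0.0)
    # enforce discrete continuity: scale each slice to the inlet flux
    other = tuple(a for a in range(3) if a != axis)
    flux = v_ax.sum(axis=other)
    inlet_flux = flux[0]
    scale = np.ones(n_axis)
    nonzero = flux > 0
    scale[nonzero] = inlet_flux / flux[nonzero]
    sl = [None, None, None]
    sl[axis] = slice(None)
    v_ax = v_ax * scale[tuple(sl)]
    vel = np.zeros((3,) + shape, dtype=np.float32)
    vel[axis] = v_ax
    return FlowSample(sample_id, compartment, spacing_mm, vel, mask)


def cardiac_chamber(
    radius_mm: float,
    peak_velocity_cms: float,
    spacing_mm: float,
    elongation: float = 1.4,
    sample_id: str = "chamber",
) -> FlowSample:
    """Ellipsoidal chamber with a smooth internal swirling flow.

    Emulates intracavitary (ventricle-like) flow: a solid-body-like rotation
    about the long axis, attenuated towards the wall so velocity vanishes at
    the boundary (no slip) and at the rotation axis.
    """
    if radius_mm < 2 * spacing_mm:
        raise ValueError(
            "under-resolved geometry: radius must be >= 2 * spacing"
        )
    rz = radius_mm * elongation
    n_xy = max(int(np.ceil(2 * radius_mm / spacing_mm)) + 6, MIN_GRID)
    n_z = min(
        max(int(np.ceil(2 * rz / spacing_mm)) + 6, MIN_GRID), MAX_GRID
    )
    shape = (n_xy, n_xy, n_z)
    x, y, z = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    cx, cy, cz = [(n - 1) / 2.0 for n in shape]
    xm = (x - cx) * spacing_mm
    ym = (y - cy) * spacing_mm
    zm = (z - cz) * spacing_mm
    rho2 = (xm / radius_mm) ** 2 + (ym / radius_mm) ** 2 + (zm / rz) ** 2
    mask = rho2 < 1.0
    # swirl about z: v = omega x r, shaped by (1 - rho^2) envelope
    envelope = np.where(mask, 1 - rho2, 0.0)
    r_xy = np.sqrt(xm**2 + ym**2)
    r_peak = radius_mm / np.sqrt(2)  # envelope*r maximum near here
    omega = peak_velocity_cms / r_peak / (1 - 0.5)  # normalize to peak speed
    vel = np.zeros((3,) + shape, dtype=np.float32)
    vel[0] = -omega * ym * envelope
    vel[1] = omega * xm * envelope
    # renormalize exactly to the requested peak speed
    speed = np.sqrt(vel[0] ** 2 + vel[1] ** 2)
    peak = speed.max()
    if peak > 0:
        vel *= peak_velocity_cms / peak
    return FlowSample(sample_id, "cardiac", spacing_mm, vel, mask)


def dissection_tube(
    radius_mm: float,
    peak_true_cms: float,
    peak_false_cms: float,
    spacing_mm: float,
    length_mm: float | None = None,
    septum_frac: float = 0.15,
    entry_mm: float | None = None,
    sample_id: str = "dissection",
) -> FlowSample:
    """Two-lumen tube: a septum splits the vessel into a fast "true" and a
    slow "false" lumen, joined at the entry and exit (tear) segments.

    The mid-vessel cross-section therefore has two disjoint lumens while the
    full 3D mask is a single connected component.
    """
    if radius_mm < 4 * spacing_mm:
        raise ValueError(
            "under-resolved geometry: radius must be >= 4 * spacing"
        )
    if length_mm is None:
        length_mm = 6 * radius_mm
    if entry_mm is None:
        entry_mm = length_mm / 6.0
    axis = 2
    shape, ax_idx, r = _tube_grid(radius_mm, length_mm, spacing_mm, axis)
    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    cx = (shape[0] - 1) / 2.0
    xm = (coords[0] - cx) * spacing_mm
    z_mm = ax_idx * spacing_mm
    tube = r < radius_mm
    septum_halfwidth = max(septum_frac * radius_mm, spacing_mm)
    in_septum = np.abs(xm) < septum_halfwidth
    mid = (z_mm > entry_mm) & (z_mm < length_mm - entry_mm)
    mask = tube & ~(in_septum & mid)
    # lumen-specific parabolic-ish axial flow, shaped by distance to mask edge
    dist = ndimage.distance_transform_edt(mask, sampling=spacing_mm)
    dmax = dist.max()
    profile = np.where(mask, dist / dmax, 0.0)
    peak_map = np.where(xm >= 0, peak_true_cms, peak_false_cms)
    v_ax = profile * (2 - profile) * peak_map  # parabolic in wall distance
    v_ax *= peak_true_cms / max(v_ax.max(), 1e-12)
    vel = np.zeros((3,) + shape, dtype=np.float32)
    vel[axis] = np.where(mask, v_ax, 0.0)
    return FlowSample(sample_id, "dissection", spacing_mm, vel, mask)


def systolic_waveform(n_frames: int, pulsatility: float = 0.6) -> np.ndarray:
    """Raised-cosine systolic pulse, peak 1 at the systolic frame.

    ``pulsatility`` sets the diastolic floor: waveform ranges in
    [1 - pulsatility, 1].
    """
    t = np.linspace(0, 1, n_frames, endpoint=False)
    pulse = 0.5 * (1 + np.cos(2 * np.pi * (t - 0.25)))
    w = (1 - pulsatility) + pulsatility * pulse
    return w / w.max()


def apply_waveform(sample: FlowSample, waveform: np.ndarray) -> FlowSample:
    """Scale the base (first-frame) field by a per-frame waveform."""
    waveform = np.asarray(waveform, dtype=np.float64)
    if np.any(waveform < 0):
        raise ValueError("waveform entries must be non-negative")
    base = sample.velocity[0]
    vel = (waveform[:, None, None, None, None] * base[None]).astype(np.float32)
    return FlowSample(
        sample.sample_id,
        sample.compartment,
        sample.spacing_mm,
        vel,
        sample.fluid_mask,
        waveform=waveform.copy(),
    )


_SUITE_DEFAULTS = {
    # (spacing_mm, radius range mm, peak range cm/s)
    "cerebro": dict(spacing=0.5, radius=(1.5, 3.0), peak=(20.0, 80.0)),
    "aortic": dict(spacing=1.25, radius=(8.0, 13.0), peak=(80.0, 250.0)),
    "cardiac": dict(spacing=1.25, radius=(14.0, 20.0), peak=(50.0, 150.0)),
    "dissection": dict(spacing=1.25, radius=(9.0, 12.0), peak=(100.0, 200.0)),
}


def compartment_suite(
    compartment: str,
    n_samples: int,
    seed: int,
    n_frames: int = 3,
) -> list[FlowSample]:
    """Seeded, parameter-randomized phantom suite for one compartment.

    Velocity scales differ by compartment (cerebrovascular slowest on small
    radii, aortic fastest including stenotic jets, cardiac intermediate in a
    chamber cavity, dissection = two-lumen tube).  Deterministic given
    ``(compartment, n_samples, seed)``.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"unknown compartment {compartment!r}")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = _SUITE_DEFAULTS[compartment]
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, COMPARTMENTS.index(compartment)])
    )
    samples = []
    for i in range(n_samples):
        radius = rng.uniform(*cfg["radius"])
        peak = rng.uniform(*cfg["peak"])
        sid = f"{compartment}-{i:02d}"
        if compartment == "cardiac":
            base = cardiac_chamber(radius, peak, cfg["spacing"], sample_id=sid)
        elif compartment == "dissection":
            base = dissection_tube(
                radius, peak, peak * rng.uniform(0.2, 0.4), cfg["spacing"],
                sample_id=sid,
            )
        else:
            length = radius * rng.uniform(6.0, 9.0)
            if compartment == "aortic" and i % 2 == 1:
                base = stenotic_tube(
                    radius, rng.uniform(0.3, 0.5), peak, cfg["spacing"],
                    length_mm=length, sample_id=sid, compartment=compartment,
                )
            else:
                base = poiseuille_tube(
                    radius, length, peak, cfg["spacing"],
                    sample_id=sid, compartment=compartment,
                )
        wave = systolic_waveform(n_frames, pulsatility=rng.uniform(0.4, 0.7))
        samples.append(apply_waveform(base, wave))
    return samples
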