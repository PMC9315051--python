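"""Transmit sensitivity maps, masks and off-resonance maps.

A :class:`TransmitSetup` bundles the per-channel complex transmit
sensitivities ``s_j(r)`` (uT/V), a boolean brain mask and an optional
off-resonance (dB0) map.  Setups are either loaded from NIfTI volumes or
produced by :func:`generate_synthetic_setup`, which emulates a head-sized
elliptical load inside a ring of circumferential transmit elements: each
element's field magnitude decays smoothly away from it and its phase
advances with propagation distance, with per-channel azimuthal phase
increments chosen so the circularly-polarized (CP) combination is
center-brightened — the qualitative structure a multi-channel head coil
presents to the optimizer at ultrahigh field.

Grids are indexed ``(y, x)`` for 2D slices and ``(z, y, x)`` for volumes;
axial slices are taken along the first axis of a volume.  Coordinates are
voxel-centered with the field of view centered on the grid midpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage


class SetupFormatError(ValueError):
    """Raised when input volumes are mutually inconsistent."""


class SetupValidationError(ValueError):
    """Raised when a setup violates a physical invariant (e.g. empty mask)."""


@dataclass
class GradientBlip:
    """An inter-sub-pulse gradient blip.

    ``phase_rolls`` gives the signed number of full 2*pi cycles of phase
    accrued across the field of view per spatial axis (ordered like the
    grid axes).  The roll is antisymmetric about the FOV center, so the
    phase at the center is zero.
    """

    duration_s: float = 100e-6
    phase_rolls: tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("blip duration must be >= 0")
        self.phase_rolls = tuple(float(c) for c in self.phase_rolls)


@dataclass
class TransmitSetup:
    """Per-channel complex transmit sensitivities plus mask and dB0 map.

    sensitivities : complex array, shape (n_channels, *grid_shape), uT/V
    mask          : bool array, shape grid_shape
    voxel_size_mm : mm per grid axis
    db0_hz        : off-resonance per voxel in Hz (defaults to zero)
    """

    sensitivities: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple[float, ...]
    db0_hz: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=complex)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.sensitivities.ndim != self.mask.ndim + 1:
            raise SetupValidationError(
                "sensitivities must have one leading channel axis over the mask grid"
            )
        if self.sensitivities.shape[1:] != self.mask.shape:
            raise SetupFormatError(
                f"channel maps {self.sensitivities.shape[1:]} do not match "
                f"mask grid {self.mask.shape}"
            )
        if self.n_channels < 1:
            raise SetupValidationError("need at least one transmit channel")
        if not self.mask.any():
            raise SetupValidationError("mask is empty")
        if len(self.voxel_size_mm) != self.mask.ndim:
            raise SetupValidationError("voxel_size_mm must give one size per grid axis")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise SetupValidationError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.sensitivities[:, self.mask])):
            raise SetupValidationError("non-finite sensitivity inside mask")
        if self.db0_hz is None:
            self.db0_hz = np.zeros(self.mask.shape)
        else:
            self.db0_hz = np.asarray(self.db0_hz, dtype=float)
            if self.db0_hz.shape != self.mask.shape:
                raise SetupFormatError("db0 map does not match the grid")

    @property
    def n_channels(self) -> int:
        return self.sensitivities.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.mask.shape

    @property
    def fov_mm(self) -> tuple[float, ...]:
        return tuple(n * v for n, v in zip(self.grid_shape, self.voxel_size_mm))

    def coordinates_mm(self) -> list[np.ndarray]:
        """Voxel-center coordinates per axis, in mm, zero at FOV center."""
        return [
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.grid_shape, self.voxel_size_mm)
        ]

    def axial_slice(self, index: int) -> "TransmitSetup":
        """Extract one axial (first-axis) slice of a 3D setup as a 2D setup."""
        if self.mask.ndim != 3:
            raise SetupValidationError("axial_slice requires a 3D setup")
        return TransmitSetup(
            sensitivities=self.sensitivities[:, index],
            mask=self.mask[index],
            voxel_size_mm=self.voxel_size_mm[1:],
            db0_hz=self.db0_hz[index],
            meta=dict(self.meta, slice_index=index),
        )


def _elliptical_mask(grid_shape, coords, semi_axes_mm) -> np.ndarray:
    grids = np.meshgrid(*coords, indexing="ij")
    q = sum((g / a) ** 2 for g, a in zip(grids, semi_axes_mm))
    return q <= 1.0


def generate_synthetic_setup(
    n_channels: int,
    grid_shape: Sequence[int],
    fov_mm: Sequence[float] | float,
    seed: int = 0,
    amp_ut_per_v: float = 0.22,
    decay_fraction: float = 0.75,
    phase_wavelength_mm: float = 250.0,
) -> TransmitSetup:
    """Generate a deterministic synthetic multi-channel transmit setup.

    Channels sit on a ring just outside an elliptical (2D) or ellipsoidal
    (3D) head-surrogate mask, in the last-two (in-plane) axes; for 3D the
    ring lies on the mid-volume plane so sensitivity falls off toward the
    superior/inferior slices.  Each channel's magnitude decays exponentially
    with distance from its element (decay length ``decay_fraction`` x head
    radius), its phase advances linearly with distance (2*pi per
    ``phase_wavelength_mm``, a wave-propagation surrogate), and channel j
    additionally carries the azimuthal phase increment +2*pi*(j-1)/Nch so
    the CP-mode combination adds coherently at the center.

    Small seeded jitters of element position and drive amplitude break the
    perfect ring symmetry; identical seeds give bit-identical setups.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if len(grid_shape) not in (2, 3):
        raise ValueError("grid must be 2D or 3D")
    if any(n <= 0 for n in grid_shape):
        raise ValueError("grid dimensions must be positive")
    if min(grid_shape[-2:]) < 8:
        raise ValueError("need at least 8 voxels per in-plane axis")
    if np.isscalar(fov_mm):
        fov_mm = (float(fov_mm),) * len(grid_shape)
    fov_mm = tuple(float(f) for f in fov_mm)
    if any(f <= 0 for f in fov_mm):
        raise ValueError("fov must be positive")

    voxel = tuple(f / n for f, n in zip(fov_mm, grid_shape))
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(grid_shape, voxel)
    ]
    # head surrogate: slightly anisotropic ellipse in-plane, tall in z
    semi = [0.42 * f for f in fov_mm[:-2]] + [0.36 * fov_mm[-2], 0.30 * fov_mm[-1]]
    mask = _elliptical_mask(grid_shape, coords, semi)
    head_radius = float(np.sqrt(semi[-1] * semi[-2]))
    ring_radius = 1.25 * max(semi[-2:])
    decay_len = decay_fraction * head_radius

    rng = np.random.default_rng(seed)
    angle_jitter = rng.uniform(-0.05, 0.05, n_channels)
    radius_jitter = rng.uniform(-0.03, 0.03, n_channels)
    amp_jitter = rng.uniform(-0.05, 0.05, n_channels)

    grids = np.meshgrid(*coords, indexing="ij")
    y, x = grids[-2], grids[-1]
    z = grids[0] if len(grid_shape) == 3 else None

    def _smooth_field(scale: float) -> np.ndarray:
        # sum of a few random long-wavelength cosines: smooth structure the
        # ring model alone would not have (dielectric/load effects surrogate)
        out = np.zeros(grid_shape)
        for _ in range(6):
            wl = rng.uniform(35.0, 140.0)  # mm
            direction = rng.uniform(0.0, 2.0 * np.pi)
            phase0 = rng.uniform(0.0, 2.0 * np.pi)
            proj = y * np.sin(direction) + x * np.cos(direction)
            if z is not None:
                proj = proj + z * rng.uniform(-0.5, 0.5)
            out += np.cos(2.0 * np.pi * proj / wl + phase0)
        return scale * out / 2.0

    # the head's dielectric loading modulates every channel's field through
    # the same spatial pattern; a shared complex ripple models that
    shared_ripple = (1.0 + _smooth_field(0.06)) * np.exp(1j * _smooth_field(0.3))

    sens = np.empty((n_channels,) + grid_shape, dtype=complex)
    for j in range(n_channels):
        theta = 2.0 * np.pi * j / n_channels + angle_jitter[j]
        r_el = ring_radius * (1.0 + radius_jitter[j])
        ey, ex = r_el * np.sin(theta), r_el * np.cos(theta)
        d2 = (y - ey) ** 2 + (x - ex) ** 2
        if z is not None:
            d2 = d2 + z**2  # elements on the mid-volume plane
        d = np.sqrt(d2)
        amp = amp_ut_per_v * (1.0 + amp_jitter[j])
        phase = -2.0 * np.pi * d / phase_wavelength_mm + 2.0 * np.pi * j / n_channels
        # small channel-specific ripple on top of the shared loading pattern
        own = (1.0 + _smooth_field(0.02)) * np.exp(1j * _smooth_field(0.05))
        sens[j] = amp * np.exp(-d / decay_len) * np.exp(1j * phase) * shared_ripple * own

    return TransmitSetup(
        sensitivities=sens,
        mask=mask,
        voxel_size_mm=voxel,
        meta={
            "generator": "synthetic_ring",
            "seed": int(seed),
            "amp_ut_per_v": amp_ut_per_v,
            "decay_fraction": decay_fraction,
            "phase_wavelength_mm": phase_wavelength_mm,
        },
    )


def cp_combination(setup: TransmitSetup) -> np.ndarray:
    """CP-mode combined field |sum_j s_j exp(-i 2*pi (j-1)/Nch)| in uT/V."""
    n = setup.n_channels
    phases = np.exp(-1j * 2.0 * np.pi * np.arange(n) / n)
    return np.abs(np.tensordot(phases, setup.sensitivities, axes=(0, 0)))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

_SIDECAR_DEFAULT = {
    "dialect": "real_imag",
    "magnitude_units": "uT_per_V",
    "phase_units": "rad",
}


def save_setup(setup: TransmitSetup, out_dir: str | Path) -> dict:
    """Write a setup to NIfTI volumes plus a sidecar JSON declaring units.

    Channel j is stored as ``channel{j:02d}_real.nii.gz`` and
    ``..._imag.nii.gz``; the mask and dB0 map get their own volumes.
    Returns the manifest (also written as ``setup.json``).
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # nibabel wants a 4x4 affine; embed voxel sizes on the diagonal
    aff4 = np.eye(4)
    for i, v in enumerate(setup.voxel_size_mm):
        aff4[i, i] = v
    channel_files = []
    for j in range(setup.n_channels):
        pair = []
        for part, arr in (
            ("real", setup.sensitivities[j].real),
            ("imag", setup.sensitivities[j].imag),
        ):
            fname = out_dir / f"channel{j:02d}_{part}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff4), fname)
            pair.append(fname.name)
        channel_files.append(pair)
    nib.save(
        nib.Nifti1Image(setup.mask.astype(np.uint8), aff4), out_dir / "mask.nii.gz"
    )
    nib.save(
        nib.Nifti1Image(np.asarray(setup.db0_hz, dtype=np.float64), aff4),
        out_dir / "db0.nii.gz",
    )
    manifest = dict(_SIDECAR_DEFAULT)
    manifest.update(
        {
            "n_channels": setup.n_channels,
            "voxel_size_mm": list(setup.voxel_size_mm),
            "channel_files": channel_files,
            "mask_file": "mask.nii.gz",
            "db0_file": "db0.nii.gz",
        }
    )
    (out_dir / "setup.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_setup(
    channel_map_files: Sequence[Sequence[str | Path]],
    mask_file: str | Path,
    db0_file: str | Path | None = None,
    dialect: str = "real_imag",
) -> TransmitSetup:
    """Load a setup from NIfTI volumes.

    ``channel_map_files`` is a sequence of (file_a, file_b) pairs per
    channel; with ``dialect='real_imag'`` these are real and imaginary
    parts, with ``dialect='mag_phase'`` magnitude (uT/V) and phase (rad).
    All volumes must share grid shape and affine.
    """
    import nibabel as nib

    if dialect not in ("real_imag", "mag_phase"):
        raise ValueError(f"unknown dialect {dialect!r}")
    mask_img = nib.load(str(mask_file))
    mask = np.asarray(mask_img.dataobj) > 0.5
    ref_shape, ref_affine = mask_img.shape, mask_img.affine

    def _load(path):
        img = nib.load(str(path))
        if img.shape != ref_shape:
            raise SetupFormatError(
                f"{path}: shape {img.shape} does not match mask {ref_shape}"
            )
        if not np.allclose(img.affine, ref_affine, atol=1e-6):
            raise SetupFormatError(f"{path}: affine does not match mask")
        return np.asarray(img.dataobj, dtype=np.float64)

    channels = []
    for pair in channel_map_files:
        a, b = (_load(p) for p in pair)
        if dialect == "real_imag":
            channels.append(a + 1j * b)
        else:
            channels.append(a * np.exp(1j * b))
    sens = np.stack(channels, axis=0)
    if mask.any() and np.isnan(sens[:, mask]).any():
        raise SetupValidationError("NaN sensitivity inside mask")
    db0 = _load(db0_file) if db0_file is not None else None
    voxel = tuple(float(abs(ref_affine[i, i])) for i in range(mask.ndim))
    return TransmitSetup(
        sensitivities=sens, mask=mask, voxel_size_mm=voxel, db0_hz=db0
    )


def load_setup_dir(setup_dir: str | Path) -> TransmitSetup:
    """Load a setup written by :func:`save_setup` from its manifest."""
    setup_dir = Path(setup_dir)
    manifest = json.loads((setup_dir / "setup.json").read_text())
    pairs = [
        [setup_dir / a, setup_dir / b] for a, b in manifest["channel_files"]
    ]
    return load_setup(
        pairs,
        setup_dir / manifest["mask_file"],
        setup_dir / manifest["db0_file"],
        dialect=manifest["dialect"],
    )


def erode_mask(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Per-axial-slice morphological erosion with a disk of radius_px.

    2D masks are eroded directly; for 3D masks each slice along the first
    axis is eroded independently (no erosion across slices).  Radius 0 is
    the identity.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius_px == 0:
        return mask.copy()
    yy, xx = np.ogrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    disk = yy**2 + xx**2 <= radius_px**2
    if mask.ndim == 2:
        return ndimage.binary_erosion(mask, structure=disk)
    out = np.zeros_like(mask)
    for k in range(mask.shape[0]):
        out[k] = ndimage.binary_erosion(mask[k], structure=disk)
    return out
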