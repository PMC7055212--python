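"""PET voxel-image handling and SUV/TNR quantification.

The standardized uptake value (SUV) normalizes a tissue activity
concentration to the administered activity per unit body mass,

    SUV = mu * W / (A_adm * exp(-0.693 * dt / T_half)),

with ``mu`` the mean activity concentration in the volume of interest
(kBq/mL), ``W`` the patient mass in grams (unit tissue density, 1 g/mL),
``A_adm`` the administered activity in kBq and the exponential correcting
for physical decay of the imaging tracer between injection and scan.
The tumor/non-tumor ratio (TNR) is the ratio of tumor SUV to the SUV of
the adjacent healthy tissue.

Lesion uptake is measured in an isocontour volume of interest (VOI): all
voxels, 26-connected to the lesion's local maximum, whose value is at
least a fixed fraction (default 50%) of that maximum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

GA68_HALF_LIFE_MIN = 67.71  # 68Ga physical half-life, minutes

# VOI volume band (mm^3) considered comparable across patients; outside it a
# warning (never an error) is emitted.
VOI_VOLUME_BAND_MM3 = (50.0, 200.0)


class ImageFormatError(ValueError):
    """Raised when a voxel image file cannot be interpreted as a 3D volume."""


class InvalidSpacingError(ValueError):
    """Raised when voxel spacing is zero or negative."""


class SeedOutOfBoundsError(IndexError):
    """Raised when a VOI seed index lies outside the image grid."""


@dataclass(frozen=True)
class VoxelImage:
    """3D scalar grid (SUV or activity concentration) with physical spacing.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz)
        Non-negative voxel values.
    spacing : tuple of float
        Voxel edge lengths in mm; all strictly positive.
    origin : tuple of float
        Physical coordinates (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ImageFormatError(
                f"expected 3D volume, got {values.ndim}D"
            )
        if any(s <= 0 for s in self.spacing):
            raise InvalidSpacingError(f"non-positive voxel spacing {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel, mm^3."""
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class AcquisitionMeta:
    """PET acquisition metadata entering the SUV formula.

    administered_activity : MBq, activity injected at t = 0
    patient_mass : kg
    scan_delay : minutes between injection and scan
    tracer_half_life : minutes (default: 68Ga)
    """

    administered_activity: float
    patient_mass: float
    scan_delay: float
    tracer_half_life: float = GA68_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.administered_activity <= 0:
            raise ValueError("administered activity must be positive")
        if self.patient_mass <= 0:
            raise ValueError("patient mass must be positive")
        if self.scan_delay < 0:
            raise ValueError("scan delay must be non-negative")
        if self.tracer_half_life <= 0:
            raise ValueError("tracer half-life must be positive")


@dataclass(frozen=True)
class VOI:
    """Volume of interest: a set of voxel indices with summary statistics."""

    voxel_indices: frozenset[tuple[int, int, int]]
    n_voxels: int
    volume: float  # mm^3
    mean_value: float
    rms_value: float  # population std of member voxels

    def __post_init__(self) -> None:
        if self.n_voxels != len(self.voxel_indices) or self.n_voxels < 1:
            raise ValueError("n_voxels must equal |voxel_indices| and be >= 1")
        if self.rms_value < 0:
            raise ValueError("rms must be non-negative")


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient uptake summary: one row of the cohort."""

    patient_id: str
    mass: float  # kg
    suv_tumor: float
    suv_tumor_err: float
    suv_healthy: float
    suv_healthy_err: float
    tnr: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.suv_tumor <= 0 or self.suv_healthy <= 0:
            raise ValueError("SUVs must be positive")
        if np.isnan(self.tnr):
            object.__setattr__(self, "tnr", self.suv_tumor / self.suv_healthy)
        elif not np.isclose(self.tnr, self.suv_tumor / self.suv_healthy, rtol=1e-6):
            raise ValueError("tnr inconsistent with suv_tumor/suv_healthy")


# ---------------------------------------------------------------------------
# Image I/O (NIfTI via nibabel)
# ---------------------------------------------------------------------------

def read_image(path) -> VoxelImage:
    """Load a NIfTI volume as a :class:`VoxelImage`.

    Voxel spacing is taken from the file geometry (header zooms). Raises
    ``FileNotFoundError`` for a missing file, :class:`ImageFormatError` for a
    non-3D volume and :class:`InvalidSpacingError` for degenerate spacing.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ImageFormatError(f"expected 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise InvalidSpacingError(f"non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return VoxelImage(values=data, spacing=tuple(float(z) for z in zooms),
                      origin=origin)


def write_image(image: VoxelImage, path) -> None:
    """Write a :class:`VoxelImage` to NIfTI, spacing encoded in the affine."""
    import nibabel as nib

    affine = np.diag(list(image.spacing) + [1.0])
    affine[:3, 3] = image.origin
    nib.save(nib.Nifti1Image(image.values.astype(np.float64), affine), str(path))


# ---------------------------------------------------------------------------
# Isocontour VOI segmentation
# ---------------------------------------------------------------------------

def _hill_climb(values: np.ndarray, seed: tuple[int, int, int]) -> tuple[int, int, int]:
    """Ascend from ``seed`` to a 26-connected local maximum (deterministic)."""
    current = tuple(int(i) for i in seed)
    shape = values.shape
    while True:
        lo = [max(c - 1, 0) for c in current]
        hi = [min(c + 2, s) for c, s in zip(current, shape)]
        block = values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        rel = np.unravel_index(int(np.argmax(block)), block.shape)
        nxt = tuple(l + r for l, r in zip(lo, rel))
        if values[nxt] <= values[current] or nxt == current:
            return current
        current = nxt


def isocontour_voi(image: VoxelImage, seed: tuple[int, int, int],
                   threshold_fraction: float = 0.5) -> VOI:
    """Threshold-isocontour segmentation around a lesion.

    Hill-climbs from ``seed`` to the lesion's local maximum, then takes the
    26-connected component of voxels whose value is at least
    ``threshold_fraction`` times that maximum. The local (not global) maximum
    is used, matching clinical isocontour tools. A warning is emitted when the
    resulting volume falls outside the comparability band
    ``VOI_VOLUME_BAND_MM3``.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    seed = tuple(int(i) for i in seed)
    if any(i < 0 or i >= s for i, s in zip(seed, image.shape)):
        raise SeedOutOfBoundsError(f"seed {seed} outside grid {image.shape}")

    peak = _hill_climb(image.values, seed)
    peak_value = image.values[peak]
    mask = image.values >= threshold_fraction * peak_value
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    component = labels == labels[peak]
    indices = frozenset(zip(*(ax.tolist() for ax in np.nonzero(component))))

    voi = _voi_from_indices(image, indices)
    lo, hi = VOI_VOLUME_BAND_MM3
    if not lo <= voi.volume <= hi:
        warnings.warn(
            f"VOI volume {voi.volume:.0f} mm^3 outside the [{lo:.0f}, {hi:.0f}] "
            "mm^3 comparability band", stacklevel=2)
    return voi


def _voi_from_indices(image: VoxelImage, indices) -> VOI:
    indices = frozenset(tuple(int(i) for i in idx) for idx in indices)
    if not indices:
        raise ValueError("empty VOI")
    vals = np.array([image.values[idx] for idx in sorted(indices)])
    return VOI(
        voxel_indices=indices,
        n_voxels=len(indices),
        volume=len(indices) * image.voxel_volume,
        mean_value=float(vals.mean()),
        rms_value=float(vals.std()),  # population std
    )


def manual_voi(image: VoxelImage, indices) -> VOI:
    """Build a VOI from an explicit voxel-index list (manually placed region).

    Entry point for background/healthy-tissue regions placed by hand rather
    than by isocontour.
    """
    for idx in indices:
        if any(i < 0 or i >= s for i, s in zip(idx, image.shape)):
            raise SeedOutOfBoundsError(f"index {tuple(idx)} outside grid")
    return _voi_from_indices(image, indices)


def voi_stats(image: VoxelImage, voi: VOI) -> tuple[float, float, int, float]:
    """Return (mean, rms, n_voxels, volume_mm3) of a VOI on an image.

    rms is the population standard deviation of the member voxel values.
    """
    if voi.n_voxels == 0:
        raise ValueError("empty VOI")
    for idx in voi.voxel_indices:
        if any(i < 0 or i >= s for i, s in zip(idx, image.shape)):
            raise SeedOutOfBoundsError(f"index {idx} outside grid")
    vals = np.array([image.values[idx] for idx in sorted(voi.voxel_indices)])
    return (float(vals.mean()), float(vals.std()), len(vals),
            len(vals) * image.voxel_volume)


# ---------------------------------------------------------------------------
# SUV / TNR
# ---------------------------------------------------------------------------

def compute_suv(mean_activity: float, meta: AcquisitionMeta) -> float:
    """SUV from a mean activity concentration (kBq/mL) and acquisition metadata.

    Decay-corrects the administered activity to scan time with the
    conventional factor exp(-0.693 * dt / T_half) and normalizes per gram of
    tissue at unit density, so the result is dimensionless.
    """
    if mean_activity < 0:
        raise ValueError("mean activity must be non-negative")
    decay = np.exp(-0.693 * meta.scan_delay / meta.tracer_half_life)
    mass_g = meta.patient_mass * 1000.0
    activity_kbq = meta.administered_activity * 1000.0
    return float(mean_activity * mass_g / (activity_kbq * decay))


def suv_error(rms: float, n_voxels: int) -> float:
    """Standard error of the mean SUV: rms / sqrt(N) over the VOI voxels."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if rms < 0:
        raise ValueError("rms must be non-negative")
    return rms / np.sqrt(n_voxels)


def compute_tnr(suv_tumor: float, suv_healthy: float,
                suv_tumor_err: float = 0.0,
                suv_healthy_err: float = 0.0) -> tuple[float, float]:
    """Tumor/non-tumor ratio with error propagated in quadrature.

    Returns ``(tnr, tnr_err)`` where the relative error of the ratio is the
    quadrature sum of the two relative SUV errors.
    """
    if suv_healthy <= 0:
        raise ValueError("healthy SUV must be positive")
    tnr = suv_tumor / suv_healthy
    rel = np.hypot(suv_tumor_err / suv_tumor if suv_tumor > 0 else 0.0,
                   suv_healthy_err / suv_healthy)
    return float(tnr), float(tnr * rel)


# ---------------------------------------------------------------------------
# VOI export
# ---------------------------------------------------------------------------

def export_voi(voi: VOI, csv_path, json_path=None) -> None:
    """Write VOI voxel indices to CSV and its stats block to JSON."""
    import pandas as pd

    idx = sorted(voi.voxel_indices)
    pd.DataFrame(idx, columns=["i", "j", "k"]).to_csv(csv_path, index=False)
    if json_path is not None:
        stats = {"n_voxels": voi.n_voxels, "volume_mm3": voi.volume,
                 "mean": voi.mean_value, "rms": voi.rms_value}
        with open(json_path, "w") as fh:
            json.dump(stats, fh, indent=2)
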