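"""Spherical ROI gray-matter volumetry on MNI-space images.

Turns per-participant 3D gray-matter maps into the participant x region
matrix of mean volumes the regression model consumes.  The measurement
pipeline per image is: Gaussian smoothing (default 5 mm FWHM) of the whole
map, then for each atlas region the arithmetic mean over the voxels whose
centers fall within a sphere (default 5 mm diameter) around the region's MNI
coordinate.  Columns are finally z-scored to zero mean and unit variance
(population convention, divide by n).

Voxel inclusion rule: a voxel belongs to a sphere iff the mm distance from
its center to the sphere center is <= diameter/2.  Smoothing is always
applied to the full image before masking, never after.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import Atlas

__all__ = [
    "FWHM_TO_SIGMA",
    "VolumeImage",
    "RegionVolumeMatrix",
    "ExtractionError",
    "gaussian_smooth",
    "sphere_mask",
    "extract_region_means",
    "zscore_columns",
    "extract_cohort",
]

logger = logging.getLogger(__name__)

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ExtractionError(ValueError):
    """Raised for geometric or numeric failures during ROI extraction."""


@dataclass
class VolumeImage:
    """A 3D scalar map plus its voxel-index -> MNI-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ExtractionError(
                f"image {self.participant_id!r}: expected 3D data, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ExtractionError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ExtractionError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ExtractionError(
                f"image {self.participant_id!r}: non-finite voxel values"
            )

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def from_nifti(cls, path: Union[str, Path], participant_id: str = "") -> "VolumeImage":
        img = nib.load(str(path))
        return cls(
            data=np.asarray(img.get_fdata(), dtype=float),
            affine=np.asarray(img.affine, dtype=float),
            participant_id=participant_id or Path(path).stem.replace(".nii", ""),
        )

    def to_nifti(self, path: Union[str, Path]) -> None:
        nib.save(nib.Nifti1Image(self.data, self.affine), str(path))


@dataclass
class RegionVolumeMatrix:
    """Participants x regions matrix of mean GM volume."""

    values: pd.DataFrame  # index participant_id, columns region names
    zscored: bool
    atlas_source: str

    def __post_init__(self) -> None:
        if self.zscored:
            col = self.values.to_numpy(dtype=float)
            if not (
                np.allclose(col.mean(axis=0), 0.0, atol=1e-8)
                and np.allclose(col.var(axis=0), 1.0, atol=1e-8)
            ):
                raise ExtractionError("zscored matrix violates mean-0/var-1 invariant")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.values.copy()
        out.insert(0, "participant_id", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: Union[str, Path], *, zscored: bool = False, atlas_source: str = ""
    ) -> "RegionVolumeMatrix":
        df = pd.read_csv(path)
        if "participant_id" not in df.columns:
            raise ExtractionError(f"{path}: missing participant_id column")
        df["participant_id"] = df["participant_id"].astype(str)
        df = df.set_index("participant_id")
        return cls(values=df.astype(float), zscored=zscored, atlas_source=atlas_source or str(path))


def gaussian_smooth(img: VolumeImage, fwhm_mm: float = 5.0) -> VolumeImage:
    """Convolve with a mass-normalized Gaussian of the given FWHM in mm.

    The per-axis kernel sigma is ``fwhm_mm * FWHM_TO_SIGMA / voxel_size``, so
    anisotropic grids are handled.  Boundary handling is zero-padding; the
    kernel is truncated at 6 sigma, keeping interior mass errors below 1e-8.
    """
    if fwhm_mm <= 0:
        raise ExtractionError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / img.voxel_sizes
    smoothed = ndimage.gaussian_filter(
        img.data, sigma=sigma_vox, mode="constant", cval=0.0, truncate=6.0
    )
    return VolumeImage(data=smoothed, affine=img.affine, participant_id=img.participant_id)


def sphere_mask(
    center_mni: Sequence[float],
    diameter_mm: float,
    img: VolumeImage,
    *,
    region_name: str = "",
    allow_clipped: bool = False,
) -> np.ndarray:
    """Boolean voxel mask of the sphere around an MNI coordinate.

    A voxel is included iff the mm distance between its center and
    ``center_mni`` is at most ``diameter_mm / 2``.  Raises when the sphere
    center falls outside the grid, when no voxel center is captured, or when
    the sphere is clipped by the grid boundary (unless ``allow_clipped``).
    """
    if diameter_mm <= 0:
        raise ExtractionError(f"diameter_mm must be positive, got {diameter_mm}")
    label = f" for region {region_name!r}" if region_name else ""
    center = np.asarray(center_mni, dtype=float)
    inv = np.linalg.inv(img.affine)
    center_vox = inv[:3, :3] @ center + inv[:3, 3]
    shape = np.array(img.data.shape)
    if np.any(center_vox < -0.5) or np.any(center_vox > shape - 0.5):
        raise ExtractionError(
            f"sphere center {tuple(center)} mm maps to voxel {tuple(center_vox.round(2))}, "
            f"outside grid of shape {tuple(shape)}{label}"
        )

    radius = diameter_mm / 2.0
    # bounding box in voxel space, padded by the radius along each axis
    pad = np.ceil(radius / img.voxel_sizes).astype(int) + 1
    lo = np.maximum(np.floor(center_vox).astype(int) - pad, 0)
    hi = np.minimum(np.floor(center_vox).astype(int) + pad + 1, shape)
    # sphere clipped iff its mm extent leaves the voxel-center hull of the grid
    reach = radius / img.voxel_sizes
    clipped = bool(np.any(center_vox - reach < 0) or np.any(center_vox + reach > shape - 1))

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    mm = vox @ img.affine[:3, :3].T + img.affine[:3, 3]
    inside = np.linalg.norm(mm - center, axis=1) <= radius + 1e-9

    mask = np.zeros(img.data.shape, dtype=bool)
    mask[ii.ravel()[inside], jj.ravel()[inside], kk.ravel()[inside]] = True
    if not mask.any():
        raise ExtractionError(
            f"sphere of diameter {diameter_mm} mm at {tuple(center)} captures no voxel center{label}"
        )
    if clipped and not allow_clipped:
        raise ExtractionError(
            f"sphere at {tuple(center)} is clipped by the grid boundary{label}; "
            "pass allow_clipped to average over in-grid voxels"
        )
    return mask


def extract_region_means(
    img: VolumeImage,
    atlas: Atlas,
    diameter_mm: float = 5.0,
    smooth_fwhm_mm: Optional[float] = 5.0,
    *,
    allow_clipped: bool = False,
) -> np.ndarray:
    """Mean (optionally smoothed) image value per atlas region, region_id order.

    ``smooth_fwhm_mm=None`` (or 0) disables smoothing.
    """
    work = img if not smooth_fwhm_mm else gaussian_smooth(img, smooth_fwhm_mm)
    means = np.empty(len(atlas), dtype=float)
    for i, region in enumerate(atlas):
        mask = sphere_mask(
            region.center_mni,
            diameter_mm,
            work,
            region_name=region.name,
            allow_clipped=allow_clipped,
        )
        vals = work.data[mask]
        if not np.all(np.isfinite(vals)):
            raise ExtractionError(
                f"NaN/Inf voxels inside sphere of region {region.name!r} "
                f"(participant {img.participant_id!r})"
            )
        means[i] = vals.mean()
    return means


def zscore_columns(m: np.ndarray) -> np.ndarray:
    """Center each column and scale to unit *population* variance (divide by n)."""
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    if m.shape[0] < 2:
        raise ExtractionError(f"need at least 2 rows to z-score, got {m.shape[0]}")
    sd = m.std(axis=0)  # population SD, ddof=0
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ExtractionError(f"zero-variance column(s) at index {zero.tolist()}")
    return (m - m.mean(axis=0)) / sd


def extract_cohort(
    image_paths: Sequence[Union[str, Path]],
    atlas: Atlas,
    diameter_mm: float = 5.0,
    smooth_fwhm_mm: Optional[float] = 5.0,
    *,
    allow_clipped: bool = False,
    participant_ids: Optional[Sequence[str]] = None,
) -> tuple[RegionVolumeMatrix, RegionVolumeMatrix]:
    """Batch driver: NIfTI files -> (raw, z-scored) region-volume matrices.

    Per-file failures are collected and reported together so one bad scan
    does not hide the rest.
    """
    if participant_ids is not None and len(participant_ids) != len(image_paths):
        raise ExtractionError("participant_ids length != number of images")
    rows, ids, failures = [], [], []
    for i, path in enumerate(image_paths):
        pid = participant_ids[i] if participant_ids is not None else ""
        try:
            img = VolumeImage.from_nifti(path, participant_id=pid)
            rows.append(
                extract_region_means(
                    img, atlas, diameter_mm, smooth_fwhm_mm, allow_clipped=allow_clipped
                )
            )
            ids.append(img.participant_id)
            logger.info("extracted %s (%d/%d)", img.participant_id, i + 1, len(image_paths))
        except Exception as exc:  # noqa: BLE001 - aggregate and re-raise below
            failures.append(f"{path}: {exc}")
    if failures:
        raise ExtractionError(
            "extraction failed for {} file(s):\n  {}".format(len(failures), "\n  ".join(failures))
        )
    raw = pd.DataFrame(np.array(rows), index=pd.Index(ids, name="participant_id"), columns=atlas.names)
    raw_m = RegionVolumeMatrix(values=raw, zscored=False, atlas_source=atlas.source)
    z = pd.DataFrame(zscore_columns(raw.to_numpy()), index=raw.index, columns=raw.columns)
    z_m = RegionVolumeMatrix(values=z, zscored=True, atlas_source=atlas.source)
    return raw_m, z_m
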