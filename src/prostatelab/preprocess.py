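"""Bring co-registered prostate volumes to the analysis grid and intensity scale.

All volumes in this package are indexed ``(z, y, x)`` with 0-based voxel
indices: ``z`` runs over axial slices (base first), ``y`` over image rows and
``x`` over image columns.  Laterality (which image side is the patient's left)
is a convention carried by the evaluation configuration, not by the arrays.

The analysis grid mirrors standard prostate-MRI pipelines: axial volumes are
cropped/resampled around the gland to a fixed in-plane matrix (default
224 x 224 at 0.29 mm x 0.29 mm) while slice spacing is left untouched
(3-4.2 mm scanner spacing).  Intensity normalization offers a plain masked
z-score and a Nyul-style decile-landmark standardization; both are
approximations of typical MRI standardization recipes and are selectable in
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

DEFAULT_PIXEL_MM = 0.29
DEFAULT_GRID_XY = 224

#: Percentile landmarks used by the "histogram" normalization method and the
#: matching template positions (percentiles of a standard normal).  Mapping a
#: volume's masked percentiles onto this template puts every cohort on a
#: common intensity scale before the final z-score.
LANDMARK_PERCENTILES = np.array([1.0, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99.0])
_NORMAL_TEMPLATE = np.array(
    [-2.3263, -1.2816, -0.8416, -0.5244, -0.2533, 0.0,
     0.2533, 0.5244, 0.8416, 1.2816, 2.3263]
)


@dataclass
class ImageVolume:
    """A 3D scalar grid with anisotropic voxel geometry.

    Parameters
    ----------
    data
        Array of shape ``(n_slices, ny, nx)``.
    pixel_size_mm
        In-plane pixel sizes ``(px, py)`` in millimetres.
    slice_spacing_mm
        Distance between consecutive axial slices in millimetres.
    origin
        Physical coordinate of voxel (0, 0, 0); informational only.
    """

    data: np.ndarray
    pixel_size_mm: tuple[float, float] = (DEFAULT_PIXEL_MM, DEFAULT_PIXEL_MM)
    slice_spacing_mm: float = 3.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got shape {self.data.shape}")
        px, py = self.pixel_size_mm
        if px <= 0 or py <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("voxel dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        px, py = self.pixel_size_mm
        return float(px * py * self.slice_spacing_mm)

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume with the same geometry and different data."""
        return replace(self, data=data)


def mask_volume_mm3(mask: np.ndarray, volume: ImageVolume) -> float:
    """Volume of a binary mask in mm^3 under the grid of ``volume``."""
    return float(np.count_nonzero(mask)) * volume.voxel_volume_mm3


def crop_resample(
    volume: ImageVolume,
    prostate_mask: np.ndarray,
    target_pixel_mm: float = DEFAULT_PIXEL_MM,
    target_xy: int = DEFAULT_GRID_XY,
    categorical: bool = False,
) -> ImageVolume:
    """Crop/resample in-plane around the prostate centroid.

    The output grid is ``target_xy x target_xy`` at ``target_pixel_mm``
    isotropic in-plane resolution, centred on the in-plane centroid of the
    prostate mask.  Slices are untouched.  Intensities are interpolated
    linearly; categorical volumes (masks, grade maps) use nearest-neighbour so
    the code set is preserved.

    Raises
    ------
    ValueError
        If the prostate extent exceeds the target field of view (the gland is
        never silently truncated) or the mask is empty.
    """
    mask = np.asarray(prostate_mask).astype(bool)
    if mask.shape != volume.shape:
        raise ValueError("mask and volume grids differ")
    if not mask.any():
        raise ValueError("prostate mask is empty; nothing to centre on")

    px, py = volume.pixel_size_mm
    zz, yy, xx = np.nonzero(mask)
    extent_y = (yy.max() - yy.min() + 1) * py
    extent_x = (xx.max() - xx.min() + 1) * px
    fov = target_xy * target_pixel_mm
    if extent_y > fov or extent_x > fov:
        raise ValueError(
            f"prostate extent ({extent_x:.1f} x {extent_y:.1f} mm) exceeds the "
            f"target field of view ({fov:.1f} mm); refusing to truncate the gland"
        )

    cy, cx = yy.mean(), xx.mean()
    # Source index of every target pixel: target grid centred on the centroid.
    off = (np.arange(target_xy) - (target_xy - 1) / 2.0) * target_pixel_mm
    src_y = cy + off / py
    src_x = cx + off / px
    gy, gx = np.meshgrid(src_y, src_x, indexing="ij")

    order = 0 if categorical else 1
    out = np.empty((volume.shape[0], target_xy, target_xy), dtype=volume.data.dtype
                   if categorical else np.float64)
    for z in range(volume.shape[0]):
        out[z] = ndimage.map_coordinates(
            volume.data[z], [gy, gx], order=order, mode="nearest"
        )
    return ImageVolume(
        data=out,
        pixel_size_mm=(target_pixel_mm, target_pixel_mm),
        slice_spacing_mm=volume.slice_spacing_mm,
        origin=volume.origin,
    )


def normalize_intensity(
    volume: ImageVolume,
    prostate_mask: np.ndarray,
    method: str = "zscore",
    template: np.ndarray | None = None,
) -> ImageVolume:
    """Normalize intensities using statistics computed inside the prostate.

    ``zscore`` subtracts the masked mean and divides by the masked standard
    deviation.  ``histogram`` first maps the masked percentile landmarks
    (:data:`LANDMARK_PERCENTILES`) piecewise-linearly onto a common template
    and then applies the masked z-score; this removes cohort-level intensity
    shifts that a plain z-score leaves in the distribution shape.
    """
    mask = np.asarray(prostate_mask).astype(bool)
    if mask.shape != volume.shape:
        raise ValueError("mask and volume grids differ")
    if not mask.any():
        raise ValueError("prostate mask is empty")
    data = volume.data.astype(np.float64)

    if method == "histogram":
        landmarks = np.percentile(data[mask], LANDMARK_PERCENTILES)
        tmpl = _NORMAL_TEMPLATE if template is None else np.asarray(template, float)
        if len(tmpl) != len(LANDMARK_PERCENTILES):
            raise ValueError("template must provide one value per landmark")
        if np.ptp(landmarks) == 0:
            raise ValueError("constant-intensity volume inside the mask")
        # np.interp needs strictly increasing xp; collapse duplicate landmarks.
        keep = np.concatenate([[True], np.diff(landmarks) > 0])
        data = np.interp(data, landmarks[keep], tmpl[keep])
        method = "zscore"

    if method != "zscore":
        raise ValueError(f"unknown normalization method: {method!r}")
    mu = data[mask].mean()
    sd = data[mask].std()
    if sd == 0:
        raise ValueError("constant-intensity volume inside the mask (zero variance)")
    return volume.like((data - mu) / sd)


def stack_adjacent_slices(volume: ImageVolume, k: int = 3) -> np.ndarray:
    """Per-slice stacks of ``k`` consecutive slices as channels.

    Returns an array of shape ``(n_slices, k, ny, nx)`` where sample ``i``
    holds slices ``i - k//2 .. i + k//2`` with edge slices replicated.  With
    ``k=3`` this is the 2.5D input convention (three consecutive slices per
    modality); ``k=1`` is plain per-slice 2D extraction.
    """
    if k % 2 != 1:
        raise ValueError("k must be odd")
    nz = volume.shape[0]
    if k > nz:
        raise ValueError(f"k={k} exceeds the {nz}-slice volume")
    half = k // 2
    idx = np.clip(np.arange(nz)[:, None] + np.arange(-half, half + 1)[None, :], 0, nz - 1)
    return volume.data[idx]  # (nz, k, ny, nx)
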