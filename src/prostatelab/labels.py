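"""Derivation of the four prostate-cancer labeling strategies.

Every label type annotates each prostate voxel as normal tissue, indolent
cancer (Gleason pattern 3) or aggressive cancer (Gleason pattern 4 and above).
Integer codes used throughout::

    0  outside the prostate
    1  normal tissue
    2  indolent cancer   (GP3)
    3  aggressive cancer (GP4+)

The four strategies:

``LRad``
    Pathology-confirmed radiologist outlines.  Each outlined 3D component is
    turned into a lesion and classed by the grade map inside the outline.
``LPath``
    Pathologist cancer outlines (no grade information), classed the same way.
``LLesionDPath``
    Lesion-level labels from the per-voxel grade map: cancer voxels are formed
    into lesions and each lesion is painted with a single class.
``LPixelDPath``
    Pixel-level labels from the grade map: same lesion footprints, but voxels
    within a kept lesion keep their own indolent/aggressive code, so mixed
    lesions stay mixed.

Lesion formation is morphological closing with a stacked-disk structuring
element followed by 3D connected-component analysis; lesion volume is
``LV = PSx * PSy * Dz * NL`` with ``NL`` counted on the closed mask; lesions
below 250 mm^3 are discarded as clinically insignificant (half the 500 mm^3
PI-RADS v2 significance threshold).

Lesions are classed with a 1 %-of-volume rule: at least 1 % aggressive voxels
makes a lesion aggressive; otherwise at least 1 % indolent voxels makes it
indolent; otherwise it is benign tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import ImageVolume

CODE_OUTSIDE = 0
CODE_NORMAL = 1
CODE_INDOLENT = 2
CODE_AGGRESSIVE = 3

LABEL_TYPES = ("LRad", "LPath", "LLesionDPath", "LPixelDPath")

MIN_LESION_VOLUME_MM3 = 250.0
CLASS_FRACTION_THRESHOLD = 0.01


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GradeMap:
    """Per-voxel categorical grade volume on an analysis grid."""

    codes: np.ndarray  # (z, y, x) integers in {0, 1, 2, 3}
    pixel_size_mm: tuple[float, float]
    slice_spacing_mm: float

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        bad = np.setdiff1d(np.unique(self.codes), [0, 1, 2, 3])
        if bad.size:
            raise ValueError(f"grade map contains invalid codes {bad.tolist()}")

    @property
    def cancer_mask(self) -> np.ndarray:
        return (self.codes == CODE_INDOLENT) | (self.codes == CODE_AGGRESSIVE)

    @property
    def voxel_volume_mm3(self) -> float:
        px, py = self.pixel_size_mm
        return float(px * py * self.slice_spacing_mm)


@dataclass
class Lesion:
    lesion_id: int
    voxels: np.ndarray          # (N, 3) integer (z, y, x) of the closed mask
    NL: int                     # voxel count on the closed mask
    volume_mm3: float
    n_aggressive: int = 0
    n_indolent: int = 0
    lesion_class: str | None = None  # "aggressive" | "indolent" | "benign"

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass
class LesionSet:
    kept: list[Lesion] = field(default_factory=list)
    discarded: list[Lesion] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self):
        return iter(self.kept)

    def __len__(self) -> int:
        return len(self.kept)

    @property
    def all_lesions(self) -> list[Lesion]:
        return list(self.kept) + list(self.discarded)

    def to_frame(self, case_id: str = "") -> pd.DataFrame:
        """Lesion table (Table-2-style statistics feedstock)."""
        rows = []
        for kept, lesions in ((True, self.kept), (False, self.discarded)):
            for les in lesions:
                rows.append(
                    dict(case_id=case_id, label_type=self.provenance,
                         lesion_id=les.lesion_id, NL=les.NL,
                         volume_mm3=les.volume_mm3,
                         n_aggressive=les.n_aggressive,
                         n_indolent=les.n_indolent,
                         lesion_class=les.lesion_class, kept=kept)
                )
        cols = ["case_id", "label_type", "lesion_id", "NL", "volume_mm3",
                "n_aggressive", "n_indolent", "lesion_class", "kept"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class LabelVolume:
    codes: np.ndarray
    label_type: str
    lesion_set: LesionSet
    pixel_size_mm: tuple[float, float] = (0.29, 0.29)
    slice_spacing_mm: float = 3.0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_structuring_element(pixel_size_mm: float,
                             disk_radii_mm: tuple[float, ...] = (0.5, 1.5, 0.5)
                             ) -> np.ndarray:
    """Stacked-disk 3D closing kernel.

    Three in-plane disks of radii 0.5, 1.5 and 0.5 mm stacked along Z (one
    slice each), converted to pixel radii by round-half-up with a minimum of
    one pixel.  At 0.29 mm pixels the radii are (2, 5, 2) pixels.  The kernel
    Z-extent is defined in slices, not millimetres, so it spans three adjacent
    slices at any slice spacing.
    """
    if pixel_size_mm <= 0:
        raise ValueError("pixel size must be positive")
    radii_px = [max(1, _round_half_up(r / pixel_size_mm)) for r in disk_radii_mm]
    rmax = max(radii_px)
    size = 2 * rmax + 1
    kernel = np.zeros((len(radii_px), size, size), dtype=bool)
    yy, xx = np.mgrid[-rmax:rmax + 1, -rmax:rmax + 1]
    for k, r in enumerate(radii_px):
        kernel[k] = (yy ** 2 + xx ** 2) <= r ** 2
    return kernel


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def binary_close(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Morphological closing with explicit padding (no border clipping)."""
    pads = [(s // 2 + 1,) * 2 for s in element.shape]
    padded = np.pad(mask.astype(bool), pads, mode="constant")
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=element),
        structure=element, border_value=0,
    )
    sl = tuple(slice(p[0], closed.shape[i] - p[1]) for i, p in enumerate(pads))
    return closed[sl]


def form_lesions(
    binary_mask: np.ndarray,
    pixel_size_mm: tuple[float, float],
    slice_spacing_mm: float,
    prostate_mask: np.ndarray | None = None,
    connectivity: int = 26,
    element: np.ndarray | None = None,
) -> LesionSet:
    """Form 3D lesions from a pixel-level annotation mask (pre-filter).

    Closing with the stacked-disk element bridges sub-kernel gaps so that a
    lesion annotated slightly discontinuously becomes one object; the closed
    mask is intersected back with the prostate, then 3D connected components
    (default 26-connectivity) become lesions.  ``NL`` and the lesion volume
    are counted on the closed mask.  An empty mask yields an empty set.
    """
    mask = np.asarray(binary_mask).astype(bool)
    if element is None:
        element = make_structuring_element(float(pixel_size_mm[0]))
    closed = binary_close(mask, element)
    if prostate_mask is not None:
        closed &= np.asarray(prostate_mask).astype(bool)
        # the original annotation is kept even where closing+masking would drop it
        closed |= mask & np.asarray(prostate_mask).astype(bool)
    labeled, n = ndimage.label(closed, structure=_connectivity_structure(connectivity))
    px, py = pixel_size_mm
    lesions = []
    for lid in range(1, n + 1):
        voxels = np.argwhere(labeled == lid)
        nl = len(voxels)
        lesions.append(
            Lesion(lesion_id=lid, voxels=voxels, NL=nl,
                   volume_mm3=lesion_volume(nl, px, py, slice_spacing_mm))
        )
    return LesionSet(kept=lesions, discarded=[], provenance="")


def lesion_volume(NL: int, PSx: float, PSy: float, Dz: float) -> float:
    """Lesion volume ``LV = PSx * PSy * Dz * NL`` in mm^3 (exact product)."""
    if PSx <= 0 or PSy <= 0 or Dz <= 0 or NL < 0:
        raise ValueError("voxel dimensions must be positive and NL >= 0")
    return PSx * PSy * Dz * NL


def filter_lesions(lesion_set: LesionSet,
                   min_volume: float = MIN_LESION_VOLUME_MM3) -> LesionSet:
    """Discard lesions with volume strictly below ``min_volume`` (250 mm^3).

    A lesion of exactly 250 mm^3 is kept ("less than 250" discards).  Both
    partitions are retained so discarded-lesion distributions can be reported.
    """
    lesions = lesion_set.all_lesions
    kept = [l for l in lesions if l.volume_mm3 >= min_volume]
    discarded = [l for l in lesions if l.volume_mm3 < min_volume]
    return LesionSet(kept=kept, discarded=discarded, provenance=lesion_set.provenance)


def classify_lesion(n_aggressive: int, n_indolent: int, NL: int,
                    threshold: float = CLASS_FRACTION_THRESHOLD) -> str:
    """Class of a lesion under the 1 % rule.

    At least ``threshold`` (default 1 %) aggressive voxels -> aggressive;
    otherwise at least 1 % indolent voxels -> indolent; otherwise benign.
    """
    if NL <= 0:
        raise ValueError("NL must be positive")
    if n_aggressive + n_indolent > NL:
        raise ValueError("grade counts exceed lesion size")
    if n_aggressive / NL >= threshold:
        return "aggressive"
    if n_indolent / NL >= threshold:
        return "indolent"
    return "benign"


def classify_from_grade_group(grade_group) -> str:
    """Map a targeted-biopsy Gleason grade group to a lesion class.

    Grade group >= 2 -> aggressive, grade group 1 -> indolent, benign biopsy
    -> normal tissue.
    """
    if grade_group in ("benign", None, 0):
        return "normal"
    if isinstance(grade_group, (int, np.integer)) and 1 <= grade_group <= 5:
        return "aggressive" if grade_group >= 2 else "indolent"
    raise ValueError(f"grade group must be 'benign' or 1..5, got {grade_group!r}")


_CLASS_CODE = {"aggressive": CODE_AGGRESSIVE, "indolent": CODE_INDOLENT,
               "benign": CODE_NORMAL, "normal": CODE_NORMAL}


def grade_lesions(lesion_set: LesionSet, grade_codes: np.ndarray,
                  threshold: float = CLASS_FRACTION_THRESHOLD) -> LesionSet:
    """Fill per-lesion grade counts and classes from a grade-code volume."""
    for les in lesion_set.all_lesions:
        codes = grade_codes[tuple(les.voxels.T)]
        les.n_aggressive = int(np.count_nonzero(codes == CODE_AGGRESSIVE))
        les.n_indolent = int(np.count_nonzero(codes == CODE_INDOLENT))
        les.lesion_class = classify_lesion(les.n_aggressive, les.n_indolent,
                                           les.NL, threshold)
    return lesion_set


# ---------------------------------------------------------------------------
# label strategies
# ---------------------------------------------------------------------------

def _majority_grade_fill(lesion: Lesion, grade_codes: np.ndarray,
                         element: np.ndarray) -> np.ndarray:
    """Per-voxel codes inside a lesion for the pixel-level strategy.

    Voxels carrying a cancer grade keep it; voxels added by closing take the
    majority cancer code among their in-kernel grade neighbours (ties go
    aggressive, matching the overlapping-patterns convention); voxels with no
    graded neighbour take the lesion-wide majority code.
    """
    shape = grade_codes.shape
    lesion_mask = lesion.mask(shape)
    out = np.full(shape, 0, dtype=np.int16)
    agg = (grade_codes == CODE_AGGRESSIVE)
    ind = (grade_codes == CODE_INDOLENT)
    out[lesion_mask & agg] = CODE_AGGRESSIVE
    out[lesion_mask & ind] = CODE_INDOLENT
    missing = lesion_mask & ~(agg | ind)
    if missing.any():
        kernel = element.astype(np.float32)
        n_agg = ndimage.convolve(agg.astype(np.float32), kernel, mode="constant")
        n_ind = ndimage.convolve(ind.astype(np.float32), kernel, mode="constant")
        lesion_major = (CODE_AGGRESSIVE
                        if lesion.n_aggressive >= lesion.n_indolent and lesion.n_aggressive > 0
                        else CODE_INDOLENT if lesion.n_indolent > 0
                        else _CLASS_CODE[lesion.lesion_class or "benign"])
        fill = np.where(n_agg >= n_ind, CODE_AGGRESSIVE, CODE_INDOLENT)
        fill[(n_agg == 0) & (n_ind == 0)] = lesion_major
        out[missing] = fill[missing]
    return out


def derive_label(
    outline_or_map,
    grade_map: GradeMap,
    label_type: str,
    prostate_mask: np.ndarray,
    connectivity: int = 26,
    min_volume: float = MIN_LESION_VOLUME_MM3,
    threshold: float = CLASS_FRACTION_THRESHOLD,
) -> LabelVolume:
    """Derive a label volume under one of the four strategies.

    Parameters
    ----------
    outline_or_map
        Binary human-outline volume for ``LRad``/``LPath``; ignored (may be
        ``None``) for the digital-pathologist strategies which consume the
        grade map directly.
    grade_map
        Per-voxel grade codes used to class lesions (and, for
        ``LPixelDPath``, to paint them).
    label_type
        One of ``LRad``, ``LPath``, ``LLesionDPath``, ``LPixelDPath``.
    """
    if label_type not in LABEL_TYPES:
        raise ValueError(f"unknown label type {label_type!r}")
    prostate = np.asarray(prostate_mask).astype(bool)
    if grade_map.codes.shape != prostate.shape:
        raise ValueError("grade map and prostate mask grids differ")

    if label_type in ("LRad", "LPath"):
        outline = np.asarray(outline_or_map).astype(bool)
        if outline.shape != prostate.shape:
            raise ValueError("outline and grade map grids differ")
        source_mask = outline & prostate
    else:
        source_mask = grade_map.cancer_mask & prostate

    element = make_structuring_element(float(grade_map.pixel_size_mm[0]))
    lesion_set = form_lesions(
        source_mask, grade_map.pixel_size_mm, grade_map.slice_spacing_mm,
        prostate_mask=prostate, connectivity=connectivity, element=element,
    )
    lesion_set = grade_lesions(lesion_set, grade_map.codes, threshold)
    lesion_set = filter_lesions(lesion_set, min_volume)
    lesion_set.provenance = label_type

    codes = np.where(prostate, CODE_NORMAL, CODE_OUTSIDE).astype(np.int16)
    for les in lesion_set.kept:
        if les.lesion_class == "benign":
            continue  # benign-classed outlines stay normal tissue
        if label_type == "LPixelDPath":
            fill = _majority_grade_fill(les, grade_map.codes, element)
            sel = fill > 0
            codes[sel] = fill[sel]
        else:
            code = _CLASS_CODE[les.lesion_class]
            if code in (CODE_INDOLENT, CODE_AGGRESSIVE):
                codes[tuple(les.voxels.T)] = code
            # benign-classed outlines stay normal tissue
    # drop benign lesions from the kept list of lesion-level strategies:
    # they carry no cancer label (the outline "was considered as benign tissue")
    lesion_set.kept = [l for l in lesion_set.kept if l.lesion_class != "benign"]
    return LabelVolume(codes=codes, label_type=label_type, lesion_set=lesion_set,
                       pixel_size_mm=grade_map.pixel_size_mm,
                       slice_spacing_mm=grade_map.slice_spacing_mm)


def lesion_table(label_volumes: dict[str, "LabelVolume"], case_id: str) -> pd.DataFrame:
    """Concatenated lesion table across label types for one case."""
    frames = [f for f in (lv.lesion_set.to_frame(case_id)
                          for lv in label_volumes.values()) if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
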