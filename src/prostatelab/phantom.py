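"""Seeded synthetic cohorts of co-registered prostate MRI with histology-grade truth.

Each phantom case emulates the data layout of a radical-prostatectomy study
after MRI-histopathology registration: axial T2w and ADC volumes on a common
analysis grid, a prostate mask, a per-voxel grade map (normal / GP3 / GP4+)
standing in for digital-pathologist output, and two imperfect human-annotation
volumes:

* a *radiologist* outline that misses a fraction of lesions entirely
  (MRI-invisible tumours, default 20 %), underestimates the extent of the
  lesions it does see (outline volume ~68 % of true lesion volume), and skips
  some slices; and
* a *pathologist* outline that captures the full lesion extent on the slices
  it annotates but skips slices, and carries no grade information.

Geometry is deliberately simple — the prostate is an ellipsoid, lesions are
random-axis ellipsoids with a nested aggressive (GP4+) core — because the
label-derivation and evaluation machinery only assumes connected cancer
objects of controllable volume and grade mixture.  Everything is a pure
function of (spec, seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import labels as lab
from .preprocess import ImageVolume


class PlacementError(RuntimeError):
    """Raised when a lesion cannot be placed inside the prostate mask."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and statistics of a synthetic cohort.

    Defaults mirror the analysis grid of the study conditions: 224 x 224
    in-plane at 0.29 x 0.29 mm pixels with 3 mm slice spacing (valid scanner
    range 3-4.2 mm).  ``rad_miss_prob`` defaults to 0.2 (about one in five
    tumours is hardly visible or invisible on MRI) and ``rad_shrink_factor``
    to 0.88 linear, i.e. outline volumes around 68 % of true lesion volumes
    once slice-skipping is included.
    """

    grid_x: int = 224
    grid_y: int = 224
    n_slices: int = 12
    pixel_size_mm: float = 0.29
    slice_spacing_mm: float = 3.0
    n_lesions: int = 2
    lesion_radius_range_mm: tuple[float, float] = (5.0, 8.0)
    lesion_z_radius_range_mm: tuple[float, float] = (3.5, 7.0)
    aggressive_fraction_range: tuple[float, float] = (0.3, 0.8)
    indolent_lesion_prob: float = 0.25
    lesion_contrast: float = 0.35
    noise_sigma: float = 0.05
    rad_miss_prob: float = 0.2
    rad_shrink_factor: float = 0.88
    rad_slice_skip_prob: float = 0.1
    path_slice_skip_prob: float = 0.2
    min_lesion_separation_mm: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        probs = (self.rad_miss_prob, self.rad_slice_skip_prob,
                 self.path_slice_skip_prob, self.indolent_lesion_prob)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        lengths = (self.pixel_size_mm, self.slice_spacing_mm,
                   *self.lesion_radius_range_mm, *self.lesion_z_radius_range_mm)
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if self.lesion_radius_range_mm[0] > self.lesion_radius_range_mm[1]:
            raise ValueError("lesion radius range min must be <= max")
        if not 0 < self.rad_shrink_factor <= 1:
            raise ValueError("rad_shrink_factor must lie in (0, 1]")
        lo, hi = self.aggressive_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("aggressive_fraction_range must satisfy 0 <= min <= max <= 1")
        if not 8 <= self.n_slices:
            raise ValueError("phantoms need at least 8 slices")

    def to_dict(self) -> dict:
        return asdict(self)

    def spec_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PlantedLesion:
    """Ground-truth record of a planted lesion.

    ``conspicuous`` is False for the MRI-invisible / hardly visible lesions:
    they are rendered at strongly reduced contrast and receive no radiologist
    outline.
    """

    lesion_id: int
    center_vox: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    voxels: np.ndarray
    n_voxels: int
    volume_mm3: float
    n_aggressive: int
    n_indolent: int
    lesion_class: str
    conspicuous: bool = True

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass(eq=False)
class PhantomCase:
    case_id: str
    t2w: ImageVolume
    adc: ImageVolume
    prostate_mask: np.ndarray
    truth_grade_map: lab.GradeMap
    truth_lesions: list[PlantedLesion]
    rad_outline: np.ndarray
    path_outline: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.prostate_mask.shape


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape: tuple[int, int, int],
                    center_vox: tuple[float, float, float],
                    radii_mm: tuple[float, float, float],
                    pixel_mm: float, dz_mm: float) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid given in millimetres."""
    nz, ny, nx = shape
    cz, cy, cx = center_vox
    rz, ry, rx = radii_mm
    z = (np.arange(nz) - cz) * dz_mm
    y = (np.arange(ny) - cy) * pixel_mm
    x = (np.arange(nx) - cx) * pixel_mm
    return ((z[:, None, None] / rz) ** 2
            + (y[None, :, None] / ry) ** 2
            + (x[None, None, :] / rx) ** 2) <= 1.0


def _prostate_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = (spec.n_slices, spec.grid_y, spec.grid_x)
    jitter = rng.uniform(-2.0, 2.0, size=2)  # mm, in-plane
    center = ((spec.n_slices - 1) / 2.0,
              (spec.grid_y - 1) / 2.0 + jitter[0] / spec.pixel_size_mm,
              (spec.grid_x - 1) / 2.0 + jitter[1] / spec.pixel_size_mm)
    semi_z = 0.40 * spec.n_slices * spec.slice_spacing_mm * rng.uniform(0.9, 1.05)
    semi_y = 17.0 * rng.uniform(0.9, 1.1)
    semi_x = 22.0 * rng.uniform(0.9, 1.1)
    fov_mm = min(spec.grid_x, spec.grid_y) * spec.pixel_size_mm
    semi_y = min(semi_y, 0.45 * fov_mm)
    semi_x = min(semi_x, 0.45 * fov_mm)
    return _ellipsoid_mask(shape, center, (semi_z, semi_y, semi_x),
                           spec.pixel_size_mm, spec.slice_spacing_mm)


def _touch_count(region: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Per-voxel count of ``region`` voxels covered by ``kernel`` centred there."""
    from scipy.signal import fftconvolve

    # kernels here are point-symmetric, so convolution equals correlation
    out = fftconvolve(region.astype(np.float32), kernel.astype(np.float32),
                      mode="same")
    return np.rint(out).astype(np.int64)


def _plant_lesions(spec: PhantomSpec, prostate: np.ndarray,
                   rng: np.random.Generator, case_id: str,
                   max_draws: int = 8) -> tuple[np.ndarray, list[PlantedLesion]]:
    """Place ellipsoidal lesions inside the prostate, well separated.

    For each lesion the semi-axes are drawn first and the set of admissible
    centres is computed directly (by convolving the gland complement and the
    separation zone with the lesion footprint), then a centre is sampled from
    it.  Admissible means the lesion fits fully inside the gland and stays
    clear of the forbidden zone around earlier lesions; if no such centre
    exists the radii are redrawn from a progressively narrower range, and as a
    last resort lesions clipped by the gland boundary are accepted provided
    most of the ellipsoid survives and the lesion stays well above the
    clinical-significance volume.

    The forbidden zone extends the configured minimum separation in-plane and
    three slices along Z (the closing kernel spans three slices and can bridge
    up to two empty slices), so morphological closing can never merge two
    planted lesions.
    """
    shape = prostate.shape
    grade = np.where(prostate, lab.CODE_NORMAL, lab.CODE_OUTSIDE).astype(np.int16)
    sep_px = max(1, int(math.ceil(spec.min_lesion_separation_mm / spec.pixel_size_mm)))
    voxvol = spec.pixel_size_mm ** 2 * spec.slice_spacing_mm
    outside = ~prostate

    def separation_zone(mask: np.ndarray) -> np.ndarray:
        near = np.zeros(shape, dtype=np.uint8)
        for z in np.flatnonzero(mask.any(axis=(1, 2))):
            d = ndimage.distance_transform_edt(~mask[z])
            near[z] = d <= sep_px
        return ndimage.maximum_filter1d(near, size=7, axis=0).astype(bool)

    def footprint(rz, ry, rx) -> np.ndarray:
        kz = int(rz / spec.slice_spacing_mm)
        ky = int(ry / spec.pixel_size_mm)
        kx = int(rx / spec.pixel_size_mm)
        kshape = (2 * kz + 1, 2 * ky + 1, 2 * kx + 1)
        return _ellipsoid_mask(kshape, (kz, ky, kx), (rz, ry, rx),
                               spec.pixel_size_mm, spec.slice_spacing_mm)

    forbidden = np.zeros(shape, dtype=bool)
    planted: list[PlantedLesion] = []
    for lid in range(1, spec.n_lesions + 1):
        placed = False
        for draw in range(max_draws):
            # later draws sample from the lower part of the radius range so
            # crowded glands still admit the requested number of lesions
            squeeze = 1.0 - draw / (max_draws - 1)
            lo, hi = spec.lesion_radius_range_mm
            zlo, zhi = spec.lesion_z_radius_range_mm
            rx = rng.uniform(lo, lo + (hi - lo) * squeeze)
            ry = rng.uniform(lo, lo + (hi - lo) * squeeze)
            rz = rng.uniform(zlo, zlo + (zhi - zlo) * squeeze)
            kern = footprint(rz, ry, rx)
            clear_of_earlier = _touch_count(forbidden, kern) == 0
            admissible = (prostate & clear_of_earlier
                          & (_touch_count(outside, kern) == 0))
            if not admissible.any() and draw >= max_draws // 2:
                # tolerate clipping by the gland boundary: most of the
                # ellipsoid must survive, well above the volume threshold
                inside_count = _touch_count(prostate, kern)
                admissible = (prostate & clear_of_earlier
                              & (inside_count * voxvol >= 300.0)
                              & (inside_count >= 0.6 * kern.sum()))
            centres = np.argwhere(admissible)
            if len(centres) == 0:
                continue
            cz, cy, cx = centres[rng.integers(len(centres))]
            ell = _ellipsoid_mask(shape, (cz, cy, cx), (rz, ry, rx),
                                  spec.pixel_size_mm, spec.slice_spacing_mm)
            mask = ell & prostate
            # a fraction of lesions is pure Gleason-pattern-3 (grade group 1);
            # the rest carry a GP4+ core drawn from the configured range
            if rng.random() < spec.indolent_lesion_prob:
                frac = 0.0
            else:
                frac = rng.uniform(*spec.aggressive_fraction_range)
            grade[mask] = lab.CODE_INDOLENT
            n_total = int(mask.sum())
            if frac > 0:
                lam = frac ** (1.0 / 3.0)
                core = _ellipsoid_mask(shape, (cz, cy, cx),
                                       (lam * rz, lam * ry, lam * rx),
                                       spec.pixel_size_mm, spec.slice_spacing_mm)
                core &= mask
                grade[core] = lab.CODE_AGGRESSIVE
                n_agg = int(core.sum())
            else:
                n_agg = 0
            n_ind = n_total - n_agg
            vol = lab.lesion_volume(n_total, spec.pixel_size_mm,
                                    spec.pixel_size_mm, spec.slice_spacing_mm)
            planted.append(PlantedLesion(
                lesion_id=lid, center_vox=(float(cz), float(cy), float(cx)),
                radii_mm=(rz, ry, rx), voxels=np.argwhere(mask),
                n_voxels=n_total, volume_mm3=vol,
                n_aggressive=n_agg, n_indolent=n_ind,
                lesion_class=lab.classify_lesion(n_agg, n_ind, n_total),
                conspicuous=bool(rng.random() >= spec.rad_miss_prob),
            ))
            forbidden |= separation_zone(mask)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"case {case_id}: could not place lesion {lid} of "
                f"{spec.n_lesions} after {max_draws} radius draws "
                f"(mask too small for the requested radii)"
            )
    return grade, planted


# ---------------------------------------------------------------------------
# modality simulation
# ---------------------------------------------------------------------------

_BASE_LEVELS = {"t2w": (0.55, 1.0), "adc": (0.70, 1.0)}  # (outside, prostate)

#: Extra relative signal drop of GP4+ voxels on ADC.  Higher-grade cancer is
#: more cellular and restricts diffusion more strongly, so the aggressive core
#: of a mixed lesion is rendered darker on ADC than its indolent rim.
_ADC_AGGRESSIVE_BOOST = 1.4

#: Contrast multiplier of inconspicuous (hardly visible / MRI-invisible)
#: lesions.  At the default lesion contrast and noise level this puts their
#: signal drop at roughly three times the smoothed noise floor: faint enough
#: that a reader (or an intensity-driven model trained without them) misses
#: them, but not strictly zero signal.
_SUBTLE_CONTRAST_SCALE = 0.12


def _contrast_maps(spec: PhantomSpec, grade: np.ndarray,
                   lesions: list["PlantedLesion"]) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel T2w and ADC signal drops for the planted lesions."""
    t2_drop = np.zeros(grade.shape)
    adc_drop = np.zeros(grade.shape)
    for les in lesions:
        scale = 1.0 if les.conspicuous else _SUBTLE_CONTRAST_SCALE
        vox = tuple(les.voxels.T)
        t2_drop[vox] = spec.lesion_contrast * scale
        adc_drop[vox] = spec.lesion_contrast * scale
    agg = grade == lab.CODE_AGGRESSIVE
    adc_drop[agg] *= _ADC_AGGRESSIVE_BOOST
    return t2_drop, adc_drop


def _render_modality(kind: str, spec: PhantomSpec, prostate: np.ndarray,
                     drop: np.ndarray, rng: np.random.Generator) -> ImageVolume:
    outside, inside = _BASE_LEVELS[kind]
    img = np.where(prostate, inside, outside).astype(np.float64) - drop
    img = ndimage.gaussian_filter(img, sigma=(0.0, 1.0, 1.0))
    img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return ImageVolume(img, (spec.pixel_size_mm, spec.pixel_size_mm),
                       spec.slice_spacing_mm)


# ---------------------------------------------------------------------------
# annotator simulators
# ---------------------------------------------------------------------------

def _erode_to_ratio(mask: np.ndarray, target_ratio: float,
                    max_iters: int = 10) -> np.ndarray:
    """Per-slice 2D erosion repeated until the volume ratio is closest to target."""
    if target_ratio >= 1.0:
        return mask.copy()
    struct = np.zeros((1, 3, 3), dtype=bool)
    struct[0] = ndimage.generate_binary_structure(2, 1)
    n0 = mask.sum()
    best, best_err = mask.copy(), abs(1.0 - target_ratio)
    cur = mask.copy()
    for _ in range(max_iters):
        cur = ndimage.binary_erosion(cur, structure=struct, border_value=0)
        ratio = cur.sum() / n0
        if ratio == 0:
            break
        err = abs(ratio - target_ratio)
        if err < best_err:
            best, best_err = cur.copy(), err
        if ratio < target_ratio:
            break
    return best


def simulate_radiologist_outline(case: PhantomCase, spec: PhantomSpec,
                                 seed) -> np.ndarray:
    """Imperfect radiologist cancer outline.

    Inconspicuous lesions (drawn with probability ``rad_miss_prob`` at
    planting, and rendered at strongly reduced contrast) get no outline at
    all; for every conspicuous lesion the lesion mask is
    eroded towards the configured volume ratio and annotated slices are then
    dropped independently with ``rad_slice_skip_prob``.  The erosion target is
    ``rad_shrink_factor**3 / (1 - rad_slice_skip_prob)`` so the *net* expected
    outline volume, slice skipping included, is ``rad_shrink_factor**3`` of
    the true lesion volume (~68 % at the default 0.88 linear factor).  An
    all-zero volume (every lesion missed) is legal output.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros(case.shape, dtype=bool)
    vol_ratio = spec.rad_shrink_factor ** 3
    keep = 1.0 - spec.rad_slice_skip_prob
    target = min(1.0, vol_ratio / keep) if keep > 0 else 1.0
    for les in case.truth_lesions:
        if not les.conspicuous:
            continue
        m = _erode_to_ratio(les.mask(case.shape), target)
        for z in np.flatnonzero(m.any(axis=(1, 2))):
            if rng.random() < spec.rad_slice_skip_prob:
                m[z] = False
        out |= m
    return out & case.prostate_mask


def simulate_pathologist_outline(case: PhantomCase, spec: PhantomSpec,
                                 seed) -> np.ndarray:
    """Pathologist cancer outline: full extent per annotated slice, no grades.

    Each (lesion, slice) pair is dropped independently with
    ``path_slice_skip_prob``; annotated slices carry the full lesion extent.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros(case.shape, dtype=bool)
    for les in case.truth_lesions:
        m = les.mask(case.shape)
        for z in np.flatnonzero(m.any(axis=(1, 2))):
            if rng.random() < spec.path_slice_skip_prob:
                m[z] = False
        out |= m
    return out & case.prostate_mask


# ---------------------------------------------------------------------------
# case / cohort generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec, case_seed: int,
                     case_id: str | None = None) -> PhantomCase:
    """Generate one phantom case; pure function of (spec, case_seed)."""
    spec.validate()
    case_id = case_id or f"case_{case_seed:04d}"
    root = np.random.SeedSequence([int(spec.seed), int(case_seed)])
    geo_ss, noise_t2_ss, noise_adc_ss, rad_ss, path_ss = root.spawn(5)
    geo_rng = np.random.default_rng(geo_ss)

    prostate = _prostate_mask(spec, geo_rng)
    grade, planted = _plant_lesions(spec, prostate, geo_rng, case_id)
    t2_drop, adc_drop = _contrast_maps(spec, grade, planted)

    t2w = _render_modality("t2w", spec, prostate, t2_drop,
                           np.random.default_rng(noise_t2_ss))
    adc = _render_modality("adc", spec, prostate, adc_drop,
                           np.random.default_rng(noise_adc_ss))
    grade_map = lab.GradeMap(grade, (spec.pixel_size_mm, spec.pixel_size_mm),
                             spec.slice_spacing_mm)
    case = PhantomCase(case_id=case_id, t2w=t2w, adc=adc, prostate_mask=prostate,
                       truth_grade_map=grade_map, truth_lesions=planted,
                       rad_outline=np.zeros_like(prostate),
                       path_outline=np.zeros_like(prostate))
    case.rad_outline = simulate_radiologist_outline(case, spec, rad_ss)
    case.path_outline = simulate_pathologist_outline(case, spec, path_ss)
    return case


def generate_cohort(spec: PhantomSpec, n_cases: int, seed: int | None = None,
                    out_dir: str | Path | None = None) -> list[PhantomCase]:
    """Generate a cohort of independent cases.

    Case seeds are derived deterministically from the master seed by counter
    (case ``i`` uses ``SeedSequence([seed, i])``), so enlarging a cohort never
    reshuffles earlier cases.  With ``out_dir`` set, volumes are written as
    NIfTI plus a JSON manifest.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    cases = []
    for i in range(n_cases):
        try:
            cases.append(generate_phantom(spec, case_seed=i, case_id=f"case_{i:04d}"))
        except PlacementError as err:
            raise PlacementError(f"cohort case index {i}: {err}") from err
    if out_dir is not None:
        save_cohort(cases, spec, out_dir)
    return cases


# ---------------------------------------------------------------------------
# NIfTI persistence
# ---------------------------------------------------------------------------

def _affine(spec_px: float, dz: float) -> np.ndarray:
    return np.diag([spec_px, spec_px, dz, 1.0])


def save_cohort(cases: list[PhantomCase], spec: PhantomSpec,
                out_dir: str | Path) -> Path:
    """Write each case as NIfTI channel files plus a cohort manifest."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(spec.pixel_size_mm, spec.slice_spacing_mm)
    manifest = {"spec": spec.to_dict(), "spec_hash": spec.spec_hash(),
                "seed": spec.seed, "cases": {}}
    for case in cases:
        cdir = out / case.case_id
        cdir.mkdir(exist_ok=True)
        channels = {
            "t2w": case.t2w.data.astype(np.float32),
            "adc": case.adc.data.astype(np.float32),
            "prostate_mask": case.prostate_mask.astype(np.uint8),
            "grade_map": case.truth_grade_map.codes.astype(np.uint8),
            "rad_outline": case.rad_outline.astype(np.uint8),
            "path_outline": case.path_outline.astype(np.uint8),
        }
        paths = {}
        for name, arr in channels.items():
            p = cdir / f"{name}.nii.gz"
            # internal (z, y, x) -> NIfTI (x, y, z)
            nib.save(nib.Nifti1Image(np.ascontiguousarray(arr.T), aff), p)
            paths[name] = str(p.relative_to(out))
        manifest["cases"][case.case_id] = paths
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out / "manifest.json"


def load_cohort(manifest_path: str | Path) -> tuple[PhantomSpec, list[PhantomCase]]:
    """Reload a saved cohort; truth lesions are re-derived from the grade map."""
    import nibabel as nib

    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    spec = PhantomSpec(**{k: tuple(v) if isinstance(v, list) else v
                          for k, v in manifest["spec"].items()})
    root = manifest_path.parent
    cases = []
    for case_id, paths in sorted(manifest["cases"].items()):
        arrs = {}
        for name, rel in paths.items():
            arrs[name] = np.asarray(nib.load(root / rel).dataobj).T
        gm = lab.GradeMap(arrs["grade_map"].astype(np.int16),
                          (spec.pixel_size_mm, spec.pixel_size_mm),
                          spec.slice_spacing_mm)
        geom = (spec.pixel_size_mm, spec.pixel_size_mm)
        planted = _lesions_from_grade_map(gm, spec)
        cases.append(PhantomCase(
            case_id=case_id,
            t2w=ImageVolume(arrs["t2w"].astype(np.float64), geom, spec.slice_spacing_mm),
            adc=ImageVolume(arrs["adc"].astype(np.float64), geom, spec.slice_spacing_mm),
            prostate_mask=arrs["prostate_mask"].astype(bool),
            truth_grade_map=gm, truth_lesions=planted,
            rad_outline=arrs["rad_outline"].astype(bool),
            path_outline=arrs["path_outline"].astype(bool),
        ))
    return spec, cases


def _lesions_from_grade_map(grade_map: lab.GradeMap,
                            spec: PhantomSpec) -> list[PlantedLesion]:
    """Recover per-lesion truth records from a grade map (connected cancer blobs)."""
    cancer = grade_map.cancer_mask
    labeled, n = ndimage.label(cancer, structure=ndimage.generate_binary_structure(3, 3))
    out = []
    for lid in range(1, n + 1):
        m = labeled == lid
        voxels = np.argwhere(m)
        n_total = len(voxels)
        codes = grade_map.codes[m]
        n_agg = int(np.count_nonzero(codes == lab.CODE_AGGRESSIVE))
        n_ind = int(np.count_nonzero(codes == lab.CODE_INDOLENT))
        out.append(PlantedLesion(
            lesion_id=lid, center_vox=tuple(voxels.mean(axis=0)),
            radii_mm=(0.0, 0.0, 0.0), voxels=voxels, n_voxels=n_total,
            volume_mm3=lab.lesion_volume(n_total, spec.pixel_size_mm,
                                         spec.pixel_size_mm, spec.slice_spacing_mm),
            n_aggressive=n_agg, n_indolent=n_ind,
            lesion_class=lab.classify_lesion(n_agg, n_ind, n_total),
        ))
    return out
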