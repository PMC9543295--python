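import numpy as np
import pytest

from prostatelab import PhantomSpec, generate_cohort, generate_phantom
from prostatelab.pipeline import derive_cohort_labels, desk_preset


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    """Small-grid spec used for model training tests (96 px at 0.6 mm)."""
    return desk_preset().spec


@pytest.fixture(scope="session")
def default_case():
    """One full-resolution phantom case (224 px at 0.29 mm)."""
    return generate_phantom(PhantomSpec(seed=7), 0)


@pytest.fixture(scope="session")
def desk_cohort(desk_spec):
    """Eight small-grid cases shared across training tests."""
    return generate_cohort(desk_spec, 8, seed=21)


@pytest.fixture(scope="session")
def desk_cohort_labels(desk_cohort):
    return derive_cohort_labels(desk_cohort)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> int:
    """Brute-force connected-component count via BFS (independent oracle)."""
    mask = np.asarray(mask).astype(bool)
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                   (0, 0, -1)]
    elif connectivity == 26:
        offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
                   for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    else:
        raise ValueError(connectivity)
    seen = np.zeros_like(mask)
    n = 0
    coords = np.argwhere(mask)
    for z0, y0, x0 in coords:
        if seen[z0, y0, x0]:
            continue
        n += 1
        stack = [(z0, y0, x0)]
        seen[z0, y0, x0] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                zz, yy, xx = z + dz, y + dy, x + dx
                if (0 <= zz < mask.shape[0] and 0 <= yy < mask.shape[1]
                        and 0 <= xx < mask.shape[2]
                        and mask[zz, yy, xx] and not seen[zz, yy, xx]):
                    seen[zz, yy, xx] = True
                    stack.append((zz, yy, xx))
    return n


def ellipsoid(shape, center, radii):
    """Voxel-unit ellipsoid mask for building toy prostates in tests."""
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    cz, cy, cx = center
    rz, ry, rx = radii
    return (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
            + ((xx - cx) / rx) ** 2) <= 1.0
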