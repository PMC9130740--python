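"""Toy block atlas standing in for anatomical region masks.

Five response regions are placed as disjoint 3×3×3 blocks on a small voxel
grid (0-based indices, no MNI space): contralateral and ipsilateral
sensorimotor cortex at the top of the volume on opposite sides, primary
visual cortex posterior-inferior, thalamus central, and the posterior
cingulate posterior-superior.  Everything else is background.
"""

from __future__ import annotations

import numpy as np

#: Region name → integer label in the label map.
REGION_LABELS = {
    "background": 0,
    "cSM1": 1,
    "iSM1": 2,
    "V1": 3,
    "thalamus": 4,
    "PCC": 5,
}

#: Regions carrying a task response (everything but background).
RESPONSE_REGIONS = ("cSM1", "iSM1", "V1", "thalamus", "PCC")

_BLOCK = 3  # region block side length, voxels

DEFAULT_GRID = (12, 12, 6)

MIN_GRID = (12, 12, 6)


def _block_origin(region: str, grid: tuple[int, int, int]) -> tuple[int, int, int]:
    nx, ny, nz = grid
    cx = nx // 2 - 1
    origins = {
        "cSM1": (1, 1, nz - _BLOCK),
        "iSM1": (nx - _BLOCK - 1, 1, nz - _BLOCK),
        "V1": (cx, ny - _BLOCK - 1, 0),
        "thalamus": (cx, ny // 2 - 1, max(0, nz // 2 - 2)),
        "PCC": (cx, ny - _BLOCK - 1, nz - _BLOCK),
    }
    return origins[region]


def region_slices(region: str, grid: tuple[int, int, int]) -> tuple[slice, slice, slice]:
    ox, oy, oz = _block_origin(region, grid)
    return (slice(ox, ox + _BLOCK), slice(oy, oy + _BLOCK), slice(oz, oz + _BLOCK))


def toy_atlas(grid: tuple[int, int, int] = DEFAULT_GRID) -> np.ndarray:
    """Integer label map for the toy atlas on ``grid``."""
    if any(g < m for g, m in zip(grid, MIN_GRID)):
        raise ValueError(f"grid {grid} too small; need at least {MIN_GRID}")
    labels = np.zeros(grid, dtype=np.int16)
    for region in RESPONSE_REGIONS:
        sl = region_slices(region, grid)
        if np.any(labels[sl] != 0):
            raise ValueError(f"region blocks overlap on grid {grid}")
        labels[sl] = REGION_LABELS[region]
    return labels


def region_mask(labels: np.ndarray, region: str) -> np.ndarray:
    """Boolean mask of one named region."""
    if region not in REGION_LABELS:
        raise ValueError(f"unknown region {region!r}")
    return labels == REGION_LABELS[region]


def sensorimotor_mask(labels: np.ndarray) -> np.ndarray:
    """Bilateral sensorimotor mask: union of cSM1 and iSM1 blocks."""
    return region_mask(labels, "cSM1") | region_mask(labels, "iSM1")
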