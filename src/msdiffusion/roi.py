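"""3D lesion ROI construction: connected components, contralateral
normal-appearing white matter (NAWM) by mirroring, and erosion-defined
core/shell sub-ROIs.

Conventions
-----------
* Lesion components are labeled under a configurable connectivity
  (default 26: faces, edges and corners) and numbered 1..K by descending
  voxel count; ties broken by the component's minimal (z, y, x) voxel.
* Each lesion's contralateral NAWM ROI is the lesion mask mapped through a
  grid involution (default: exact left-right flip along the x axis),
  restricted to white matter and cleaned of any voxel belonging to any
  lesion, so the pair is never contaminated by tissue of the other type.
  Pairs retaining too little of the mirrored mask are marked invalid.
* The core is the 3D binary erosion of the lesion with the full 3x3x3
  structuring element: exactly the voxels whose 26 neighbors all lie inside
  the lesion.  Shell = lesion minus core is then single-voxel thick in the
  26-adjacency sense.  Lesions whose erosion is empty (thinner than 3
  voxels in some direction) are ineligible for the core/shell analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ROILabelVolume",
    "ROIPair",
    "CoreShell",
    "label_components",
    "mirror_nawm",
    "core_shell_split",
    "lr_flip",
    "roi_table",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ROILabelVolume:
    """Integer-labeled 3D connected components, size-ordered."""

    labels: np.ndarray  # int array, 0 = background
    sizes: np.ndarray  # voxel count per id, index 0 <-> id 1
    voxel_size: np.ndarray
    connectivity: int = 26

    @property
    def n_rois(self) -> int:
        return len(self.sizes)

    def mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def volumes_mm3(self) -> np.ndarray:
        return self.sizes * float(np.prod(self.voxel_size))


@dataclass
class ROIPair:
    """A lesion and its contralateral NAWM homologue."""

    lesion_id: int
    lesion_mask: np.ndarray
    nawm_mask: np.ndarray
    valid: bool


@dataclass
class CoreShell:
    lesion_id: int
    core_mask: np.ndarray
    shell_mask: np.ndarray


def _min_zyx(mask: np.ndarray) -> tuple[int, int, int]:
    x, y, z = np.nonzero(mask)
    i = np.lexsort((x, y, z))[0]
    return (int(z[i]), int(y[i]), int(x[i]))


def label_components(
    mask: np.ndarray, connectivity: int = 26, voxel_size=(2.0, 2.0, 2.0)
) -> ROILabelVolume:
    """Label connected components of a binary mask, sorted by descending size.

    An empty mask yields zero ROIs (not an error).
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = np.asarray(mask).astype(bool)
    raw, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    if n == 0:
        return ROILabelVolume(
            labels=np.zeros_like(raw, dtype=np.int32),
            sizes=np.zeros(0, dtype=int),
            voxel_size=np.asarray(voxel_size, dtype=float),
            connectivity=connectivity,
        )
    sizes = ndimage.sum_labels(mask, raw, index=np.arange(1, n + 1)).astype(int)
    keys = [(-int(sizes[k]), _min_zyx(raw == k + 1)) for k in range(n)]
    order = sorted(range(n), key=lambda k: keys[k])
    relabel = np.zeros(n + 1, dtype=np.int32)
    for new_id, old in enumerate(order, start=1):
        relabel[old + 1] = new_id
    return ROILabelVolume(
        labels=relabel[raw],
        sizes=sizes[order],
        voxel_size=np.asarray(voxel_size, dtype=float),
        connectivity=connectivity,
    )


def lr_flip(mask: np.ndarray) -> np.ndarray:
    """Exact left-right mirror: reversal of the grid x axis."""
    return mask[::-1]


def mirror_nawm(
    lesions: ROILabelVolume,
    wm_mask: np.ndarray,
    flip_transform: Callable[[np.ndarray], np.ndarray] = lr_flip,
    min_retention: float = 0.5,
) -> list[ROIPair]:
    """Pair every lesion with its mirrored contralateral NAWM ROI.

    The mirrored mask is intersected with white matter and cleaned of every
    lesion voxel; a pair whose NAWM retains fewer than ``min_retention`` of
    the mirrored voxels (or none) is marked invalid and excluded from
    downstream pairing.

    ``flip_transform`` must be an involution on the grid (applying it twice
    is the identity); any grid involution is accepted so an externally
    supplied left-right registration map can be plugged in.
    """
    wm_mask = np.asarray(wm_mask).astype(bool)
    probe = lesions.labels
    twice = flip_transform(flip_transform(probe))
    if not np.array_equal(np.asarray(twice), probe):
        raise ValueError("flip_transform is not an involution on this grid")

    all_lesions = lesions.labels > 0
    pairs: list[ROIPair] = []
    for roi_id in range(1, lesions.n_rois + 1):
        lm = lesions.mask(roi_id)
        mirrored = np.asarray(flip_transform(lm)).astype(bool)
        nawm = mirrored & wm_mask & ~all_lesions
        retained = nawm.sum() / max(mirrored.sum(), 1)
        valid = bool(nawm.any() and retained >= min_retention)
        pairs.append(
            ROIPair(lesion_id=roi_id, lesion_mask=lm, nawm_mask=nawm, valid=valid)
        )
    return pairs


_CUBE = np.ones((3, 3, 3), dtype=bool)


def core_shell_split(lesion_mask: np.ndarray, lesion_id: int = 0) -> CoreShell | None:
    """Split a lesion into erosion core and single-voxel-thick shell.

    Core voxels keep all 26 neighbors inside the lesion (full-cube erosion;
    out-of-grid counts as background, so edge-touching lesions lose their
    border layer to the shell).  Returns ``None`` for ineligible lesions
    (erosion empty, i.e. too small to encapsulate a 3x3x3 voxel cube).
    """
    lesion_mask = np.asarray(lesion_mask).astype(bool)
    if not lesion_mask.any():
        raise ValueError("empty lesion mask")
    core = ndimage.binary_erosion(lesion_mask, structure=_CUBE, border_value=0)
    if not core.any():
        return None
    return CoreShell(
        lesion_id=lesion_id, core_mask=core, shell_mask=lesion_mask & ~core
    )


def roi_table(
    lesions: ROILabelVolume,
    pairs: list[ROIPair] | None = None,
    cores: dict[int, CoreShell | None] | None = None,
) -> pd.DataFrame:
    """Per-ROI summary: id, size, volume, pairing validity, core eligibility."""
    vol = float(np.prod(lesions.voxel_size))
    rows = []
    for roi_id in range(1, lesions.n_rois + 1):
        size = int(lesions.sizes[roi_id - 1])
        row = {
            "id": roi_id,
            "size_voxels": size,
            "volume_mm3": size * vol,
        }
        if pairs is not None:
            row["pair_valid"] = pairs[roi_id - 1].valid
        if cores is not None:
            cs = cores.get(roi_id)
            row["core_eligible"] = cs is not None
            row["core_voxels"] = int(cs.core_mask.sum()) if cs else 0
            row["shell_voxels"] = int(cs.shell_mask.sum()) if cs else 0
        rows.append(row)
    return pd.DataFrame(rows)
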