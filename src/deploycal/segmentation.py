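"""Voxel containers, lesion extraction from probability maps, and Dice overlap.

The classifier emits a 3-D tumor-probability map per examination.  Candidate
lesions are the connected components of the thresholded map inside the
prostate; spatial congruence with the radiologist's hand-drawn volumes of
interest (VOIs) is scored with the Dice coefficient 2|A∩B|/(|A|+|B|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GeometryError, MissingDataError

__all__ = [
    "VoxelMask",
    "VoxelProbabilityMap",
    "OverlapResult",
    "LesionOverlap",
    "dice",
    "extract_lesions",
    "mean_lesion_dice",
]


@dataclass
class VoxelMask:
    """A binary 3-D mask with isotropic-or-not voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got shape {self.data.shape}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise GeometryError("mask values must be 0/1")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def volume(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def union(self, other: "VoxelMask") -> "VoxelMask":
        _check_same_grid(self, other)
        return VoxelMask((self.data | other.data), self.spacing)


@dataclass
class VoxelProbabilityMap:
    """A 3-D array of tumor-class probabilities in [0, 1]."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"map must be 3-D, got shape {self.data.shape}")
        if self.data.min() < 0 or self.data.max() > 1:
            raise GeometryError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def max_inside(self, mask: VoxelMask) -> float:
        """Maximum tumor probability within ``mask`` (0.0 if mask is empty)."""
        if mask.shape != self.shape:
            raise GeometryError(f"mask shape {mask.shape} != map shape {self.shape}")
        sel = mask.data.astype(bool)
        if not sel.any():
            return 0.0
        return float(self.data[sel].max())


def _check_same_grid(a, b) -> None:
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a: VoxelMask, b: VoxelMask) -> float:
    """Dice overlap 2|a∩b| / (|a|+|b|) of two binary masks on one grid."""
    _check_same_grid(a, b)
    na, nb = a.volume(), b.volume()
    if na == 0 and nb == 0:
        raise DegenerateInputError("Dice is undefined for two empty masks")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


# 26-connectivity: all voxels sharing a face, edge or corner
_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def extract_lesions(
    prob_map: VoxelProbabilityMap,
    threshold: float,
    prostate: VoxelMask | None = None,
    min_voxels: int = 10,
) -> list[VoxelMask]:
    """Connected components of ``{map >= threshold}`` inside the prostate.

    Components smaller than ``min_voxels`` are discarded.  The list is ordered
    by component size descending, ties broken by the lexicographically smallest
    foreground voxel index, so the output is deterministic.
    """
    binary = prob_map.data >= threshold
    if prostate is not None:
        _check_same_grid(prob_map, prostate)
        binary &= prostate.data.astype(bool)
    labels, n = ndimage.label(binary, structure=_STRUCT_26)
    components: list[tuple[int, tuple, np.ndarray]] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        if size < min_voxels:
            continue
        first = tuple(np.argwhere(comp)[0])
        components.append((size, first, comp))
    components.sort(key=lambda c: (-c[0], c[1]))
    return [VoxelMask(comp.astype(np.uint8), prob_map.spacing) for _, _, comp in components]


@dataclass
class LesionOverlap:
    """Dice of one manual lesion VOI against the derived components hitting it."""

    lesion_id: str
    dice: float
    zero_overlap: bool


@dataclass
class OverlapResult:
    mode: str
    per_lesion: list[LesionOverlap] = field(default_factory=list)

    @property
    def mean_including_zeros(self) -> float:
        return float(np.mean([o.dice for o in self.per_lesion]))

    @property
    def mean_excluding_zeros(self) -> float | None:
        vals = [o.dice for o in self.per_lesion if not o.zero_overlap]
        return float(np.mean(vals)) if vals else None

    @property
    def n_zero_overlap(self) -> int:
        return sum(o.zero_overlap for o in self.per_lesion)


def _manual_mask(lesion, mode: str) -> VoxelMask:
    t2w, dwi = lesion.t2w_voi, lesion.dwi_voi
    if mode == "t2w":
        mask = t2w
    elif mode == "dwi":
        mask = dwi
    elif mode == "combined":
        if t2w is not None and dwi is not None:
            mask = t2w.union(dwi)
        else:
            mask = t2w if t2w is not None else dwi
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if mask is None:
        raise MissingDataError(f"lesion {lesion.lesion_id} has no {mode} VOI")
    return mask


def mean_lesion_dice(manual_lesions, derived: list[VoxelMask], mode: str = "combined") -> OverlapResult:
    """Score each manual lesion VOI against the union of derived components
    intersecting it (Dice 0, flagged, when none intersect).

    ``manual_lesions`` are lesion records carrying ``t2w_voi``/``dwi_voi``;
    ``mode`` selects the T2w VOI, the DWI VOI, or their union.  The cohort mean
    is reported both including and excluding zero-overlap lesions.
    """
    manual_lesions = list(manual_lesions)
    if not manual_lesions:
        raise DegenerateInputError("no manual lesions supplied")
    result = OverlapResult(mode=mode)
    for lesion in manual_lesions:
        voi = _manual_mask(lesion, mode)
        hits = [d for d in derived if int((d.data & voi.data).sum()) > 0]
        if not hits:
            result.per_lesion.append(LesionOverlap(lesion.lesion_id, 0.0, True))
            continue
        merged = hits[0]
        for h in hits[1:]:
            merged = merged.union(h)
        result.per_lesion.append(LesionOverlap(lesion.lesion_id, dice(voi, merged), False))
    return result
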