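import numpy as np
import pytest

from deploycal.errors import DegenerateInputError, GeometryError
from deploycal.segmentation import (
    VoxelMask,
    VoxelProbabilityMap,
    dice,
    extract_lesions,
    mean_lesion_dice,
)
from deploycal.synthetic import generate_voxel_phantom


def cube(shape, lo, hi):
    arr = np.zeros(shape, dtype=np.uint8)
    arr[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = 1
    return VoxelMask(arr)


def test_dice_identical_disjoint_and_counted():
    a = cube((8, 8, 8), (0, 0, 0), (2, 2, 2))
    assert dice(a, a) == 1.0
    b = cube((8, 8, 8), (4, 4, 4), (6, 6, 6))
    assert dice(a, b) == 0.0
    # |a|=4, |b|=6, |a∩b|=3 -> 2*3/10
    a = cube((8, 8, 8), (0, 0, 0), (4, 1, 1))
    b = cube((8, 8, 8), (1, 0, 0), (7, 1, 1))
    assert dice(a, b) == pytest.approx(0.6)


def test_dice_symmetric():
    a = cube((6, 6, 6), (0, 0, 0), (3, 3, 1))
    b = cube((6, 6, 6), (1, 1, 0), (4, 4, 1))
    assert dice(a, b) == dice(b, a)


def test_dice_errors():
    a = cube((6, 6, 6), (0, 0, 0), (2, 2, 2))
    with pytest.raises(GeometryError):
        dice(a, cube((5, 5, 5), (0, 0, 0), (2, 2, 2)))
    empty = VoxelMask(np.zeros((6, 6, 6), dtype=np.uint8))
    with pytest.raises(DegenerateInputError):
        dice(empty, empty)


def flood_fill_components(binary):
    """Independent 26-connectivity component oracle (BFS)."""
    binary = binary.astype(bool)
    seen = np.zeros_like(binary)
    comps = []
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for idx in np.argwhere(binary):
        idx = tuple(idx)
        if seen[idx]:
            continue
        stack, comp = [idx], set()
        seen[idx] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for off in offsets:
                w = tuple(np.add(v, off))
                if all(0 <= w[d] < binary.shape[d] for d in range(3)) and binary[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(comp)
    return comps


def test_extract_on_zero_map_and_subthreshold_blob():
    empty = VoxelProbabilityMap(np.zeros((8, 8, 8)))
    assert extract_lesions(empty, 0.5, min_voxels=1) == []
    prob, _ = generate_voxel_phantom([{"center": (4, 4, 4), "sigma": 2.0, "amplitude": 0.3}], (9, 9, 9))
    assert extract_lesions(prob, 0.5, min_voxels=1) == []


def test_two_blobs_match_flood_fill_oracle():
    prob, _ = generate_voxel_phantom(
        [
            {"center": (5, 5, 5), "sigma": 2.0, "amplitude": 0.9},
            {"center": (15, 15, 15), "sigma": 1.5, "amplitude": 0.8},
        ],
        grid=(21, 21, 21),
    )
    derived = extract_lesions(prob, 0.5, min_voxels=1)
    oracle = flood_fill_components(prob.data >= 0.5)
    assert len(derived) == len(oracle) == 2
    derived_sets = [set(map(tuple, np.argwhere(m.data))) for m in derived]
    # size-descending ordering
    assert derived[0].volume() >= derived[1].volume()
    assert {frozenset(s) for s in derived_sets} == {frozenset(c) for c in oracle}


def test_min_voxels_filter_and_prostate_restriction():
    prob, _ = generate_voxel_phantom(
        [
            {"center": (5, 5, 5), "sigma": 2.0, "amplitude": 0.9},
            {"center": (15, 15, 15), "sigma": 0.8, "amplitude": 0.9},
        ],
        grid=(21, 21, 21),
    )
    sizes = [m.volume() for m in extract_lesions(prob, 0.5, min_voxels=1)]
    big = extract_lesions(prob, 0.5, min_voxels=min(sizes) + 1)
    assert len(big) == 1 and big[0].volume() == max(sizes)
    prostate = cube((21, 21, 21), (0, 0, 0), (10, 10, 10))
    inside = extract_lesions(prob, 0.5, prostate=prostate, min_voxels=1)
    assert len(inside) == 1
    assert tuple(np.argwhere(inside[0].data).mean(axis=0).round()) == (5, 5, 5)


def test_extracted_components_are_disjoint_and_cover_superlevel_set():
    prob, _ = generate_voxel_phantom(
        [
            {"center": (5, 5, 5), "sigma": 2.0, "amplitude": 0.9},
            {"center": (14, 14, 14), "sigma": 1.8, "amplitude": 0.7},
        ],
        grid=(20, 20, 20),
    )
    derived = extract_lesions(prob, 0.4, min_voxels=1)
    union = np.zeros(prob.shape, dtype=int)
    for m in derived:
        union += m.data
    assert union.max() <= 1  # pairwise disjoint
    np.testing.assert_array_equal(union > 0, prob.data >= 0.4)


class _Lesion:
    def __init__(self, lesion_id, t2w=None, dwi=None):
        self.lesion_id = lesion_id
        self.t2w_voi = t2w
        self.dwi_voi = dwi


def test_mean_dice_exact_match_and_no_overlap():
    a = cube((10, 10, 10), (0, 0, 0), (3, 3, 3))
    res = mean_lesion_dice([_Lesion("L1", t2w=a)], [a], mode="t2w")
    assert res.mean_including_zeros == 1.0 and res.n_zero_overlap == 0
    far = cube((10, 10, 10), (6, 6, 6), (9, 9, 9))
    res = mean_lesion_dice([_Lesion("L1", t2w=a)], [far], mode="t2w")
    assert res.mean_including_zeros == 0.0
    assert res.n_zero_overlap == 1
    assert res.mean_excluding_zeros is None


def test_mean_dice_empty_manual_set_rejected():
    with pytest.raises(DegenerateInputError):
        mean_lesion_dice([], [], mode="t2w")


def test_combined_mode_uses_voi_union():
    t2w = cube((10, 10, 10), (0, 0, 0), (2, 2, 2))
    dwi = cube((10, 10, 10), (2, 0, 0), (4, 2, 2))
    derived = cube((10, 10, 10), (0, 0, 0), (4, 2, 2))
    res = mean_lesion_dice([_Lesion("L1", t2w=t2w, dwi=dwi)], [derived], mode="combined")
    assert res.mean_including_zeros == 1.0


def test_phantom_mean_dice_matches_voxel_count_oracle():
    prob, vois = generate_voxel_phantom(
        [
            {"center": (5, 5, 5), "sigma": 2.0, "amplitude": 0.9, "voi_offset": (1, 0, 0), "voi_radii": (3, 3, 3)},
            {"center": (15, 15, 15), "sigma": 2.0, "amplitude": 0.9, "voi_offset": (0, 2, 0), "voi_radii": (3, 3, 3)},
        ],
        grid=(21, 21, 21),
    )
    derived = extract_lesions(prob, 0.5, min_voxels=1)
    lesions = [_Lesion(f"L{i}", t2w=v) for i, v in enumerate(vois)]
    res = mean_lesion_dice(lesions, derived, mode="t2w")
    expected = []
    for v in vois:
        b = v.data.astype(bool)
        hits = [d.data.astype(bool) for d in derived if (d.data.astype(bool) & b).any()]
        merged = np.logical_or.reduce(hits) if hits else np.zeros_like(b)
        expected.append(2 * np.sum(merged & b) / (np.sum(merged) + np.sum(b)))
    assert res.mean_including_zeros == pytest.approx(np.mean(expected))
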