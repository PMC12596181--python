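"""Volume Overlap Fraction scoring against brute-force oracles."""

import numpy as np
import pytest

from cryoset import (
    DIRECTIONS,
    BinaryVolume,
    DensityMap,
    binary_iou,
    project_volume,
    validate_pairs,
    vof_score,
    voxelize_model,
)
from cryoset.errors import UsageError
from cryoset.model import Atom, AtomicModel

from conftest import make_entry


def _model(positions, element="C"):
    atoms = [
        Atom(
            chain_id="A",
            residue_number=i + 1,
            residue_name="ALA",
            atom_name="CA",
            element=element,
            position=tuple(float(x) for x in p),
            file_order=i,
        )
        for i, p in enumerate(positions)
    ]
    return AtomicModel(atoms)


def brute_projection(vol, direction):
    """Independent oracle: explicit loops over discrete lines."""
    nx, ny, nz = vol.shape
    if direction == "X":
        out = np.zeros((ny, nz))
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    out[y, z] += vol[x, y, z]
        return out
    if direction == "Y":
        out = np.zeros((nx, nz))
    elif direction == "Z":
        out = np.zeros((nx, ny))
    elif direction == "D_xy":
        out = np.zeros((nx + ny - 1, nz))
    elif direction == "D_yz":
        out = np.zeros((nx, ny + nz - 1))
    elif direction == "D_xz":
        out = np.zeros((nx + nz - 1, ny))
    else:
        raise AssertionError(direction)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                v = vol[x, y, z]
                if direction == "Y":
                    out[x, z] += v
                elif direction == "Z":
                    out[x, y] += v
                elif direction == "D_xy":
                    out[x - y + ny - 1, z] += v
                elif direction == "D_yz":
                    out[x, y - z + nz - 1] += v
                elif direction == "D_xz":
                    out[x - z + nz - 1, y] += v
    return out


def brute_vof(map_grid, model_grid):
    """Independent recomputation of all six IoUs and the final scores."""
    ious, dices = {}, {}
    for d in DIRECTIONS:
        a = brute_projection(np.asarray(map_grid, dtype=float), d) >= 1.0
        b = brute_projection(np.asarray(model_grid, dtype=float), d) >= 1.0
        na, nb = a.sum(), b.sum()
        if na == 0 and nb == 0:
            ious[d], dices[d] = 1.0, 1.0
        elif na == 0 or nb == 0:
            ious[d], dices[d] = 0.0, 0.0
        else:
            inter = (a & b).sum()
            ious[d] = inter / (na + nb - inter)
            dices[d] = inter / (na + nb)
    dropped = max(DIRECTIONS, key=lambda d: ious[d])
    keep = [d for d in DIRECTIONS if d != dropped]
    return ious, float(np.mean([ious[d] for d in keep])), float(
        np.mean([dices[d] for d in keep])
    )


# ---------------------------------------------------------------------------
# voxelization


def test_empty_model_voxelizes_to_zero():
    frame = DensityMap(np.zeros((8, 8, 8)))
    vol = voxelize_model(_model([]), frame)
    assert vol.grid.sum() == 0


def test_single_atom_sphere_is_19_voxels():
    """Radius 1.5 A on a 1 A grid: offsets with squared distance <= 2.25."""
    frame = DensityMap(np.zeros((9, 9, 9)))
    vol = voxelize_model(_model([(4.0, 4.0, 4.0)]), frame, radius=1.5)
    assert int(vol.grid.sum()) == 19
    # brute-force enumeration of integer offsets
    count = sum(
        1
        for dx in range(-2, 3)
        for dy in range(-2, 3)
        for dz in range(-2, 3)
        if dx * dx + dy * dy + dz * dz <= 2.25
    )
    assert count == 19


def test_atom_outside_frame_skipped():
    frame = DensityMap(np.zeros((4, 4, 4)))
    vol = voxelize_model(_model([(50.0, 50.0, 50.0)]), frame)
    assert vol.grid.sum() == 0
    assert vol.skipped_atoms == 1


def test_hydrogens_excluded_by_default():
    frame = DensityMap(np.zeros((8, 8, 8)))
    vol = voxelize_model(_model([(4.0, 4.0, 4.0)], element="H"), frame)
    assert vol.grid.sum() == 0


# ---------------------------------------------------------------------------
# projections


def test_axis_projection_cube():
    img = project_volume(np.ones((2, 2, 2)), "Z")
    np.testing.assert_array_equal(img, np.full((2, 2), 2.0))


def test_projection_empty_volume():
    img = project_volume(np.zeros((3, 3, 3)), "X")
    assert img.sum() == 0


def test_diagonal_projection_single_voxel():
    vol = np.zeros((3, 3, 3))
    vol[0, 0, 0] = 1.0
    img = project_volume(vol, "D_xy")
    assert (img != 0).sum() == 1
    assert img[2, 0] == 1.0  # x - y + (ny - 1) = 2


@pytest.mark.parametrize("direction", DIRECTIONS)
@pytest.mark.parametrize("seed", [0, 1])
def test_projection_matches_brute_force(direction, seed):
    rng = np.random.default_rng(seed)
    vol = rng.integers(0, 2, size=(5, 6, 7)).astype(float)
    np.testing.assert_array_equal(
        project_volume(vol, direction), brute_projection(vol, direction)
    )


def test_unknown_direction_rejected():
    with pytest.raises(UsageError):
        project_volume(np.zeros((2, 2, 2)), "Q")


# ---------------------------------------------------------------------------
# IoU / Dice


def test_iou_examples():
    a = np.zeros((4, 4), dtype=bool)
    b = np.zeros((4, 4), dtype=bool)
    a[0, :4] = True  # |A| = 4
    b[0, 2:] = True
    b[1, :2] = True  # |B| = 4, overlap 2
    iou, dice = binary_iou(a, b)
    assert iou == pytest.approx(2 / 6)
    assert dice == pytest.approx(2 / 8)
    assert binary_iou(a, a) == (1.0, 0.5)  # identical masks: iou 1, dice-like 1/2
    disjoint = np.zeros_like(a)
    disjoint[3, :] = True
    assert binary_iou(a, disjoint)[0] == 0.0
    assert binary_iou(np.zeros_like(a), np.zeros_like(a)) == (1.0, 1.0)
    assert binary_iou(a, np.zeros_like(a)) == (0.0, 0.0)


def test_iou_shape_mismatch():
    with pytest.raises(UsageError):
        binary_iou(np.zeros((2, 2)), np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# VOF


def test_vof_identical_volumes_is_one(rng):
    grid = rng.integers(0, 2, size=(6, 6, 6)).astype(np.uint8)
    grid[2, 3, 3] = 1  # ensure non-empty
    norm_map = DensityMap(grid.astype(float))
    fs = vof_score(norm_map, BinaryVolume(grid))
    assert fs.vof == 1.0
    assert fs.dice_like == pytest.approx(0.5)


def test_vof_empty_model_is_zero(rng):
    grid = np.zeros((6, 6, 6))
    grid[2:4, 2:4, 2:4] = 1.0
    fs = vof_score(DensityMap(grid), BinaryVolume(np.zeros((6, 6, 6))))
    assert fs.vof == 0.0


@pytest.mark.parametrize("seed", range(4))
def test_vof_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    map_grid = rng.integers(0, 2, size=(7, 8, 6)).astype(float)
    model_grid = rng.integers(0, 2, size=(7, 8, 6)).astype(np.uint8)
    fs = vof_score(DensityMap(map_grid), BinaryVolume(model_grid))
    ious, vof, dice = brute_vof(map_grid, model_grid)
    for d in DIRECTIONS:
        assert fs.iou[d] == pytest.approx(ious[d], abs=0)
    assert fs.vof == pytest.approx(vof, abs=0)
    assert fs.dice_like == pytest.approx(dice, abs=0)


def test_vof_monotone_in_model_coverage(rng):
    """Nested models: covering more of the map never lowers the VOF."""
    grid = np.zeros((10, 10, 10))
    grid[2:8, 2:8, 2:8] = 1.0
    norm_map = DensityMap(grid)
    prev = -1.0
    for extent in (3, 5, 8):
        model_grid = np.zeros((10, 10, 10), dtype=np.uint8)
        model_grid[2:extent, 2:extent, 2:extent] = 1
        fs = vof_score(norm_map, BinaryVolume(model_grid))
        assert fs.vof >= prev
        prev = fs.vof


def test_validate_pairs_thresholding():
    frame_grid = np.zeros((9, 9, 9))
    frame_grid[3:6, 3:6, 3:6] = 1.0
    norm_map = DensityMap(frame_grid)
    good = _model([(4.0, 4.0, 4.0)])  # covers the blob
    bad = _model([(1.0, 1.0, 1.0)])  # misses it
    pairs = [
        (norm_map, good, make_entry("EMD-GOOD")),
        (norm_map, bad, make_entry("EMD-BAD")),
    ]
    scores = {
        e.emdb_id: vof_score(m, mod, radius=1.5).vof for m, mod, e in pairs
    }
    threshold = (scores["EMD-GOOD"] + scores["EMD-BAD"]) / 2
    kept, report, _ = validate_pairs(pairs, threshold)
    assert [e.emdb_id for _, _, e in kept] == ["EMD-GOOD"]
    assert "EMD-BAD" in report.stage("mmf").discarded
    # threshold zero discards nothing
    kept_all, _, _ = validate_pairs(pairs, 0.0)
    assert len(kept_all) == 2
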