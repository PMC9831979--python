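"""Round-trip, binarisation and compatibility validation for NIfTI I/O."""

import nibabel as nib
import numpy as np
import pandas as pd
import pytest

from muscleq import (
    AcquisitionGeometry,
    DataError,
    GeometryError,
    IncompatibilityError,
    InputError,
    LabelMask,
    load_case,
    read_manifest,
    save_mask,
    save_volume,
)
from muscleq.image_io import LC_SEMANTICS, load_mask

GEOM = AcquisitionGeometry(spacing=(0.14, 0.14, 1.0), shape=(12, 10, 4))


def _write_triplet(tmp_path, fat, water, mask, spacing=(0.14, 0.14, 1.0)):
    geom = AcquisitionGeometry(spacing=spacing, shape=tuple(fat.shape))
    paths = {}
    for name, data in (("fat", fat), ("water", water)):
        paths[name] = save_volume(data, geom, tmp_path / f"{name}.nii.gz")
    mask_geom = AcquisitionGeometry(spacing=spacing, shape=tuple(mask.shape))
    img = nib.Nifti1Image(mask.astype(np.uint8), np.diag(list(spacing) + [1.0]))
    paths["mask"] = tmp_path / "mask.nii.gz"
    nib.save(img, str(paths["mask"]))
    return paths


def test_case_roundtrip_preserves_values_and_spacing(tmp_path, rng):
    fat = rng.uniform(0, 500, GEOM.shape).astype(np.float32)
    water = rng.uniform(0, 500, GEOM.shape).astype(np.float32)
    mask = (rng.random(GEOM.shape) > 0.5).astype(np.uint8)
    paths = _write_triplet(tmp_path, fat, water, mask)
    pair, lc = load_case(paths["fat"], paths["water"], paths["mask"])
    np.testing.assert_array_equal(pair.fat, fat)
    np.testing.assert_array_equal(pair.water, water)
    np.testing.assert_array_equal(lc.data, mask)
    assert np.allclose(pair.geometry.spacing, (0.14, 0.14, 1.0), atol=1e-6)


def test_mask_binarization_of_itk_style_labels(tmp_path, rng):
    fat = np.ones(GEOM.shape, np.float32)
    mask = np.zeros(GEOM.shape, np.uint8)
    mask[2:5, 3:6, 1:3] = 7  # arbitrary nonzero label as ITK-SNAP would store
    paths = _write_triplet(tmp_path, fat, fat, mask)
    _, lc = load_case(paths["fat"], paths["water"], paths["mask"])
    assert set(np.unique(lc.data)) == {0, 1}
    np.testing.assert_array_equal(lc.data != 0, mask != 0)


def test_grid_mismatch_raises_and_names_file(tmp_path):
    fat = np.zeros((8, 8, 4), np.float32)
    water = np.zeros((8, 8, 3), np.float32)
    geom_f = AcquisitionGeometry(spacing=(0.14, 0.14, 1.0), shape=(8, 8, 4))
    geom_w = AcquisitionGeometry(spacing=(0.14, 0.14, 1.0), shape=(8, 8, 3))
    f = save_volume(fat, geom_f, tmp_path / "f.nii.gz")
    w = save_volume(water, geom_w, tmp_path / "w.nii.gz")
    m = save_mask(LabelMask(np.ones((8, 8, 4), np.uint8), geom_f), tmp_path / "m.nii.gz")
    with pytest.raises(IncompatibilityError, match="w.nii.gz"):
        load_case(f, w, m)


def test_spacing_mismatch_beyond_tolerance_raises(tmp_path):
    shape = (8, 8, 4)
    fat = np.zeros(shape, np.float32)
    f = save_volume(fat, AcquisitionGeometry((0.14, 0.14, 1.0), shape), tmp_path / "f.nii.gz")
    w = save_volume(fat, AcquisitionGeometry((0.15, 0.14, 1.0), shape), tmp_path / "w.nii.gz")
    m = save_mask(
        LabelMask(np.ones(shape, np.uint8), AcquisitionGeometry((0.14, 0.14, 1.0), shape)),
        tmp_path / "m.nii.gz",
    )
    with pytest.raises(IncompatibilityError, match="spacing"):
        load_case(f, w, m)


def test_negative_voxels_rejected(tmp_path):
    shape = (8, 8, 4)
    geom = AcquisitionGeometry((0.14, 0.14, 1.0), shape)
    fat = np.full(shape, -1.0, np.float32)
    f = save_volume(fat, geom, tmp_path / "f.nii.gz")
    w = save_volume(np.zeros(shape, np.float32), geom, tmp_path / "w.nii.gz")
    m = save_mask(LabelMask(np.ones(shape, np.uint8), geom), tmp_path / "m.nii.gz")
    with pytest.raises(DataError, match="negative"):
        load_case(f, w, m)


def test_missing_spacing_is_an_error_not_a_default():
    """Geometry never defaults silently: a header whose zooms come back
    non-positive (nibabel repairs literal zeros upstream, but other
    sources may not) is rejected rather than assumed to be 1 mm."""

    class _NoSpacingHeader:
        def get_zooms(self):
            return (0.0, 0.0, 0.0)

    class _NoSpacingImage:
        header = _NoSpacingHeader()
        shape = (8, 8, 4)

    from muscleq.image_io import _geometry_from_header

    with pytest.raises(GeometryError, match="spacing"):
        _geometry_from_header(_NoSpacingImage(), "nospacing.nii")
    with pytest.raises(GeometryError):
        AcquisitionGeometry(spacing=(0.0, 0.14, 1.0), shape=(8, 8, 4))


def test_empty_mask_roundtrip(tmp_path):
    geom = AcquisitionGeometry((0.14, 0.14, 1.0), (8, 8, 4))
    mask = LabelMask(np.zeros((8, 8, 4), np.uint8), geom, LC_SEMANTICS)
    path = save_mask(mask, tmp_path / "empty.nii.gz")
    back = load_mask(path, LC_SEMANTICS)
    assert back.count(1) == 0
    np.testing.assert_array_equal(back.data, mask.data)


def test_mask_spacing_survives_roundtrip_to_1e6_mm(tmp_path, small_control_phantom):
    _, _, lc, _ = small_control_phantom
    path = save_mask(lc, tmp_path / "lc.nii.gz")
    back = load_mask(path, LC_SEMANTICS)
    assert np.allclose(back.geometry.spacing, lc.geometry.spacing, atol=1e-6)


def test_label_outside_semantics_rejected():
    with pytest.raises(InputError, match="semantics"):
        LabelMask(np.full((4, 4, 2), 5, np.uint8), AcquisitionGeometry((1, 1, 1), (4, 4, 2)))


def test_manifest_requires_columns_and_rows(tmp_path):
    p = tmp_path / "m.csv"
    pd.DataFrame({"animal_id": ["a"], "group": ["g"]}).to_csv(p, index=False)
    with pytest.raises(InputError, match="missing columns"):
        read_manifest(p)
    pd.DataFrame(
        columns=["animal_id", "group", "fat_path", "water_path", "mask_path"]
    ).to_csv(p, index=False)
    with pytest.raises(InputError, match="no cases"):
        read_manifest(p)
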