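import json

import numpy as np
import pytest

from cardiofat3d.mtr import MTRatioMap
from cardiofat3d.pdffmap import PDFFMap, TissueMask
from cardiofat3d.quantify import (LABEL_FAT, LABEL_OUTSIDE, LABEL_TISSUE,
                                  PipelineConfig, ROIBox, classify_fat_voxels,
                                  overlay_composite, quantify_box,
                                  quantify_labels, run_pipeline)


def _pdff_with(values, mask=None):
    values = np.asarray(values, dtype=float)
    return PDFFMap(values=values, mask_applied=mask is not None, te_ref_ms=3.08)


def test_classification_boundary_convention():
    values = np.array([10.0, 40.0, 41.0, 90.0]).reshape(4, 1, 1)
    mask = TissueMask(mask=np.ones((4, 1, 1), bool), noise_sd=0.0, k=3.0)
    labels = classify_fat_voxels(_pdff_with(values), mask, threshold_pct=40.0)
    np.testing.assert_array_equal(
        labels.ravel(), [LABEL_TISSUE, LABEL_TISSUE, LABEL_FAT, LABEL_FAT])


def test_classification_threshold_100_no_fat():
    values = np.full((3, 3, 3), 100.0)
    mask = TissueMask(mask=np.ones((3, 3, 3), bool), noise_sd=0.0, k=3.0)
    labels = classify_fat_voxels(_pdff_with(values), mask, threshold_pct=100.0)
    assert (labels == LABEL_FAT).sum() == 0
    with pytest.raises(ValueError):
        classify_fat_voxels(_pdff_with(values), mask, threshold_pct=0.0)


def test_classification_matches_phantom_truth(default_truth):
    """Noise-free: the fat-label set equals the truth fat-fraction > T set."""
    truth = default_truth
    pdff = PDFFMap(values=np.where(truth.foreground, truth.fat_fraction, np.nan),
                   mask_applied=True, te_ref_ms=3.08)
    mask = TissueMask(mask=truth.foreground, noise_sd=0.0, k=3.0)
    labels = classify_fat_voxels(pdff, mask, threshold_pct=40.0)
    np.testing.assert_array_equal(labels == LABEL_FAT,
                                  truth.foreground & (truth.fat_fraction > 40.0))
    assert np.all((labels == LABEL_OUTSIDE) == truth.background)


def _labels_with_counts(n_fat, n_tissue, shape):
    labels = np.zeros(shape, dtype=np.int8)
    flat = labels.ravel()
    flat[:n_fat] = LABEL_FAT
    flat[n_fat:n_fat + n_tissue] = LABEL_TISSUE
    return flat.reshape(shape)


def test_quantify_box_printed_count_worked_example():
    """68,032 fat voxels at 200 um isotropic -> 0.54 cm^3 of fat."""
    shape = (50, 50, 50)
    labels = _labels_with_counts(68032, 20000, shape)
    box = ROIBox("rvot", (0.0, 0.0, 0.0), (10.0, 10.0, 10.0))
    row = quantify_box(labels, box, (0.2, 0.2, 0.2))
    assert row["fat_voxels"] == 68032
    assert round(row["fat_cm3"], 2) == 0.54


def test_quantify_box_all_fat_cube():
    labels = np.full((10, 10, 10), LABEL_FAT, dtype=np.int8)
    box = ROIBox("cube", (0.0, 0.0, 0.0), (10.0, 10.0, 10.0))
    row = quantify_box(labels, box, (1.0, 1.0, 1.0))
    assert row["fat_cm3"] == pytest.approx(1.0)
    assert row["fat_ratio_pct"] == 100.0
    assert row["tissue_cm3"] == 0.0


def test_quantify_empty_box_warns_zero_row():
    labels = np.zeros((10, 10, 10), dtype=np.int8)
    box = ROIBox("empty", (0.0, 0.0, 0.0), (5.0, 5.0, 5.0))
    with pytest.warns(UserWarning):
        row = quantify_box(labels, box, (1.0, 1.0, 1.0))
    assert row["total_cm3"] == 0.0 and row["fat_ratio_pct"] == 0.0


def test_box_geometry_and_errors():
    box = ROIBox("b", (1.1, 0.0, 2.0), (2.0, 3.0, 1.0))
    lo, hi = box.voxel_bounds((1.0, 1.0, 1.0), (10, 10, 10))
    assert lo == (1, 0, 2) and hi == (4, 3, 3)
    with pytest.raises(ValueError):
        ROIBox("bad", (0.0, 0.0, 0.0), (0.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        ROIBox("out", (100.0, 0.0, 0.0), (1.0, 1.0, 1.0)).voxel_bounds(
            (1.0, 1.0, 1.0), (10, 10, 10))


def test_conservation_and_tiling():
    rng = np.random.default_rng(0)
    labels = rng.integers(0, 3, (8, 8, 8)).astype(np.int8)
    spacing = (0.5, 0.5, 0.5)
    report = quantify_labels(labels, spacing)
    whole = report.iloc[0]
    assert whole["fat_cm3"] + whole["tissue_cm3"] == pytest.approx(whole["total_cm3"])
    boxes = [ROIBox(f"tile{i}{j}", (2.0 * i, 2.0 * j, 0.0), (2.0, 2.0, 4.0))
             for i in range(2) for j in range(2)]
    tiled = quantify_labels(labels, spacing, boxes)
    assert tiled.iloc[1:]["fat_voxels"].sum() == whole["fat_voxels"]


def test_fat_count_monotone_in_threshold(default_truth):
    truth = default_truth
    pdff = PDFFMap(values=np.where(truth.foreground, truth.fat_fraction, np.nan),
                   mask_applied=True, te_ref_ms=3.08)
    mask = TissueMask(mask=truth.foreground, noise_sd=0.0, k=3.0)
    counts = [(classify_fat_voxels(pdff, mask, t) == LABEL_FAT).sum()
              for t in (5.0, 40.0, 50.0, 90.0, 100.0)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_overlay_composite_labels():
    pdff = _pdff_with(np.array([80.0, 10.0, 10.0]).reshape(3, 1, 1))
    mtr = MTRatioMap(values=np.array([90.0, 90.0, 50.0]).reshape(3, 1, 1),
                     valid=np.ones((3, 1, 1), bool))
    base, overlay, labels, meta = overlay_composite(pdff, mtr, threshold_pct=40.0)
    assert labels[0, 0, 0] == 2  # fat
    assert labels[1, 0, 0] == 1  # high MTR without fat
    assert labels[2, 0, 0] == 0  # other
    assert overlay[0, 0, 0] == 80.0 and np.isnan(overlay[1, 0, 0])
    assert meta["high_mtr_pct"] == 70.0
    with pytest.raises(ValueError):
        overlay_composite(pdff, MTRatioMap(values=np.zeros((2, 1, 1)),
                                           valid=np.ones((2, 1, 1), bool)), 40.0)


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    cfg = PipelineConfig(out_dir=str(out / "run"), seed=5, noise_sd=0.001,
                         mt_noise_sd=0.02, relaxometry_noise_sd=0.1,
                         save_nifti=True,
                         rois=[{"name": "rim", "origin_mm": (0.4, 0.4, 0.4),
                                "size_mm": (2.0, 2.0, 2.0)}])
    run_pipeline(cfg)
    return cfg, out / "run"


def test_pipeline_writes_artifact_set(pipeline_run):
    _, out = pipeline_run
    for name in ("water.nii.gz", "fat.nii.gz", "fieldmap_hz.nii.gz", "pdff.nii.gz",
                 "mask.nii.gz", "mtr.nii.gz", "report.csv", "runlog.json",
                 "histogram_model.json"):
        assert (out / name).exists(), name


def test_pipeline_rerun_is_byte_identical(pipeline_run, tmp_path):
    cfg, out = pipeline_run
    cfg2 = cfg.model_copy(update={"out_dir": str(tmp_path / "rerun")})
    run_pipeline(cfg2)
    assert (tmp_path / "rerun" / "report.csv").read_bytes() == \
        (out / "report.csv").read_bytes()


def test_pipeline_without_mt_flags_absence(tmp_path):
    cfg = PipelineConfig(out_dir=str(tmp_path / "nomt"), seed=5, with_mt=False,
                         save_nifti=False)
    run_pipeline(cfg)
    log = json.loads((tmp_path / "nomt" / "runlog.json").read_text())
    assert "skipped" in log["stages"]["mtr"]
    assert not (tmp_path / "nomt" / "mtr.nii.gz").exists()
    assert (tmp_path / "nomt" / "report.csv").exists()


def test_pipeline_end_to_end_fat_ratio_matches_truth(tmp_path):
    """Noise-free phantom: reported whole-volume fat ratio within 1 pp of
    the ground-truth ratio at the same threshold."""
    from cardiofat3d.phantom import PhantomConfig, make_truth

    cfg = PipelineConfig(out_dir=str(tmp_path / "exact"), seed=2, noise_sd=0.0,
                         mt_noise_sd=0.0, relaxometry_noise_sd=0.0,
                         save_nifti=False)
    run_pipeline(cfg)
    log = json.loads((tmp_path / "exact" / "runlog.json").read_text())
    threshold = log["stages"]["thresholds"]["threshold_pct"]
    reported = log["stages"]["quantify"]["whole_volume_fat_ratio_pct"]
    truth = make_truth(PhantomConfig(seed=2))
    fg = truth.foreground
    expected = 100.0 * np.mean(truth.fat_fraction[fg] > threshold)
    assert reported == pytest.approx(expected, abs=1.0)
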