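"""Dose metrics and contour-substitution difference statistics."""

import numpy as np
import pytest

from stratseg import (
    DoseGrid,
    Mask,
    StructureSet,
    diff_clinical,
    diff_direct,
    dvh,
    max_dose,
    mean_dose,
)
from stratseg.dosimetry import resample_mask_to_dose


def uniform_dose(value=50.0, shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0)):
    return DoseGrid(np.full(shape, value), spacing)


def two_voxel_mask(shape=(8, 8, 8), spacing=(2.0, 2.0, 2.0)):
    m = np.zeros(shape, dtype=np.uint8)
    m[1, 1, 1] = 1
    m[1, 1, 2] = 1
    return Mask(m, spacing)


def test_mean_and_max_dose_simple_cases():
    dose = uniform_dose(50.0)
    mask = two_voxel_mask()
    assert mean_dose(mask, dose) == 50.0
    assert max_dose(mask, dose) == 50.0

    grad = np.zeros((8, 8, 8))
    grad[1, 1, 1], grad[1, 1, 2] = 40.0, 60.0
    dose2 = DoseGrid(grad, (2.0, 2.0, 2.0))
    assert mean_dose(mask, dose2) == pytest.approx(50.0)
    assert max_dose(mask, dose2) == pytest.approx(60.0)

    single = np.zeros((8, 8, 8), dtype=np.uint8)
    single[3, 4, 5] = 1
    assert max_dose(Mask(single, (2.0, 2.0, 2.0)), dose2) == grad[3, 4, 5]


def test_dose_metrics_match_bruteforce_on_random_grids():
    rng = np.random.default_rng(0)
    for _ in range(25):
        dose_data = rng.uniform(0, 70, size=(16, 16, 16))
        dose = DoseGrid(dose_data, (1.0, 1.0, 1.0))
        m = (rng.random((16, 16, 16)) < 0.2).astype(np.uint8)
        if not m.any():
            continue
        mask = Mask(m, (1.0, 1.0, 1.0))
        sel = m.astype(bool)
        assert mean_dose(mask, dose) == pytest.approx(dose_data[sel].mean(), abs=1e-9)
        assert max_dose(mask, dose) == pytest.approx(dose_data[sel].max(), abs=1e-9)


def test_mask_resampling_between_grids():
    """A mask on a fine 1 mm grid lands on the matching coarse 2 mm dose
    voxels under nearest-neighbour transfer in physical coordinates."""
    fine = np.zeros((8, 8, 8), dtype=np.uint8)
    fine[0:2, 0:2, 0:2] = 1  # physical cube [0, 2) mm
    mask = Mask(fine, (1.0, 1.0, 1.0))
    dose = DoseGrid(np.arange(64).reshape(4, 4, 4).astype(float), (2.0, 2.0, 2.0))
    sel = resample_mask_to_dose(mask, dose)
    assert sel[0, 0, 0] and sel.sum() >= 1
    # dose voxel centres at 4 mm sit outside the 2 mm cube
    assert not sel[2:].any()
    empty = Mask(np.zeros((8, 8, 8), dtype=np.uint8), (1.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="empty"):
        mean_dose(empty, dose)


def test_dvh_monotone_with_unit_start():
    rng = np.random.default_rng(1)
    dose = DoseGrid(rng.uniform(0, 60, size=(10, 10, 10)), (2, 2, 2))
    mask = Mask((rng.random((10, 10, 10)) < 0.3).astype(np.uint8), (2, 2, 2))
    curve = dvh(mask, dose, bin_width_gy=1.0)
    assert curve.fraction_volume[0] == 1.0
    assert (np.diff(curve.fraction_volume) <= 1e-12).all()
    assert curve.fraction_volume[-1] == 0.0


def test_dvh_step_function_for_uniform_dose():
    dose = uniform_dose(30.0)
    mask = two_voxel_mask()
    curve = dvh(mask, dose, bin_width_gy=5.0)
    for edge, frac in zip(curve.dose_edges_gy, curve.fraction_volume):
        assert frac == (1.0 if edge <= 30.0 else 0.0)
    with pytest.raises(ValueError, match="bin"):
        dvh(mask, dose, bin_width_gy=0.0)


# -- contour-substitution differences ---------------------------------------


def _sets_and_dose():
    ref_mask = two_voxel_mask()
    sub = np.zeros((8, 8, 8), dtype=np.uint8)
    sub[1, 1, 2], sub[1, 1, 3] = 1, 1  # shifted by one dose voxel
    sub_mask = Mask(sub, (2.0, 2.0, 2.0))
    dose_data = np.zeros((8, 8, 8))
    dose_data[1, 1, 1:5] = [40.0, 60.0, 20.0, 10.0]
    dose = DoseGrid(dose_data, (2.0, 2.0, 2.0))
    ref = StructureSet.from_masks({"brainstem": ref_mask})
    subst = StructureSet.from_masks({"brainstem": sub_mask})
    return ref, subst, dose


def test_diff_direct_identity_and_hand_computed_value():
    ref, subst, dose = _sets_and_dose()
    report0 = diff_direct(ref, ref, dose)
    assert report0.per_oar["brainstem"]["diff_mean_pct"] == 0.0
    assert report0.per_oar["brainstem"]["diff_max_pct"] == 0.0

    report = diff_direct(ref, subst, dose)
    # ref mean (40+60)/2 = 50, sub mean (60+20)/2 = 40 -> -20%
    assert report.per_oar["brainstem"]["diff_mean_pct"] == pytest.approx(-20.0)
    # ref max 60, sub max 60 -> 0%
    assert report.per_oar["brainstem"]["diff_max_pct"] == pytest.approx(0.0)
    assert report.mode == "direct"


def test_diff_direct_ten_percent_example():
    dose_data = np.zeros((8, 8, 8))
    dose_data[1, 1, 1:3] = 50.0
    dose_data[1, 1, 3] = 60.0
    dose_data[1, 1, 0] = 50.0
    dose = DoseGrid(dose_data, (2.0, 2.0, 2.0))
    ref = StructureSet.from_masks({"parotid_left": two_voxel_mask()})  # mean 50
    sub = np.zeros((8, 8, 8), dtype=np.uint8)
    sub[1, 1, 2], sub[1, 1, 3] = 1, 1  # mean (50+60)/2 = 55
    subst = StructureSet.from_masks({"parotid_left": Mask(sub, (2.0, 2.0, 2.0))})
    report = diff_direct(ref, subst, dose)
    assert report.per_oar["parotid_left"]["diff_mean_pct"] == pytest.approx(10.0)


def test_diff_clinical_identity_and_hand_value():
    ref, subst, dose_replanned = _sets_and_dose()
    report0 = diff_clinical(ref, ref, dose_replanned)
    assert report0.per_oar["brainstem"]["diff_mean_pct"] == 0.0
    assert report0.mode == "clinical"
    # both terms evaluated on the substitute (replanned) grid
    report = diff_clinical(ref, subst, dose_replanned)
    assert report.per_oar["brainstem"]["diff_mean_pct"] == pytest.approx(
        (40.0 - 50.0) / 50.0 * 100.0
    )


def test_percentage_diffs_invariant_to_dose_scaling():
    ref, subst, dose = _sets_and_dose()
    scaled = DoseGrid(dose.data * 3.7, dose.spacing, dose.origin)
    r1 = diff_direct(ref, subst, dose)
    r2 = diff_direct(ref, subst, scaled)
    assert r1.per_oar["brainstem"]["diff_mean_pct"] == pytest.approx(
        r2.per_oar["brainstem"]["diff_mean_pct"]
    )
    assert r1.per_oar["brainstem"]["diff_max_pct"] == pytest.approx(
        r2.per_oar["brainstem"]["diff_max_pct"]
    )


def test_zero_reference_dose_raises():
    ref = StructureSet.from_masks({"brainstem": two_voxel_mask()})
    zero = DoseGrid(np.zeros((8, 8, 8)), (2.0, 2.0, 2.0))
    with pytest.raises(ZeroDivisionError, match="brainstem"):
        diff_direct(ref, ref, zero)


def test_summary_reports_exceedance_fractions():
    ref, subst, dose = _sets_and_dose()
    summary = diff_direct(ref, subst, dose).summary()
    assert summary["n_oars"] == 1
    assert summary["abs_mean_of_diff_mean_pct"] == pytest.approx(20.0)
    assert summary["frac_mean_diff_gt_10pct"] == 1.0
    assert summary["frac_mean_diff_gt_30pct"] == 0.0
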