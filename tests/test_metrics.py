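"""Segmentation metrics against exhaustive brute-force oracles.

The oracle extracts surface voxels by explicit 6-neighbour inspection and
computes every pairwise physical distance; the implementation must agree to
numerical precision on small random masks.
"""

import numpy as np
import pytest

from stratseg import Mask, StructureSet, asd, dsc, evaluate_case, hausdorff, perturb_mask
from stratseg.core import GeometryError


# -- independent oracle -----------------------------------------------------


def oracle_surface(mask: np.ndarray) -> np.ndarray:
    pts = []
    shape = mask.shape
    for z, y, x in np.argwhere(mask > 0):
        on_border = z in (0, shape[0] - 1) or y in (0, shape[1] - 1) or x in (0, shape[2] - 1)
        exposed = on_border
        if not exposed:
            for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                if mask[z + dz, y + dy, x + dx] == 0:
                    exposed = True
                    break
        if exposed:
            pts.append((z, y, x))
    return np.asarray(pts, dtype=float)


def oracle_metrics(a: np.ndarray, b: np.ndarray, spacing) -> dict:
    sa, sb = oracle_surface(a), oracle_surface(b)
    sp = np.asarray(spacing)
    d = np.sqrt(((sa[:, None, :] * sp - sb[None, :, :] * sp) ** 2).sum(-1))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    return {
        "hd": max(d_ab.max(), d_ba.max()),
        "hd95": max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)),
        "asd": 0.5 * (d_ab.mean() + d_ba.mean()),
    }


def random_mask(rng, shape=(12, 12, 12), p=0.12) -> np.ndarray:
    m = (rng.random(shape) < p).astype(np.uint8)
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = 1
    return m


# -- direct examples --------------------------------------------------------


def test_dsc_identical_disjoint_and_half():
    spacing = (1.0, 1.0, 1.0)
    a = np.zeros((4, 4, 4), dtype=np.uint8)
    a[1, 1, :2] = 1
    a[1, 2, :2] = 1  # |A| = 4
    b = np.zeros_like(a)
    b[1, 1, :2] = 1
    b[2, 2, :2] = 1  # |B| = 4, overlap 2
    ma, mb = Mask(a, spacing), Mask(b, spacing)
    assert dsc(ma, ma) == 1.0
    assert dsc(ma, mb) == pytest.approx(0.5)
    empty = Mask(np.zeros_like(a), spacing)
    assert dsc(ma, empty) == 0.0
    assert dsc(empty, empty) == 1.0


def test_single_voxels_three_mm_apart():
    a = np.zeros((5, 5, 5), dtype=np.uint8)
    b = np.zeros_like(a)
    a[2, 2, 2] = 1
    b[2, 2, 3] = 1  # one voxel along x at 3 mm spacing
    ma, mb = Mask(a, (1.0, 1.0, 3.0)), Mask(b, (1.0, 1.0, 3.0))
    hd, hd95 = hausdorff(ma, mb)
    assert hd == pytest.approx(3.0)
    assert hd95 == pytest.approx(3.0)
    assert asd(ma, mb) == pytest.approx(3.0)


def test_identical_masks_zero_distances():
    rng = np.random.default_rng(0)
    m = Mask(random_mask(rng), (1.0, 2.0, 1.5))
    hd, hd95 = hausdorff(m, m)
    assert hd == 0.0 and hd95 == 0.0 and asd(m, m) == 0.0


def test_empty_mask_distances_raise():
    m = Mask(np.ones((3, 3, 3), dtype=np.uint8), (1, 1, 1))
    empty = Mask(np.zeros((3, 3, 3), dtype=np.uint8), (1, 1, 1))
    with pytest.raises(ValueError, match="empty"):
        hausdorff(m, empty)
    with pytest.raises(ValueError, match="empty"):
        asd(empty, m)


def test_geometry_mismatch_raises():
    a = Mask(np.ones((3, 3, 3), dtype=np.uint8), (1, 1, 1))
    b = Mask(np.ones((3, 3, 3), dtype=np.uint8), (2, 1, 1))
    with pytest.raises(GeometryError):
        dsc(a, b)


# -- oracle equivalence and properties --------------------------------------


@pytest.mark.parametrize("spacing", [(1.0, 1.0, 1.0), (2.5, 1.0, 1.5)])
def test_metrics_match_bruteforce_oracle(spacing):
    rng = np.random.default_rng(42)
    for _ in range(50):
        a = random_mask(rng)
        b = random_mask(rng)
        ma, mb = Mask(a, spacing), Mask(b, spacing)
        ref = oracle_metrics(a, b, spacing)
        hd, hd95 = hausdorff(ma, mb)
        assert hd == pytest.approx(ref["hd"], abs=1e-9)
        assert hd95 == pytest.approx(ref["hd95"], abs=1e-9)
        assert asd(ma, mb) == pytest.approx(ref["asd"], abs=1e-9)
        assert hd95 <= hd + 1e-12


def test_symmetry_and_spacing_scaling():
    rng = np.random.default_rng(3)
    a, b = random_mask(rng), random_mask(rng)
    m1, m2 = Mask(a, (1, 1, 1)), Mask(b, (1, 1, 1))
    s1, s2 = Mask(a, (2, 2, 2)), Mask(b, (2, 2, 2))
    assert dsc(m1, m2) == dsc(m2, m1)
    assert hausdorff(m1, m2)[0] == pytest.approx(hausdorff(m2, m1)[0])
    assert asd(m1, m2) == pytest.approx(asd(m2, m1))
    # distances scale linearly with spacing; overlap does not change
    assert hausdorff(s1, s2)[0] == pytest.approx(2 * hausdorff(m1, m2)[0])
    assert asd(s1, s2) == pytest.approx(2 * asd(m1, m2))
    assert dsc(s1, s2) == pytest.approx(dsc(m1, m2))


def test_dsc_translation_invariance():
    rng = np.random.default_rng(5)
    a = random_mask(rng, shape=(10, 10, 10))
    b = random_mask(rng, shape=(10, 10, 10))
    big_a = np.zeros((14, 14, 14), dtype=np.uint8)
    big_b = np.zeros_like(big_a)
    big_a[2:12, 2:12, 2:12] = a
    big_b[2:12, 2:12, 2:12] = b
    shifted_a = np.roll(big_a, (1, 2, 1), axis=(0, 1, 2))
    shifted_b = np.roll(big_b, (1, 2, 1), axis=(0, 1, 2))
    assert dsc(Mask(big_a, (1, 1, 1)), Mask(big_b, (1, 1, 1))) == pytest.approx(
        dsc(Mask(shifted_a, (1, 1, 1)), Mask(shifted_b, (1, 1, 1)))
    )


# -- case evaluation --------------------------------------------------------


def test_evaluate_case_perfect_prediction(small_case, registry):
    _, _, ss = small_case
    report = evaluate_case(ss, ss, registry)
    assert len(report.per_oar) == 42
    for row in report.per_oar.values():
        assert row["dsc"] == 1.0
        assert row["hd_mm"] == 0.0 and row["asd_mm"] == 0.0
    means = report.stratum_means(registry)
    assert means["all"]["dsc"] == 1.0
    assert means["anchor"]["hd_mm"] == 0.0


def test_evaluate_case_skips_missing_names(small_case, registry):
    _, _, ss = small_case
    partial = StructureSet({n: ss[n] for n in ss.names()[:10]}, ss.grid)
    report = evaluate_case(partial, ss, registry)
    assert len(report.per_oar) == 10
    assert len(report.skipped) == 32
    with pytest.raises(ValueError, match="no common"):
        other = StructureSet({"pituitary": ss["brainstem"]}, ss.grid)
        evaluate_case(StructureSet({"brainstem": ss["brainstem"]}, ss.grid), other, registry)


def test_evaluate_case_perturbed_predictions_degrade(small_case, registry):
    _, _, ss = small_case
    pred = StructureSet(
        {n: perturb_mask(ss[n], 2.0, seed=i) for i, n in enumerate(ss.names()[:9])},
        ss.grid,
    )
    report = evaluate_case(pred, ss, registry)
    means = report.stratum_means(registry)
    assert means["anchor"]["dsc"] < 1.0
    assert means["anchor"]["asd_mm"] > 0.0
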