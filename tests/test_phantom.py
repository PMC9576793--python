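"""Phantom generator: determinism, geometry, contrast calibration, dose
fields, and contour perturbation."""

import numpy as np
import pytest

from stratseg import (
    DoseFieldConfig,
    Mask,
    PhantomConfig,
    StructureSpec,
    dsc,
    generate_dose_grid,
    generate_phantom,
    perturb_mask,
)



def tiny_config(seed=7, counts=(2, 2, 2)):
    return PhantomConfig(
        shape=(24, 32, 32),
        anchor=StructureSpec(counts[0], (5.0, 8.0), 300.0),
        mid=StructureSpec(counts[1], (3.0, 4.5), 100.0),
        small_hard=StructureSpec(counts[2], (2.0, 3.0), 30.0),
        seed=seed,
    )


def test_fixed_seed_reproducibility():
    v1, s1 = generate_phantom(tiny_config(seed=7))
    v2, s2 = generate_phantom(tiny_config(seed=7))
    assert np.array_equal(v1.data, v2.data)
    assert s1.names() == s2.names()
    for name in s1.names():
        assert np.array_equal(s1[name].data, s2[name].data)


def test_structure_count_and_nonempty():
    _, ss = generate_phantom(tiny_config())
    assert len(ss) == 6
    for name in ss.names():
        assert not ss[name].is_empty()


def test_masks_strictly_inside_volume_and_disjoint(small_case):
    _, vol, ss = small_case
    occupancy = np.zeros(vol.data.shape, dtype=int)
    for name in ss.names():
        m = ss[name].data
        # strictly inside: no foreground on any border plane
        assert m[0].sum() == m[-1].sum() == 0
        assert m[:, 0].sum() == m[:, -1].sum() == 0
        assert m[:, :, 0].sum() == m[:, :, -1].sum() == 0
        occupancy += m
    assert occupancy.max() == 1  # rejection sampling forbids overlap


def test_contrast_calibration_monte_carlo():
    """Mean in-mask intensity offset matches the configured anchor contrast
    within 3 standard errors over 20 seeds (the generator's own parameter)."""
    offsets = []
    for seed in range(20):
        config = PhantomConfig(
            shape=(24, 32, 32),
            anchor=StructureSpec(2, (5.0, 8.0), 300.0, contrast_spread=0.0),
            mid=StructureSpec(0, (3.0, 4.5), 100.0),
            small_hard=StructureSpec(2, (2.0, 3.0), 30.0, contrast_spread=0.0),
            noise_std=10.0,
            seed=seed,
        )
        vol, ss = generate_phantom(config)
        anchor_fg = np.zeros(vol.data.shape, dtype=bool)
        all_fg = np.zeros(vol.data.shape, dtype=bool)
        for name in ss.names():
            all_fg |= ss[name].data > 0
        for name in ("brainstem", "cerebellum"):
            anchor_fg |= ss[name].data > 0
        offsets.append(vol.data[anchor_fg].mean() - vol.data[~all_fg].mean())
    offsets = np.asarray(offsets)
    sem = offsets.std(ddof=1) / np.sqrt(len(offsets))
    assert abs(offsets.mean() - 300.0) <= 3 * sem + 1e-9


def test_stratum_contrast_ordering(small_case):
    _, vol, ss = small_case
    means = {}
    for stratum, names in (
        ("anchor", [n for n in ss.names()][:9]),
        ("small_hard", [n for n in ss.names()][-14:]),
    ):
        fg = np.zeros(vol.data.shape, dtype=bool)
        for n in names:
            fg |= ss[n].data > 0
        means[stratum] = vol.data[fg].mean()
    assert means["anchor"] > means["small_hard"]


def test_placement_error_when_volume_too_crowded():
    from stratseg import PlacementError

    config = PhantomConfig(
        shape=(12, 16, 16),
        anchor=StructureSpec(9, (7.0, 9.0), 300.0),
        mid=StructureSpec(0, (3.0, 4.0), 100.0),
        small_hard=StructureSpec(0, (2.0, 3.0), 30.0),
        seed=0,
    )
    with pytest.raises((PlacementError, ValueError)):
        generate_phantom(config)


# -- dose fields ------------------------------------------------------------


def test_dose_peak_at_centroid_and_bounds(small_case):
    _, _, ss = small_case
    target = ss["brainstem"]
    config = DoseFieldConfig(prescription_dose=70.0, background_dose=0.0)
    dose = generate_dose_grid(target, config)
    assert dose.data.min() >= 0.0
    # maximum attained at the voxel nearest the centroid
    centroid_mm = target.grid.voxel_centers_mm(
        np.argwhere(target.data > 0).mean(axis=0)
    )
    peak_idx = np.unravel_index(np.argmax(dose.data), dose.data.shape)
    peak_mm = dose.grid.voxel_centers_mm(np.asarray(peak_idx))
    assert np.all(np.abs(peak_mm - centroid_mm) <= np.asarray(dose.spacing))
    assert dose.data.max() <= 70.0 + 1e-9
    assert dose.data.max() >= 70.0 * np.exp(-3.0**2 / (2 * 20.0**2))  # within a voxel


def test_dose_closed_form_at_one_sigma():
    mask = np.zeros((21, 21, 21), dtype=np.uint8)
    mask[10, 10, 10] = 1
    target = Mask(mask, (2.0, 2.0, 2.0))
    config = DoseFieldConfig(
        prescription_dose=60.0,
        background_dose=10.0,
        falloff_sigma_mm=20.0,
        grid_spacing_mm=None,
    )
    dose = generate_dose_grid(target, config)
    assert dose.data[10, 10, 10] == pytest.approx(60.0, abs=1e-9)
    # voxel 10 grid steps along x = 20 mm = one sigma from the centroid
    expected = 10.0 + 0.6065306597 * 50.0
    assert dose.data[10, 10, 0] == pytest.approx(expected, rel=1e-6)
    assert dose.data.min() >= 10.0


def test_dose_requires_nonempty_target():
    empty = Mask(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
    with pytest.raises(ValueError, match="nonempty"):
        generate_dose_grid(empty, DoseFieldConfig())


# -- contour perturbation ---------------------------------------------------


def _sphere(radius_mm=20.0, spacing=2.0, half=16):
    n = 2 * half + 1
    ax = (np.arange(n) - half) * spacing
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return Mask((d2 <= radius_mm**2).astype(np.uint8), (spacing,) * 3)


def test_perturb_zero_magnitude_is_identity():
    m = _sphere()
    out = perturb_mask(m, 0.0, seed=3)
    assert np.array_equal(out.data, m.data)


def test_perturb_deterministic_given_seed():
    m = _sphere()
    a = perturb_mask(m, 2.0, seed=1)
    b = perturb_mask(m, 2.0, seed=1)
    c = perturb_mask(m, 2.0, seed=2)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_perturb_overlap_decreases_with_magnitude():
    """Mean DSC against the original is strictly larger at 1 mm than 3 mm
    over 50 seeds (Monte-Carlo monotonicity of the perturbation size)."""
    m = _sphere()
    d1 = np.mean([dsc(perturb_mask(m, 1.0, s), m) for s in range(50)])
    d3 = np.mean([dsc(perturb_mask(m, 3.0, s), m) for s in range(50)])
    assert d1 > d3
    assert d3 > 0.5  # still recognizably the same structure
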