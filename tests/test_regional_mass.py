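"""Mass arithmetic, apical selection, insertion angles and septum extraction."""

import math

import numpy as np
import pytest

from cardiomass import regional_mass as rm
from cardiomass.errors import (
    DegenerateContactError,
    EmptyAnatomyError,
    InsufficientCoverageError,
    NoSeptumError,
)
from cardiomass.mask_io import MaskStack
from cardiomass.simulate import PhantomSpec, generate_phantom_stack


def _stack(labels, spacing=(1.0, 1.0), thickness=8.0, gap=2.0):
    return MaskStack(np.asarray(labels), pixel_spacing=spacing,
                     slice_thickness=thickness, slice_gap=gap)


# ---------------------------------------------------------------------------
# slice_region_mass


@pytest.mark.parametrize(
    "count, spacing, expected",
    [
        (1000, (1.0, 1.0), 10.55),  # 10 cm^3 at density 1.055 g/cm^3
        (0, (1.0, 1.0), 0.0),
        (100, (1.0, 1.0), 1.055),  # exactly the density constant
    ],
)
def test_slice_region_mass_arithmetic(count, spacing, expected):
    stack = _stack(np.zeros((1, 2, 2), int), spacing=spacing)
    assert rm.slice_region_mass(count, stack) == pytest.approx(expected)


def test_slice_region_mass_thickness_only_mode():
    stack = _stack(np.zeros((1, 2, 2), int))
    assert rm.slice_region_mass(100, stack, "thickness_only") == pytest.approx(0.8 * 1.055)


def test_negative_count_rejected():
    with pytest.raises(ValueError):
        rm.slice_region_mass(-1, _stack(np.zeros((1, 2, 2), int)))


def test_mass_scales_with_pixel_area():
    labels = np.zeros((1, 10, 10), int)
    labels[0, 2:8, 2:8] = 2
    m1 = rm.total_lv_mass(_stack(labels, spacing=(1.0, 1.0)))
    m2 = rm.total_lv_mass(_stack(labels, spacing=(2.0, 2.0)))
    assert m2 == pytest.approx(4.0 * m1)


def test_no_myocardium_is_an_error():
    with pytest.raises(EmptyAnatomyError):
        rm.total_lv_mass(_stack(np.zeros((2, 4, 4), int)))


# ---------------------------------------------------------------------------
# apical selection


def test_apical_selection_takes_stack_tail():
    labels = np.zeros((10, 6, 6), int)
    labels[:, 2, 2] = 2
    assert rm.select_apical_slices(_stack(labels)) == [6, 7, 8, 9]


def test_apical_selection_skips_empty_tail_slices():
    labels = np.zeros((10, 6, 6), int)
    labels[:8, 2, 2] = 2  # two most apex-ward slices contain no myocardium
    assert rm.select_apical_slices(_stack(labels)) == [4, 5, 6, 7]


def test_exactly_four_slices_selects_all_and_apical_equals_total():
    labels = np.zeros((4, 6, 6), int)
    labels[:, 2, 2:4] = 2
    stack = _stack(labels)
    assert rm.select_apical_slices(stack) == [0, 1, 2, 3]
    assert rm.apical_mass(stack) == pytest.approx(rm.total_lv_mass(stack))


def test_insufficient_slices_raise():
    labels = np.zeros((3, 6, 6), int)
    labels[:, 2, 2] = 2
    with pytest.raises(InsufficientCoverageError):
        rm.select_apical_slices(_stack(labels))


def test_total_is_apical_plus_remainder(tapered_phantom):
    _, stack, _ = tapered_phantom
    picked = rm.select_apical_slices(stack)
    rest = [i for i in rm.myocardial_slice_indices(stack) if i not in picked]
    rest_count = int((stack.labels[rest] == 2).sum())
    assert rm.total_lv_mass(stack) == pytest.approx(
        rm.apical_mass(stack) + rm.slice_region_mass(rest_count, stack)
    )


def test_tapered_apical_mass_below_uniform_share(tapered_phantom):
    _, stack, _ = tapered_phantom
    assert rm.apical_mass(stack) < 0.4 * rm.total_lv_mass(stack)


# ---------------------------------------------------------------------------
# insertion angles


def _brute_force_interval(slice_labels, spacing):
    """Oracle: scan every pair of contact angles for the tightest cover."""
    from scipy import ndimage

    rv = slice_labels == 3
    contact = (slice_labels == 2) & ndimage.binary_dilation(rv, np.ones((3, 3), bool))
    lv = (slice_labels == 1) | (slice_labels == 2)
    ii, jj = np.nonzero(lv)
    cr, cc = ii.mean(), jj.mean()
    ci, cj = np.nonzero(contact)
    ang = np.degrees(np.arctan2((ci - cr) * spacing[0], (cj - cc) * spacing[1])) % 360.0
    best = None
    for a in ang:
        width = ((ang - a) % 360.0).max()
        if best is None or width < best[2]:
            best = (a, (a + width) % 360.0, width)
    return best


@pytest.mark.parametrize("arc", [(60.0, 150.0), (330.0, 30.0), (183.0, 268.0)])
def test_insertion_angles_match_bruteforce_and_truth(arc):
    spec = PhantomSpec(grid_shape=(160, 160), pixel_spacing=0.5, n_slices=1, septal_arc=arc)
    stack, _ = generate_phantom_stack(spec)
    got = rm.rv_insertion_angles(stack.labels[0], stack.pixel_spacing)
    oracle = _brute_force_interval(stack.labels[0], stack.pixel_spacing)
    assert got[0] == pytest.approx(oracle[0], abs=1e-9)
    assert got[1] == pytest.approx(oracle[1], abs=1e-9)
    px = math.degrees(math.atan2(0.5, spec.outer_radius))
    for g, t in zip(got, arc, strict=True):
        assert abs((g - t + 180.0) % 360.0 - 180.0) <= px


def test_no_rv_returns_none():
    labels = np.zeros((6, 6), int)
    labels[2:4, 2:4] = 2
    assert rm.rv_insertion_angles(labels) is None


def test_wide_contact_arc_is_degenerate():
    spec = PhantomSpec(grid_shape=(120, 120), n_slices=1, septal_arc=(0.0, 179.0))
    stack, _ = generate_phantom_stack(spec)
    with pytest.raises(DegenerateContactError):
        rm.rv_insertion_angles(stack.labels[0], stack.pixel_spacing)


# ---------------------------------------------------------------------------
# septum


def test_septal_fraction_of_uniform_annulus(uniform_annulus):
    _, stack, _ = uniform_annulus
    frac = rm.septal_mass(stack) / rm.total_lv_mass(stack)
    assert frac == pytest.approx(0.25, abs=0.02)


def test_septal_pixels_subset_and_conservation(uniform_annulus):
    _, stack, _ = uniform_annulus
    sl = stack.labels[0]
    ang = rm.rv_insertion_angles(sl, stack.pixel_spacing)
    sep = rm.septal_pixels(sl, ang, stack.pixel_spacing)
    myo = sl == 2
    assert (sep & ~myo).sum() == 0  # subset
    assert sep.sum() + (myo & ~sep).sum() == myo.sum()  # exact conservation


def test_septal_mass_counts_only_contact_slices():
    spec = PhantomSpec(grid_shape=(96, 96), n_slices=10, apical_taper=0.02)
    full, _ = generate_phantom_stack(spec)
    partial = full.labels.copy()
    partial[6:] = np.where(partial[6:] == 3, 0, partial[6:])  # strip RV from 4 slices
    pstack = MaskStack(partial, pixel_spacing=full.pixel_spacing,
                       slice_thickness=8.0, slice_gap=2.0)
    per_slice = [
        int(rm.septal_pixels(full.labels[k],
                             rm.rv_insertion_angles(full.labels[k], full.pixel_spacing),
                             full.pixel_spacing).sum())
        for k in range(6)
    ]
    expected = rm.slice_region_mass(sum(per_slice), full)
    assert rm.septal_mass(pstack) == pytest.approx(expected)


def test_nearest_fallback_reuses_neighbour_angles():
    spec = PhantomSpec(grid_shape=(96, 96), n_slices=10, apical_taper=0.02)
    full, _ = generate_phantom_stack(spec)
    partial = np.where(full.labels == 3, 0, full.labels)
    partial[:5] = full.labels[:5]  # RV only in the basal half
    pstack = MaskStack(partial, pixel_spacing=full.pixel_spacing,
                       slice_thickness=8.0, slice_gap=2.0)
    assert rm.septal_mass(pstack, fallback="nearest") > rm.septal_mass(pstack, fallback="zero")


def test_no_rv_anywhere_raises():
    spec = PhantomSpec(grid_shape=(96, 96), n_slices=6, defects=("no_rv",))
    stack, _ = generate_phantom_stack(spec)
    with pytest.raises(NoSeptumError):
        rm.septal_mass(stack)


def test_septal_never_exceeds_total(tapered_phantom):
    _, stack, _ = tapered_phantom
    assert rm.septal_mass(stack) <= rm.total_lv_mass(stack)


# ---------------------------------------------------------------------------
# symmetry properties


def test_rotation_by_90_degrees(uniform_annulus):
    _, stack, _ = uniform_annulus
    ang = rm.rv_insertion_angles(stack.labels[0], stack.pixel_spacing)
    rot = MaskStack(np.rot90(stack.labels[0], k=1)[None], pixel_spacing=stack.pixel_spacing,
                    slice_thickness=8.0, slice_gap=2.0)
    ang_r = rm.rv_insertion_angles(rot.labels[0], rot.pixel_spacing)
    assert (ang[0] - ang_r[0]) % 360.0 == pytest.approx(90.0, abs=1e-9)
    assert (ang[1] - ang_r[1]) % 360.0 == pytest.approx(90.0, abs=1e-9)
    assert rm.total_lv_mass(rot) == pytest.approx(rm.total_lv_mass(stack), rel=1e-12)
    assert rm.septal_mass(rot) == pytest.approx(rm.septal_mass(stack), rel=5e-3)


def test_translation_by_whole_pixels_changes_nothing():
    base = PhantomSpec(grid_shape=(140, 140), n_slices=5, apical_taper=0.02,
                       septal_arc=(100.0, 190.0))
    moved = PhantomSpec(grid_shape=(140, 140), n_slices=5, apical_taper=0.02,
                        septal_arc=(100.0, 190.0), lv_center=(59.5, 79.5))
    s1, _ = generate_phantom_stack(base)
    s2, _ = generate_phantom_stack(moved)
    assert rm.total_lv_mass(s1) == rm.total_lv_mass(s2)
    assert rm.septal_mass(s1) == rm.septal_mass(s2)
    a1 = rm.rv_insertion_angles(s1.labels[2], s1.pixel_spacing)
    a2 = rm.rv_insertion_angles(s2.labels[2], s2.pixel_spacing)
    assert a1 == pytest.approx(a2, abs=1e-9)


# ---------------------------------------------------------------------------
# per-subject record


def test_quantify_intact_phantom_within_tolerance(tapered_phantom):
    _, stack, truth = tapered_phantom
    rec = rm.quantify_subject(stack)
    assert rec.qc_passed
    assert rec.total_mass_g == pytest.approx(truth.total_mass_g, rel=0.02)
    assert rec.apical_mass_g == pytest.approx(truth.apical_mass_g, rel=0.02)
    assert rec.septal_mass_g == pytest.approx(truth.septal_mass_g, rel=0.05)
    assert rec.n_slices_used == 10 and rec.n_septal_slices == 10


def test_quantify_gates_on_qc():
    spec = PhantomSpec(grid_shape=(96, 96), n_slices=10, apical_taper=0.02,
                       defects=("broken_annulus",))
    stack, _ = generate_phantom_stack(spec)
    rec = rm.quantify_subject(stack)
    assert not rec.qc_passed and "broken_annulus" in rec.qc_reasons
    assert rec.total_mass_g is None and rec.septal_mass_g is None


def test_quantify_batch_preserves_order(tapered_phantom):
    _, stack, _ = tapered_phantom
    stacks = []
    for i in range(3):
        s = MaskStack(stack.labels.copy(), pixel_spacing=stack.pixel_spacing,
                      slice_thickness=8.0, slice_gap=2.0, subject_id=f"S{i}")
        stacks.append(s)
    table = rm.quantify_batch(stacks)
    assert list(table["subject_id"]) == ["S0", "S1", "S2"]
    assert table["qc_passed"].all()
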