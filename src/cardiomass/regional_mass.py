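"""Total, apical and septal left-ventricular mass from a segmentation stack.

Mass follows the pixel-sum convention: myocardial pixels per slice are
converted to area (pixel spacing), to volume (slice thickness + gap, i.e. the
contiguous-coverage convention) and to grams (myocardial density
1.055 g/cm^3). The apical region is the four most apex-ward slices that
contain myocardium. The septum is, per slice, the myocardial segment bounded
by the two RV insertion points: the endpoints of the smallest circular
angular interval (about the LV centroid) containing every myocardial pixel
that touches the RV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    DegenerateContactError,
    EmptyAnatomyError,
    InsufficientCoverageError,
    NoSeptumError,
)
from .mask_io import LV_CAVITY, LV_MYOCARDIUM, RV_CAVITY, MaskStack, QCCriteria, qc_stack
from .simulate.phantom import DEFAULT_N_APICAL, MYOCARDIAL_DENSITY_G_PER_MM3

log = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)


def slice_region_mass(
    pixel_count: int,
    stack: MaskStack,
    volume_mode: str = "thickness_plus_gap",
) -> float:
    """Convert a per-slice pixel count into grams of myocardium.

    ``volume_mode="thickness_only"`` drops the inter-slice gap from the slice
    volume (non-default reading of the coverage convention).
    """
    if pixel_count < 0:
        raise ValueError("pixel_count must be >= 0")
    if volume_mode == "thickness_plus_gap":
        coverage = stack.slice_thickness + stack.slice_gap
    elif volume_mode == "thickness_only":
        coverage = stack.slice_thickness
    else:
        raise ValueError(f"unknown volume_mode {volume_mode!r}")
    return pixel_count * stack.pixel_area_mm2 * coverage * MYOCARDIAL_DENSITY_G_PER_MM3


def myocardial_slice_indices(stack: MaskStack) -> np.ndarray:
    """Indices (base->apex) of slices containing LV myocardium."""
    return np.flatnonzero((stack.labels == LV_MYOCARDIUM).any(axis=(1, 2)))


def total_lv_mass(stack: MaskStack, volume_mode: str = "thickness_plus_gap") -> float:
    """Sum of slice masses over every myocardial pixel in the stack."""
    stack = stack.normalized()
    count = int((stack.labels == LV_MYOCARDIUM).sum())
    if count == 0:
        raise EmptyAnatomyError(f"{stack.subject_id or 'stack'}: no myocardial pixels")
    return slice_region_mass(count, stack, volume_mode)


def select_apical_slices(stack: MaskStack, n_apical: int = DEFAULT_N_APICAL) -> list[int]:
    """The ``n_apical`` most apex-ward myocardium-containing slice indices."""
    if n_apical < 1:
        raise ValueError("n_apical must be >= 1")
    idx = myocardial_slice_indices(stack.normalized())
    if len(idx) < n_apical:
        raise InsufficientCoverageError(
            f"only {len(idx)} myocardial slice(s), need {n_apical} for the apical region"
        )
    return idx[-n_apical:].tolist()


def apical_mass(
    stack: MaskStack,
    n_apical: int = DEFAULT_N_APICAL,
    volume_mode: str = "thickness_plus_gap",
) -> float:
    """Myocardial mass restricted to the apical slices."""
    stack = stack.normalized()
    picked = select_apical_slices(stack, n_apical)
    count = int((stack.labels[picked] == LV_MYOCARDIUM).sum())
    return slice_region_mass(count, stack, volume_mode)


# ---------------------------------------------------------------------------
# Septum


def _pixel_angles(
    mask: np.ndarray, centroid: tuple[float, float], spacing: tuple[float, float]
) -> np.ndarray:
    ii, jj = np.nonzero(mask)
    dy = (ii - centroid[0]) * spacing[0]
    dx = (jj - centroid[1]) * spacing[1]
    return np.degrees(np.arctan2(dy, dx)) % 360.0


def _lv_centroid(slice_labels: np.ndarray) -> tuple[float, float]:
    lv = (slice_labels == LV_CAVITY) | (slice_labels == LV_MYOCARDIUM)
    ii, jj = np.nonzero(lv)
    return float(ii.mean()), float(jj.mean())


def _min_circular_interval(angles: np.ndarray) -> tuple[float, float, float]:
    """Smallest circular interval [a, b] covering all angles; returns (a, b, span)."""
    a = np.sort(np.asarray(angles, dtype=float) % 360.0)
    if len(a) == 1:
        return float(a[0]), float(a[0]), 0.0
    gaps = np.diff(np.concatenate([a, a[:1] + 360.0]))
    k = int(np.argmax(gaps))
    start = a[(k + 1) % len(a)]
    end = a[k]
    return float(start), float(end), float(360.0 - gaps[k])


def angle_in_interval(angle: float, t1: float, t2: float) -> bool:
    """Membership in the closed circular interval running t1 -> t2 (ccw)."""
    return ((angle - t1) % 360.0) <= ((t2 - t1) % 360.0)


def rv_insertion_angles(
    slice_labels: np.ndarray,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> tuple[float, float] | None:
    """RV insertion points of one slice as angles (deg) about the LV centroid.

    The contact set is every myocardial pixel 8-adjacent to an RV pixel; the
    returned pair delimits the smallest circular interval containing all
    contact-pixel angles. None when there is no RV contact; raises
    :class:`DegenerateContactError` when the interval spans >= 180 deg.
    """
    rv = slice_labels == RV_CAVITY
    if not rv.any():
        return None
    contact = (slice_labels == LV_MYOCARDIUM) & ndimage.binary_dilation(rv, structure=_EIGHT)
    if not contact.any():
        return None
    centroid = _lv_centroid(slice_labels)
    angles = _pixel_angles(contact, centroid, pixel_spacing)
    t1, t2, span = _min_circular_interval(angles)
    if span >= 180.0:
        raise DegenerateContactError(f"RV contact arc spans {span:.1f} deg >= 180 deg")
    return t1, t2


def septal_pixels(
    slice_labels: np.ndarray,
    angles: tuple[float, float],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Boolean mask of myocardial pixels inside the closed insertion interval."""
    t1, t2 = angles
    myo = slice_labels == LV_MYOCARDIUM
    out = np.zeros_like(myo)
    if not myo.any():
        return out
    centroid = _lv_centroid(slice_labels)
    ii, jj = np.nonzero(myo)
    dy = (ii - centroid[0]) * pixel_spacing[0]
    dx = (jj - centroid[1]) * pixel_spacing[1]
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    inside = ((theta - t1) % 360.0) <= ((t2 - t1) % 360.0)
    out[ii[inside], jj[inside]] = True
    return out


def _septal_decomposition(
    stack: MaskStack, fallback: str = "zero"
) -> list[tuple[tuple[float, float] | None, int]]:
    """Per slice: (insertion angles or None, septal pixel count).

    ``fallback="nearest"`` reuses the nearest contact slice's angles on slices
    without RV contact; the default contributes zero for such slices.
    Degenerate (>= 180 deg) contact arcs are flagged and excluded like
    no-contact slices.
    """
    stack = stack.normalized()
    per_slice_angles: list[tuple[float, float] | None] = []
    for k in range(stack.n_slices):
        try:
            per_slice_angles.append(rv_insertion_angles(stack.labels[k], stack.pixel_spacing))
        except DegenerateContactError as exc:
            log.warning("%s slice %d: %s; excluded from septum", stack.subject_id, k, exc)
            per_slice_angles.append(None)

    if fallback == "nearest":
        contact_idx = [k for k, a in enumerate(per_slice_angles) if a is not None]
        if contact_idx:
            filled = []
            for k, a in enumerate(per_slice_angles):
                if a is None and (stack.labels[k] == LV_MYOCARDIUM).any():
                    nearest = min(contact_idx, key=lambda c: abs(c - k))
                    filled.append(per_slice_angles[nearest])
                else:
                    filled.append(a)
            per_slice_angles = filled
    elif fallback != "zero":
        raise ValueError(f"unknown septum fallback {fallback!r}")

    out = []
    for k, ang in enumerate(per_slice_angles):
        if ang is None:
            out.append((None, 0))
        else:
            count = int(septal_pixels(stack.labels[k], ang, stack.pixel_spacing).sum())
            out.append((ang, count))
    return out


def septal_mass(
    stack: MaskStack,
    fallback: str = "zero",
    volume_mode: str = "thickness_plus_gap",
) -> float:
    """Mass of the septal segment summed over slices with defined insertion angles."""
    stack = stack.normalized()
    decomp = _septal_decomposition(stack, fallback)
    if all(ang is None for ang, _ in decomp):
        raise NoSeptumError(f"{stack.subject_id or 'stack'}: no slice shows RV contact")
    count = sum(c for _, c in decomp)
    return slice_region_mass(count, stack, volume_mode)


# ---------------------------------------------------------------------------
# Per-subject record


@dataclass
class RegionalMassRecord:
    """Per-subject quantification result; masses are None when QC failed."""

    subject_id: str
    total_mass_g: float | None = None
    apical_mass_g: float | None = None
    septal_mass_g: float | None = None
    n_slices_used: int = 0
    n_septal_slices: int = 0
    insertion_angles_per_slice: list[tuple[float, float] | None] = field(default_factory=list)
    qc_passed: bool = False
    qc_reasons: list[str] = field(default_factory=list)


def quantify_subject(
    stack: MaskStack,
    qc_criteria: QCCriteria | None = None,
    n_apical: int = DEFAULT_N_APICAL,
    fallback: str = "zero",
    volume_mode: str = "thickness_plus_gap",
) -> RegionalMassRecord:
    """QC gate then all three masses; QC failure yields a flagged, mass-less record."""
    stack = stack.normalized()
    qc = qc_stack(stack, qc_criteria)
    rec = RegionalMassRecord(
        subject_id=stack.subject_id, qc_passed=qc.passed, qc_reasons=list(qc.reasons)
    )
    if not qc.passed:
        return rec
    decomp = _septal_decomposition(stack, fallback)
    rec.insertion_angles_per_slice = [ang for ang, _ in decomp]
    rec.n_septal_slices = sum(1 for ang, _ in decomp if ang is not None)
    rec.n_slices_used = int(len(myocardial_slice_indices(stack)))
    rec.total_mass_g = total_lv_mass(stack, volume_mode)
    rec.apical_mass_g = apical_mass(stack, n_apical, volume_mode)
    septal_count = sum(c for _, c in decomp)
    rec.septal_mass_g = slice_region_mass(septal_count, stack, volume_mode)
    return rec


def quantify_batch(stacks, **kwargs) -> pd.DataFrame:
    """Quantify an iterable of stacks into the per-subject output table."""
    rows = []
    for stack in stacks:
        rec = quantify_subject(stack, **kwargs)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "total_mass_g": rec.total_mass_g,
                "apical_mass_g": rec.apical_mass_g,
                "septal_mass_g": rec.septal_mass_g,
                "n_slices_used": rec.n_slices_used,
                "n_septal_slices": rec.n_septal_slices,
                "qc_passed": int(rec.qc_passed),
                "qc_reasons": ",".join(rec.qc_reasons) or ".",
            }
        )
    return pd.DataFrame(rows)
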