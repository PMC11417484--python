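"""Read, validate, write and quality-control labelled short-axis segmentation stacks.

A stack is a 3-D integer label volume (slice, row, col) with the label
convention 0 = background, 1 = LV cavity, 2 = LV myocardium, 3 = RV cavity,
plus the acquisition geometry needed to turn pixel counts into volumes:
in-plane pixel spacing, slice thickness and inter-slice gap (all mm).
Slices are normalised internally to base->apex order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ValidationError

log = logging.getLogger(__name__)

BACKGROUND, LV_CAVITY, LV_MYOCARDIUM, RV_CAVITY = 0, 1, 2, 3
VALID_LABELS = frozenset((BACKGROUND, LV_CAVITY, LV_MYOCARDIUM, RV_CAVITY))

#: fallback acquisition geometry when a header carries no usable values
DEFAULT_SLICE_THICKNESS_MM = 8.0
DEFAULT_SLICE_GAP_MM = 2.0

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = ndimage.generate_binary_structure(2, 1)


@dataclass
class MaskStack:
    """A labelled segmentation volume plus its slice geometry.

    ``labels`` is indexed (slice, row, col); slice index 0 is the most basal
    slice once normalised (``slice_order == "base_to_apex"``).
    """

    labels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = DEFAULT_SLICE_THICKNESS_MM
    slice_gap: float = DEFAULT_SLICE_GAP_MM
    slice_order: str = "base_to_apex"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.shape[0] < 1:
            raise ValidationError("labels must be a 3-D (slice, row, col) array with >= 1 slice")
        if self.labels.size == 0:
            raise ValidationError("empty label volume")
        present = set(np.unique(self.labels).tolist())
        unknown = present - VALID_LABELS
        if unknown:
            raise ValidationError(f"unknown label value(s): {sorted(unknown)}")
        if min(self.pixel_spacing) <= 0:
            raise ValidationError(f"non-positive pixel spacing {self.pixel_spacing}")
        if self.slice_thickness <= 0:
            raise ValidationError("slice_thickness must be > 0")
        if self.slice_gap < 0:
            raise ValidationError("slice_gap must be >= 0")
        if self.slice_order not in ("base_to_apex", "apex_to_base"):
            raise ValidationError(f"unknown slice_order {self.slice_order!r}")

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @property
    def slice_spacing(self) -> float:
        """Centre-to-centre slice distance (mm) = thickness + gap."""
        return self.slice_thickness + self.slice_gap

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]

    def normalized(self) -> "MaskStack":
        """Return a copy in base->apex slice order."""
        if self.slice_order == "base_to_apex":
            return self
        return replace(self, labels=self.labels[::-1].copy(), slice_order="base_to_apex")


def write_mask_stack(stack: MaskStack, path: str | Path) -> None:
    """Write a stack as NIfTI-1; pixel spacing and slice spacing go in the header.

    NIfTI has no slice-thickness field distinct from slice spacing, so the
    thickness is recorded in the header ``descrip`` string and recovered by
    :func:`read_mask_stack`.
    """
    path = Path(path)
    data = np.transpose(stack.labels.astype(np.uint8), (1, 2, 0))
    affine = np.diag(
        [stack.pixel_spacing[0], stack.pixel_spacing[1], stack.slice_spacing, 1.0]
    )
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((stack.pixel_spacing[0], stack.pixel_spacing[1], stack.slice_spacing))
    img.header["descrip"] = f"thickness={stack.slice_thickness:g}mm".encode()
    nib.save(img, str(path))


def read_mask_stack(
    path: str | Path,
    label_map: dict[int, int] | None = None,
    slice_order: str = "base_to_apex",
    slice_thickness: float | None = None,
    slice_gap: float | None = None,
    subject_id: str | None = None,
) -> MaskStack:
    """Load a NIfTI label stack and normalise it to base->apex order.

    Geometry comes from the header (gap = slice spacing - thickness) unless
    overridden; explicit overrides are logged. ``label_map`` remaps file label
    values onto the canonical 0/1/2/3 encoding and must cover every value
    present in the file.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    labels = np.transpose(data, (2, 0, 1)).astype(np.int64)

    if label_map is not None:
        out = np.full_like(labels, -1)
        for src, dst in label_map.items():
            out[labels == src] = dst
        leftover = set(np.unique(labels).tolist()) - set(label_map)
        if leftover:
            raise ValidationError(f"unknown label value(s): {sorted(leftover)}")
        labels = out

    zooms = img.header.get_zooms()[:3]
    if min(zooms[:2]) <= 0 or zooms[2] <= 0:
        raise ValidationError(f"{path}: non-positive spacing in header {zooms}")
    spacing = (float(zooms[0]), float(zooms[1]))
    slice_spacing = float(zooms[2])

    if slice_thickness is None:
        descrip = img.header["descrip"].tobytes().decode(errors="ignore")
        m = re.search(r"thickness=([\d.]+)mm", descrip)
        if m:
            slice_thickness = float(m.group(1))
        else:
            slice_thickness = min(DEFAULT_SLICE_THICKNESS_MM, slice_spacing)
            log.warning(
                "%s: header carries no slice thickness; assuming %g mm", path, slice_thickness
            )
    else:
        log.warning("%s: slice thickness overridden to %g mm", path, slice_thickness)
    if slice_gap is None:
        slice_gap = max(slice_spacing - slice_thickness, 0.0)
    else:
        log.warning("%s: slice gap overridden to %g mm", path, slice_gap)

    stack = MaskStack(
        labels=labels,
        pixel_spacing=spacing,
        slice_thickness=float(slice_thickness),
        slice_gap=float(slice_gap),
        slice_order=slice_order,
        subject_id=subject_id if subject_id is not None else Path(path).name.split(".")[0],
    )
    return stack.normalized()


# ---------------------------------------------------------------------------
# Quality control


@dataclass(frozen=True)
class QCCriteria:
    """Configurable exclusion rules for a segmentation stack."""

    min_myocardial_slices: int = 6
    require_rv_in_mid_third: bool = True
    check_ring_in_mid_third: bool = True
    # the most apical myocardial slice must show a cavity markedly smaller
    # than the mid-ventricular maximum; anatomy without any apex-ward taper
    # (or with the true apex missing) fails this cap
    apex_cap_fraction: float = 0.95


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    n_myocardial_slices: int = 0


def _ring_intact(slice_labels: np.ndarray) -> bool:
    """True when the myocardium forms a single closed ring around the cavity.

    Single 8-connected myocardial component, and the LV cavity must not reach
    the image border through non-myocardial pixels (4-connectivity on the
    complement, the dual of 8-connectivity on the ring).
    """
    myo = slice_labels == LV_MYOCARDIUM
    if not myo.any():
        return False
    _, n_comp = ndimage.label(myo, structure=_EIGHT)
    if n_comp != 1:
        return False
    cavity = slice_labels == LV_CAVITY
    if not cavity.any():
        return False
    comp, _ = ndimage.label(~myo, structure=_FOUR)
    border = np.zeros_like(myo)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    outside_ids = np.unique(comp[border & ~myo])
    return not np.isin(comp[cavity], outside_ids).any()


def qc_stack(stack: MaskStack, criteria: QCCriteria | None = None) -> QCResult:
    """Apply the exclusion rules; failures are reported, never raised."""
    criteria = criteria or QCCriteria()
    stack = stack.normalized()
    labels = stack.labels
    reasons: list[str] = []

    myo_per_slice = (labels == LV_MYOCARDIUM).any(axis=(1, 2))
    myo_idx = np.flatnonzero(myo_per_slice)
    n_myo = len(myo_idx)
    if n_myo < criteria.min_myocardial_slices:
        reasons.append("too_few_slices")

    n = stack.n_slices
    mid = range(n // 3, n - n // 3) if n >= 3 else range(n)
    mid_idx = [i for i in mid if myo_per_slice[i]]

    if criteria.require_rv_in_mid_third:
        has_rv = any((labels[i] == RV_CAVITY).any() for i in mid_idx)
        if not has_rv:
            reasons.append("no_rv_contact")

    if criteria.check_ring_in_mid_third and mid_idx:
        if not all(_ring_intact(labels[i]) for i in mid_idx):
            reasons.append("broken_annulus")

    if n_myo and mid_idx:
        cavity_areas = (labels == LV_CAVITY).sum(axis=(1, 2))
        mid_max = max(cavity_areas[i] for i in mid_idx)
        apex_slice = myo_idx[-1]
        if mid_max > 0 and cavity_areas[apex_slice] > criteria.apex_cap_fraction * mid_max:
            reasons.append("apex_not_capped")

    return QCResult(passed=not reasons, reasons=reasons, n_myocardial_slices=n_myo)


def append_qc_log(path: str | Path, subject_id: str, result: QCResult) -> None:
    """Append one QC outcome to a TSV audit log, creating the header if new."""
    path = Path(path)
    new = not path.exists()
    with path.open("a") as fh:
        if new:
            fh.write("subject_id\tpassed\treasons\tn_myocardial_slices\n")
        fh.write(
            f"{subject_id}\t{int(result.passed)}\t"
            f"{','.join(result.reasons) or '.'}\t{result.n_myocardial_slices}\n"
        )
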