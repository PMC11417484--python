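"""Annular myocardium phantoms with closed-form ground-truth masses.

Each phantom slice is a circular annulus of LV myocardium (label 2) around an
LV cavity disc (label 1), with an RV blob (label 3) realised as a half-annulus
segment hugging the epicardium over exactly the configured septal arc, so the
RV insertion angles are known by construction. Radii may taper linearly
toward the apex. All truth masses come from the analytic annulus area
pi*(R_out^2 - R_in^2) per slice times slice coverage (thickness + gap) times
myocardial density 1.055 g/cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..errors import GeometryError
from ..mask_io import LV_CAVITY, LV_MYOCARDIUM, RV_CAVITY, MaskStack

#: myocardial density, grams per mm^3 (1.055 g/cm^3)
MYOCARDIAL_DENSITY_G_PER_MM3 = 1.055e-3

#: number of apex-ward slices that define the apical region
DEFAULT_N_APICAL = 4


def arc_span_deg(arc: tuple[float, float]) -> float:
    """Angular span of a half-open arc (start, end) in circular arithmetic."""
    return (arc[1] - arc[0]) % 360.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic short-axis stack.

    ``septal_arc`` is the half-open angular interval [start, end) deg over
    which the RV touches the epicardium; angles are measured in the
    (row, col) plane as atan2(drow, dcol) mod 360. ``rv_offset`` is the radial
    extent (mm) of the RV segment beyond the epicardial radius.
    ``apical_taper`` shrinks both radii by that fraction per slice toward the
    apex (slice 0 is the base).
    """

    grid_shape: tuple[int, int] = (128, 128)
    pixel_spacing: float = 1.0
    n_slices: int = 10
    slice_thickness: float = 8.0
    slice_gap: float = 2.0
    lv_center: tuple[float, float] | None = None
    inner_radius: float = 20.0
    outer_radius: float = 28.0
    septal_arc: tuple[float, float] = (240.0, 330.0)
    apical_taper: float = 0.0
    rv_offset: float = 8.0
    seed: int = 0
    defects: tuple[str, ...] = ()

    def validate(self) -> None:
        if not (self.outer_radius > self.inner_radius > 0):
            raise GeometryError(
                f"need outer_radius > inner_radius > 0, got {self.outer_radius}, {self.inner_radius}"
            )
        span = arc_span_deg(self.septal_arc)
        if span >= 180.0:
            raise GeometryError(f"septal arc span {span:g} deg >= 180 deg is unsupported")
        if self.n_slices < 1:
            raise GeometryError("n_slices must be >= 1")
        if self.pixel_spacing <= 0:
            raise GeometryError("pixel_spacing must be > 0")
        if self.apical_taper * (self.n_slices - 1) >= 1.0:
            raise GeometryError("apical_taper collapses the annulus before the last slice")
        cr, cc = self.center
        r_need = self.outer_radius / self.pixel_spacing
        rows, cols = self.grid_shape
        if (
            cr - r_need < -0.5
            or cc - r_need < -0.5
            or cr + r_need > rows - 0.5
            or cc + r_need > cols - 0.5
        ):
            raise GeometryError("outer radius does not fit inside the grid")

    @property
    def center(self) -> tuple[float, float]:
        if self.lv_center is not None:
            return self.lv_center
        return ((self.grid_shape[0] - 1) / 2.0, (self.grid_shape[1] - 1) / 2.0)


@dataclass
class PhantomTruth:
    """Closed-form masses for a phantom, in grams."""

    total_mass_g: float
    apical_mass_g: float
    septal_mass_g: float
    per_slice_areas_mm2: list[float] = field(default_factory=list)


def _slice_scale(spec: PhantomSpec, k: int) -> float:
    return 1.0 - spec.apical_taper * k


def analytic_truth(spec: PhantomSpec, n_apical: int = DEFAULT_N_APICAL) -> PhantomTruth:
    """Closed-form total/apical/septal masses for a (defect-free) phantom."""
    cov = spec.slice_thickness + spec.slice_gap
    arc_frac = arc_span_deg(spec.septal_arc) / 360.0
    missing = _missing_apex_count(spec)
    areas = []
    for k in range(spec.n_slices):
        s = _slice_scale(spec, k)
        area = math.pi * ((spec.outer_radius * s) ** 2 - (spec.inner_radius * s) ** 2)
        areas.append(0.0 if k >= spec.n_slices - missing else area)
    masses = [a * cov * MYOCARDIAL_DENSITY_G_PER_MM3 for a in areas]
    present = [m for m in masses if m > 0]
    n_ap = min(n_apical, len(present))
    apical = sum(present[-n_ap:]) if n_ap else 0.0
    septal = 0.0 if "no_rv" in spec.defects else sum(masses) * arc_frac
    return PhantomTruth(
        total_mass_g=sum(masses),
        apical_mass_g=apical,
        septal_mass_g=septal,
        per_slice_areas_mm2=areas,
    )


def _missing_apex_count(spec: PhantomSpec) -> int:
    for d in spec.defects:
        if d.startswith("missing_apex"):
            _, _, k = d.partition(":")
            return int(k) if k else 2
    return 0


def _rasterize_slice(spec: PhantomSpec, k: int) -> np.ndarray:
    rows, cols = spec.grid_shape
    cr, cc = spec.center
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    dy = (ii - cr) * spec.pixel_spacing
    dx = (jj - cc) * spec.pixel_spacing
    r = np.hypot(dy, dx)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0

    s = _slice_scale(spec, k)
    r_in, r_out = spec.inner_radius * s, spec.outer_radius * s

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[r < r_in] = LV_CAVITY
    labels[(r >= r_in) & (r < r_out)] = LV_MYOCARDIUM

    if "no_rv" not in spec.defects:
        t1, t2 = spec.septal_arc
        in_arc = ((theta - t1) % 360.0) < arc_span_deg(spec.septal_arc)
        rv = in_arc & (r >= r_out) & (r < r_out + spec.rv_offset * s)
        labels[rv] = RV_CAVITY
    return labels


def generate_phantom_stack(
    spec: PhantomSpec, subject_id: str = "phantom"
) -> tuple[MaskStack, PhantomTruth]:
    """Rasterise a phantom and return it with its analytic truth.

    Slices are ordered base -> apex. Supported defects: ``missing_apex[:k]``
    (blank the last k slices), ``broken_annulus`` (carve a 2-pixel radial gap
    in a mid slice, opposite the septum), ``no_rv``.
    """
    spec.validate()
    labels = np.stack([_rasterize_slice(spec, k) for k in range(spec.n_slices)])

    missing = _missing_apex_count(spec)
    if missing:
        labels[spec.n_slices - missing :] = 0

    if "broken_annulus" in spec.defects:
        k = spec.n_slices // 2
        sl = labels[k]
        cr, cc = spec.center
        # carve a thin radial gap at the angle opposite the septal arc centre
        mid = (spec.septal_arc[0] + arc_span_deg(spec.septal_arc) / 2.0 + 180.0) % 360.0
        ii, jj = np.nonzero(sl == LV_MYOCARDIUM)
        theta = np.degrees(np.arctan2(ii - cr, jj - cc)) % 360.0
        gap_halfwidth = math.degrees(spec.pixel_spacing / spec.inner_radius)
        cut = np.abs((theta - mid + 180.0) % 360.0 - 180.0) <= gap_halfwidth
        sl[ii[cut], jj[cut]] = 0

    stack = MaskStack(
        labels=labels,
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
        slice_thickness=spec.slice_thickness,
        slice_gap=spec.slice_gap,
        slice_order="base_to_apex",
        subject_id=subject_id,
    )
    return stack, analytic_truth(spec)


def random_phantom_specs(
    n: int,
    seed: int,
    grid_shape: tuple[int, int] = (128, 128),
    pixel_spacing: float = 1.0,
    n_slices: int = 10,
    inner_range: tuple[float, float] = (16.0, 24.0),
    wall_range: tuple[float, float] = (6.0, 12.0),
    arc_span_range: tuple[float, float] = (70.0, 110.0),
    taper_range: tuple[float, float] = (0.01, 0.04),
) -> list[PhantomSpec]:
    """Draw a batch of varied, valid phantom geometries (one per subject)."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        inner = rng.uniform(*inner_range)
        wall = rng.uniform(*wall_range)
        start = rng.uniform(0.0, 360.0)
        span = rng.uniform(*arc_span_range)
        specs.append(
            PhantomSpec(
                grid_shape=grid_shape,
                pixel_spacing=pixel_spacing,
                n_slices=n_slices,
                inner_radius=inner,
                outer_radius=inner + wall,
                septal_arc=(start, (start + span) % 360.0),
                apical_taper=rng.uniform(*taper_range),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs
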