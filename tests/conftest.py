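import numpy as np
import pytest

from cardiomass.mask_io import MaskStack
from cardiomass.simulate import PhantomSpec, generate_phantom_stack


@pytest.fixture(scope="session")
def tapered_phantom():
    """A QC-clean 10-slice tapered phantom with its analytic truth."""
    spec = PhantomSpec(
        grid_shape=(96, 96),
        pixel_spacing=1.0,
        n_slices=10,
        inner_radius=18.0,
        outer_radius=26.0,
        septal_arc=(200.0, 290.0),
        apical_taper=0.02,
    )
    stack, truth = generate_phantom_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def uniform_annulus():
    """Single-slice uniform annulus, 90-degree septal arc, 0.5 mm pixels."""
    spec = PhantomSpec(
        grid_shape=(160, 160),
        pixel_spacing=0.5,
        n_slices=1,
        inner_radius=20.0,
        outer_radius=28.0,
        septal_arc=(60.0, 150.0),
    )
    stack, truth = generate_phantom_stack(spec)
    return spec, stack, truth


@pytest.fixture
def small_stack():
    """Tiny hand-built stack for IO contract tests."""
    labels = np.zeros((3, 8, 8), dtype=np.uint8)
    labels[:, 3:5, 3:5] = 1
    labels[:, 2, 2:6] = 2
    labels[:, 5, 2:6] = 2
    labels[:, 3:5, 2] = 2
    labels[:, 3:5, 5] = 2
    labels[1, 6, 3:5] = 3
    return MaskStack(labels=labels, pixel_spacing=(1.5, 1.5), slice_thickness=8.0, slice_gap=2.0)
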