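"""Shared fixtures: hand-built contour stacks with closed-form volumes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lvfusion.chunks import ContourStack
from lvfusion.geometry import ImagePlane, PlanarContour

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def zplane(z: float) -> ImagePlane:
    """SAX-style plane z = const with frame (x-hat, y-hat)."""
    return ImagePlane((0.0, 0.0, z), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0))


def vertical_plane() -> ImagePlane:
    """LAX-style plane y = 0 with frame (x-hat, z-hat)."""
    return ImagePlane((0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (0.0, 0.0, 1.0))


def circle_points(r: float, n: int = 96, center=(0.0, 0.0)) -> np.ndarray:
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)])


def circle_contour(z: float, r: float, n: int = 96, slice_index: int | None = None,
                   center=(0.0, 0.0), **kw) -> PlanarContour:
    return PlanarContour(zplane(z), circle_points(r, n, center),
                         slice_index=slice_index, **kw)


def cylinder_stack(
    r: float = 20.0,
    z_top: float = 20.0,
    spacing: float = 10.0,
    n_slices: int = 5,
    lax_z_top: float | None = None,
    lax_z_bottom: float | None = None,
    n_vertices: int = 96,
) -> ContourStack:
    """Manual circular-cylinder stack with a rectangular axial LAX contour."""
    sax = [circle_contour(z_top - i * spacing, r, n_vertices, slice_index=i)
           for i in range(n_slices)]
    zt = z_top if lax_z_top is None else lax_z_top
    zb = (z_top - (n_slices - 1) * spacing) if lax_z_bottom is None else lax_z_bottom
    lax = PlanarContour(vertical_plane(),
                        np.array([[r, zt], [r, zb], [-r, zb], [-r, zt]], dtype=float))
    return ContourStack(sax, lax, slice_thickness=spacing, inter_slice_gap=0.0)


@pytest.fixture
def unit_square() -> PlanarContour:
    return PlanarContour(zplane(0.0),
                         np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float))
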