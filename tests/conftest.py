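"""Shared fixtures: small grids, simple anatomies, and a tiny cohort."""

import numpy as np
import pytest

from brachychoice.grid import GridSpec
from brachychoice.structures import (
    ContourSlice,
    Structure,
    StructureRole,
    StructureSet,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_grid():
    """16^3 voxels at 2 mm, centered on the origin."""
    return GridSpec(spacing=(2.0, 2.0, 2.0), shape=(16, 16, 16), origin=(-15.0, -15.0, -15.0))


def square_contour(z, half=10.0, center=(0.0, 0.0)):
    cx, cy = center
    pts = np.array(
        [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
        ]
    )
    return ContourSlice(z, pts)


def circle_contour(z, radius, center=(0.0, 0.0), n=256):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return ContourSlice(z, pts)


@pytest.fixture
def straight_tandem():
    """Vertical 40 mm tandem through the origin."""
    return np.array([[0.0, 0.0, -20.0], [0.0, 0.0, 0.0], [0.0, 0.0, 20.0]])


@pytest.fixture
def simple_structure_set(straight_tandem):
    """One cubic HR-CTV around the tandem plus a bladder slab anterior."""
    ctv = Structure(
        "HR-CTV",
        StructureRole.HR_CTV,
        [square_contour(z, half=10.0) for z in (-6.0, -4.0, -2.0, 0.0, 2.0, 4.0, 6.0)],
    )
    bladder = Structure(
        "Bladder",
        StructureRole.BLADDER,
        [square_contour(z, half=8.0, center=(0.0, -24.0)) for z in (-4.0, -2.0, 0.0, 2.0)],
    )
    return StructureSet(
        patient_id="T01",
        insertion_id="T01-1",
        structures=[ctv, bladder],
        tandem=straight_tandem,
        true_label=0,
    )


def random_star_polygon(rng, n_vertices, r_lo=4.0, r_hi=20.0, center=(0.0, 0.0)):
    """A random simple (star-shaped) polygon: sorted angles, random radii."""
    theta = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    # keep angles distinct so edges are well defined
    theta += np.linspace(0, 1e-3, n_vertices)
    r = rng.uniform(r_lo, r_hi, n_vertices)
    return np.column_stack(
        [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
    )
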