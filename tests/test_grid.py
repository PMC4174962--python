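"""Tensor-grid axes: breakpoint preservation and refinement contracts."""

import math

import numpy as np
import pytest

from fesim.grid import SegmentedAxis, TensorGrid


def test_edges_hit_breakpoints_exactly():
    ax = SegmentedAxis.from_spacing([0.0, 0.0087, 0.015, 0.0582], 2e-3)
    for b in ax.breakpoints:
        assert np.min(np.abs(ax.edges - b)) == 0.0


def test_refinement_preserves_breakpoints_and_doubles_cells():
    axes = tuple(
        SegmentedAxis.from_spacing([0.0, 0.01, 0.05], 3e-3) for _ in range(2)
    ) + (SegmentedAxis.from_spacing([0.0, 2 * math.pi], 0.1, periodic=True),)
    # build a cylindrical-compatible grid: (r, theta, z) ordering
    grid = TensorGrid("cylindrical", (axes[0], axes[2], axes[1]))
    for level in range(3):
        finer = grid.refined()
        assert finer.n_cells >= 2 * grid.n_cells
        for a0, a1 in zip(grid.axes, finer.axes):
            assert a0.breakpoints == a1.breakpoints
        grid = finer


def test_widths_sum_to_span():
    ax = SegmentedAxis.from_spacing([-0.2, -0.05, 0.05, 0.2], [9e-3, 2e-3, 9e-3])
    assert ax.widths.sum() == pytest.approx(0.4)
    assert np.all(ax.widths > 0)


def test_invalid_axes_rejected():
    with pytest.raises(ValueError, match="increasing"):
        SegmentedAxis((0.0, 0.0), (1,))
    with pytest.raises(ValueError, match="count"):
        SegmentedAxis((0.0, 1.0), (1, 2))
    with pytest.raises(ValueError, match="periodic"):
        TensorGrid("cylindrical", (
            SegmentedAxis.from_spacing([0.0, 0.1], 0.01),
            SegmentedAxis.from_spacing([0.0, 1.0], 0.1),  # not periodic
            SegmentedAxis.from_spacing([0.0, 0.1], 0.01),
        ))


def test_cell_volumes_fill_cylinder():
    r = SegmentedAxis.from_spacing([0.0, 0.05], 2e-3)
    th = SegmentedAxis.from_spacing([0.0, 2 * math.pi], 0.2, periodic=True)
    z = SegmentedAxis.from_spacing([0.0, 0.1], 5e-3)
    grid = TensorGrid("cylindrical", (r, th, z))
    assert grid.cell_volumes().sum() == pytest.approx(math.pi * 0.05**2 * 0.1)
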