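"""Non-uniform tensor-product grids with mandatory breakpoints.

Axes are built from a sorted list of breakpoints (layer interfaces,
electrode patch edges, inclusion extents) with a per-interval target
spacing; each interval is subdivided uniformly.  Breakpoints therefore
coincide with cell faces at every refinement level, so tissue interfaces
and electrode edges are grid-aligned exactly where the geometry allows it.

Refinement multiplies every interval's subdivision count by 2^(1/3)
(rounded up), which at least doubles the total cell count of a 3-D grid
per level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SegmentedAxis", "TensorGrid", "REFINE_FACTOR"]

REFINE_FACTOR = 2.0 ** (1.0 / 3.0)


@dataclass(frozen=True)
class SegmentedAxis:
    """One grid axis: breakpoints plus per-interval subdivision counts."""

    breakpoints: tuple[float, ...]
    counts: tuple[int, ...]
    periodic: bool = False

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.breakpoints) - 1:
            raise ValueError("need one count per breakpoint interval")
        if any(c < 1 for c in self.counts):
            raise ValueError("subdivision counts must be >= 1")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def from_spacing(
        cls, breakpoints, spacings, periodic: bool = False
    ) -> "SegmentedAxis":
        """Build an axis with ~`spacings[i]` cell width inside interval i."""
        bp = tuple(float(b) for b in breakpoints)
        if np.isscalar(spacings):
            spacings = [float(spacings)] * (len(bp) - 1)
        counts = tuple(
            max(1, math.ceil((b2 - b1) / h))
            for b1, b2, h in zip(bp, bp[1:], spacings)
        )
        return cls(bp, counts, periodic)

    def refined(self, levels: int = 1) -> "SegmentedAxis":
        counts = self.counts
        for _ in range(levels):
            counts = tuple(math.ceil(c * REFINE_FACTOR - 1e-12) for c in counts)
        return SegmentedAxis(self.breakpoints, counts, self.periodic)

    def doubled(self) -> "SegmentedAxis":
        """Halve every cell along this axis (nested refinement)."""
        return SegmentedAxis(self.breakpoints,
                             tuple(2 * c for c in self.counts), self.periodic)

    @property
    def n_cells(self) -> int:
        return int(sum(self.counts))

    @property
    def edges(self) -> np.ndarray:
        segs = [
            np.linspace(b1, b2, c + 1)
            for b1, b2, c in zip(self.breakpoints, self.breakpoints[1:], self.counts)
        ]
        out = [segs[0]]
        for s in segs[1:]:
            out.append(s[1:])
        return np.concatenate(out)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def span(self) -> float:
        return self.breakpoints[-1] - self.breakpoints[0]


@dataclass(frozen=True)
class TensorGrid:
    """A 3-D tensor-product grid.

    ``system`` is "cartesian" (axes x, y, z) or "cylindrical" (axes r, θ, z
    with θ periodic over 2π).
    """

    system: str
    axes: tuple[SegmentedAxis, SegmentedAxis, SegmentedAxis]

    def __post_init__(self) -> None:
        if self.system not in ("cartesian", "cylindrical"):
            raise ValueError(f"unknown coordinate system {self.system!r}")
        if self.system == "cylindrical":
            th = self.axes[1]
            if not th.periodic or abs(th.span - 2.0 * math.pi) > 1e-12:
                raise ValueError("cylindrical θ axis must be periodic over 2π")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(a.n_cells for a in self.axes)

    @property
    def n_cells(self) -> int:
        n0, n1, n2 = self.shape
        return n0 * n1 * n2

    def refined(self, levels: int = 1) -> "TensorGrid":
        return TensorGrid(self.system, tuple(a.refined(levels) for a in self.axes))

    def refined_axis(self, axis: int) -> "TensorGrid":
        """Double the cell count of one axis (exactly doubles total cells)."""
        axes = list(self.axes)
        axes[axis] = axes[axis].doubled()
        return TensorGrid(self.system, tuple(axes))

    def cell_centers(self) -> np.ndarray:
        """Cartesian (x, y, z) coordinates of all cell centres, shape (N, 3)."""
        c0, c1, c2 = (a.centers for a in self.axes)
        A, B, C = np.meshgrid(c0, c1, c2, indexing="ij")
        if self.system == "cylindrical":
            x = A * np.cos(B)
            y = A * np.sin(B)
            return np.column_stack([x.ravel(), y.ravel(), C.ravel()])
        return np.column_stack([A.ravel(), B.ravel(), C.ravel()])

    def cell_volumes(self) -> np.ndarray:
        """Cell volumes, shape = grid shape."""
        w0, w1, w2 = (a.widths for a in self.axes)
        if self.system == "cylindrical":
            rc = self.axes[0].centers
            return (rc * w0)[:, None, None] * w1[None, :, None] * w2[None, None, :]
        return w0[:, None, None] * w1[None, :, None] * w2[None, None, :]
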