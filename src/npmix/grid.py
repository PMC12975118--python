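"""Support-grid construction for location and scale mixtures."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import InputError, MixtureData, ValidationError

__all__ = ["SupportSet", "build_grid_1d", "build_grid_box", "build_scale_grid"]


@dataclass
class SupportSet:
    """A fixed set of candidate support points.

    For ``kind="location"`` the rows of ``points`` are candidate means in
    R^d; for ``kind="scale"`` ``points`` is ``(m, 1)`` holding candidate
    variances of centered Gaussians.
    """

    points: np.ndarray
    kind: str = "location"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.kind not in ("location", "scale"):
            raise ValidationError(f"unknown support kind {self.kind!r}")
        if self.points.shape[0] < 2:
            raise ValidationError("need at least two support points")
        if self.kind == "scale":
            if self.points.shape[1] != 1:
                raise ValidationError("scale support must be a single column")
            if np.any(self.points <= 0):
                raise ValidationError("scale support requires positive variances")
        # keep sorted lexicographically; merge exact duplicates
        order = np.lexsort(self.points.T[::-1])
        pts = self.points[order]
        keep = np.ones(pts.shape[0], dtype=bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
        self.points = pts[keep]

    @property
    def m(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


def build_grid_1d(data: MixtureData, m: int) -> SupportSet:
    """Equally spaced points spanning ``[min Y, max Y]`` (inclusive), d=1."""
    if data.d != 1:
        raise InputError("build_grid_1d requires one-dimensional data")
    if m < 2:
        raise InputError("need m >= 2 grid points")
    lo, hi = data.Y.min(), data.Y.max()
    if hi <= lo:
        raise InputError(
            "all observations are identical; supply an explicit grid instead"
        )
    return SupportSet(np.linspace(lo, hi, m)[:, None], kind="location")


def build_grid_box(data: MixtureData, per_dim: int) -> SupportSet:
    """Cartesian product of per-coordinate equally spaced grids over the
    minimum axis-aligned bounding box of the data (``per_dim**d`` points)."""
    if data.d < 2:
        raise InputError("build_grid_box requires d >= 2; use build_grid_1d")
    if per_dim < 2:
        raise InputError("need per_dim >= 2")
    axes = []
    for j in range(data.d):
        lo, hi = data.Y[:, j].min(), data.Y[:, j].max()
        if hi <= lo:
            raise InputError(
                f"coordinate {j} is degenerate; supply an explicit grid instead"
            )
        axes.append(np.linspace(lo, hi, per_dim))
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([ax.ravel() for ax in mesh])
    return SupportSet(points, kind="location")


def build_scale_grid(data: MixtureData, m: int) -> SupportSet:
    """Geometric grid of variances from ``(0.05*sd)**2`` up to ``max Y**2``."""
    if data.d != 1:
        raise InputError("build_scale_grid requires one-dimensional data")
    if m < 2:
        raise InputError("need m >= 2 grid points")
    y = data.Y.ravel()
    v_max = float(np.max(y**2))
    if v_max <= 0:
        raise InputError("all observations are zero; no scale grid exists")
    v_min = (0.05 * float(np.std(y))) ** 2
    if v_min <= 0:
        v_min = 1e-6 * v_max
    return SupportSet(
        np.geomspace(v_min, v_max, m)[:, None], kind="scale"
    )
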