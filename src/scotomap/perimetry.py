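"""Perimetric sensitivity grids and scotoma contrast masks.

Standard automated perimetry (SAP, e.g. on a Humphrey Field Analyzer) measures
contrast sensitivity at a fixed set of visual-field locations and reports, per
location, the deviation from an age-corrected norm in decibels (dB).  Negative
deviations mean sensitivity loss.  This module ingests such grids, integrates
the two eyes into a binocular grid, and converts sensitivity loss into a
pixel-wise contrast-attenuation mask that simulates the scotoma on a retinotopy
stimulus: a 3 dB sensitivity decrease halves the stimulus contrast
(multiplier = 10^(deviation/10)).

Coordinates are degrees of visual angle, x positive rightward, y positive
upward, origin at fixation.  The right-eye coordinate convention is used for
both eyes; mirroring, if needed, is handled upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "PerimetryGrid",
    "FrameGeometry",
    "ContrastMask",
    "db_to_contrast",
    "integrate_binocular",
    "interpolate_deviation",
    "build_contrast_mask",
    "read_grid_csv",
    "write_grid_csv",
]

MAX_ECC_DEG = 40.0
EYES = ("left", "right", "binocular")


@dataclass(frozen=True)
class PerimetryGrid:
    """Per-eye or binocular sensitivity deviations (dB) at visual-field points.

    Parameters
    ----------
    points : (n, 2) array
        Test-point coordinates in degrees of visual angle.
    deviation_db : (n,) array
        Sensitivity deviation per point; <= 0 means loss.
    eye : {"left", "right", "binocular"}
    layout_name : str
        Free-text layout label, e.g. ``"24-2"``.
    """

    points: np.ndarray
    deviation_db: np.ndarray
    eye: str = "binocular"
    layout_name: str = "custom"

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        dev = np.atleast_1d(np.asarray(self.deviation_db, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of degrees")
        if dev.shape[0] != pts.shape[0]:
            raise ValueError(
                f"deviation_db has {dev.shape[0]} entries for {pts.shape[0]} points"
            )
        if pts.shape[0] == 0:
            raise ValueError("perimetry grid has no points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if not np.all(np.isfinite(dev)):
            raise ValueError("all deviations must be finite")
        if np.any(np.abs(pts) > MAX_ECC_DEG):
            raise ValueError(f"|x|,|y| must be <= {MAX_ECC_DEG} degrees")
        uniq = np.unique(pts, axis=0)
        if uniq.shape[0] != pts.shape[0]:
            raise ValueError("point coordinates must be unique")
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "deviation_db", dev)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class FrameGeometry:
    """Pixel raster geometry of a stimulus frame.

    ``center`` is the (row, col) pixel of fixation; y grows upward in degrees
    while rows grow downward, so ``y = (center_row - row) * deg_per_pixel``.
    """

    shape: tuple[int, int]
    deg_per_pixel: float
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.deg_per_pixel <= 0:
            raise ValueError("deg_per_pixel must be positive")
        if self.center is None:
            h, w = self.shape
            object.__setattr__(self, "center", ((h - 1) / 2.0, (w - 1) / 2.0))

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) degree coordinates of every pixel, each of ``shape``."""
        h, w = self.shape
        cy, cx = self.center
        cols = np.arange(w, dtype=float)
        rows = np.arange(h, dtype=float)
        x = (cols - cx) * self.deg_per_pixel
        y = (cy - rows) * self.deg_per_pixel
        return np.meshgrid(x, y)


@dataclass(frozen=True)
class ContrastMask:
    """2-D multiplicative contrast attenuation, values in [0, 1]."""

    values: np.ndarray
    deg_per_pixel: float
    center: tuple[float, float]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("mask values must be 2-D")
        if not np.all(np.isfinite(vals)):
            raise ValueError("mask values must be finite")
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    @property
    def geometry(self) -> FrameGeometry:
        return FrameGeometry(self.values.shape, self.deg_per_pixel, self.center)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",")

    def to_nifti(self, path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.values.astype(np.float32), affine=np.eye(4))
        nib.save(img, str(path))


def db_to_contrast(deviation_db):
    """Contrast multiplier implied by a perimetric sensitivity deviation.

    A deviation of d dB (d <= 0) attenuates stimulus contrast by 10^(d/10):
    -3 dB halves the contrast, -10 dB leaves 10%.  Gains (d > 0) map to 1,
    i.e. contrast is never boosted above the native stimulus contrast.

    Accepts scalars or arrays; returns the same shape.
    """
    dev = np.asarray(deviation_db, dtype=float)
    if not np.all(np.isfinite(dev)):
        raise ValueError("deviation_db must be finite")
    mult = np.power(10.0, np.minimum(dev, 0.0) / 10.0)
    out = np.clip(mult, 0.0, 1.0)
    return float(out) if np.isscalar(deviation_db) else out


def integrate_binocular(left: PerimetryGrid, right: PerimetryGrid) -> PerimetryGrid:
    """Combine two monocular grids into the binocular grid.

    The binocular sensitivity at each point is the better (maximum) of the two
    eyes' deviations; both grids must share the exact point layout.
    """
    if left.eye != "left" or right.eye != "right":
        raise ValueError(
            f"expected a left and a right grid, got {left.eye!r} and {right.eye!r}"
        )
    if left.n_points != right.n_points:
        raise ValueError(
            f"layout mismatch: left has {left.n_points} points, right has {right.n_points}"
        )
    same = np.isclose(left.points, right.points)
    if not same.all():
        i = int(np.argmin(same.all(axis=1)))
        raise ValueError(
            "layout mismatch at point "
            f"{i}: left {tuple(left.points[i])} vs right {tuple(right.points[i])}"
        )
    return PerimetryGrid(
        points=left.points,
        deviation_db=np.maximum(left.deviation_db, right.deviation_db),
        eye="binocular",
        layout_name=left.layout_name,
    )


def interpolate_deviation(grid: PerimetryGrid, xy: np.ndarray) -> np.ndarray:
    """Interpolate the grid's dB values at arbitrary (n, 2) degree positions.

    Linear interpolation on the Delaunay triangulation of the test points
    inside their convex hull, nearest-point beyond it.  Degenerate layouts
    (fewer than 3 points, collinear points) fall back to nearest-point
    everywhere.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    nearest = NearestNDInterpolator(grid.points, grid.deviation_db)
    out = None
    if grid.n_points >= 3:
        try:
            lin = LinearNDInterpolator(grid.points, grid.deviation_db)
            out = lin(xy)
        except QhullError:
            out = None
    if out is None:
        out = np.full(xy.shape[0], np.nan)
    hole = ~np.isfinite(out)
    if hole.any():
        out[hole] = nearest(xy[hole])
    return out


def build_contrast_mask(
    grid: PerimetryGrid,
    frame_spec: FrameGeometry,
    floor_db: float | None = None,
) -> ContrastMask:
    """Rasterize a binocular perimetry grid into a contrast-attenuation mask.

    dB deviations are interpolated to pixel resolution (linear within the
    convex hull of the test points, nearest-point beyond it) and then mapped
    pointwise through :func:`db_to_contrast`.

    Parameters
    ----------
    floor_db : float, optional
        If given, pixels whose interpolated deviation falls at or below this
        value are treated as blind (contrast multiplier 0).  The perimetric
        convention treats around -15 dB as functionally blind; disabled by
        default.
    """
    if grid.eye != "binocular":
        raise ValueError(
            "contrast masks are built from binocular grids; call integrate_binocular first"
        )
    X, Y = frame_spec.pixel_coords()
    xy = np.column_stack([X.ravel(), Y.ravel()])
    dev = interpolate_deviation(grid, xy)
    mult = db_to_contrast(dev)
    if floor_db is not None:
        mult = np.where(dev <= floor_db, 0.0, mult)
    values = mult.reshape(frame_spec.shape)
    return ContrastMask(values, frame_spec.deg_per_pixel, frame_spec.center)


# -- CSV dialect: header row x_deg,y_deg,deviation_db, one file per eye -------


def read_grid_csv(path, eye: str = "binocular", layout_name: str | None = None) -> PerimetryGrid:
    df = pd.read_csv(path)
    required = ["x_deg", "y_deg", "deviation_db"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"perimetry CSV missing columns: {missing}")
    return PerimetryGrid(
        points=df[["x_deg", "y_deg"]].to_numpy(float),
        deviation_db=df["deviation_db"].to_numpy(float),
        eye=eye,
        layout_name=layout_name or "csv",
    )


def write_grid_csv(grid: PerimetryGrid, path) -> None:
    pd.DataFrame(
        {
            "x_deg": grid.points[:, 0],
            "y_deg": grid.points[:, 1],
            "deviation_db": grid.deviation_db,
        }
    ).to_csv(path, index=False)
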