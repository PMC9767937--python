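"""fMRI-based visual-field reconstruction and normative deviation maps.

A visual area's fitted pRFs (or micro-probe weights) are back-projected onto a
lattice covering the stimulated field: the sampling density at a position is
the VE-weighted sum of the Gaussian receptive fields covering it.  Densities
are normalized to a maximum of 1 and expressed in decibels (10*log10), so an
intact field sits near 0 dB and poorly sampled regions fall toward the floor.

A subject's sensitivity map is then classified per position against a
normative control group by its empirical two-sided percentile, using the
boundary set {90, 95, 98, 99, 99.5}%: positions inside the innermost band are
"within"; positions beyond a boundary are labeled below@B or above@B at the
outermost boundary they violate.  With ~18 controls the extreme boundaries
saturate at the sample extremes — a documented small-sample limitation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .prf import PRFModel, ProbeMap

__all__ = [
    "VFGrid",
    "SensitivityMap",
    "DeviationMap",
    "BOUNDARIES",
    "backproject_density",
    "to_db",
    "reconstruct_sensitivity",
    "NormativeDeviation",
    "normative_deviation",
    "class_at_or_beyond",
]

BOUNDARIES = (90.0, 95.0, 98.0, 99.0, 99.5)
FLOOR_DB_DEFAULT = -40.0


@dataclass(frozen=True)
class VFGrid:
    """Lattice of visual-field positions within the mapped radius."""

    positions: np.ndarray  # (n, 2) degrees
    spacing: float
    field_radius: float = 7.0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, float))
        if pos.shape[1] != 2 or pos.shape[0] == 0:
            raise ValueError("positions must be a non-empty (n, 2) array")
        if np.any(np.hypot(pos[:, 0], pos[:, 1]) > self.field_radius + 1e-9):
            raise ValueError("all positions must lie within the field radius")
        object.__setattr__(self, "positions", pos)

    @classmethod
    def disc(cls, field_radius: float = 7.0, spacing: float = 0.25) -> "VFGrid":
        ax = np.arange(-field_radius, field_radius + 1e-9, spacing)
        xx, yy = np.meshgrid(ax, ax)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= field_radius + 1e-9]
        return cls(pts, spacing, field_radius)

    @property
    def n_positions(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class SensitivityMap:
    """Reconstructed visual-field sensitivity in dB (max 0, floored)."""

    values: np.ndarray
    grid: VFGrid
    floor_db: float = FLOOR_DB_DEFAULT

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, float)
        if vals.shape != (self.grid.n_positions,):
            raise ValueError("values must align with the grid positions")
        if np.any(vals > 1e-9):
            raise ValueError("sensitivity values must be <= 0 dB")
        if np.any(vals < self.floor_db - 1e-9):
            raise ValueError("sensitivity values must be >= floor_db")
        object.__setattr__(self, "values", vals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid.positions[:, 0],
                "y": self.grid.positions[:, 1],
                "db": self.values,
            }
        )


@dataclass(frozen=True)
class DeviationMap:
    """Per-position normative classification of a sensitivity map."""

    classes: np.ndarray  # array of strings: within / below@B / above@B
    grid: VFGrid
    boundaries: tuple[float, ...] = BOUNDARIES

    def fraction(self, predicate) -> float:
        return float(np.mean(predicate(self.classes)))

    def outside_band_fraction(self, boundary: float = 90.0) -> float:
        """Fraction of positions beyond the two-sided ``boundary``% band."""
        return float(
            np.mean(
                class_at_or_beyond(self.classes, "below", boundary)
                | class_at_or_beyond(self.classes, "above", boundary)
            )
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid.positions[:, 0],
                "y": self.grid.positions[:, 1],
                "class": self.classes,
            }
        )


def class_at_or_beyond(classes: np.ndarray, side: str, boundary: float) -> np.ndarray:
    """Boolean mask of positions classed ``side``@boundary or more extreme.

    Classification nests: a position beyond the 99% boundary is also beyond
    95 and 90, so "below@95 or worse" is ``class_at_or_beyond(c, "below", 95)``.
    """
    if side not in ("below", "above"):
        raise ValueError("side must be 'below' or 'above'")
    levels = [b for b in BOUNDARIES if b >= boundary]
    wanted = {f"{side}@{b:g}" for b in levels}
    return np.isin(classes, sorted(wanted))


def backproject_density(models, grid: VFGrid, weight: str = "ve") -> np.ndarray:
    """Visual-field sampling density from pRF models or a micro-probe map.

    For a list of :class:`PRFModel`, density(p) = sum_v w_v * exp(-|p - c_v|^2
    / (2 sigma_v^2)) with w_v the model's VE (or beta with ``weight="beta"``).
    For a :class:`ProbeMap`, each probe contributes its summed voxel weight
    through a Gaussian of the probe size.  The result is normalized to a
    maximum of 1.
    """
    pos = grid.positions
    if isinstance(models, ProbeMap):
        centers = models.probes
        sigmas = np.full(len(centers), models.sigma_probe)
        weights = models.weights.sum(axis=0)
    else:
        models = list(models)
        if len(models) == 0:
            raise ValueError("no models to back-project")
        centers = np.array([[m.x0, m.y0] for m in models])
        sigmas = np.array([m.sigma for m in models])
        if weight == "ve":
            weights = np.array([m.ve for m in models])
        elif weight == "beta":
            weights = np.array([abs(m.beta) for m in models])
        else:
            raise ValueError("weight must be 've' or 'beta'")
    d2 = (pos[:, 0:1] - centers[None, :, 0]) ** 2 + (
        pos[:, 1:2] - centers[None, :, 1]
    ) ** 2
    density = (np.exp(-d2 / (2 * sigmas[None, :] ** 2)) * weights[None, :]).sum(axis=1)
    peak = density.max()
    if peak <= 0:
        raise ValueError("density is identically zero; no responsive models")
    return density / peak


def to_db(
    density: np.ndarray, grid: VFGrid, floor_db: float = FLOOR_DB_DEFAULT
) -> SensitivityMap:
    """Convert a normalized sampling density to a dB sensitivity map."""
    density = np.asarray(density, float)
    if np.any(density < 0):
        raise ValueError("density must be non-negative")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(density)
    db = np.maximum(db, floor_db)
    db = np.minimum(db, 0.0)
    return SensitivityMap(db, grid, floor_db)


def reconstruct_sensitivity(
    models, grid: VFGrid | None = None, floor_db: float = FLOOR_DB_DEFAULT,
    weight: str = "ve",
) -> SensitivityMap:
    """Back-project models and convert to dB in one step."""
    grid = grid or VFGrid.disc()
    return to_db(backproject_density(models, grid, weight=weight), grid, floor_db)


class NormativeDeviation(BaseEstimator):
    """Per-position empirical percentile classification against controls.

    ``fit`` takes the normative control maps (a (n_controls, n_positions)
    array or a list of :class:`SensitivityMap`); ``transform`` classifies a
    subject map per position by the outermost two-sided boundary its
    percentile violates.
    """

    def __init__(self, boundaries: tuple[float, ...] = BOUNDARIES, min_controls: int = 5):
        self.boundaries = boundaries
        self.min_controls = min_controls

    @staticmethod
    def _values(maps) -> np.ndarray:
        if isinstance(maps, SensitivityMap):
            return maps.values[None, :]
        if isinstance(maps, np.ndarray):
            return np.atleast_2d(maps)
        return np.vstack([m.values for m in maps])

    def fit(self, controls, y=None):
        vals = self._values(controls)
        if vals.shape[0] < self.min_controls:
            raise ValueError(
                f"need at least {self.min_controls} control maps, got {vals.shape[0]}"
            )
        self.control_values_ = vals
        self.n_controls_ = vals.shape[0]
        return self

    def transform(self, subject) -> np.ndarray:
        if not hasattr(self, "control_values_"):
            raise ValueError("estimator is not fitted")
        sub = self._values(subject)[0]
        ctl = self.control_values_
        n = self.n_controls_
        below = (ctl < sub[None, :]).sum(axis=0)
        ties = (ctl == sub[None, :]).sum(axis=0)
        pct = (below + 0.5 * ties) / n  # empirical two-sided percentile
        classes = np.full(sub.shape, "within", dtype=object)
        for b in sorted(self.boundaries):  # outermost boundary wins
            tail = (1.0 - b / 100.0) / 2.0
            classes[pct < tail] = f"below@{b:g}"
            classes[pct > 1.0 - tail] = f"above@{b:g}"
        return np.asarray(classes, dtype="U12")


def normative_deviation(
    subject: SensitivityMap,
    controls: list[SensitivityMap],
    exclude: int | None = None,
) -> DeviationMap:
    """Classify a subject map against a control group.

    ``exclude`` drops one control by index before fitting — the matched
    control whose simulated scotoma corresponds to the subject, which would
    otherwise contaminate the norm.
    """
    ctl = list(controls)
    if exclude is not None:
        ctl = [m for i, m in enumerate(ctl) if i != exclude]
    est = NormativeDeviation().fit(ctl)
    classes = est.transform(subject)
    return DeviationMap(classes, subject.grid)
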