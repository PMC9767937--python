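"""Synthetic ground truth: pRF sheets, glaucoma/control cohorts, forward BOLD.

This module makes every downstream stage testable without any acquisition: it
samples ground-truth pRF "sheets" (units with center, size, gain, visual-area
label), degrades them with perimetry-linked gain loss, injects plasticity
signatures (pRF shifts away from a scotoma, size enlargements), and forward-
simulates BOLD through the same Gaussian-overlap + HRF model the fitter
inverts, plus cosine drift and AR(1) Gaussian noise.

The cohort generator mirrors the study design: matched glaucoma/control pairs
(default 19), where the glaucoma member views the full stimulus through a
damaged retina (gain attenuation, optional plasticity) and the matched control
views a simulated-scotoma (SS) stimulus with a healthy sheet; a no-simulation
(NS) control dataset completes the triplet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .hemodynamics import HRFSpec, convolve_hrf
from .perimetry import (
    PerimetryGrid,
    build_contrast_mask,
    db_to_contrast,
    interpolate_deviation,
)
from .prf import PRFModel, _flat_coords
from .stimulus import ApertureMovie, apply_scotoma, make_lcr_movie
from .timeseries import TimeSeriesSet

__all__ = [
    "SimSpec",
    "GroundTruthSheet",
    "EstimationNoise",
    "QuadrantRegion",
    "CircularRegion",
    "sample_sheet",
    "inject_plasticity",
    "apply_damage",
    "simulate_bold",
    "sheet_to_models",
    "layout_24_2",
    "archetype_grid",
    "make_cohort",
    "CohortPair",
    "CohortBundle",
    "ARCHETYPES",
]

AREAS = ("V1", "V2", "V3")
AREA_PROBS = (0.6, 0.25, 0.15)


@dataclass(frozen=True)
class SimSpec:
    """Simulation conditions.

    ``noise_sd`` (percent signal) is the reference noise level, calibrated so
    a default sheet fitted by the conventional mapper lands at a median
    variance explained of about 0.5.  ``size_intercept``/``size_slope`` give
    the linear growth of pRF size with eccentricity typical of early visual
    cortex; ``damage_exponent`` (kappa) couples local perimetric loss to unit
    gain as ``gain *= (10^(dev/10))^kappa``.
    """

    n_units: int = 500
    size_intercept: float = 0.5  # degrees
    size_slope: float = 0.15  # degrees per degree of eccentricity
    sigma_jitter: float = 0.2  # lognormal sd of multiplicative size jitter
    gain: float = 2.0  # percent signal at sustained full-field drive
    noise_sd: float = 0.25  # percent signal, AR(1) marginal sd
    ar1: float = 0.3
    drift_amp: float = 0.1  # percent signal, cosine drift scale
    damage_exponent: float = 1.0  # kappa
    n_runs: int = 4  # runs acquired and averaged before fitting
    field_radius: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruthSheet:
    """Ground-truth pRF units: centers, sizes, gains and area labels."""

    x0: np.ndarray
    y0: np.ndarray
    sigma: np.ndarray
    gain: np.ndarray
    area: np.ndarray
    field_radius: float = 7.0

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "sigma", "gain"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        object.__setattr__(self, "area", np.asarray(self.area))
        if self.x0.size == 0:
            raise ValueError("empty sheet")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if np.any(self.gain < 0):
            raise ValueError("gain must be non-negative")
        ecc = np.hypot(self.x0, self.y0)
        if np.any(ecc > self.field_radius + 2 * self.sigma):
            raise ValueError("unit centers lie too far outside the field")

    @property
    def n_units(self) -> int:
        return self.x0.size

    @property
    def ecc(self) -> np.ndarray:
        return np.hypot(self.x0, self.y0)

    def to_json(self, path) -> None:
        payload = {
            "x0": self.x0.tolist(),
            "y0": self.y0.tolist(),
            "sigma": self.sigma.tolist(),
            "gain": self.gain.tolist(),
            "area": self.area.tolist(),
            "field_radius": self.field_radius,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass(frozen=True)
class EstimationNoise:
    """Fit-error emulation for the fast (fit-free) analysis path.

    Defaults are calibrated to the conventional mapper's measured recovery at
    the reference noise level: Gaussian position scatter per axis and
    lognormal multiplicative size scatter.
    """

    pos_sd: float = 0.19  # degrees per axis
    sigma_rel_sd: float = 0.24  # lognormal sd of sigma


class QuadrantRegion:
    """One visual-field quadrant, named UL/UR/LL/LR; ``center`` is its centroid."""

    SIGNS = {"UL": (-1, 1), "UR": (1, 1), "LL": (-1, -1), "LR": (1, -1)}

    def __init__(self, name: str, field_radius: float = 7.0):
        if name not in self.SIGNS:
            raise ValueError(f"quadrant must be one of {sorted(self.SIGNS)}")
        self.name = name
        sx, sy = self.SIGNS[name]
        # centroid of a quarter disc sits at 4R/(3*pi) along each axis
        c = 4 * field_radius / (3 * np.pi)
        self.center = np.array([sx * c, sy * c])
        self._signs = (sx, sy)

    def contains(self, x, y):
        sx, sy = self._signs
        return (np.sign(x) == sx) & (np.sign(y) == sy)


class CircularRegion:
    def __init__(self, cx: float, cy: float, radius: float):
        self.center = np.array([cx, cy])
        self.radius = radius

    def contains(self, x, y):
        return np.hypot(x - self.center[0], y - self.center[1]) <= self.radius


def sample_sheet(spec: SimSpec, rng: np.random.Generator | None = None) -> GroundTruthSheet:
    """Draw a ground-truth sheet: centers uniform over the stimulated disc,
    sizes growing linearly with eccentricity plus lognormal jitter."""
    if spec.n_units <= 0:
        raise ValueError("n_units must be positive")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    r = spec.field_radius * np.sqrt(rng.uniform(size=spec.n_units))
    theta = rng.uniform(0, 2 * np.pi, size=spec.n_units)
    x0 = r * np.cos(theta)
    y0 = r * np.sin(theta)
    sigma = spec.size_intercept + spec.size_slope * r
    if spec.sigma_jitter > 0:
        sigma = sigma * np.exp(rng.normal(0.0, spec.sigma_jitter, size=spec.n_units))
    gain = np.full(spec.n_units, spec.gain)
    area = rng.choice(AREAS, size=spec.n_units, p=AREA_PROBS)
    return GroundTruthSheet(x0, y0, sigma, gain, area, spec.field_radius)


def inject_plasticity(
    sheet: GroundTruthSheet,
    region,
    mode: str,
    magnitude: float,
) -> GroundTruthSheet:
    """Inject a plasticity signature into units whose center lies in ``region``.

    ``enlarge`` multiplies their sigma by (1 + magnitude); ``shift`` moves
    their centers by ``magnitude`` degrees radially away from the region
    center (the scotoma centroid).  ``region`` needs ``contains(x, y)`` and a
    ``center`` attribute; plain callables are wrapped with the affected
    units' centroid as center.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if mode not in ("shift", "enlarge"):
        raise ValueError(f"unknown plasticity mode {mode!r}")
    if callable(region) and not hasattr(region, "contains"):
        fn = region
        mask = np.asarray(fn(sheet.x0, sheet.y0), bool)
        center = (
            np.array([sheet.x0[mask].mean(), sheet.y0[mask].mean()])
            if mask.any()
            else np.zeros(2)
        )
    else:
        mask = np.asarray(region.contains(sheet.x0, sheet.y0), bool)
        center = np.asarray(region.center, float)
    if magnitude == 0 or not mask.any():
        return sheet
    if mode == "enlarge":
        sigma = sheet.sigma.copy()
        sigma[mask] *= 1.0 + magnitude
        return replace(sheet, sigma=sigma)
    dx = sheet.x0[mask] - center[0]
    dy = sheet.y0[mask] - center[1]
    norm = np.hypot(dx, dy)
    norm = np.where(norm == 0, 1.0, norm)
    x0 = sheet.x0.copy()
    y0 = sheet.y0.copy()
    x0[mask] += magnitude * dx / norm
    y0[mask] += magnitude * dy / norm
    # keep shifted units inside the sheet's validity margin
    ecc = np.hypot(x0, y0)
    limit = sheet.field_radius + 2 * sheet.sigma
    over = ecc > limit
    if over.any():
        scale = limit[over] / ecc[over]
        x0[over] *= scale
        y0[over] *= scale
    return replace(sheet, x0=x0, y0=y0)


def apply_damage(
    sheet: GroundTruthSheet, grid: PerimetryGrid, kappa: float
) -> GroundTruthSheet:
    """Attenuate unit gains by the local perimetric loss raised to kappa."""
    if grid.eye != "binocular":
        raise ValueError("damage requires a binocular perimetry grid")
    if kappa == 0:
        return sheet
    dev = interpolate_deviation(grid, np.column_stack([sheet.x0, sheet.y0]))
    factor = db_to_contrast(dev) ** kappa
    return replace(sheet, gain=sheet.gain * factor)


def _unit_drives(sheet: GroundTruthSheet, movie: ApertureMovie) -> np.ndarray:
    """Noiseless neural drive of every unit, (n_units, T), normalized by each
    unit's full Gaussian mass (receptive fields reaching beyond the raster
    contribute proportionally less drive)."""
    frames_flat, xf, yf = _flat_coords(movie)
    mass = 2.0 * np.pi * sheet.sigma**2 / movie.deg_per_pixel**2
    out = np.empty((sheet.n_units, frames_flat.shape[0]))
    chunk = max(1, int(2e7 // frames_flat.shape[1]))
    for a in range(0, sheet.n_units, chunk):
        b = min(a + chunk, sheet.n_units)
        g = np.exp(
            -(
                (xf[None, :] - sheet.x0[a:b, None]) ** 2
                + (yf[None, :] - sheet.y0[a:b, None]) ** 2
            )
            / (2 * sheet.sigma[a:b, None] ** 2)
        )
        g /= mass[a:b, None]
        out[a:b] = g @ frames_flat.T
    return out


def _reference_peak(movie: ApertureMovie, hrf: HRFSpec) -> float:
    """Peak of the HRF-convolved response to sustained full-field drive."""
    ones = np.ones(movie.frames.shape[0])
    return float(np.max(convolve_hrf(ones, hrf, movie.tr_seconds)))


def noiseless_signal(
    sheet: GroundTruthSheet, movie: ApertureMovie, hrf: HRFSpec | None = None
) -> np.ndarray:
    """Drift- and noise-free percent-signal response of every unit."""
    hrf = hrf or HRFSpec()
    drives = _unit_drives(sheet, movie)
    conv = convolve_hrf(drives, hrf, movie.tr_seconds)
    ref = _reference_peak(movie, hrf)
    return sheet.gain[:, None] * conv / ref


def simulate_bold(
    sheet: GroundTruthSheet,
    movie: ApertureMovie,
    hrf: HRFSpec | None = None,
    spec: SimSpec | None = None,
    rng: np.random.Generator | None = None,
) -> TimeSeriesSet:
    """Forward-simulate BOLD percent-signal-change series for a sheet.

    Per unit: Gaussian-overlap drive through the aperture movie, HRF
    convolution normalized so a sustained full-field drive peaks at the unit's
    gain, plus a slow cosine drift (per-unit Gaussian amplitude of scale
    ``drift_amp`` at the run's slowest nonzero DCT frequency) and AR(1)
    Gaussian noise with marginal sd ``noise_sd``.
    """
    if movie.n_frames == 0:
        raise ValueError("empty movie")
    spec = spec or SimSpec()
    hrf = hrf or HRFSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    signal = noiseless_signal(sheet, movie, hrf)
    T = signal.shape[1]
    t = np.arange(T)
    if spec.drift_amp > 0:
        amp = rng.normal(0.0, spec.drift_amp, size=(sheet.n_units, 1))
        signal = signal + amp * np.cos(np.pi * (t + 0.5) / T)[None, :]
    if spec.noise_sd > 0:
        e = rng.normal(0.0, 1.0, size=(sheet.n_units, T))
        e *= spec.noise_sd * np.sqrt(1.0 - spec.ar1**2)
        e[:, 0] /= np.sqrt(1.0 - spec.ar1**2)  # stationary start
        noise = lfilter([1.0], [1.0, -spec.ar1], e, axis=1)
        signal = signal + noise
    return TimeSeriesSet(data=signal, tr_seconds=movie.tr_seconds)


def simulate_runs(
    sheet: GroundTruthSheet,
    movie: ApertureMovie,
    hrf: HRFSpec | None = None,
    spec: SimSpec | None = None,
    n_runs: int | None = None,
    rng: np.random.Generator | None = None,
) -> TimeSeriesSet:
    """Average of independently-noised repetitions of the same run.

    Retinotopy protocols acquire several identical runs per condition and
    average them before fitting; drift and noise are drawn fresh per run
    while the stimulus-locked signal repeats, so noise variance shrinks by
    the number of runs.
    """
    spec = spec or SimSpec()
    n_runs = n_runs if n_runs is not None else spec.n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    acc = None
    for _ in range(n_runs):
        run = simulate_bold(sheet, movie, hrf, spec, rng=rng).data
        acc = run if acc is None else acc + run
    return TimeSeriesSet(acc / n_runs, movie.tr_seconds)


def sheet_to_models(
    sheet: GroundTruthSheet,
    movie: ApertureMovie,
    hrf: HRFSpec | None = None,
    spec: SimSpec | None = None,
    estimation_noise: EstimationNoise | None = None,
    rng: np.random.Generator | None = None,
) -> list[PRFModel]:
    """Convert a ground-truth sheet into PRFModel records with expected VE.

    The fast, fit-free analysis path: each unit's variance explained is the
    analytic expectation var(signal) / (var(signal) + var(noise)), with the
    noiseless signal variance computed through the forward model on the
    dummy-stripped design and the noise variance taken from the simulation
    conditions (AR(1) marginal variance plus expected drift power, divided by
    the number of averaged runs).  An optional :class:`EstimationNoise`
    perturbs positions and sizes to emulate fitting error.
    """
    spec = spec or SimSpec()
    hrf = hrf or HRFSpec()
    design = movie.design()
    signal = noiseless_signal(sheet, design, hrf)
    var_s = signal.var(axis=1)
    var_n = (spec.noise_sd**2 + spec.drift_amp**2 / 2.0) / max(spec.n_runs, 1)
    ve = var_s / (var_s + var_n) if var_n > 0 else (var_s > 0).astype(float)
    x0, y0, sigma = sheet.x0.copy(), sheet.y0.copy(), sheet.sigma.copy()
    if estimation_noise is not None:
        rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
        x0 += rng.normal(0.0, estimation_noise.pos_sd, size=sheet.n_units)
        y0 += rng.normal(0.0, estimation_noise.pos_sd, size=sheet.n_units)
        sigma *= np.exp(rng.normal(0.0, estimation_noise.sigma_rel_sd, sheet.n_units))
    return [
        PRFModel(
            x0=float(x0[i]),
            y0=float(y0[i]),
            sigma=float(sigma[i]),
            beta=float(sheet.gain[i]),
            baseline=0.0,
            ve=float(min(ve[i], 1.0)),
            area=str(sheet.area[i]),
        )
        for i in range(sheet.n_units)
    ]


# ----------------------------------------------------------------------------
# perimetry archetypes and cohorts
# ----------------------------------------------------------------------------


def layout_24_2() -> np.ndarray:
    """Test-point coordinates (degrees) of the 24-2 perimetry pattern."""
    pts = []
    rows = {
        21: (3, 9),
        15: (3, 9, 15),
        9: (3, 9, 15, 21),
        3: (3, 9, 15, 21, 27),
    }
    for ay, axs in rows.items():
        for y in (ay, -ay):
            for ax in axs:
                for x in (ax, -ax):
                    if ax == 27 and x < 0:
                        continue  # nasal extension on one side only
                    pts.append((float(x), float(y)))
    return np.array(sorted(set(pts)))


def _quadrant_loss(pts: np.ndarray, depth_db: float, quadrant: str = "UR") -> np.ndarray:
    sx, sy = QuadrantRegion.SIGNS[quadrant]
    dev = np.zeros(len(pts))
    mask = (np.sign(pts[:, 0]) == sx) & (np.sign(pts[:, 1]) == sy)
    dev[mask] = depth_db
    return dev


def _arcuate(pts: np.ndarray, depth_db: float, hemifield: str = "upper") -> np.ndarray:
    ecc = np.hypot(pts[:, 0], pts[:, 1])
    half = pts[:, 1] > 0 if hemifield == "upper" else pts[:, 1] < 0
    mask = half & (ecc >= 6) & (ecc <= 18)
    dev = np.zeros(len(pts))
    dev[mask] = depth_db
    return dev


def _nasal_step(pts: np.ndarray, depth_db: float) -> np.ndarray:
    mask = (pts[:, 0] >= 3) & (pts[:, 1] > 0)
    dev = np.zeros(len(pts))
    dev[mask] = depth_db
    return dev


def _no_loss(pts: np.ndarray, depth_db: float) -> np.ndarray:
    return np.zeros(len(pts))


ARCHETYPES = {
    "quadrant": _quadrant_loss,
    "arcuate": _arcuate,
    "nasal_step": _nasal_step,
    "none": _no_loss,
}


def archetype_grid(
    name: str, depth_db: float = -20.0, layout: np.ndarray | None = None, **kwargs
) -> PerimetryGrid:
    """Binocular perimetry grid of a named scotoma archetype.

    Archetypes: ``quadrant`` (dense quadrant loss), ``arcuate`` (arcuate
    bundle defect), ``nasal_step``, ``none`` (healthy).  ``depth_db`` is the
    loss at affected points (<= 0).
    """
    try:
        fn = ARCHETYPES[name]
    except KeyError:
        raise ValueError(f"unknown archetype {name!r}; choose from {sorted(ARCHETYPES)}")
    pts = layout if layout is not None else layout_24_2()
    dev = fn(pts, depth_db, **kwargs)
    return PerimetryGrid(pts, dev, eye="binocular", layout_name=f"24-2:{name}")


@dataclass
class CohortPair:
    pair_id: int
    archetype: str
    depth_db: float
    grid: PerimetryGrid
    glaucoma_sheet: GroundTruthSheet
    control_sheet: GroundTruthSheet
    seeds: dict
    ts_glaucoma: TimeSeriesSet | None = None
    ts_control_ss: TimeSeriesSet | None = None
    ts_control_ns: TimeSeriesSet | None = None


@dataclass
class CohortBundle:
    pairs: list[CohortPair]
    spec: SimSpec

    def __len__(self) -> int:
        return len(self.pairs)

    def manifest(self) -> dict:
        return {
            "n_pairs": len(self.pairs),
            "seed": self.spec.seed,
            "pairs": [
                {
                    "pair_id": p.pair_id,
                    "archetype": p.archetype,
                    "depth_db": p.depth_db,
                    "seeds": p.seeds,
                }
                for p in self.pairs
            ],
        }


def make_cohort(
    n_pairs: int = 19,
    scotoma_archetypes: tuple[str, ...] = ("quadrant", "arcuate", "nasal_step"),
    spec: SimSpec | None = None,
    depth_range: tuple[float, float] = (-30.0, -5.0),
    plasticity_mode: str | None = None,
    plasticity_magnitude: float = 0.0,
    plasticity_region: str = "UR",
    simulate: bool = False,
    movie: ApertureMovie | None = None,
    hrf: HRFSpec | None = None,
) -> CohortBundle:
    """Generate matched glaucoma/control pairs.

    Per pair: a glaucoma perimetry grid drawn from the archetype cycle with a
    loss depth uniform over ``depth_range``; a glaucoma sheet (healthy draw,
    then gain damage with the spec's kappa, then optional plasticity inside
    the scotomatous region); and an independent healthy control sheet.  With
    ``simulate=True`` the three per-pair BOLD datasets (glaucoma full-field,
    control SS, control NS) are forward-simulated.

    All randomness derives from ``spec.seed`` through spawned substreams; the
    spawn keys are recorded per pair so any pair can be regenerated.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    for name in scotoma_archetypes:
        if name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {name!r}")
    spec = spec or SimSpec()
    hrf = hrf or HRFSpec()
    if simulate and movie is None:
        movie = make_lcr_movie()
    root = np.random.SeedSequence(spec.seed)
    pair_seeds = root.spawn(n_pairs)
    pairs: list[CohortPair] = []
    for i in range(n_pairs):
        streams = pair_seeds[i].spawn(6)
        rng_depth = np.random.default_rng(streams[0])
        archetype = scotoma_archetypes[i % len(scotoma_archetypes)]
        depth = float(rng_depth.uniform(*depth_range)) if archetype != "none" else 0.0
        grid = archetype_grid(archetype, depth_db=depth)
        g_sheet = sample_sheet(spec, rng=np.random.default_rng(streams[1]))
        g_sheet = apply_damage(g_sheet, grid, spec.damage_exponent)
        if plasticity_mode is not None and plasticity_magnitude > 0:
            region = QuadrantRegion(plasticity_region, spec.field_radius)
            g_sheet = inject_plasticity(
                g_sheet, region, plasticity_mode, plasticity_magnitude
            )
        c_sheet = sample_sheet(spec, rng=np.random.default_rng(streams[2]))
        pair = CohortPair(
            pair_id=i,
            archetype=archetype,
            depth_db=depth,
            grid=grid,
            glaucoma_sheet=g_sheet,
            control_sheet=c_sheet,
            seeds={"root": int(spec.seed), "pair_index": i},
        )
        if simulate:
            mask = build_contrast_mask(grid, movie.geometry)
            ss_movie = apply_scotoma(movie, mask)
            # glaucoma participants are scanned for 6 retinotopy runs,
            # controls for 4 per condition
            pair.ts_glaucoma = simulate_runs(
                g_sheet, movie, hrf, spec, n_runs=6,
                rng=np.random.default_rng(streams[3]),
            )
            pair.ts_control_ss = simulate_runs(
                c_sheet, ss_movie, hrf, spec, n_runs=4,
                rng=np.random.default_rng(streams[4]),
            )
            pair.ts_control_ns = simulate_runs(
                c_sheet, movie, hrf, spec, n_runs=4,
                rng=np.random.default_rng(streams[5]),
            )
        pairs.append(pair)
    return CohortBundle(pairs=pairs, spec=spec)
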