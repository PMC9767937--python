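"""Population receptive field estimation.

A voxel's population receptive field (pRF) is modeled as an isotropic 2-D
Gaussian in visual space with center (x0, y0) and size sigma (degrees).  The
neural drive at frame t is the aperture-weighted Gaussian mass,

    n(t) = sum_pixels frame(t) * G(x, y; x0, y0, sigma) / sum_pixels G,

and the predicted BOLD series is ``baseline + beta * (n (*) h)`` with h the
hemodynamic response sampled at the TR.  Fitting is a two-stage search:
an exhaustive coarse grid over candidate (x0, y0, sigma) scored by variance
explained (VE = 1 - RSS/TSS, amplitude and baseline solved by least squares),
followed by derivative-free local refinement.  The full-field (FF) and
scotoma-field (SF) variants differ only in the effective aperture handed to
the fitter.

Micro-probing is a complementary dense-probe technique: a lattice of small
fixed-size Gaussians is regressed against the series one probe at a time and
the per-probe VE weights are aggregated into a weighted centroid and spread,
exposing sub-pRF structure that a single-Gaussian fit averages away.

Polar angle convention: theta = 0 at the upper vertical meridian, increasing
counterclockwise, so the upper-left quadrant spans (0, pi/2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator

from .hemodynamics import HRFSpec, convolve_hrf
from .stimulus import ApertureMovie
from .timeseries import TimeSeriesSet

__all__ = [
    "PRFModel",
    "GridSpec",
    "ProbeMap",
    "GaussianPRFMapper",
    "MicroProber",
    "preprocess",
    "dct_basis",
    "predict_timeseries",
    "fit_prf",
    "micro_probe",
    "threshold_models",
    "polar_angle",
]

VE_THRESHOLD_DEFAULT = 0.15
ECC_RANGE_DEFAULT = (0.0, 7.0)


def polar_angle(x0, y0):
    """Polar angle with 0 at the upper vertical meridian, counterclockwise.

    The upper-left quadrant spans (0, pi/2]; a center on the upper meridian
    itself (theta = 0) belongs to the upper-right quadrant.
    """
    return np.mod(-np.arctan2(x0, y0), 2 * np.pi)


@dataclass(frozen=True)
class PRFModel:
    """A fitted 2-D Gaussian pRF."""

    x0: float
    y0: float
    sigma: float
    beta: float
    baseline: float
    ve: float
    degenerate: bool = False
    area: str = "V1"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.ve > 1 + 1e-12:
            raise ValueError("variance explained cannot exceed 1")

    @property
    def ecc(self) -> float:
        return math.hypot(self.x0, self.y0)

    @property
    def polar(self) -> float:
        return float(polar_angle(self.x0, self.y0))


@dataclass(frozen=True)
class GridSpec:
    """Coarse-search lattice of candidate centers and sizes (degrees)."""

    xs: np.ndarray = field(default_factory=lambda: np.arange(-8.0, 8.01, 0.5))
    ys: np.ndarray = field(default_factory=lambda: np.arange(-8.0, 8.01, 0.5))
    sigmas: tuple[float, ...] = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        xs = np.asarray(self.xs, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        if xs.size == 0 or ys.size == 0 or len(self.sigmas) == 0:
            raise ValueError("grid must be non-empty")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("candidate sigmas must be positive")
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)


@dataclass(frozen=True)
class ProbeMap:
    """Micro-probing output: probe lattice plus per-voxel VE weights."""

    probes: np.ndarray  # (n_probes, 2) degrees
    sigma_probe: float
    weights: np.ndarray  # (n_voxels, n_probes), >= 0
    centers: np.ndarray  # (n_voxels, 2) weighted centroids (nan if degenerate)
    spread: np.ndarray  # (n_voxels,) weighted RMS distance to centroid
    degenerate: np.ndarray  # (n_voxels,) bool

    def to_long_frame(self) -> pd.DataFrame:
        n_vox, n_probes = self.weights.shape
        return pd.DataFrame(
            {
                "unit_id": np.repeat(np.arange(n_vox), n_probes),
                "probe_x": np.tile(self.probes[:, 0], n_vox),
                "probe_y": np.tile(self.probes[:, 1], n_vox),
                "weight": self.weights.ravel(),
            }
        )


# ----------------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------------


def dct_basis(n_frames: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """DCT-II nuisance basis: all components with frequency below the cutoff.

    Component k has frequency k / (2 * n_frames * tr) Hz; the constant (k = 0)
    is always included.  Returns an (n_frames, n_kept) column matrix.
    """
    t = np.arange(n_frames)
    ks = [0]
    k = 1
    while k / (2.0 * n_frames * tr) < cutoff_hz:
        ks.append(k)
        k += 1
    cols = [np.cos(np.pi * k * (t + 0.5) / n_frames) for k in ks]
    return np.column_stack(cols)


def preprocess(
    ts: TimeSeriesSet,
    dummy: int = 8,
    cutoff_hz: float = 0.001,
    psc: str | bool = "auto",
) -> TimeSeriesSet:
    """Discard dummy frames, convert to percent signal change, detrend.

    The first ``dummy`` frames are dropped (saturation transients), each
    series is expressed as percent change about its temporal mean, and a
    discrete-cosine basis with frequencies below ``cutoff_hz`` is regressed
    out (this always removes the mean).

    ``psc`` controls the percent-signal-change conversion: ``True`` divides by
    the mean (raw scanner units), ``False`` only centers, and ``"auto"``
    divides when the input is strictly positive (raw-intensity-like) and
    centers otherwise (already in percent units).
    """
    data = ts.data
    if data.shape[1] <= dummy:
        raise ValueError(
            f"series of length {data.shape[1]} cannot drop {dummy} dummy frames"
        )
    data = data[:, dummy:]
    mean = data.mean(axis=1, keepdims=True)
    if psc == "auto":
        psc = bool(np.all(data > 0))
    if psc:
        safe = np.where(mean == 0, 1.0, mean)
        data = 100.0 * (data - mean) / safe
    else:
        data = data - mean
    basis = dct_basis(data.shape[1], ts.tr_seconds, cutoff_hz)
    coef, *_ = np.linalg.lstsq(basis, data.T, rcond=None)
    data = data - (basis @ coef).T
    return TimeSeriesSet(data=data, tr_seconds=ts.tr_seconds)


# ----------------------------------------------------------------------------
# forward model
# ----------------------------------------------------------------------------


def _flat_coords(movie: ApertureMovie) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X, Y = movie.pixel_coords()
    T = movie.frames.shape[0]
    return movie.frames.reshape(T, -1), X.ravel(), Y.ravel()


def _gaussian_mass(sigma: float, deg_per_pixel: float) -> float:
    """Full Gaussian mass in pixel units: the continuous integral 2*pi*sigma^2
    expressed in pixel counts.  Normalizing the drive by the full mass (rather
    than the on-raster sum) keeps receptive fields that extend beyond the
    stimulated raster properly weak instead of inflating their tails."""
    return 2.0 * np.pi * sigma**2 / deg_per_pixel**2


def gaussian_drive(
    frames_flat: np.ndarray,
    xf: np.ndarray,
    yf: np.ndarray,
    x0: float,
    y0: float,
    sigma: float,
    deg_per_pixel: float,
) -> np.ndarray:
    """Aperture overlap of one Gaussian pRF, normalized by its full mass."""
    g = np.exp(-((xf - x0) ** 2 + (yf - y0) ** 2) / (2.0 * sigma**2))
    return frames_flat @ g / _gaussian_mass(sigma, deg_per_pixel)


def predict_timeseries(
    model: PRFModel, apertures: ApertureMovie, hrf: HRFSpec | None = None
) -> np.ndarray:
    """Predicted BOLD series of a pRF model for a dummy-stripped aperture movie."""
    if apertures.dummy_frames != 0:
        raise ValueError("apertures must be dummy-stripped (use movie.design())")
    hrf = hrf or HRFSpec()
    frames_flat, xf, yf = _flat_coords(apertures)
    drive = gaussian_drive(
        frames_flat, xf, yf, model.x0, model.y0, model.sigma, apertures.deg_per_pixel
    )
    conv = convolve_hrf(drive, hrf, apertures.tr_seconds)
    return model.baseline + model.beta * conv


def _candidate_predictions(
    movie: ApertureMovie, grid: GridSpec, hrf: HRFSpec
) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved predictions of every grid candidate.

    Exploits the separability of the isotropic Gaussian: for each candidate
    sigma the drive over all (x0, y0) lattice points reduces to two small
    matrix contractions per frame instead of a per-candidate raster sum.

    Returns ``(params, preds)`` with ``params`` of shape (n_cand, 3) as
    (x0, y0, sigma) and ``preds`` of shape (n_cand, T).
    """
    F = movie.frames.astype(float)  # (T, H, W)
    X, Y = movie.pixel_coords()
    x = X[0, :]  # (W,)
    y = Y[:, 0]  # (H,)
    h = hrf.sample(movie.tr_seconds)
    params, preds = [], []
    for sigma in grid.sigmas:
        gx = np.exp(-((x[:, None] - grid.xs[None, :]) ** 2) / (2 * sigma**2))  # (W, nx)
        gy = np.exp(-((y[:, None] - grid.ys[None, :]) ** 2) / (2 * sigma**2))  # (H, ny)
        A = np.tensordot(F, gy, axes=([1], [0]))  # (T, W, ny)
        D = np.tensordot(A, gx, axes=([1], [0]))  # (T, ny, nx)
        D = D / _gaussian_mass(sigma, movie.deg_per_pixel)
        drives = D.reshape(D.shape[0], -1).T  # (ny * nx, T); x0 fastest
        conv = fftconvolve(drives, h[None, :], axes=1)[:, : drives.shape[1]]
        yy, xx = np.meshgrid(grid.ys, grid.xs, indexing="ij")
        params.append(
            np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, sigma)])
        )
        preds.append(conv)
    return np.vstack(params), np.vstack(preds)


def _ve_matrix(preds: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Variance explained of every candidate (rows) for every voxel (cols).

    With a free amplitude and baseline the least-squares VE equals the squared
    correlation between prediction and series.
    """
    pc = preds - preds.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(pc, axis=1, keepdims=True)
    pc = np.divide(pc, pn, out=np.zeros_like(pc), where=pn > 0)
    yc = data - data.mean(axis=1, keepdims=True)
    yn = np.linalg.norm(yc, axis=1, keepdims=True)
    yc = np.divide(yc, yn, out=np.zeros_like(yc), where=yn > 0)
    return (pc @ yc.T) ** 2


def _beta_baseline(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form least squares of y on [1, pred]."""
    pc = pred - pred.mean()
    denom = pc @ pc
    if denom <= 0:
        return 0.0, float(y.mean())
    beta = float(pc @ (y - y.mean()) / denom)
    baseline = float(y.mean() - beta * pred.mean())
    return beta, baseline


# ----------------------------------------------------------------------------
# estimators
# ----------------------------------------------------------------------------


class GaussianPRFMapper(BaseEstimator):
    """Conventional 2-D Gaussian pRF fitting, scikit-learn style.

    Parameters
    ----------
    apertures : ApertureMovie
        Dummy-stripped effective aperture (FF or SF, see
        :func:`scotomap.stimulus.effective_aperture`).
    grid : GridSpec, optional
        Coarse-search lattice; defaults to a 0.5 degree lattice over +/- 8
        degrees with seven candidate sizes.
    hrf : HRFSpec, optional
    refine : bool
        Run derivative-free local refinement from the best coarse candidate,
        bounded to +/- 10 degrees in position and [0.05, 10] degrees in size.

    Attributes
    ----------
    models_ : list of PRFModel
    x0_, y0_, sigma_, beta_, baseline_, ve_ : arrays, one entry per voxel
    degenerate_ : bool array, flags zero-variance input series
    """

    def __init__(
        self,
        apertures: ApertureMovie | None = None,
        grid: GridSpec | None = None,
        hrf: HRFSpec | None = None,
        refine: bool = True,
        position_bound: float = 10.0,
        sigma_bounds: tuple[float, float] = (0.05, 10.0),
    ):
        self.apertures = apertures
        self.grid = grid
        self.hrf = hrf
        self.refine = refine
        self.position_bound = position_bound
        self.sigma_bounds = sigma_bounds

    # -- internals ---------------------------------------------------------

    def _as_array(self, X) -> np.ndarray:
        if isinstance(X, TimeSeriesSet):
            return X.data
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2:
            raise ValueError("X must be a (voxels, T) array or TimeSeriesSet")
        if not np.all(np.isfinite(arr)):
            raise ValueError("time series must be finite")
        return arr

    def _selection_rank(self, params: np.ndarray) -> np.ndarray:
        """Deterministic tie-break order: smaller sigma, then smaller
        eccentricity, then (x0, y0); independent of candidate order."""
        rho = np.hypot(params[:, 0], params[:, 1])
        order = np.lexsort((params[:, 1], params[:, 0], rho, params[:, 2]))
        rank = np.empty(len(order), dtype=int)
        rank[order] = np.arange(len(order))
        return rank

    def _refine_one(
        self,
        y: np.ndarray,
        start: np.ndarray,
        frames_flat: np.ndarray,
        xf: np.ndarray,
        yf: np.ndarray,
        h: np.ndarray,
    ) -> tuple[np.ndarray, float]:
        T = frames_flat.shape[0]
        yc = y - y.mean()
        yn = np.linalg.norm(yc)
        if yn == 0:
            return start, 0.0
        yc = yc / yn

        def neg_ve(p):
            x0, y0, sigma = p
            g = np.exp(-((xf - x0) ** 2 + (yf - y0) ** 2) / (2.0 * sigma**2))
            drive = frames_flat @ g  # normalization drops out of the correlation
            pred = np.convolve(drive, h)[:T]
            pc = pred - pred.mean()
            pn = np.linalg.norm(pc)
            if pn == 0:
                return 0.0
            return -float((pc @ yc / pn) ** 2)

        b = self.position_bound
        res = minimize(
            neg_ve,
            start,
            method="Nelder-Mead",
            bounds=[(-b, b), (-b, b), self.sigma_bounds],
            options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 300},
        )
        return np.asarray(res.x, dtype=float), float(-res.fun)

    # -- API ---------------------------------------------------------------

    def fit(self, X, y=None):
        if self.apertures is None:
            raise ValueError("GaussianPRFMapper requires an aperture movie")
        if self.apertures.dummy_frames != 0:
            raise ValueError("apertures must be dummy-stripped")
        data = self._as_array(X)
        grid = self.grid or GridSpec()
        hrf = self.hrf or HRFSpec()
        params, preds = _candidate_predictions(self.apertures, grid, hrf)
        rank = self._selection_rank(params)
        ve = _ve_matrix(preds, data)  # (n_cand, n_vox)

        frames_flat, xf, yf = _flat_coords(self.apertures)
        h = hrf.sample(self.apertures.tr_seconds)

        n_vox = data.shape[0]
        models: list[PRFModel] = []
        coarse_idx = np.empty(n_vox, dtype=int)
        for v in range(n_vox):
            yv = data[v]
            tss = np.sum((yv - yv.mean()) ** 2)
            if tss == 0:
                coarse_idx[v] = -1
                models.append(
                    PRFModel(
                        x0=0.0,
                        y0=0.0,
                        sigma=min(grid.sigmas),
                        beta=0.0,
                        baseline=float(yv.mean()),
                        ve=0.0,
                        degenerate=True,
                    )
                )
                continue
            col = ve[:, v]
            vmax = col.max()
            tied = np.flatnonzero(col == vmax)
            best = tied[np.argmin(rank[tied])]
            coarse_idx[v] = best
            p_best = params[best].copy()
            ve_best = float(vmax)
            if self.refine:
                p_ref, ve_ref = self._refine_one(yv, p_best, frames_flat, xf, yf, h)
                if ve_ref >= ve_best and self.sigma_bounds[0] <= p_ref[2]:
                    p_best, ve_best = p_ref, ve_ref
            drive = gaussian_drive(
                frames_flat, xf, yf, p_best[0], p_best[1], p_best[2],
                self.apertures.deg_per_pixel,
            )
            pred = np.convolve(drive, h)[: frames_flat.shape[0]]
            beta, baseline = _beta_baseline(pred, yv)
            models.append(
                PRFModel(
                    x0=float(p_best[0]),
                    y0=float(p_best[1]),
                    sigma=float(p_best[2]),
                    beta=beta,
                    baseline=baseline,
                    ve=min(ve_best, 1.0),
                )
            )

        self.models_ = models
        self.coarse_index_ = coarse_idx
        self.coarse_params_ = params
        self.x0_ = np.array([m.x0 for m in models])
        self.y0_ = np.array([m.y0 for m in models])
        self.sigma_ = np.array([m.sigma for m in models])
        self.beta_ = np.array([m.beta for m in models])
        self.baseline_ = np.array([m.baseline for m in models])
        self.ve_ = np.array([m.ve for m in models])
        self.degenerate_ = np.array([m.degenerate for m in models])
        self.n_features_in_ = data.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray:
        """Predicted time series of the fitted models (X is ignored)."""
        if not hasattr(self, "models_"):
            raise ValueError("estimator is not fitted")
        hrf = self.hrf or HRFSpec()
        return np.vstack(
            [predict_timeseries(m, self.apertures, hrf) for m in self.models_]
        )

    def score(self, X, y=None) -> float:
        """Median variance explained on already-fitted voxels."""
        if not hasattr(self, "ve_"):
            raise ValueError("estimator is not fitted")
        return float(np.median(self.ve_))

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.models_):
            rows.append(
                {
                    "unit_id": i,
                    "x0": m.x0,
                    "y0": m.y0,
                    "sigma": m.sigma,
                    "beta": m.beta,
                    "baseline": m.baseline,
                    "ve": m.ve,
                    "ecc": m.ecc,
                    "polar": m.polar,
                    "area": m.area,
                    "degenerate": m.degenerate,
                }
            )
        return pd.DataFrame(rows)


class MicroProber(BaseEstimator):
    """Dense small-Gaussian probing of voxel response fields.

    A lattice of weak probes (fixed ``probe_sigma``, default 0.5 degrees at
    1 degree spacing over the stimulated field) is regressed one at a time
    against each voxel's series; the per-probe weight is its variance
    explained (clipped at zero).  Per voxel the weighted centroid and the
    weighted RMS distance to it summarize sub-pRF position and spread.
    """

    def __init__(
        self,
        apertures: ApertureMovie | None = None,
        hrf: HRFSpec | None = None,
        probe_sigma: float = 0.5,
        spacing: float = 1.0,
        extent: float = 7.0,
    ):
        self.apertures = apertures
        self.hrf = hrf
        self.probe_sigma = probe_sigma
        self.spacing = spacing
        self.extent = extent

    def probe_lattice(self) -> np.ndarray:
        ax = np.arange(-self.extent, self.extent + 1e-9, self.spacing)
        xx, yy = np.meshgrid(ax, ax)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= self.extent + 1e-9]
        if pts.shape[0] == 0:
            raise ValueError("empty probe set: spacing exceeds the field extent")
        return pts

    def fit(self, X, y=None):
        if self.apertures is None:
            raise ValueError("MicroProber requires an aperture movie")
        if self.apertures.dummy_frames != 0:
            raise ValueError("apertures must be dummy-stripped")
        data = GaussianPRFMapper._as_array(self, X)
        hrf = self.hrf or HRFSpec()
        probes = self.probe_lattice()
        grid = GridSpec(
            xs=np.unique(probes[:, 0]),
            ys=np.unique(probes[:, 1]),
            sigmas=(self.probe_sigma,),
        )
        params, preds = _candidate_predictions(self.apertures, grid, hrf)
        # keep only lattice points inside the circular extent, in probe order
        keep = []
        lookup = {(round(p[0], 9), round(p[1], 9)): i for i, p in enumerate(params)}
        for p in probes:
            keep.append(lookup[(round(p[0], 9), round(p[1], 9))])
        preds = preds[keep]
        ve = _ve_matrix(preds, data).T  # (n_vox, n_probes)
        weights = np.clip(ve, 0.0, None)
        tss = np.sum((data - data.mean(axis=1, keepdims=True)) ** 2, axis=1)
        degenerate = tss == 0
        weights[degenerate] = 0.0
        total = weights.sum(axis=1)
        degenerate = degenerate | (total == 0)
        centers = np.full((data.shape[0], 2), np.nan)
        spread = np.full(data.shape[0], np.nan)
        ok = ~degenerate
        if ok.any():
            w = weights[ok]
            centers[ok] = (w @ probes) / w.sum(axis=1, keepdims=True)
            d2 = (
                (probes[None, :, 0] - centers[ok][:, 0:1]) ** 2
                + (probes[None, :, 1] - centers[ok][:, 1:2]) ** 2
            )
            spread[ok] = np.sqrt((w * d2).sum(axis=1) / w.sum(axis=1))
        self.probe_map_ = ProbeMap(
            probes=probes,
            sigma_probe=self.probe_sigma,
            weights=weights,
            centers=centers,
            spread=spread,
            degenerate=degenerate,
        )
        self.weights_ = weights
        self.centers_ = centers
        self.spread_ = spread
        self.degenerate_ = degenerate
        self.n_features_in_ = data.shape[1]
        return self

    def transform(self, X=None) -> np.ndarray:
        """Return the fitted per-voxel probe weights (X is ignored)."""
        if not hasattr(self, "weights_"):
            raise ValueError("estimator is not fitted")
        return self.weights_


# ----------------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------------


def fit_prf(
    ts_row: np.ndarray,
    apertures: ApertureMovie,
    grid: GridSpec | None = None,
    hrf: HRFSpec | None = None,
    refine: bool = True,
) -> PRFModel:
    """Fit a single preprocessed series; see :class:`GaussianPRFMapper`."""
    mapper = GaussianPRFMapper(apertures=apertures, grid=grid, hrf=hrf, refine=refine)
    mapper.fit(np.atleast_2d(ts_row))
    return mapper.models_[0]


def micro_probe(
    ts_row: np.ndarray,
    apertures: ApertureMovie,
    probe_spec: dict | None = None,
    hrf: HRFSpec | None = None,
) -> ProbeMap:
    """Micro-probe a single series; see :class:`MicroProber`."""
    prober = MicroProber(apertures=apertures, hrf=hrf, **(probe_spec or {}))
    prober.fit(np.atleast_2d(ts_row))
    return prober.probe_map_


def threshold_models(
    models: list[PRFModel],
    ve_min: float = VE_THRESHOLD_DEFAULT,
    ecc_range: tuple[float, float] = ECC_RANGE_DEFAULT,
) -> list[PRFModel]:
    """Keep responsive models: VE >= ve_min and eccentricity within range.

    Order is preserved; the returned list's length is the responsive count.
    """
    lo, hi = ecc_range
    return [
        m
        for m in models
        if (not m.degenerate) and m.ve >= ve_min and lo <= m.ecc <= hi
    ]
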