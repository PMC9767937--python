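"""Group- and pair-level statistics for pRF properties and BOLD responsiveness.

The analysis vocabulary: BOLD modulation (the standard deviation of a voxel's
percent-signal-change series) summarizes responsiveness; pRF properties are
binned over eccentricity (1 degree bins) or summarized per visual-field
quadrant; per-subject property distributions become normalized histograms
whose pairwise deviation (sum of absolute per-bin differences) is ranked
against a baseline of control-vs-control deviations to decide whether a
glaucoma-control pair differs beyond normal intersubject variability; and
severity correlations use a linear mixed model with a random slope and
intercept per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .prf import PRFModel, polar_angle
from .timeseries import TimeSeriesSet

__all__ = [
    "BinnedProfile",
    "NormalizedHistogram",
    "PairDeviation",
    "RankResult",
    "QuadrantSummary",
    "MixedSlopeResult",
    "SizeTestResult",
    "bold_modulation",
    "bin_by_eccentricity",
    "normalized_hist",
    "pair_deviation",
    "deviation_rank",
    "quadrant_of",
    "quadrant_summary",
    "euclidean_distance",
    "mixed_slope",
    "size_distribution_test",
]

QUADRANTS = ("UL", "UR", "LL", "LR")


# ----------------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class BinnedProfile:
    edges: np.ndarray  # (n_bins + 1,)
    mean: np.ndarray  # nan where a bin is empty
    ci_low: np.ndarray
    ci_high: np.ndarray
    count: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0


@dataclass(frozen=True)
class NormalizedHistogram:
    dimension: str  # eccentricity | polar | size
    edges: np.ndarray
    mass: np.ndarray
    n: int
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty and abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("histogram mass must sum to 1")


@dataclass(frozen=True)
class PairDeviation:
    per_bin: np.ndarray  # signed a - b
    edges: np.ndarray

    @property
    def aggregate(self) -> float:
        return float(np.abs(self.per_bin).sum())


@dataclass(frozen=True)
class RankResult:
    pair: float
    baseline: np.ndarray
    rank: float
    percentile: float
    significant: bool
    per_bin_ranks: np.ndarray | None = None


@dataclass(frozen=True)
class QuadrantSummary:
    """Per-quadrant means of pRF size, position and BOLD modulation."""

    table: pd.DataFrame  # index UL/UR/LL/LR

    def __getitem__(self, quadrant: str) -> pd.Series:
        return self.table.loc[quadrant]

    @property
    def empty_quadrants(self) -> list[str]:
        return list(self.table.index[self.table["n"] == 0])


@dataclass(frozen=True)
class MixedSlopeResult:
    slope: float
    intercept: float
    r2: float  # signed: carries the slope's sign
    p: float
    slope_se: float
    method: str  # "mixedlm" or "ols"

    @property
    def slope_ci(self) -> tuple[float, float]:
        return (self.slope - 1.96 * self.slope_se, self.slope + 1.96 * self.slope_se)


@dataclass(frozen=True)
class SizeTestResult:
    medians: dict
    group_medians: dict
    t: float
    p: float
    cumulative: dict  # group -> sorted sigma values for ECDF plotting


# ----------------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------------


def bold_modulation(ts: TimeSeriesSet | np.ndarray) -> np.ndarray:
    """Per-unit BOLD modulation: the standard deviation of each series."""
    data = ts.data if isinstance(ts, TimeSeriesSet) else np.atleast_2d(np.asarray(ts, float))
    return data.std(axis=1)


def bin_by_eccentricity(
    values: np.ndarray,
    models: list[PRFModel],
    width: float = 1.0,
    max_ecc: float = 7.0,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> BinnedProfile:
    """Mean of ``values`` in half-open eccentricity bins [k*w, (k+1)*w).

    Per-bin 95% intervals come from a bootstrap over the bin's members;
    empty bins are recorded as missing (nan), not zero.
    """
    values = np.asarray(values, float)
    ecc = np.array([m.ecc for m in models])
    if values.shape[0] != ecc.shape[0]:
        raise ValueError("values and models must be aligned")
    rng = rng if rng is not None else np.random.default_rng(0)
    edges = np.arange(0.0, max_ecc + width / 2, width)
    n_bins = len(edges) - 1
    mean = np.full(n_bins, np.nan)
    lo = np.full(n_bins, np.nan)
    hi = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    idx = np.floor(ecc / width).astype(int)
    for b in range(n_bins):
        members = values[(idx == b) & (ecc < max_ecc)]
        count[b] = members.size
        if members.size == 0:
            continue
        mean[b] = members.mean()
        if members.size == 1:
            lo[b] = hi[b] = members[0]
        else:
            boots = rng.choice(members, size=(n_boot, members.size)).mean(axis=1)
            lo[b], hi[b] = np.percentile(boots, [2.5, 97.5])
    return BinnedProfile(edges, mean, lo, hi, count)


DEFAULT_EDGES = {
    "eccentricity": np.arange(0.0, 7.5, 1.0),
    "polar": np.linspace(0.0, 2 * np.pi, 17),
    "size": np.arange(0.0, 6.5, 0.5),
}


def normalized_hist(
    models: list[PRFModel], dimension: str, edges: np.ndarray | None = None
) -> NormalizedHistogram:
    """Histogram of responsive voxels along one pRF dimension, unit mass.

    ``dimension`` is ``eccentricity``, ``polar`` or ``size``; models should
    already be thresholded (VE and eccentricity range).  Values beyond the
    edge range fall into the nearest boundary bin so mass is conserved.
    """
    if dimension not in DEFAULT_EDGES:
        raise ValueError(f"dimension must be one of {sorted(DEFAULT_EDGES)}")
    edges = np.asarray(edges if edges is not None else DEFAULT_EDGES[dimension], float)
    if dimension == "eccentricity":
        vals = np.array([m.ecc for m in models])
    elif dimension == "polar":
        vals = np.array([m.polar for m in models])
    else:
        vals = np.array([m.sigma for m in models])
    n = len(models)
    if n == 0:
        return NormalizedHistogram(dimension, edges, np.zeros(len(edges) - 1), 0, empty=True)
    vals = np.clip(vals, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(vals, bins=edges)
    return NormalizedHistogram(dimension, edges, counts / n, n)


def pair_deviation(a: NormalizedHistogram, b: NormalizedHistogram) -> PairDeviation:
    """Signed per-bin difference a - b and its absolute aggregate."""
    if a.edges.shape != b.edges.shape or not np.allclose(a.edges, b.edges):
        raise ValueError("histograms must share identical edges")
    return PairDeviation(per_bin=a.mass - b.mass, edges=a.edges)


def _midrank(value: float, pool: np.ndarray) -> float:
    return 1.0 + float(np.sum(pool < value)) + 0.5 * float(np.sum(pool == value))


def deviation_rank(
    pair: PairDeviation,
    baseline: list[PairDeviation],
    significance_percentile: float = 95.0,
) -> RankResult:
    """Rank a pair's deviation within the baseline control-vs-control pool.

    The rank is the mid-rank of the pair's aggregate among the baseline
    aggregates (1 if smaller than all, n+1 if larger than all); the pair is
    significant when its percentile, 100 * rank / (n + 1), exceeds the
    one-sided criterion (default 95).  Per-bin absolute deviations are ranked
    the same way.
    """
    if len(baseline) < 5:
        raise ValueError("baseline must contain at least 5 deviations")
    base_vals = np.array([b.aggregate for b in baseline])
    rank = _midrank(pair.aggregate, base_vals)
    percentile = 100.0 * rank / (len(baseline) + 1)
    per_bin = np.array(
        [
            _midrank(
                abs(pair.per_bin[i]),
                np.abs(np.array([b.per_bin[i] for b in baseline])),
            )
            for i in range(pair.per_bin.size)
        ]
    )
    return RankResult(
        pair=pair.aggregate,
        baseline=base_vals,
        rank=rank,
        percentile=percentile,
        significant=bool(percentile > significance_percentile),
        per_bin_ranks=per_bin,
    )


def quadrant_of(x0, y0) -> np.ndarray:
    """Quadrant labels from pRF centers under the polar-angle convention.

    theta = 0 sits on the upper vertical meridian and increases
    counterclockwise; boundary centers go to the counterclockwise quadrant,
    so the upper meridian itself belongs to UR and the left horizontal
    meridian to LL.
    """
    theta = np.atleast_1d(polar_angle(x0, y0))
    out = np.empty(theta.shape, dtype="U2")
    out[(theta > 0) & (theta <= np.pi / 2)] = "UL"
    out[(theta > np.pi / 2) & (theta <= np.pi)] = "LL"
    out[(theta > np.pi) & (theta <= 3 * np.pi / 2)] = "LR"
    out[(theta > 3 * np.pi / 2) | (theta == 0)] = "UR"
    return out


def quadrant_summary(
    models: list[PRFModel], modulations: np.ndarray | None = None
) -> QuadrantSummary:
    """Per-quadrant mean pRF size, mean position, mean BOLD modulation, count."""
    x0 = np.array([m.x0 for m in models])
    y0 = np.array([m.y0 for m in models])
    sigma = np.array([m.sigma for m in models])
    quad = quadrant_of(x0, y0) if len(models) else np.array([], dtype="U2")
    mods = (
        np.asarray(modulations, float)
        if modulations is not None
        else np.full(len(models), np.nan)
    )
    rows = []
    for q in QUADRANTS:
        mask = quad == q
        n = int(mask.sum())
        rows.append(
            {
                "quadrant": q,
                "mean_sigma": float(sigma[mask].mean()) if n else np.nan,
                "mean_x": float(x0[mask].mean()) if n else np.nan,
                "mean_y": float(y0[mask].mean()) if n else np.nan,
                "mean_modulation": (
                    float(np.nanmean(mods[mask]))
                    if n and np.any(np.isfinite(mods[mask]))
                    else np.nan
                ),
                "n": n,
            }
        )
    return QuadrantSummary(pd.DataFrame(rows).set_index("quadrant"))


def euclidean_distance(p, q) -> float:
    """Euclidean distance between two visual-field positions (degrees)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    return float(np.hypot(*(p - q)))


def mixed_slope(
    y: np.ndarray, x: np.ndarray, subject: np.ndarray
) -> MixedSlopeResult:
    """Fixed-effect slope of y on x with a random slope+intercept per subject.

    Degenerate designs (a single subject, or subjects with fewer than two
    points) and non-converging mixed fits fall back to ordinary least squares
    with a warning.  The reported r-squared carries the slope's sign.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    subject = np.asarray(subject)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x, subject = y[keep], x[keep], subject[keep]
    if np.ptp(x) == 0:
        raise ValueError("x is constant; no slope is identifiable")
    labels, counts = np.unique(subject, return_counts=True)
    use_mixed = len(labels) >= 2 and np.all(counts >= 2)
    exog = sm.add_constant(x)
    slope = intercept = se = p = None
    method = "ols"
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(y, exog, groups=subject, exog_re=exog)
                res = md.fit(reml=True, method="lbfgs")
                if np.isfinite(res.fe_params[1]) and np.isfinite(res.bse_fe[1]):
                    intercept, slope = res.fe_params
                    se = float(res.bse_fe[1])
                    p = float(res.pvalues[1])
                    method = "mixedlm"
        except Exception:
            pass
    if method == "ols":
        if use_mixed is False and len(labels) > 1:
            warnings.warn("degenerate mixed design; falling back to OLS")
        res = sm.OLS(y, exog).fit()
        intercept, slope = res.params
        se = float(res.bse[1])
        p = float(res.pvalues[1])
    yhat = intercept + slope * x
    if np.std(yhat) == 0 or np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(yhat, y)[0, 1] ** 2)
    r2 = float(np.sign(slope) * r2) if slope != 0 else 0.0
    return MixedSlopeResult(
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
        p=float(p),
        slope_se=se,
        method=method,
    )


def size_distribution_test(
    models_by_participant: dict, group_labels: dict
) -> SizeTestResult:
    """Compare per-participant median pRF sizes between two groups (Welch t).

    ``models_by_participant`` maps a participant id to their thresholded
    models; ``group_labels`` maps the same ids to one of two group names.
    """
    groups: dict[str, list[float]] = {}
    medians: dict = {}
    cumulative: dict[str, list[float]] = {}
    for pid, models in models_by_participant.items():
        g = group_labels[pid]
        med = float(np.median([m.sigma for m in models]))
        medians[pid] = med
        groups.setdefault(g, []).append(med)
        cumulative.setdefault(g, []).extend(m.sigma for m in models)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(groups)}")
    names = sorted(groups)
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 participants")
    a, b = np.asarray(groups[names[0]]), np.asarray(groups[names[1]])
    if np.array_equal(a, b) or (a.std() == 0 and b.std() == 0 and a.mean() == b.mean()):
        t, p = 0.0, 1.0  # identical groups: no evidence of a difference
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = sps.ttest_ind(a, b, equal_var=False)
    return SizeTestResult(
        medians=medians,
        group_medians={g: float(np.median(v)) for g, v in groups.items()},
        t=float(t),
        p=float(p),
        cumulative={g: np.sort(np.array(v)) for g, v in cumulative.items()},
    )
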