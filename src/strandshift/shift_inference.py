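"""Distributional-shift inference from annual stranding statistics.

The distributional state of a species in year *t* is summarized by one number
on the along-shelf axis: the **center of distribution** (annual mean poleward
distance of its stranding events) or, for species whose equatorward range
limit lies inside the study region, the **trailing edge** (annual 5th
percentile).  Shifts are the OLS slope of that annual statistic on year, with
95% confidence intervals from an event-level nonparametric bootstrap
(resampling rows with replacement, keeping each event's distance–year pairing,
B = 1000) and family-wise Type-I error control by the Dunn–Šidák adjustment
α' = 1 − (1 − α)^(1/m).

Community composition is tracked the same way: the annual proportion of
stranding events contributed by each climatic category (warm / cool / arctic /
cosmopolitan) or by a single species, regressed on year and on regional SST
anomaly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

STAT_KINDS = ("mean", "q05", "proportion")

#: percentile used for the trailing edge, interpolated between order
#: statistics at position (n-1)p (numpy's default "linear" rule).
TRAILING_EDGE_PERCENTILE = 5.0


@dataclass
class AnnualStatSeries:
    """Per-year statistic (km, or a proportion) with per-year event counts."""

    years: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    kind: str

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.kind not in STAT_KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if not (self.years.size == self.values.size == self.counts.size):
            raise ValueError("years/values/counts must align")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name=self.kind)


@dataclass
class TrendFit:
    """OLS fit of an annual statistic on a predictor (year or SST anomaly)."""

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n_obs: int
    boot_ci_low: float | None = None
    boot_ci_high: float | None = None
    n_boot: int = 0
    alpha_adjusted: float | None = None
    boot_redraws: int = 0

    @property
    def significant(self) -> bool | None:
        if self.alpha_adjusted is None:
            return None
        return self.p_value < self.alpha_adjusted


def ols_fit(x, y) -> TrendFit:
    """Plain OLS of y on x with two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations for a trend fit")
    res = stats.linregress(x, y)
    p = res.pvalue
    if np.isnan(p):  # zero-residual degenerate fit: slope exactly determined
        p = 0.0 if res.slope != 0 else 1.0
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(p),
        r_squared=float(res.rvalue**2),
        n_obs=int(x.size),
    )


# ---------------------------------------------------------------------------
# Annual statistics
# ---------------------------------------------------------------------------

def annual_statistic(records: pd.DataFrame, kind: str = "mean") -> AnnualStatSeries:
    """Annual mean or 5th-percentile poleward distance for one species.

    Years with zero events are absent from the series (omitted, not imputed).
    The 5th percentile interpolates linearly between order statistics; with a
    single event it is that event's distance.
    """
    if kind not in ("mean", "q05"):
        raise ValueError("annual_statistic supports kind 'mean' or 'q05'")
    d = records.dropna(subset=["poleward_distance_km"])
    if d.empty:
        raise ValueError("no records with poleward distance")
    g = d.groupby("year")["poleward_distance_km"]
    if kind == "mean":
        vals = g.mean()
    else:
        vals = g.quantile(TRAILING_EDGE_PERCENTILE / 100.0, interpolation="linear")
    counts = g.size()
    return AnnualStatSeries(vals.index.to_numpy(), vals.to_numpy(), counts.to_numpy(), kind)


def fit_trend(series: AnnualStatSeries) -> TrendFit:
    """Unweighted OLS of the annual statistic on calendar year."""
    return ols_fit(series.years, series.values)


# ---------------------------------------------------------------------------
# Event-level bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    records: pd.DataFrame,
    kind: str = "mean",
    n_boot: int = 1000,
    seed: int | None = None,
    ci: tuple[float, float] = (0.025, 0.975),
) -> tuple[float, float, int]:
    """Percentile bootstrap CI for the shift slope.

    Each of ``n_boot`` resamples draws event rows with replacement (original
    sample size, distance–year pairing conserved), recomputes the annual
    statistic, and refits the OLS slope on year.  Returns
    ``(ci_low, ci_high, n_redraws)`` where ``n_redraws`` counts resamples that
    had to be redrawn because they covered fewer than 3 distinct years.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI quantiles will be unstable")
    d = records.dropna(subset=["poleward_distance_km"])
    years = d["year"].to_numpy(int)
    dist = d["poleward_distance_km"].to_numpy(float)
    n = years.size
    if n == 0:
        raise ValueError("no records with poleward distance")
    uyears = np.unique(years)
    yidx = np.searchsorted(uyears, years)
    T = uyears.size
    xf = uyears.astype(float)
    rng = np.random.default_rng(seed)

    slopes = np.empty(n_boot)
    redraws = 0
    filled = 0
    while filled < n_boot:
        todo = n_boot - filled
        idx = rng.integers(0, n, size=(todo, n))
        yi = yidx[idx]
        if kind == "mean":
            flat = yi + (np.arange(todo)[:, None] * T)
            counts = np.bincount(flat.ravel(), minlength=todo * T).reshape(todo, T)
            sums = np.bincount(flat.ravel(), weights=dist[idx].ravel(), minlength=todo * T).reshape(todo, T)
            with np.errstate(invalid="ignore"):
                means = sums / counts
            ok = (counts > 0).sum(axis=1) >= 3
            s = _masked_ols_slopes(xf, means, counts > 0)
        else:
            s = np.empty(todo)
            ok = np.empty(todo, dtype=bool)
            for b in range(todo):
                s[b], ok[b] = _q05_slope(xf, yi[b], dist[idx[b]], T)
        k = int(ok.sum())
        slopes[filled : filled + k] = s[ok]
        filled += k
        redraws += todo - k
    lo, hi = np.quantile(slopes, ci)
    return float(lo), float(hi), redraws


def _masked_ols_slopes(x: np.ndarray, y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise OLS slope of y on x using only masked-True columns."""
    w = mask.astype(float)
    nw = w.sum(axis=1)
    xm = (w * x).sum(axis=1) / nw
    yv = np.where(mask, y, 0.0)
    ym = yv.sum(axis=1) / nw
    dx = (x[None, :] - xm[:, None]) * w
    sxy = (dx * (yv - ym[:, None] * w)).sum(axis=1)
    sxx = (dx * (x[None, :] - xm[:, None])).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return sxy / sxx


def _q05_slope(xf, yi, d, T) -> tuple[float, bool]:
    order = np.argsort(yi, kind="stable")
    yi, d = yi[order], d[order]
    uy, starts = np.unique(yi, return_index=True)
    if uy.size < 3:
        return np.nan, False
    q = np.empty(uy.size)
    bounds = np.append(starts, yi.size)
    for j in range(uy.size):
        q[j] = np.percentile(d[bounds[j] : bounds[j + 1]], TRAILING_EDGE_PERCENTILE)
    res = stats.linregress(xf[uy], q)
    return float(res.slope), True


def sidak_adjust(alpha: float, m: int) -> float:
    """Dunn–Šidák family-wise adjustment: α' = 1 − (1 − α)^(1/m)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def shift_trend(
    records: pd.DataFrame,
    kind: str = "mean",
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    m_comparisons: int = 1,
) -> TrendFit:
    """Full shift inference for one species: trend + bootstrap CI + adjusted α."""
    series = annual_statistic(records, kind)
    fit = fit_trend(series)
    lo, hi, redraws = bootstrap_ci(records, kind, n_boot=n_boot, seed=seed)
    fit.boot_ci_low, fit.boot_ci_high = lo, hi
    fit.n_boot = n_boot
    fit.boot_redraws = redraws
    fit.alpha_adjusted = sidak_adjust(alpha, m_comparisons)
    return fit


# ---------------------------------------------------------------------------
# Composition and relative-abundance trends
# ---------------------------------------------------------------------------

@dataclass
class CompositionResult:
    proportions: pd.DataFrame  # years x categories, rows sum to 1
    vs_year: dict[str, TrendFit]
    vs_anomaly: dict[str, TrendFit] = field(default_factory=dict)


def composition_series(
    records: pd.DataFrame,
    registry: pd.DataFrame,
    region: str | None = None,
    anomaly: pd.Series | None = None,
) -> CompositionResult:
    """Annual climatic-category composition of strandings, with trends.

    The denominator each year is all odontocete events in the region-year, so
    category proportions sum to 1.  Each category's proportion is regressed on
    year, and on regional SST anomaly when an anomaly series (indexed by year)
    is supplied.
    """
    d = records if region is None else records[records["region"] == region]
    unmapped = sorted(set(d["species_id"]) - set(registry["species_id"]))
    if unmapped:
        raise ValueError(f"species missing from registry: {unmapped}")
    cat = d["species_id"].map(registry.set_index("species_id")["climatic_category"])
    tab = pd.crosstab(d["year"], cat)
    props = tab.div(tab.sum(axis=1), axis=0)
    vs_year = {c: ols_fit(props.index, props[c]) for c in props.columns}
    vs_anom = {}
    if anomaly is not None:
        common = props.index.intersection(anomaly.index)
        vs_anom = {c: ols_fit(anomaly.loc[common], props.loc[common, c]) for c in props.columns}
    return CompositionResult(props, vs_year, vs_anom)


@dataclass
class ProportionTrend:
    proportions: pd.Series
    vs_year: TrendFit
    vs_anomaly: TrendFit | None = None


def species_proportion_trend(
    records: pd.DataFrame,
    species_id: str,
    region: str | None = None,
    anomaly: pd.Series | None = None,
) -> ProportionTrend:
    """Relative abundance of one species in the stranding record through time."""
    d = records if region is None else records[records["region"] == region]
    total = d.groupby("year").size()
    sp = d[d["species_id"] == species_id].groupby("year").size()
    props = (sp.reindex(total.index, fill_value=0) / total).astype(float)
    vs_year = ols_fit(props.index, props.values)
    vs_anom = None
    if anomaly is not None:
        common = props.index.intersection(anomaly.index)
        vs_anom = ols_fit(anomaly.loc[common], props.loc[common])
    return ProportionTrend(props, vs_year, vs_anom)


# ---------------------------------------------------------------------------
# Center / trailing-edge convergence and domain-edge censoring
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    years: np.ndarray
    gap_km: np.ndarray
    converged: bool
    min_recent_gap_km: float


def convergence_check(
    center: AnnualStatSeries,
    trailing: AnnualStatSeries,
    threshold_km: float = 50.0,
    last_k: int = 5,
) -> ConvergenceResult:
    """Gap between center and trailing edge; flags near-convergence.

    When the trailing edge shifts faster than the center the gap shrinks; a
    minimum gap below ``threshold_km`` within the last ``last_k`` shared years
    flags that the distribution is pressing against the poleward domain limit.
    """
    common = np.intersect1d(center.years, trailing.years)
    if common.size == 0:
        raise ValueError("center and trailing series share no years")
    c = center.to_series().loc[common].to_numpy()
    t = trailing.to_series().loc[common].to_numpy()
    gap = c - t
    recent = gap[-min(last_k, gap.size):]
    mg = float(np.min(recent))
    return ConvergenceResult(common, gap, mg < threshold_km, mg)


def censoring_fraction(records: pd.DataFrame, domain_max_km: float, tail: float = 0.10) -> float:
    """Diagnostic: fraction of events in the terminal ``tail`` share of the domain.

    The center of distribution is computed from in-domain records only; once a
    species' distribution presses past the poleward end of the study domain
    the annual mean understates the true shift.  A large value of this
    fraction signals that censoring regime.  (Diagnostic defined by this
    package, not part of the source analysis tradition.)
    """
    d = records["poleward_distance_km"].dropna()
    if d.empty:
        return float("nan")
    return float((d >= (1.0 - tail) * domain_max_km).mean())
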