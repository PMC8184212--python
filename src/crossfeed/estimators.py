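"""Estimators that turn assay-style tabular data into phenotype numbers.

Each function mirrors one quantification step used when characterizing
cross-feeding strains: growth rate from a fluorescence time course,
saturating-kinetics fits, steady-state detection, the chemostat exchange
ratio, bead-calibrated cytometry densities, bioassay concentrations from a
standard curve, community growth rate from log-slopes, generation counting
from optical density, and chemostat flow-rate arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .model import MoserParams, moser_rate

__all__ = [
    "GrowthRateEstimate",
    "MoserFit",
    "SteadyState",
    "ExchangeRatioEstimate",
    "CytometrySample",
    "StandardCurve",
    "Concentration",
    "CommunityRateFit",
    "growth_rate_from_timeseries",
    "fit_moser",
    "fit_standard_curve",
    "detect_steady_state",
    "exchange_ratio",
    "exchange_ratio_replicates",
    "cytometry_densities",
    "bioassay_concentration",
    "community_growth_rate",
    "generations_from_od",
    "dilution_rate_from_doubling",
    "doubling_time_from_dilution",
    "flow_rate_for_doubling",
]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float(xc @ (y - y.mean()) / (xc @ xc))


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Maximal sliding-window log-slope of a growth signal.

    ``rate`` is the largest ordinary-least-squares slope of
    ln(signal/signal[0]) over any run of ``window_size`` consecutive points,
    or 0 (with ``no_growth`` set) when no window has a positive slope.
    """

    rate: float
    window_size: int
    window_start_index: int
    all_window_slopes: np.ndarray
    no_growth: bool = False


def growth_rate_from_timeseries(
    times: Sequence[float], intensities: Sequence[float], window: int = 3
) -> GrowthRateEstimate:
    """Growth rate (1/hr) from an exponentially growing signal.

    The signal (e.g. total fluorescence intensity of a microscopy frame) is
    normalized to its time-zero value; the OLS slope of the log signal is
    computed over every run of ``window`` consecutive points (overlapping)
    and the maximum positive slope is the growth rate.  If no window slope
    is positive the estimate is 0, flagged ``no_growth`` — the convention
    for cultures that fail to grow at very low nutrient.

    ``window`` is 3 or 4 consecutive time points.
    """
    if window not in (3, 4):
        raise ValueError("window must be 3 or 4")
    t = np.asarray(times, float)
    y = np.asarray(intensities, float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and intensities must be 1-D arrays of equal length")
    if len(t) < window:
        raise ValueError(f"need at least {window} points, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("intensities must be positive")

    logy = np.log(y / y[0])
    slopes = np.array(
        [_ols_slope(t[i : i + window], logy[i : i + window]) for i in range(len(t) - window + 1)]
    )
    best = int(np.argmax(slopes))
    if slopes[best] <= 0:
        return GrowthRateEstimate(0.0, window, best, slopes, no_growth=True)
    return GrowthRateEstimate(float(slopes[best]), window, best, slopes)


@dataclass(frozen=True)
class MoserFit:
    """Least-squares fit of the saturating growth law to (L, rate) data."""

    params: MoserParams
    rss: float
    stderr: dict
    n_points: int


def fit_moser(points: Sequence[tuple[float, float]]) -> MoserFit:
    """Fit b(L) = b_max L^n / (K^n + L^n) to (concentration µM, rate 1/hr) pairs.

    Requires at least 4 distinct concentrations.  The initial guess is
    b_max = 1.1·max(rate), K = concentration at half-max by interpolation,
    n = 2, with bounds b_max ∈ (0, 10], K ∈ (0, 1e4], n ∈ [0.5, 10].
    Returns parameters, residual sum of squares and approximate per-parameter
    standard errors from the Jacobian.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (L, rate) pairs")
    L, rate = pts[:, 0], pts[:, 1]
    if np.any(L < 0):
        raise ValueError("concentrations must be non-negative")
    if len(np.unique(L)) < 4:
        raise ValueError("need >= 4 distinct concentrations to fit three parameters")
    if np.allclose(rate, rate[0]):
        raise ValueError("degenerate data: all rates equal")

    bmax0 = 1.1 * float(rate.max())
    half = rate.max() / 2.0
    order = np.argsort(L)
    K0 = float(np.interp(half, rate[order], L[order]))
    if not np.isfinite(K0) or K0 <= 0:
        K0 = float(np.median(L[L > 0]))
    p0 = (bmax0, K0, 2.0)
    bounds = ([1e-12, 1e-12, 0.5], [10.0, 1e4, 10.0])

    def f(Lv, b_max, K, n):
        return moser_rate(Lv, MoserParams(b_max, K, n))

    try:
        popt, pcov = optimize.curve_fit(f, L, rate, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as e:  # pragma: no cover - depends on optimizer
        raise RuntimeError(f"growth-law fit did not converge (initial guess {p0}): {e}")
    resid = rate - f(L, *popt)
    se = np.sqrt(np.diag(pcov))
    return MoserFit(
        params=MoserParams(*popt),
        rss=float(resid @ resid),
        stderr={"b_max": float(se[0]), "K": float(se[1]), "n": float(se[2])},
        n_points=len(L),
    )


class SteadyState(NamedTuple):
    reached: bool
    t_onset: float | None
    mean: float | None


def detect_steady_state(
    times: Sequence[float],
    values: Sequence[float],
    window_fraction: float = 0.3,
    rel_tol: float = 0.10,
) -> SteadyState:
    """Declare a plateau in a noisy time series (relative-range criterion).

    The mean over the trailing ``window_fraction`` of points defines the
    candidate plateau level.  Steady state is declared when the range
    (max − min) of the trailing window stays within ``rel_tol`` of that
    level; the onset is the earliest time after which the whole remaining
    series satisfies the same range criterion.  A steadily drifting signal
    whose trailing-window drift exceeds the band is reported not-reached.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if len(t) < 5:
        raise ValueError("need at least 5 points")
    if t.shape != v.shape:
        raise ValueError("times and values must have equal length")
    w = max(2, int(np.ceil(window_fraction * len(t))))
    m = float(v[-w:].mean())
    scale = max(abs(m), 1e-12 * max(1.0, float(np.abs(v).max())))
    band = rel_tol * scale
    if v[-w:].max() - v[-w:].min() > band:
        return SteadyState(False, None, None)
    # earliest index from which the remaining series stays inside the band
    idx = len(v) - w
    while idx > 0 and (v[idx - 1 :].max() - v[idx - 1 :].min()) <= band:
        idx -= 1
    return SteadyState(True, float(t[idx]), m)


@dataclass(frozen=True)
class ExchangeRatioEstimate:
    """Exchange ratio dil·H_ss/L0 (1/hr) from a chemostat.

    At steady state with near-complete nutrient depletion this
    population-level quantity equals the per-cell release rate divided by
    the per-birth consumption amount (r/c): product outflow dil·H_ss equals
    per-cell release times density, and nutrient inflow dil·L0 equals
    consumption times the birth flux.
    """

    value: float
    dil: float
    H_ss: float
    L_0: float
    replicates: tuple | None = None
    ci: tuple[float, float] | None = None


def exchange_ratio(dil: float, H_ss: float, L_0: float) -> ExchangeRatioEstimate:
    """Exchange ratio (1/hr) from dilution rate, steady-state product
    concentration and feed nutrient concentration (both µM)."""
    if dil < 0 or H_ss < 0:
        raise ValueError("dil and H_ss must be >= 0")
    if not L_0 > 0:
        raise ValueError("L_0 must be > 0")
    return ExchangeRatioEstimate(value=dil * H_ss / L_0, dil=dil, H_ss=H_ss, L_0=L_0)


def exchange_ratio_replicates(
    dil: float, H_ss_values: Sequence[float], L_0: float, level: float = 0.95
) -> ExchangeRatioEstimate:
    """Replicate-averaged exchange ratio with a t-interval over runs."""
    vals = np.array([exchange_ratio(dil, h, L_0).value for h in H_ss_values])
    if len(vals) < 2:
        raise ValueError("need >= 2 replicates for an interval")
    m, se = float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals)))
    tcrit = stats.t.ppf(0.5 + level / 2, df=len(vals) - 1)
    return ExchangeRatioEstimate(
        value=m,
        dil=dil,
        H_ss=float(np.mean(H_ss_values)),
        L_0=L_0,
        replicates=tuple(vals),
        ci=(m - tcrit * se, m + tcrit * se),
    )


@dataclass(frozen=True)
class CytometrySample:
    """Event counts from one flow-cytometry acquisition with a bead spike.

    A fixed volume of a fluorescent-bead stock of known density is mixed
    into each sample; the ratio of cell events to bead events calibrates
    absolute cell densities.
    """

    fluorescent_cell_events: int
    nonfluorescent_cell_events: int
    bead_events: int
    bead_stock_density: float  # beads/ml
    bead_volume: float  # ml
    sample_volume: float  # ml

    def __post_init__(self) -> None:
        if min(self.fluorescent_cell_events, self.nonfluorescent_cell_events, self.bead_events) < 0:
            raise ValueError("event counts must be >= 0")
        if self.bead_stock_density <= 0 or self.bead_volume <= 0 or self.sample_volume <= 0:
            raise ValueError("bead stock density and volumes must be > 0")


def cytometry_densities(s: CytometrySample) -> tuple[float, float]:
    """(live, dead) cell densities in cells/ml from bead-calibrated counts.

    Beads spiked into the sample represent a known density
    bead_stock_density·bead_volume/sample_volume, so each cell event
    represents that density divided by the bead event count.  Fluorescent
    events are live cells; non-fluorescent, dead.
    """
    if s.bead_events <= 0:
        raise ValueError("bead_events must be > 0 to calibrate densities")
    beads_per_ml = s.bead_stock_density * s.bead_volume / s.sample_volume
    live = s.fluorescent_cell_events / s.bead_events * beads_per_ml
    dead = s.nonfluorescent_cell_events / s.bead_events * beads_per_ml
    return live, dead


@dataclass(frozen=True)
class StandardCurve:
    """Linear standard curve: turbidity = intercept + slope·concentration."""

    slope: float
    intercept: float
    valid_range: tuple[float, float]  # concentration range of the calibration (µM)
    points: tuple = ()

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be > 0")

    def turbidity_range(self) -> tuple[float, float]:
        lo, hi = self.valid_range
        return self.intercept + self.slope * lo, self.intercept + self.slope * hi


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS fit of turbidity against concentration for a yield-based bioassay
    (a tester auxotroph grown to exhaustion of the assayed metabolite)."""
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 (concentration, turbidity) points")
    res = stats.linregress(pts[:, 0], pts[:, 1])
    if res.slope <= 0:
        raise ValueError(f"standard curve slope must be positive, got {res.slope:.4g}")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        valid_range=(float(pts[:, 0].min()), float(pts[:, 0].max())),
        points=tuple(map(tuple, pts)),
    )


class Concentration(NamedTuple):
    value: float  # µM
    in_range: bool


def bioassay_concentration(curve: StandardCurve, turbidity: float) -> Concentration:
    """Invert the standard curve: concentration = (turbidity − intercept)/slope.

    Readings outside the calibrated turbidity range are extrapolations; the
    value is still returned but flagged (and a warning emitted).
    """
    value = (turbidity - curve.intercept) / curve.slope
    lo, hi = curve.turbidity_range()
    in_range = lo <= turbidity <= hi
    if not in_range:
        warnings.warn(
            f"turbidity {turbidity:.4g} outside calibrated range [{lo:.4g}, {hi:.4g}];"
            " extrapolated concentration",
            stacklevel=2,
        )
    return Concentration(float(value), in_range)


@dataclass(frozen=True)
class CommunityRateFit:
    """Steady exponential growth rate of a community trajectory."""

    rate: float
    window: tuple[int, int]  # [start, stop) indices of the fitted points


def community_growth_rate(
    times: Sequence[float], abundances: Sequence[float], rel_tol: float = 0.15
) -> CommunityRateFit:
    """Steady-state growth rate (1/hr) from total-abundance time courses.

    Communities show an initial lag before settling into steady exponential
    growth; the rate is the OLS slope of ln(abundance) over the longest
    trailing run of points whose consecutive pairwise log-slopes all lie
    within ``rel_tol`` (relative) of their mean.  Requires the run to span
    at least 3 points.
    """
    t = np.asarray(times, float)
    y = np.asarray(abundances, float)
    if len(t) < 4:
        raise ValueError("need at least 4 points")
    if t.shape != y.shape:
        raise ValueError("times and abundances must have equal length")
    if np.any(y <= 0):
        raise ValueError("abundances must be positive")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    logy = np.log(y)
    slopes = np.diff(logy) / np.diff(t)
    n_sl = len(slopes)
    start = None
    for k in range(n_sl - 1):  # need >= 2 slopes (3 points)
        seg = slopes[k:]
        m = seg.mean()
        if np.all(np.abs(seg - m) <= rel_tol * abs(m)):
            start = k
            break
    if start is None:
        raise ValueError("no trailing window of >= 3 points with consistent log-slope")
    rate = _ols_slope(t[start:], logy[start:])
    return CommunityRateFit(rate=rate, window=(start, len(t)))


def generations_from_od(records: Sequence[tuple[float, float]]) -> float:
    """Accumulated generations from (OD, fold-dilution-applied-after-reading)
    records of a periodically diluted batch coculture.

    The accumulated density at reading k is OD_k times the product of all
    fold-dilutions applied before that reading; generations elapsed is the
    log2 fold-change of accumulated density from the first reading.
    """
    recs = list(records)
    if not recs:
        raise ValueError("need at least one (OD, fold_dilution) record")
    acc = []
    mult = 1.0
    for od, fold in recs:
        if od <= 0:
            raise ValueError("OD readings must be positive")
        if fold < 1:
            raise ValueError("fold dilutions must be >= 1")
        acc.append(od * mult)
        mult *= fold
    return float(np.log2(acc[-1] / acc[0]))


def dilution_rate_from_doubling(doubling_time: float) -> float:
    """Chemostat dilution rate (1/hr) giving the stated doubling time: ln2/T."""
    if not doubling_time > 0:
        raise ValueError("doubling time must be > 0")
    return float(np.log(2) / doubling_time)


def doubling_time_from_dilution(dilution_rate: float) -> float:
    """Doubling time (hr) at a given dilution rate: ln2/dil."""
    if not dilution_rate > 0:
        raise ValueError("dilution rate must be > 0")
    return float(np.log(2) / dilution_rate)


def flow_rate_for_doubling(doubling_time: float, volume: float) -> float:
    """Pump flow rate (ml/hr) for a culture volume (ml) and target doubling
    time (hr): volume·ln2/T."""
    if not volume > 0:
        raise ValueError("volume must be > 0")
    return volume * dilution_rate_from_doubling(doubling_time)
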