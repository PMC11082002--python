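"""Tipping-point detection: structural-change breakpoints, sliding-window
early-warning signals, and ARIMA forecast-deviation between states.

Breakpoints minimize the residual sum of squares of piecewise-constant
segment means by exact dynamic programming; the number of breaks is chosen
by BIC.  Early-warning signals are the classic critical-slowing-down pair:
sample variance and lag-1 autocorrelation in a short sliding window over the
community state series (NMDS1), with Kendall-tau trend tests over the
declared pre-transition range.  The forecast test fits an ARIMA model to the
first state and asks how often the second state's observations fall outside
the model's 95% prediction band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.tsa.arima.model import ARIMA


@dataclass
class BreakpointResult:
    m: int                      # chosen number of breakpoints
    indices: list               # first index of each new segment (0-based)
    ages: list | None           # ages attached to those indices
    rss: dict                   # m -> minimal RSS
    bic: dict                   # m -> BIC
    segments: list              # (start, stop) per segment at the chosen m


@dataclass
class EWSSeries:
    window: int
    window_ends: np.ndarray     # 0-based index of each window's last sample
    ages: np.ndarray | None
    variance: np.ndarray
    lag1_ac: np.ndarray
    degenerate: np.ndarray      # True where a window had zero variance
    tau_var: float = np.nan
    p_var: float = np.nan
    tau_ac: float = np.nan
    p_ac: float = np.nan


@dataclass
class ARIMAFit:
    order: tuple
    params: dict
    sigma2: float
    nonstationary: bool
    results: object = field(repr=False, default=None)


@dataclass
class ForecastDeviation:
    forecast: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    observed: np.ndarray
    outside: np.ndarray
    fraction_outside: float
    deviates: bool              # fraction_outside > nominal 5% benchmark
    level: float = 0.95


# ---------------------------------------------------------------------------
# Structural-change breakpoints

_RSS_FLOOR = 1e-12


def _segment_rss(prefix: np.ndarray, prefix2: np.ndarray, a: int, b: int) -> float:
    """RSS of a constant mean on x[a:b] from prefix sums."""
    s = prefix[b] - prefix[a]
    s2 = prefix2[b] - prefix2[a]
    return s2 - s * s / (b - a)


def detect_breakpoints(series, max_m: int = 3, min_seg: int = 5,
                       ages=None) -> BreakpointResult:
    """Optimal piecewise-constant segmentation, model order chosen by BIC.

    For each candidate number of breaks m <= ``max_m`` the segmentation
    minimizing total segment RSS is found by exact dynamic programming with a
    minimum segment length; BIC = n ln(RSS/n) + (2m + 1) ln n selects m
    (each break contributes a position and a mean parameter).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if min_seg < 1:
        raise ValueError("min_seg must be >= 1")
    if n < 2 * min_seg:
        raise ValueError(f"need at least {2 * min_seg} points for one break")
    if (max_m + 1) * min_seg > n:
        raise ValueError(
            f"max_m={max_m} infeasible: {max_m + 1} segments of >= {min_seg} "
            f"points need {(max_m + 1) * min_seg} > {n} samples")
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])

    # cost[m][b] = minimal RSS of x[0:b] split into m+1 segments
    cost = np.full((max_m + 1, n + 1), np.inf)
    back = np.zeros((max_m + 1, n + 1), dtype=int)
    for b in range(min_seg, n + 1):
        cost[0, b] = _segment_rss(prefix, prefix2, 0, b)
    for m in range(1, max_m + 1):
        for b in range((m + 1) * min_seg, n + 1):
            lo, hi = m * min_seg, b - min_seg
            cand = cost[m - 1, lo:hi + 1] + np.array(
                [_segment_rss(prefix, prefix2, c, b) for c in range(lo, hi + 1)])
            j = int(np.argmin(cand))
            cost[m, b] = cand[j]
            back[m, b] = lo + j

    rss = {m: float(cost[m, n]) for m in range(max_m + 1) if np.isfinite(cost[m, n])}
    bic = {m: n * np.log(max(v, _RSS_FLOOR) / n) + (2 * m + 1) * np.log(n)
           for m, v in rss.items()}
    m_best = min(bic, key=bic.get)

    breaks = []
    b = n
    for m in range(m_best, 0, -1):
        b = int(back[m, b])
        breaks.append(b)
    breaks = sorted(breaks)
    bounds = [0] + breaks + [n]
    segments = list(zip(bounds[:-1], bounds[1:]))
    age_list = None
    if ages is not None:
        age = np.asarray(ages, dtype=float)
        age_list = [float(age[i]) for i in breaks]
    return BreakpointResult(m=m_best, indices=breaks, ages=age_list,
                            rss=rss, bic=bic, segments=segments)


def brute_force_breakpoints(series, m: int, min_seg: int = 1) -> tuple[list, float]:
    """Exhaustive search over all contiguous m-break segmentations (test oracle)."""
    from itertools import combinations

    x = np.asarray(series, dtype=float)
    n = x.size
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])
    best, best_breaks = np.inf, []
    for combo in combinations(range(1, n), m):
        bounds = [0, *combo, n]
        if any(b - a < min_seg for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        rss = sum(_segment_rss(prefix, prefix2, a, b)
                  for a, b in zip(bounds[:-1], bounds[1:]))
        if rss < best - 1e-12:
            best, best_breaks = rss, list(combo)
    return best_breaks, float(best)


# ---------------------------------------------------------------------------
# Early-warning signals


def sliding_ews(state, window: int = 5, ages=None,
                pre_transition_end: int | None = None) -> EWSSeries:
    """Sliding-window variance and lag-1 autocorrelation (right-aligned windows).

    Each window's statistics are assigned to its last sample, so signals lead
    up to the transition.  Kendall's tau of each signal against time is
    computed over windows ending at or before ``pre_transition_end`` (sample
    index; default: all windows).
    """
    x = np.asarray(state, dtype=float)
    n = x.size
    if window < 3:
        raise ValueError("window must be at least 3")
    if n < window + 1:
        raise ValueError(f"need more than {window} samples")
    ends = np.arange(window - 1, n)
    var = np.empty(ends.size)
    ac = np.empty(ends.size)
    degen = np.zeros(ends.size, dtype=bool)
    for k, end in enumerate(ends):
        seg = x[end - window + 1:end + 1]
        var[k] = seg.var(ddof=1)
        a, b = seg[:-1], seg[1:]
        if a.std() == 0 or b.std() == 0:
            ac[k] = 0.0
            degen[k] = True
        else:
            ac[k] = np.corrcoef(a, b)[0, 1]
    age_arr = None
    time_axis = ends.astype(float)
    if ages is not None:
        age_arr = np.asarray(ages, dtype=float)[ends]
        time_axis = age_arr
    out = EWSSeries(window=window, window_ends=ends, ages=age_arr,
                    variance=var, lag1_ac=ac, degenerate=degen)
    mask = np.ones(ends.size, dtype=bool)
    if pre_transition_end is not None:
        mask = ends <= pre_transition_end
    if mask.sum() >= 3:
        t = time_axis[mask]
        if np.ptp(var[mask]) > 0:
            out.tau_var, out.p_var = map(float, stats.kendalltau(t, var[mask]))
        if np.ptp(ac[mask]) > 0:
            out.tau_ac, out.p_ac = map(float, stats.kendalltau(t, ac[mask]))
    return out


# ---------------------------------------------------------------------------
# ARIMA forecast deviation


def fit_arima(series, order: tuple = (1, 1, 0), trend=None) -> ARIMAFit:
    """Fit an ARIMA(p, d, q) state model by maximum likelihood.

    ``trend`` follows statsmodels conventions ('t' adds a linear-in-levels
    drift, needed e.g. for a differenced model to extrapolate a ramp).  A
    non-stationary AR estimate (|phi| >= 1) is flagged but still returned.
    """
    x = np.asarray(series, dtype=float)
    p, d, q = order
    if x.size < p + d + 2:
        raise ValueError(f"need at least {p + d + 2} observations for order {order}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = ARIMA(x, order=order, trend=trend).fit()
    params = dict(zip(res.param_names, map(float, res.params)))
    ar = [v for k, v in params.items() if k.startswith("ar.")]
    nonstat = bool(ar) and max(abs(v) for v in ar) >= 1.0
    if nonstat:
        warnings.warn(f"non-stationary AR estimate: {ar}")
    return ARIMAFit(order=tuple(order), params=params,
                    sigma2=float(params.get("sigma2", np.nan)),
                    nonstationary=nonstat, results=res)


def forecast_deviation(fit: ARIMAFit, observed, level: float = 0.95) -> ForecastDeviation:
    """h-step forecasts with prediction intervals vs the observed second state.

    The deviation verdict is ``fraction_outside > 1 - level`` (more
    exceedances than the band's nominal rate).
    """
    obs = np.asarray(observed, dtype=float)
    h = obs.size
    if h <= 0:
        raise ValueError("observed series is empty")
    fc = fit.results.get_forecast(steps=h)
    mean = np.asarray(fc.predicted_mean, dtype=float)
    ci = np.asarray(fc.conf_int(alpha=1 - level), dtype=float)
    lower, upper = ci[:, 0], ci[:, 1]
    outside = (obs < lower) | (obs > upper)
    frac = float(outside.mean())
    return ForecastDeviation(forecast=mean, lower=lower, upper=upper,
                             observed=obs, outside=outside,
                             fraction_outside=frac,
                             deviates=frac > (1 - level), level=level)
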