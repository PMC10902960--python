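"""Joinpoint (segmented) log-linear regression with APC and AAPC.

The model is a continuous piecewise-linear regression on the log scale:

    ln y_t = beta_0 + beta_1 t + sum_i beta_{i+1} (t - T_i)_+ + eps_t

where (t - T_i)_+ is the positive part and T_i are the joinpoints
(breakpoints). The slope of segment i is b_i = beta_1 + sum_{j<=i}
beta_{j+1}; continuity at every joinpoint is automatic from the hinge
basis. The annual percent change of a segment is APC_i = (exp(b_i)-1)*100;
the average annual percent change over the whole period is the
segment-length-weighted geometric summary

    AAPC = (exp(sum_i w_i b_i / sum_i w_i) - 1) * 100,

w_i the number of years in segment i.

Breakpoint placement is an exhaustive grid search over the observed time
points subject to a minimum-observations-per-segment rule; the number of
joinpoints k is selected by an information criterion of the form
n ln(SSE/n) + p ln(n). Two penalties are offered:

* ``"weighted_bic"`` (default): p = 3k + 2. Each joinpoint is charged a
  slope change plus a double-weighted location parameter, compensating
  for the exhaustive location search (the maximum SSE reduction over all
  candidate placements is stochastically larger than a single chi-square
  draw, so an unweighted penalty systematically overfits k).
* ``"bic"``: p = 2(k+1), the plain parameter count.

All fits are ordinary least squares on ln(y); inference uses the t
distribution on the residual degrees of freedom (asymptotic, not
permutation-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "JoinpointFit",
    "SegmentAPC",
    "AAPCResult",
    "fit_segments",
    "select_model",
    "apc",
    "aapc",
    "aapc_from_apcs",
    "max_feasible_joinpoints",
]


@dataclass
class SegmentAPC:
    start: float
    end: float
    slope: float
    slope_se: float
    apc: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class AAPCResult:
    aapc: float
    ci_low: float
    ci_high: float
    p_value: float
    weights: np.ndarray


@dataclass
class JoinpointFit:
    """A fitted segmented log-linear model."""

    times: np.ndarray
    values: np.ndarray
    breakpoints: np.ndarray  # joinpoint times, possibly empty
    coef: np.ndarray  # (beta_0, beta_1, beta_2, ...)
    cov: np.ndarray  # OLS covariance of coef
    sse: float
    df_resid: int
    fitted_log: np.ndarray
    residuals: np.ndarray
    criterion: float | None = None

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) + 1

    def segment_bounds(self) -> list[tuple[float, float]]:
        edges = [float(self.times[0]), *map(float, self.breakpoints), float(self.times[-1])]
        return list(zip(edges[:-1], edges[1:]))

    def segment_slopes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-segment slope b_i and its standard error."""
        k = len(self.breakpoints)
        slopes = np.empty(k + 1)
        ses = np.empty(k + 1)
        for i in range(k + 1):
            c = np.zeros(len(self.coef))
            c[1] = 1.0
            c[2 : 2 + i] = 1.0
            slopes[i] = c @ self.coef
            ses[i] = float(np.sqrt(c @ self.cov @ c))
        return slopes, ses

    def predict_log(self, t) -> np.ndarray:
        X = _design(np.asarray(t, dtype=float), self.breakpoints)
        return X @ self.coef


def _design(t: np.ndarray, breakpoints) -> np.ndarray:
    cols = [np.ones_like(t), t]
    for bp in breakpoints:
        cols.append(np.clip(t - bp, 0.0, None))
    return np.column_stack(cols)


def fit_segments(times, values, breakpoints=()) -> JoinpointFit:
    """OLS fit of the hinge model at fixed breakpoints.

    ``values`` must be strictly positive (log model). Breakpoints must be
    strictly increasing and strictly inside the time range, and every
    segment must retain at least two observations.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and equally long")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(y <= 0):
        raise ValueError("log-linear model requires a strictly positive series")
    bps = np.asarray(sorted(breakpoints), dtype=float)
    if len(bps) != len(set(bps.tolist())):
        raise ValueError("duplicate breakpoints")
    if len(bps) and (bps[0] <= t[0] or bps[-1] >= t[-1]):
        raise ValueError("breakpoints must lie strictly inside the time range")
    edges = np.concatenate(([t[0] - 1], bps, [t[-1]]))
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.count_nonzero((t > lo) & (t <= hi)) < 2:
            raise ValueError(f"degenerate segment ({lo}, {hi}]: fewer than 2 observations")
    X = _design(t, bps)
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough observations for the requested model")
    ly = np.log(y)
    coef, _, _, _ = np.linalg.lstsq(X, ly, rcond=None)
    fitted = X @ coef
    resid = ly - fitted
    sse = float(resid @ resid)
    df = n - p
    sigma2 = sse / df if df > 0 else np.nan
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return JoinpointFit(t, y, bps, coef, cov, sse, df, fitted, resid)


def max_feasible_joinpoints(n: int, min_seg: int = 2) -> int:
    """Largest k such that k+1 segments of >= min_seg observations fit in n points."""
    return max(0, n // min_seg - 1)


def _bic(sse: float, n: int, k: int, criterion: str) -> float:
    p = 3 * k + 2 if criterion == "weighted_bic" else 2 * (k + 1)
    return n * np.log(max(sse, 1e-300) / n) + p * np.log(n)


def select_model(
    times,
    values,
    max_joinpoints: int = 3,
    criterion: str = "weighted_bic",
    min_seg: int = 2,
) -> JoinpointFit:
    """Exhaustive breakpoint search + information-criterion choice of k.

    Candidate breakpoints are the observed time points (interior ones
    respecting the minimum-segment rule). For each k up to
    ``max_joinpoints`` the placement minimising SSE is kept; k is then
    chosen by the criterion ("weighted_bic" default, "bic" selectable;
    see module docstring), ties resolved toward fewer joinpoints.
    Deterministic given inputs.
    """
    if criterion not in ("bic", "weighted_bic"):
        raise ValueError('criterion must be "bic" or "weighted_bic"')
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(t)
    kmax_feasible = max_feasible_joinpoints(n, min_seg)
    if max_joinpoints > kmax_feasible:
        raise ValueError(
            f"max_joinpoints={max_joinpoints} infeasible for n={n} "
            f"with min {min_seg} observations per segment; feasible maximum is {kmax_feasible}"
        )
    # interior candidates: keep min_seg points before the first and after the last breakpoint
    candidates = t[min_seg : n - min_seg + 1]
    best: JoinpointFit | None = None
    best_crit = np.inf
    for k in range(max_joinpoints + 1):
        best_k: JoinpointFit | None = None
        for combo in combinations(candidates, k):
            combo = np.asarray(combo)
            # enforce min_seg observations strictly within every interior segment
            if k and np.any(np.diff(np.searchsorted(t, combo)) < min_seg):
                continue
            try:
                fit = fit_segments(t, y, combo)
            except ValueError:
                continue
            if best_k is None or fit.sse < best_k.sse:
                best_k = fit
        if best_k is None:
            continue
        crit = _bic(best_k.sse, n, k, criterion)
        best_k.criterion = crit
        if crit < best_crit - 1e-12:
            best_crit = crit
            best = best_k
    assert best is not None
    return best


def apc(fit: JoinpointFit, alpha: float = 0.05) -> list[SegmentAPC]:
    """Per-segment annual percent change with t-based confidence intervals."""
    slopes, ses = fit.segment_slopes()
    tq = stats.t.ppf(1 - alpha / 2, fit.df_resid) if fit.df_resid > 0 else np.inf
    out = []
    for (lo, hi), b, se in zip(fit.segment_bounds(), slopes, ses):
        ci_l = (np.exp(b - tq * se) - 1) * 100
        ci_h = (np.exp(b + tq * se) - 1) * 100
        tstat = b / se if se > 0 else np.inf * np.sign(b)
        p = 2 * stats.t.sf(abs(tstat), fit.df_resid) if fit.df_resid > 0 else np.nan
        out.append(
            SegmentAPC(lo, hi, float(b), float(se), float((np.exp(b) - 1) * 100),
                       float(ci_l), float(ci_h), float(p))
        )
    return out


def aapc(fit: JoinpointFit, alpha: float = 0.05) -> AAPCResult:
    """Average annual percent change over the fitted period.

    The weighted mean slope L = sum w_i b_i / sum w_i (w_i = years in
    segment i) is linear in the coefficients, so its variance comes
    directly from the OLS covariance (delta method on exp(L)).
    """
    bounds = fit.segment_bounds()
    w = np.array([hi - lo for lo, hi in bounds])
    k = len(fit.breakpoints)
    # L = c' beta with c accumulating hinge contributions
    c = np.zeros(len(fit.coef))
    c[1] = 1.0  # beta_1 contributes to every segment
    for i in range(1, k + 1):
        c[1 + i] = w[i:].sum() / w.sum()  # hinge i contributes from segment i on
    L = float(c @ fit.coef)
    se = float(np.sqrt(c @ fit.cov @ c))
    zq = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(L / se)) if se > 0 else np.nan
    return AAPCResult(
        aapc=float((np.exp(L) - 1) * 100),
        ci_low=float((np.exp(L - zq * se) - 1) * 100),
        ci_high=float((np.exp(L + zq * se) - 1) * 100),
        p_value=float(p),
        weights=w,
    )


def aapc_from_apcs(segment_apcs, segment_weights) -> float:
    """AAPC (percent) from per-segment APCs and segment lengths in years.

    b_i = ln(1 + APC_i/100); AAPC = (exp(sum w_i b_i / sum w_i) - 1) * 100.
    """
    a = np.asarray(segment_apcs, dtype=float)
    w = np.asarray(segment_weights, dtype=float)
    if a.shape != w.shape:
        raise ValueError("APC and weight lists must have equal length")
    if np.any(w <= 0):
        raise ValueError("segment weights must be positive")
    if np.any(a <= -100):
        raise ValueError("APC <= -100% has no log representation")
    b = np.log1p(a / 100.0)
    return float((np.exp(np.sum(w * b) / np.sum(w)) - 1) * 100)
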