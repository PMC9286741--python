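"""Piecewise-linear smoothing of longitudinal body weight (l1 trend filtering).

Each mouse's raw weight series y over its measurement ages is replaced by
the minimiser of

    (1/2) sum_t (y_t - x_t)^2  +  lambda * sum_t |x_{t-1} - 2 x_t + x_{t+1}|

whose solutions are piecewise linear in the measurement index, with knots
where the penalised second difference is nonzero.  Growth rate is the exact
slope of consecutive fitted points (grams/day).  The penalty is chosen by
minimising squared error on randomly held-out ages pooled across mice.

The solver is ADMM on the split x, z = D x (D the second-difference
operator), with the x-update a pentadiagonal symmetric solve
(scipy.linalg.solveh_banded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .data_io import PhenotypeSeries, logger

#: Default penalty grid: logarithmic, 30 points spanning 1e-2..1e4.
DEFAULT_LAMBDA_GRID = np.logspace(-2, 4, 30)

KNOT_TOL = 1e-6


@dataclass
class TrendFit:
    """Piecewise-linear fit of one mouse's weight series.

    growth_rate[i] is the exact slope of the fitted segment between
    grid_ages[i] and grid_ages[i+1], in grams per day.
    """

    mouse_id: str
    grid_ages: np.ndarray
    fitted_weights: np.ndarray
    growth_rate: np.ndarray
    lam: float
    objective: float

    @property
    def n_knots(self) -> int:
        d2 = np.diff(self.fitted_weights, 2)
        return int((np.abs(d2) > KNOT_TOL).sum())


def _second_difference(n: int) -> np.ndarray:
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i:i + 3] = (1.0, -2.0, 1.0)
    return D


def trend_objective(y: np.ndarray, x: np.ndarray, lam: float) -> float:
    """(1/2)||y - x||^2 + lam * ||D2 x||_1."""
    d2 = np.diff(x, 2)
    return 0.5 * float(np.sum((y - x) ** 2)) + lam * float(np.abs(d2).sum())


def _ols_line(y: np.ndarray) -> np.ndarray:
    t = np.arange(len(y), dtype=float)
    A = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ coef


def _admm_l1_trend(y: np.ndarray, lam: float, tol: float = 1e-8,
                   max_iter: int = 20000) -> np.ndarray:
    n = len(y)
    m = n - 2
    rho = max(1.0, lam)
    # banded form of I + rho D'D (pentadiagonal, upper storage)
    D = _second_difference(n)
    A = np.eye(n) + rho * (D.T @ D)
    ab = np.zeros((3, n))
    ab[2] = np.diag(A)
    ab[1, 1:] = np.diag(A, 1)
    ab[0, 2:] = np.diag(A, 2)
    z = np.zeros(m)
    u = np.zeros(m)
    x = y.copy()
    thr = lam / rho
    for it in range(max_iter):
        x = sla.solveh_banded(ab, y + rho * (D.T @ (z - u)), lower=False)
        Dx = np.diff(x, 2)
        z_new = np.sign(Dx + u) * np.maximum(np.abs(Dx + u) - thr, 0.0)
        dual = rho * np.linalg.norm(D.T @ (z_new - z))
        z = z_new
        u = u + Dx - z
        primal = np.linalg.norm(Dx - z)
        scale = max(1.0, np.linalg.norm(y))
        if primal < tol * scale and dual < tol * scale:
            break
    else:
        logger.warning("l1 trend ADMM hit max_iter (lam=%g)", lam)
    return x


def fit_l1_trend(series: PhenotypeSeries, lam: float) -> TrendFit:
    """Fit the l1 trend-filtering objective to one mouse's series.

    lam = 0 reproduces the raw measurements; very large lam yields the
    ordinary least-squares straight line (all second differences zero).
    """
    if len(series.ages) < 3:
        raise ValueError(
            f"{series.mouse_id}: need >= 3 ages for second differences"
        )
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    y = series.weights.astype(float)
    if lam == 0:
        x = y.copy()
    else:
        x = _admm_l1_trend(y, lam)
        # very strong penalties: snap to the exact analytic OLS-line limit
        line = _ols_line(y)
        if trend_objective(y, line, lam) <= trend_objective(y, x, lam) + 1e-12:
            x = line
    slopes = np.diff(x) / np.diff(series.ages)
    return TrendFit(series.mouse_id, series.ages.copy(), x, slopes, float(lam),
                    trend_objective(y, x, lam))


def sample_at_ages(fit: TrendFit, ages) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of the fit (and its piecewise-constant slope).

    Ages outside the mouse's measurement span yield NaN (the mouse drops out
    of that age's cross-section) rather than an error.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    lo, hi = fit.grid_ages[0], fit.grid_ages[-1]
    w = np.interp(ages, fit.grid_ages, fit.fitted_weights)
    seg = np.clip(np.searchsorted(fit.grid_ages, ages, side="right") - 1, 0,
                  len(fit.growth_rate) - 1)
    g = fit.growth_rate[seg]
    out = (ages < lo) | (ages > hi)
    w[out] = np.nan
    g[out] = np.nan
    return w, g


def select_lambda(all_series, holdout_fraction: float = 0.1, seed: int = 0,
                  grid=None, return_table: bool = False):
    """Choose the penalty minimising pooled held-out squared error.

    For each mouse a seed-controlled random subset of interior ages (at
    least one, while keeping >= 3 training points) is held out; for each
    lambda in the grid the trend is fit to the remaining ages and evaluated
    at the held-out ages by linear interpolation.  Returns the grid value
    with the smallest mean squared error pooled across mice.
    """
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.atleast_1d(grid)
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    if len(grid) == 1 and not return_table:
        return float(grid[0])
    rng = np.random.default_rng(seed)
    splits = []
    for s in all_series:
        T = len(s.ages)
        interior = np.arange(1, T - 1)
        n_hold = min(max(1, int(round(holdout_fraction * T))), T - 3)
        if n_hold < 1 or len(interior) < n_hold:
            raise ValueError(f"{s.mouse_id}: series too short to hold out ages")
        held = rng.choice(interior, size=n_hold, replace=False)
        mask = np.ones(T, dtype=bool)
        mask[held] = False
        splits.append((s, mask))
    errors = np.zeros(len(grid))
    counts = 0
    for s, mask in splits:
        train = PhenotypeSeries(s.mouse_id, s.ages[mask], s.weights[mask],
                                source=s.source)
        for gi, lam in enumerate(grid):
            fit = fit_l1_trend(train, float(lam))
            pred, _ = sample_at_ages(fit, s.ages[~mask])
            errors[gi] += float(np.sum((pred - s.weights[~mask]) ** 2))
        counts += int((~mask).sum())
    mse = errors / counts
    best = float(grid[int(np.argmin(mse))])
    if return_table:
        return best, dict(zip(map(float, grid), mse))
    return best
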