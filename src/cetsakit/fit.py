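"""Brute-force Boltzmann sigmoid fitting of melting curves.

Each normalized curve is fitted by exhaustive sum-of-squares minimization
over a dense parameter grid (midpoint x slope x plateau), optionally
followed by a Nelder-Mead polish started at the grid optimum and bounded
by the grid ranges.  The melting temperature Tm is the temperature where the
fitted curve crosses 0.5 soluble fraction, which for the three-parameter
sigmoid has the closed form Tm = m + s * ln((1 - p)/(0.5 - p) - 1);
curves whose plateau sits at or above 0.5 never cross and carry an
undefined Tm.  Goodness of fit is the Pearson correlation r between
observed and fitted fractions, plus the RMSE.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, minimize

from .errors import ValidationError
from .normalize import MeltCurve
from .synthetic import MeltParams, boltzmann

_FLAT_TOL = 1e-12


@dataclass(frozen=True)
class GridSpec:
    """Search grid for the brute-force fit.

    Defaults span the ten-temperature gradient with sub-degree midpoint
    resolution (~40k grid points per curve): midpoints every 0.25 degC over
    [35, 75], 25 log-spaced slopes in [0.3, 8] and plateaus every 0.05 up
    to 0.45.
    """

    midpoint_range: tuple[float, float] = (35.0, 75.0)
    midpoint_step: float = 0.25
    slope_range: tuple[float, float] = (0.3, 8.0)
    n_slopes: int = 25
    plateau_range: tuple[float, float] = (0.0, 0.45)
    plateau_step: float = 0.05
    refine: bool = True

    def __post_init__(self) -> None:
        if self.midpoint_step <= 0 or self.plateau_step <= 0 or self.n_slopes < 2:
            raise ValidationError("grid steps must be positive, n_slopes >= 2")
        if (self.midpoint_range[0] >= self.midpoint_range[1]
                or self.slope_range[0] >= self.slope_range[1]
                or self.plateau_range[0] > self.plateau_range[1]):
            raise ValidationError("grid ranges must be non-empty")
        if self.slope_range[0] <= 0:
            raise ValidationError("slopes must be positive")
        if not (0.0 <= self.plateau_range[0] and self.plateau_range[1] < 1.0):
            raise ValidationError("plateau range must lie in [0, 1)")

    @classmethod
    def for_gradient(cls, temperatures, **kwargs) -> "GridSpec":
        """Grid whose midpoint range covers [T_min - 2, T_max + 8]."""
        temps = np.asarray(tuple(temperatures), dtype=float)
        kwargs.setdefault("midpoint_range", (float(temps.min() - 2), float(temps.max() + 8)))
        return cls(**kwargs)

    def midpoints(self) -> np.ndarray:
        lo, hi = self.midpoint_range
        return np.arange(lo, hi + self.midpoint_step / 2, self.midpoint_step)

    def slopes(self) -> np.ndarray:
        return np.geomspace(self.slope_range[0], self.slope_range[1], self.n_slopes)

    def plateaus(self) -> np.ndarray:
        lo, hi = self.plateau_range
        return np.arange(lo, hi + self.plateau_step / 2, self.plateau_step)


# model-matrix cache: one entry per (grid, gradient) pair
_MODEL_CACHE: dict[tuple, tuple[np.ndarray, ...]] = {}


def _grid_model(grid: GridSpec, temperatures: tuple[float, ...]):
    key = (grid, temperatures)
    cached = _MODEL_CACHE.get(key)
    if cached is None:
        m, s, p = grid.midpoints(), grid.slopes(), grid.plateaus()
        mm, ss, pp = (a.ravel() for a in np.meshgrid(m, s, p, indexing="ij"))
        t = np.asarray(temperatures, dtype=float)
        # grid points ordered lexicographically by (m, s, p): argmin's
        # first-occurrence rule then implements the deterministic tie-break
        model = boltzmann(t[None, :], mm[:, None], ss[:, None], pp[:, None])
        cached = (mm, ss, pp, model, len(s), len(p))
        _MODEL_CACHE[key] = cached
    return cached


@dataclass
class BoltzmannFit:
    """Fitted melt model with derived Tm and goodness-of-fit statistics."""

    params: MeltParams
    tm: float
    tm_defined: bool
    sse: float
    r: float
    rmse: float
    grid_params: MeltParams
    grid_sse: float
    refined: bool = False
    non_melter: bool = False
    degenerate_r: bool = False


def melting_temperature(params: MeltParams) -> float:
    """Temperature where the fitted curve crosses 0.5; NaN when p >= 0.5."""
    if params.plateau >= 0.5:
        return math.nan
    return params.midpoint + params.slope * math.log(
        (1.0 - params.plateau) / (0.5 - params.plateau) - 1.0)


def fit_quality(curve: MeltCurve, params: MeltParams) -> tuple[float, float]:
    """Pearson r between observed and fitted fractions, and the RMSE.

    Zero variance in either vector (non-melters, constant fits) makes the
    correlation undefined; it is reported as 0.
    """
    observed = curve.fractions
    fitted = boltzmann(curve.temperatures, params.midpoint, params.slope, params.plateau)
    resid = observed - fitted
    rmse = float(np.sqrt(np.mean(resid * resid)))
    if np.std(observed) < _FLAT_TOL or np.std(fitted) < _FLAT_TOL:
        return 0.0, rmse
    r = float(np.corrcoef(observed, fitted)[0, 1])
    return r, rmse


def fit_boltzmann_bruteforce(curve: MeltCurve, grid: GridSpec | None = None) -> BoltzmannFit:
    """Fit one curve by exhaustive grid search, then optional local polish.

    The returned grid optimum attains the exact minimum SSE over the full
    grid; ties are broken lexicographically by (midpoint, slope, plateau).
    Refinement (Nelder-Mead started at the grid optimum, bounded by the
    grid ranges) can only lower the SSE.  All-constant curves are flagged
    as non-melters with an undefined Tm.
    """
    y = np.asarray(curve.fractions, dtype=float)
    if y.size < 4:
        raise ValidationError(f"curve has {y.size} points; need >= 4 to fit")
    temps_key = tuple(float(t) for t in curve.temperatures)
    if grid is None:
        grid = GridSpec.for_gradient(temps_key)
    mm, ss, pp, model, n_s, n_p = _grid_model(grid, temps_key)

    diff = model - y[None, :]
    sse_all = (diff * diff).sum(axis=1)
    i = int(np.argmin(sse_all))
    grid_params = MeltParams(float(mm[i]), float(ss[i]), float(pp[i]))
    grid_sse = float(sse_all[i])

    non_melter = bool(np.ptp(y) < _FLAT_TOL)
    params, sse, refined = grid_params, grid_sse, False

    if grid.refine and not non_melter:
        t = np.asarray(temps_key)
        # polish within the full grid ranges: confining the simplex to one
        # grid cell strands it when discretization trades midpoint error
        # against slope/plateau error, leaving Tm off by ~2 grid steps on
        # otherwise exactly representable curves
        lower = [grid.midpoint_range[0], grid.slope_range[0], grid.plateau_range[0]]
        upper = [grid.midpoint_range[1], grid.slope_range[1], grid.plateau_range[1]]

        def objective(x):
            f = boltzmann(t, x[0], x[1], x[2])
            r = f - y
            return float((r * r).sum())

        res = minimize(objective,
                       x0=[grid_params.midpoint, grid_params.slope, grid_params.plateau],
                       method="Nelder-Mead", bounds=Bounds(lower, upper),
                       options={"xatol": 1e-6, "fatol": 1e-15,
                                "maxiter": 500, "maxfev": 800})
        if res.fun < sse:
            params = MeltParams(float(res.x[0]), float(res.x[1]), float(res.x[2]))
            sse, refined = float(res.fun), True

    tm = melting_temperature(params)
    tm_defined = math.isfinite(tm) and not non_melter
    r, rmse = fit_quality(curve, params)
    degenerate = non_melter or np.std(curve.fractions) < _FLAT_TOL
    return BoltzmannFit(params=params, tm=tm, tm_defined=tm_defined, sse=sse,
                        r=r, rmse=rmse, grid_params=grid_params, grid_sse=grid_sse,
                        refined=refined, non_melter=non_melter, degenerate_r=degenerate)


FIT_COLUMNS = ("protein_id", "condition", "replicate", "midpoint", "slope",
               "plateau", "tm", "tm_defined", "sse", "grid_sse", "r", "rmse",
               "non_melter")


def fit_dataset(curves: list[MeltCurve], grid: GridSpec | None = None) -> pd.DataFrame:
    """Fit every curve; one row per (protein, condition, replicate).

    Replicate curves are fitted individually, never averaged: the Tm-shift
    statistics downstream need replicate-level melting temperatures.
    """
    rows = []
    for curve in curves:
        fit = fit_boltzmann_bruteforce(curve, grid)
        rows.append((curve.protein_id, curve.condition, curve.replicate,
                     fit.params.midpoint, fit.params.slope, fit.params.plateau,
                     fit.tm, fit.tm_defined, fit.sse, fit.grid_sse, fit.r,
                     fit.rmse, fit.non_melter))
    return pd.DataFrame(rows, columns=list(FIT_COLUMNS))
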