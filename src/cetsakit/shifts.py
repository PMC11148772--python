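"""Tm-shift computation and hit calling.

The thermal shift of a protein is dTm = Tm(treated) - Tm(vehicle),
computed per replicate pair and tested across replicates with a
one-sample Student t-test against zero (a sign-flip permutation test is
available for designs where t assumptions are doubtful).  A protein is
called a specific interactor when three filters hold jointly: the worst
fit correlation across all its curves exceeds the r threshold (default
0.7), the replicate p-value is below the p threshold (default 0.01), and
every replicate shift has the same sign.  No multiple-testing correction
gates the call; a Benjamini-Hochberg q-value column is emitted for
reference.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .fit import BoltzmannFit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HitThresholds:
    """Filter thresholds for calling specific interactors."""

    r_threshold: float = 0.7
    p_threshold: float = 0.01
    require_sign_consistency: bool = True
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_threshold <= 1.0):
            raise ValidationError("r_threshold must be in [0, 1]")
        if not (0.0 < self.p_threshold < 1.0):
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.min_replicates < 1:
            raise ValidationError("min_replicates must be >= 1")


def delta_tm(fit_treated: BoltzmannFit, fit_vehicle: BoltzmannFit) -> float:
    """Tm(treated) - Tm(vehicle); positive = stabilization. NaN if either undefined."""
    if not (fit_treated.tm_defined and fit_vehicle.tm_defined):
        return float("nan")
    return fit_treated.tm - fit_vehicle.tm


def replicate_shift_test(delta_tms, method: str = "t") -> float:
    """Two-sided p-value for the replicate Tm shifts being nonzero.

    ``method="t"`` is a one-sample Student t-test against 0.  Degenerate
    zero-variance input gives p = 0 for a nonzero mean and p = 1 for an
    exact null.  ``method="permutation"`` enumerates all sign flips of the
    replicate shifts.  Fewer than two finite replicates are not testable
    (NaN).
    """
    x = np.asarray(delta_tms, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    if method == "t":
        if np.std(x, ddof=1) == 0.0:
            return 1.0 if x.mean() == 0.0 else 0.0
        return float(stats.ttest_1samp(x, 0.0).pvalue)
    if method == "permutation":
        observed = abs(x.mean())
        count = 0
        total = 0
        for signs in itertools.product((-1.0, 1.0), repeat=x.size):
            total += 1
            if abs(np.mean(x * np.asarray(signs))) >= observed - 1e-12:
                count += 1
        return count / total
    raise ValidationError(f"unknown test method {method!r}")


def shift_results(fits: pd.DataFrame, vehicle: str = "vehicle",
                  treated: str = "treated", method: str = "t") -> pd.DataFrame:
    """Per-protein Tm shift table from a replicate-level fit table.

    Pairs vehicle and treated fits by replicate id; replicates where either
    Tm is undefined contribute no shift.  ``min_fit_r`` is the worst fit
    correlation over all the protein's curves in both arms.
    """
    required = {"protein_id", "condition", "replicate", "tm", "tm_defined", "r"}
    missing = required - set(fits.columns)
    if missing:
        raise ValidationError(f"fit table is missing columns: {sorted(missing)}")
    proteins = fits["protein_id"].unique()
    defined = fits[fits["tm_defined"].astype(bool)]
    veh = defined[defined["condition"] == vehicle].set_index(["protein_id", "replicate"])["tm"]
    trt = defined[defined["condition"] == treated].set_index(["protein_id", "replicate"])["tm"]
    shared = veh.index.intersection(trt.index)
    deltas = (trt.loc[shared] - veh.loc[shared]).rename("delta_tm")
    min_r = fits.groupby("protein_id")["r"].min()
    replicates = sorted(fits["replicate"].unique())

    rows = []
    for pid in proteins:
        d = deltas.loc[[pid]] if pid in deltas.index.get_level_values(0) else pd.Series(dtype=float)
        by_rep = {rep: np.nan for rep in replicates}
        for (_, rep), value in d.items():
            by_rep[rep] = value
        values = d.to_numpy()
        finite = values[np.isfinite(values)]
        mean = float(finite.mean()) if finite.size else float("nan")
        p = replicate_shift_test(finite, method=method)
        sign_consistent = bool(finite.size > 0
                               and (np.all(finite > 0) or np.all(finite < 0)))
        row = {"protein_id": pid}
        row.update({f"delta_tm_rep{rep}": by_rep[rep] for rep in replicates})
        row.update({"mean_delta_tm": mean, "n_replicates": int(finite.size),
                    "p_value": p, "min_fit_r": float(min_r.get(pid, np.nan)),
                    "sign_consistent": sign_consistent})
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    q = np.full(len(out), np.nan)
    testable = out["p_value"].notna().to_numpy()
    if testable.any():
        q[testable] = multipletests(out.loc[testable, "p_value"], method="fdr_bh")[1]
    out["q_value"] = q
    return out


def call_hits(results: pd.DataFrame, thresholds: HitThresholds | None = None) -> pd.DataFrame:
    """Apply the three-filter conjunction and sort by |mean shift|.

    A hit requires min_fit_r above the correlation threshold, p below the
    p threshold, enough replicate shifts, and (by default) strict sign
    agreement across replicates.
    """
    thresholds = thresholds or HitThresholds()
    out = results.copy()
    if out.empty:
        out["is_hit"] = pd.Series(dtype=bool)
        return out
    testable = out["p_value"].notna() & (out["n_replicates"] >= thresholds.min_replicates)
    is_hit = (testable
              & (out["min_fit_r"] > thresholds.r_threshold)
              & (out["p_value"] < thresholds.p_threshold))
    if thresholds.require_sign_consistency:
        is_hit &= out["sign_consistent"]
    out["is_hit"] = is_hit.fillna(False).astype(bool)
    order = out["mean_delta_tm"].abs()
    return out.iloc[np.argsort(-order.fillna(-np.inf).to_numpy(), kind="stable")].reset_index(drop=True)


@dataclass
class DensityCurve:
    """Gaussian kernel density of Tm shifts on an explicit grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    degenerate: bool = False


def tm_shift_density(delta_tms, bandwidth="auto", grid_size: int = 256,
                     padding: float = 3.0) -> DensityCurve:
    """Gaussian KDE of the Tm-shift distribution.

    ``bandwidth="auto"`` uses Silverman's rule; when the data are all
    identical (zero spread) a fixed minimal bandwidth of 0.1 degC is used
    and flagged.  The density integrates to 1 (trapezoid) to within 1e-3.
    """
    x = np.asarray(delta_tms, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValidationError("need >= 2 finite shifts for a density estimate")
    degenerate = False
    if bandwidth == "auto":
        sd = np.std(x, ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        scale = min(sd, iqr / 1.34) if iqr > 0 else sd
        h = 0.9 * scale * x.size ** (-0.2)
        if not h > 0:
            h, degenerate = 0.1, True
            logger.warning("zero-spread shifts; falling back to bandwidth 0.1 degC")
    else:
        h = float(bandwidth)
        if not h > 0:
            raise ValidationError("bandwidth must be positive")
    grid = np.linspace(x.min() - padding * h, x.max() + padding * h, grid_size)
    z = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2 * np.pi))
    return DensityCurve(grid, density, h, degenerate)
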