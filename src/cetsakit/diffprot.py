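"""Global differential-proteome statistics for multiplexed TMT runs.

Spectrum-level reporter intensities are expressed as log2 ratios against
the mean of the control channels, aggregated to proteins by an
inverse-variance weighted mean (an intensity-dependent variance model
v = a + b/I estimated from the data; uniform weights are the fallback),
standardized across proteins to Z-scores with mean 0 and sd 1, compared
between channel groups with a Student t-test, and fed into a
hypergeometric over-representation test against user-supplied gene sets.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import NumericalError, ValidationError

logger = logging.getLogger(__name__)


def log2_ratio_to_control(intensities: pd.Series, control_channels: Sequence[str],
                          include_controls: bool = False) -> pd.Series:
    """log2 of each channel's intensity over the control-channel mean."""
    controls = [c for c in control_channels if c in intensities.index]
    if len(controls) != len(control_channels):
        missing = sorted(set(control_channels) - set(intensities.index))
        raise ValidationError(f"control channels missing from record: {missing}")
    control_mean = float(intensities[controls].mean())
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise ValidationError(f"non-positive control mean ({control_mean})")
    channels = intensities.index if include_controls else [
        c for c in intensities.index if c not in set(control_channels)]
    with np.errstate(divide="ignore"):
        return np.log2(intensities[channels] / control_mean)


def spectrum_ratio_table(spectra: pd.DataFrame, control_channels: Sequence[str],
                         include_controls: bool = True) -> pd.DataFrame:
    """Per-spectrum log2 ratios vs the control mean, long format.

    ``spectra`` is a long table (spectrum_id, protein_id, channel,
    intensity).  Spectra with a non-positive control mean are dropped with
    a warning.  Output columns: spectrum_id, protein_id, channel,
    log2_ratio, mean_intensity, weight (initialized to 1).
    """
    required = {"spectrum_id", "protein_id", "channel", "intensity"}
    missing = required - set(spectra.columns)
    if missing:
        raise ValidationError(f"spectrum table is missing columns: {sorted(missing)}")
    wide = spectra.pivot_table(index=["spectrum_id", "protein_id"],
                               columns="channel", values="intensity", aggfunc="first")
    ctrl = [c for c in control_channels if c in wide.columns]
    if len(ctrl) != len(control_channels):
        raise ValidationError(
            f"control channels absent from table: {sorted(set(control_channels) - set(wide.columns))}")
    control_mean = wide[ctrl].mean(axis=1)
    keep = control_mean > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d spectra with non-positive control mean", n_dropped)
    wide = wide[keep]
    control_mean = control_mean[keep]
    channels = list(wide.columns) if include_controls else [
        c for c in wide.columns if c not in set(control_channels)]
    with np.errstate(divide="ignore"):
        ratios = np.log2(wide[channels].div(control_mean, axis=0))
    out = (ratios.reset_index()
           .melt(id_vars=["spectrum_id", "protein_id"],
                 var_name="channel", value_name="log2_ratio"))
    mean_int = wide.mean(axis=1).rename("mean_intensity").reset_index()
    out = out.merge(mean_int, on=["spectrum_id", "protein_id"], how="left")
    out["weight"] = 1.0
    return out


def estimate_inverse_variance_weights(records: pd.DataFrame,
                                      floor: float = 1e-4) -> pd.DataFrame:
    """Set spectrum weights from an intensity-dependent variance model.

    Residuals of each spectrum ratio around its (protein, channel) mean
    estimate the measurement variance; a global model v = a + b/I is fitted
    by least squares on squared residuals, floored, and inverted into
    weights.  Falls back to uniform weights when the model cannot be
    estimated (too few replicated spectra).
    """
    out = records.copy()
    group_mean = out.groupby(["protein_id", "channel"])["log2_ratio"].transform("mean")
    group_size = out.groupby(["protein_id", "channel"])["log2_ratio"].transform("size")
    resid = out["log2_ratio"] - group_mean
    mask = (group_size > 1) & np.isfinite(resid) & np.isfinite(out["mean_intensity"])
    if mask.sum() < 10:
        logger.warning("too few replicated spectra for a variance model; uniform weights")
        out["weight"] = 1.0
        return out
    r2 = (resid[mask] ** 2) * group_size[mask] / (group_size[mask] - 1)
    design = np.column_stack([np.ones(mask.sum()), 1.0 / out.loc[mask, "mean_intensity"]])
    coef, *_ = np.linalg.lstsq(design, r2.to_numpy(), rcond=None)
    v = coef[0] + coef[1] / out["mean_intensity"]
    v = np.maximum(v, max(floor, float(np.median(r2)) * 1e-3))
    out["weight"] = 1.0 / v
    return out


def aggregate_weighted(records: pd.DataFrame) -> pd.DataFrame:
    """Weighted mean log2 ratio per (protein, channel).

    With exactly uniform weights this reduces to the plain arithmetic mean
    (computed as such, so the equality is exact).
    """
    if records.empty:
        return pd.DataFrame(columns=["protein_id", "channel", "log2_ratio", "n_spectra"])
    if "weight" not in records.columns:
        records = records.assign(weight=1.0)

    def _agg(group: pd.DataFrame) -> pd.Series:
        w = group["weight"].to_numpy()
        x = group["log2_ratio"].to_numpy()
        if np.all(w == w[0]):
            value = float(x.mean())
        else:
            value = float(np.sum(w * x) / np.sum(w))
        return pd.Series({"log2_ratio": value, "n_spectra": len(group)})

    out = (records.groupby(["protein_id", "channel"], sort=True)
           .apply(_agg, include_groups=False).reset_index())
    out["n_spectra"] = out["n_spectra"].astype(int)
    return out


def standardize_zscores(values) -> np.ndarray:
    """Standardize to mean 0 / sample-sd 1 across proteins."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("need >= 3 values to standardize")
    sd = np.std(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise NumericalError("zero dispersion; z-scores are undefined")
    return (x - x.mean()) / sd


def ttest_proteins(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample Student t-test (pooled variance by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene/protein sets for over-representation testing."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValidationError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one tab-separated line per set (name, description, members)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT lines need >= 3 fields")
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise ValidationError(f"{path}:{lineno}: gene set {parts[0]!r} is empty")
            sets[parts[0]] = members
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return GeneSetCollection(sets)


def hypergeometric_enrichment(hits: Iterable[str], collection: GeneSetCollection,
                              universe: Iterable[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    The universe should be the quantified proteins (not the whole
    annotation) to avoid detection bias; hit identifiers outside the
    universe are excluded with a warning.  BH correction is applied across
    sets.
    """
    universe_set = set(universe)
    hit_set = set(hits)
    outside = hit_set - universe_set
    if outside:
        logger.warning("excluding %d hit identifiers outside the universe", len(outside))
        hit_set &= universe_set
    m_total = len(universe_set)
    n_hits = len(hit_set)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe_set
        k = len(members & hit_set)
        # P(overlap >= k) drawing n_hits from a universe with len(members) marked
        p = float(stats.hypergeom.sf(k - 1, m_total, len(members), n_hits)) if members else 1.0
        rows.append((name, len(members), k, p))
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p_value"])
    if not out.empty:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out.attrs["n_hits_outside_universe"] = len(outside)
    out.attrs["n_hits_tested"] = n_hits
    return out
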