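"""Tabular I/O for TMT reporter-ion data.

The pipeline starts from quantified reporter tables (one intensity per
protein or PSM and channel), not from raw spectra.  This module reads and
writes those tables, maps TMT channels onto the temperature gradient,
corrects isotope impurities by solving the channel cross-contamination
linear system, and aggregates PSM-level intensities to proteins with a
sum-based bootstrap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import NumericalError, ValidationError

logger = logging.getLogger(__name__)

#: Channel labels of a 10-plex TMT set, in mass order.
TMT10_CHANNELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
)

#: The ten-temperature CETSA gradient (degC).
DEFAULT_TEMPERATURES: tuple[float, ...] = (
    37.0, 41.0, 44.0, 47.0, 50.0, 53.0, 56.0, 59.0, 63.0, 67.0,
)

LONG_COLUMNS = ("protein_id", "condition", "replicate", "channel", "temperature_c", "intensity")


@dataclass(frozen=True)
class TemperatureGradient:
    """Ordered mapping of TMT channel labels to heating temperatures."""

    channels: tuple[str, ...]
    temperatures: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.temperatures):
            raise ValidationError("channels and temperatures differ in length")
        if len(self.channels) < 4:
            raise ValidationError("a gradient needs at least 4 temperature points")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")
        t = np.asarray(self.temperatures, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValidationError("temperatures must be strictly increasing")

    @classmethod
    def tmt10(cls) -> "TemperatureGradient":
        """The standard 10-plex gradient: 37-67 degC over TMT channels 126-131."""
        return cls(TMT10_CHANNELS, DEFAULT_TEMPERATURES)

    @classmethod
    def for_temperatures(cls, temperatures: Iterable[float]) -> "TemperatureGradient":
        temps = tuple(float(t) for t in temperatures)
        if len(temps) == len(TMT10_CHANNELS):
            channels = TMT10_CHANNELS
        else:
            channels = tuple(f"C{i:02d}" for i in range(1, len(temps) + 1))
        return cls(channels, temps)

    @property
    def n(self) -> int:
        return len(self.channels)

    def temperature_of(self, channel: str) -> float:
        try:
            return self.temperatures[self.channels.index(channel)]
        except ValueError:
            raise ValidationError(f"channel {channel!r} is not in the gradient") from None

    def to_mapping(self) -> dict[str, float]:
        return dict(zip(self.channels, self.temperatures))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TemperatureGradient":
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise ValidationError(f"{path}: expected a channel -> temperature map")
        items = sorted(mapping.items(), key=lambda kv: float(kv[1]))
        return cls(tuple(str(k) for k, _ in items), tuple(float(v) for _, v in items))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)


@dataclass
class ReporterDataset:
    """Long-format reporter-ion intensities with an attached gradient.

    ``data`` holds one row per (protein, condition, replicate, channel)
    — or per PSM when a ``psm_id`` column is present — with non-negative
    finite intensities.
    """

    data: pd.DataFrame
    gradient: TemperatureGradient

    def __post_init__(self) -> None:
        missing = [c for c in ("protein_id", "condition", "replicate", "channel", "intensity")
                   if c not in self.data.columns]
        if missing:
            raise ValidationError(f"reporter table is missing columns: {missing}")
        unknown = set(self.data["channel"].unique()) - set(self.gradient.channels)
        if unknown:
            raise ValidationError(f"channels not in the gradient: {sorted(unknown)}")
        try:
            vals = self.data["intensity"].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric intensity values: {exc}") from exc
        if not np.all(np.isfinite(vals)):
            raise ValidationError("non-finite intensity values present")
        if np.any(vals < 0):
            bad = self.data.index[vals < 0][0]
            raise ValidationError(f"negative intensity at row {bad}")
        keys = ["protein_id", "condition", "replicate", "channel"]
        if self.is_psm_level:
            keys.append("psm_id")
        dup = self.data.duplicated(subset=keys)
        if dup.any():
            offender = self.data.loc[dup.idxmax(), keys].tolist()
            raise ValidationError(f"duplicate key {offender} in reporter table")
        if "temperature_c" not in self.data.columns:
            self.data = self.data.assign(
                temperature_c=self.data["channel"].map(self.gradient.to_mapping())
            )

    @property
    def is_psm_level(self) -> bool:
        return "psm_id" in self.data.columns

    @property
    def n_proteins(self) -> int:
        return self.data["protein_id"].nunique()

    def write(self, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
        write_reporter_table(self, path, metadata=metadata)


def _header_lines(metadata: Mapping[str, object] | None) -> list[str]:
    from . import __version__

    lines = [f"# cetsakit {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: Mapping[str, object] | None = None, sep: str = "\t",
                index: bool = False) -> None:
    """Write a table with ``# key=value`` header comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(metadata):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=index)


def write_reporter_table(dataset: ReporterDataset, path: str | Path,
                         metadata: Mapping[str, object] | None = None) -> None:
    cols = [c for c in LONG_COLUMNS if c in dataset.data.columns]
    if dataset.is_psm_level:
        cols.insert(1, "psm_id")
    write_table(dataset.data[cols], path, metadata=metadata)


def read_reporter_table(path: str | Path, schema: str = "long",
                        gradient: TemperatureGradient | None = None) -> ReporterDataset:
    """Read a reporter-ion table.

    ``schema="long"`` expects the tab-separated long layout written by
    :func:`write_reporter_table`; ``schema="wide"`` expects a CSV with one
    column per channel plus ``protein_id``/``condition``/``replicate`` id
    columns, which is melted to long form.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input table not found: {path}")
    if schema == "long":
        df = pd.read_csv(path, sep="\t", comment="#")
        if gradient is None:
            if "temperature_c" not in df.columns:
                raise ValidationError("long table without temperature_c needs an explicit gradient")
            pairs = (df[["channel", "temperature_c"]].drop_duplicates()
                     .sort_values("temperature_c"))
            gradient = TemperatureGradient(
                tuple(pairs["channel"].astype(str)), tuple(pairs["temperature_c"].astype(float)))
        df["channel"] = df["channel"].astype(str)
    elif schema == "wide":
        if gradient is None:
            raise ValidationError("wide tables require an explicit gradient")
        df = pd.read_csv(path, comment="#")
        id_cols = ["protein_id", "condition", "replicate"]
        missing = [c for c in id_cols if c not in df.columns]
        if missing:
            raise ValidationError(f"wide table is missing id columns: {missing}")
        absent = [c for c in gradient.channels if c not in df.columns]
        if absent:
            raise ValidationError(f"wide table is missing channel columns: {absent}")
        df = df.melt(id_vars=id_cols, value_vars=list(gradient.channels),
                     var_name="channel", value_name="intensity")
    else:
        raise ValidationError(f"unknown schema {schema!r} (expected 'long' or 'wide')")
    return ReporterDataset(df, gradient)


# ---------------------------------------------------------------------------
# Isotope impurity correction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpurityMatrix:
    """Channel cross-contamination matrix.

    Entry (i, j) is the fraction of channel j's true signal that is
    observed in channel i; columns therefore sum to at most 1 (signal
    falling outside the plex is lost).
    """

    values: np.ndarray
    channels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("impurity matrix must be square")
        if np.any(a < 0):
            raise ValidationError("impurity matrix entries must be non-negative")
        colsums = a.sum(axis=0)
        if np.any(colsums > 1 + 1e-6):
            raise ValidationError("impurity matrix columns must sum to <= 1")
        diag = np.diag(a)
        off = colsums - diag
        if np.any(diag < off - 1e-9):
            raise ValidationError("impurity matrix must be diagonally dominant by column")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def identity(cls, channels: Iterable[str] | int) -> "ImpurityMatrix":
        if isinstance(channels, int):
            n, labels = channels, ()
        else:
            labels = tuple(channels)
            n = len(labels)
        return cls(np.eye(n), labels)

    @classmethod
    def from_vendor_csv(cls, path: str | Path,
                        channels: Iterable[str] | None = None) -> "ImpurityMatrix":
        """Expand a vendor-style -2/-1/+1/+2 percentage table to a square matrix.

        The CSV needs a ``channel`` column plus ``minus2``/``minus1``/
        ``plus1``/``plus2`` columns giving, in percent, the fraction of each
        channel's signal that leaks into the channel 2 below, 1 below,
        1 above and 2 above (in gradient order).  Leakage beyond the plex
        boundary is lost, so those columns sum below 100.
        """
        table = pd.read_csv(path, comment="#")
        if "channel" not in table.columns:
            raise ValidationError("vendor impurity CSV needs a 'channel' column")
        table["channel"] = table["channel"].astype(str)
        labels = tuple(channels) if channels is not None else tuple(table["channel"])
        order = {c: i for i, c in enumerate(labels)}
        missing = [c for c in labels if c not in set(table["channel"])]
        if missing:
            raise ValidationError(f"vendor impurity CSV is missing channels: {missing}")
        n = len(labels)
        a = np.zeros((n, n))
        offsets = {"minus2": -2, "minus1": -1, "plus1": 1, "plus2": 2}
        for _, row in table.iterrows():
            if row["channel"] not in order:
                continue
            j = order[row["channel"]]
            total = 0.0
            for col, off in offsets.items():
                frac = float(row.get(col, 0.0) or 0.0) / 100.0
                total += frac
                i = j + off
                if 0 <= i < n:
                    a[i, j] = frac
            a[j, j] = 1.0 - total
        return cls(a, labels)


@dataclass
class CorrectionResult:
    """Impurity-corrected channel intensities with clipping diagnostics."""

    values: np.ndarray
    clipped: np.ndarray
    warning: bool


def correct_isotope_impurities(observed: np.ndarray, impurity: ImpurityMatrix,
                               tol: float = 1e-6) -> CorrectionResult:
    """Solve ``impurity @ corrected = observed`` for the true channel signal.

    Small negative solutions (above ``-tol`` relative to the total signal)
    are clipped to zero and flagged; larger negative components are kept
    and raise the ``warning`` flag.
    """
    b = np.asarray(observed, dtype=float)
    a = impurity.values
    if b.shape[-1] != a.shape[0]:
        raise ValidationError(
            f"observed vector has {b.shape[-1]} channels, matrix expects {a.shape[0]}")
    try:
        x = np.linalg.solve(a, b.T).T if b.ndim > 1 else np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"impurity matrix is singular: {exc}") from exc
    atol = tol * max(1.0, float(np.sum(np.abs(b))))
    small_neg = (x < 0) & (x > -atol)
    large_neg = x <= -atol
    x = np.where(small_neg, 0.0, x)
    if np.any(large_neg):
        logger.warning("impurity correction produced %d large negative components",
                       int(np.sum(large_neg)))
    return CorrectionResult(x, small_neg, bool(np.any(large_neg)))


def correct_dataset(dataset: ReporterDataset, impurity: ImpurityMatrix) -> ReporterDataset:
    """Apply isotope impurity correction to every measurement vector."""
    if impurity.n != dataset.gradient.n:
        raise ValidationError("impurity matrix size does not match the gradient")
    keys = ["protein_id", "condition", "replicate"]
    if dataset.is_psm_level:
        keys.append("psm_id")
    wide = dataset.data.pivot_table(index=keys, columns="channel",
                                    values="intensity", aggfunc="first")
    wide = wide.reindex(columns=list(dataset.gradient.channels))
    result = correct_isotope_impurities(wide.to_numpy(), impurity)
    corrected = pd.DataFrame(np.clip(result.values, 0.0, None),
                             index=wide.index, columns=wide.columns)
    long = (corrected.reset_index()
            .melt(id_vars=keys, var_name="channel", value_name="intensity"))
    long = long.dropna(subset=["intensity"]).reset_index(drop=True)
    return ReporterDataset(long, dataset.gradient)


# ---------------------------------------------------------------------------
# PSM -> protein aggregation
# ---------------------------------------------------------------------------

def aggregate_psms_to_protein(dataset: ReporterDataset, n_bootstrap: int = 1000,
                              seed: int | None = None) -> pd.DataFrame:
    """Sum PSM reporter intensities to protein level, with bootstrap intervals.

    The point estimate is the channel-wise sum over a protein's PSMs within
    each (condition, replicate).  When ``n_bootstrap`` > 0, PSMs are
    resampled with replacement and re-summed; the 2.5/97.5 percentile
    interval and the resampling standard deviation are reported per channel.
    """
    if not dataset.is_psm_level:
        raise ValidationError("dataset has no psm_id column; nothing to aggregate")
    if n_bootstrap < 0:
        raise ValidationError("n_bootstrap must be >= 0")
    rng = np.random.default_rng(seed)
    channels = list(dataset.gradient.channels)
    temp_map = dataset.gradient.to_mapping()
    rows = []
    dropped = 0
    grouped = dataset.data.groupby(["protein_id", "condition", "replicate"], sort=True)
    for (pid, cond, rep), grp in grouped:
        mat = grp.pivot(index="psm_id", columns="channel", values="intensity")
        mat = mat.reindex(columns=channels)
        if mat.isna().to_numpy().any():
            dropped += 1
            logger.warning("dropping %s/%s/rep%s: incomplete channel coverage", pid, cond, rep)
            continue
        v = mat.to_numpy()
        n_psm = v.shape[0]
        sums = v.sum(axis=0)
        if n_bootstrap > 0:
            idx = rng.integers(0, n_psm, size=(n_bootstrap, n_psm))
            resampled = v[idx].sum(axis=1)
            sd = resampled.std(axis=0, ddof=1)
            lo, hi = np.percentile(resampled, [2.5, 97.5], axis=0)
        else:
            sd = lo = hi = np.full(len(channels), np.nan)
        for k, ch in enumerate(channels):
            rows.append((pid, cond, rep, ch, temp_map[ch], sums[k], n_psm,
                         sd[k], lo[k], hi[k]))
    if dropped:
        logger.warning("aggregation dropped %d incomplete protein curves", dropped)
    return pd.DataFrame(rows, columns=["protein_id", "condition", "replicate", "channel",
                                       "temperature_c", "intensity", "n_psms",
                                       "boot_sd", "boot_lo", "boot_hi"])


def as_reporter_dataset(quant: pd.DataFrame, gradient: TemperatureGradient) -> ReporterDataset:
    """Wrap an aggregated protein quantification table as a ReporterDataset."""
    cols = [c for c in LONG_COLUMNS if c in quant.columns]
    return ReporterDataset(quant[cols].copy(), gradient)
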