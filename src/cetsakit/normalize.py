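"""Soluble-fraction normalization of melting curves.

Reporter intensities are converted to soluble fractions relative to the
lowest-temperature channel (reference = 1); log2 ratios to the reference
are recoverable as ``log2(fraction)``.  An optional affine baseline
correction rescales each curve against the signal remaining at the
highest temperature, which is how the 0-1 heatmap display is produced.
Fitting normally runs on uncorrected fractions: the sigmoid's plateau
parameter absorbs the high-temperature baseline, and correcting twice
would distort it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import CurveInvalidError, NotCorrectableError, ValidationError
from .io_tmt import ReporterDataset, TemperatureGradient

logger = logging.getLogger(__name__)


@dataclass(eq=False)
class MeltCurve:
    """One protein x condition x replicate soluble-fraction curve."""

    protein_id: str
    condition: str
    replicate: int
    temperatures: np.ndarray
    fractions: np.ndarray
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.temperatures.shape != self.fractions.shape:
            raise ValidationError("temperatures and fractions differ in length")
        if not np.all(np.isfinite(self.fractions)):
            raise ValidationError("non-finite fraction values")
        if np.any(self.fractions < 0):
            raise ValidationError("negative soluble fractions")

    @property
    def n(self) -> int:
        return self.temperatures.size

    @property
    def log2_ratios(self) -> np.ndarray:
        """log2 of each fraction relative to the reference channel."""
        with np.errstate(divide="ignore"):
            return np.log2(self.fractions)

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.protein_id, self.condition, self.replicate)


def fraction_soluble(intensities: np.ndarray, gradient: TemperatureGradient,
                     protein_id: str = "", condition: str = "",
                     replicate: int = 0) -> MeltCurve:
    """Normalize channel intensities to the lowest-temperature reference.

    fraction(T) = I(T) / I(T_ref), so the reference point is exactly 1.
    A zero or negative reference intensity makes the curve undefined.
    """
    values = np.asarray(intensities, dtype=float)
    if values.size != gradient.n:
        raise ValidationError(
            f"expected {gradient.n} intensities, got {values.size}")
    ref = values[0]
    if not np.isfinite(ref) or ref <= 0:
        raise CurveInvalidError(
            f"reference intensity at {gradient.temperatures[0]} degC is {ref}; "
            "curve cannot be normalized")
    return MeltCurve(protein_id, condition, int(replicate),
                     np.asarray(gradient.temperatures, dtype=float), values / ref)


def baseline_correct(curve: MeltCurve) -> MeltCurve:
    """Rescale a curve by the signal lost at the highest temperature.

    corrected(T) = (f(T) - f(T_max)) / (1 - f(T_max)), so the two extreme
    points span exactly [0, 1].  Non-melters (f(T_max) >= 1) cannot be
    corrected.  The operation is idempotent: a corrected curve has
    f(T_max) = 0 and passes through unchanged.
    """
    f_max = curve.fractions[-1]
    if f_max >= 1.0:
        raise NotCorrectableError(
            f"{curve.protein_id}: fraction at the highest temperature is {f_max:.3g} >= 1")
    corrected = (curve.fractions - f_max) / (1.0 - f_max)
    return replace(curve, fractions=corrected, baseline_corrected=True)


def curves_from_dataset(dataset: ReporterDataset,
                        apply_baseline: bool = False) -> list[MeltCurve]:
    """Build one normalized curve per (protein, condition, replicate).

    Curves with missing channels or a non-positive reference intensity are
    dropped (no imputation) and counted in a log warning.  When
    ``apply_baseline`` is set, curves that cannot be baseline-corrected
    are kept uncorrected.
    """
    gradient = dataset.gradient
    wide = dataset.data.pivot_table(index=["protein_id", "condition", "replicate"],
                                    columns="channel", values="intensity",
                                    aggfunc="sum")
    wide = wide.reindex(columns=list(gradient.channels))
    values = wide.to_numpy()
    complete = ~np.isnan(values).any(axis=1)
    ref_ok = values[:, 0] > 0
    n_incomplete = int(np.sum(~complete))
    n_bad_ref = int(np.sum(complete & ~ref_ok))
    if n_incomplete:
        logger.warning("dropped %d curves with missing channels", n_incomplete)
    if n_bad_ref:
        logger.warning("dropped %d curves with non-positive reference intensity", n_bad_ref)
    curves: list[MeltCurve] = []
    temps = np.asarray(gradient.temperatures, dtype=float)
    for (pid, cond, rep), row, ok in zip(wide.index, values, complete & ref_ok):
        if not ok:
            continue
        curve = MeltCurve(str(pid), str(cond), int(rep), temps, row / row[0])
        if apply_baseline:
            try:
                curve = baseline_correct(curve)
            except NotCorrectableError:
                logger.debug("%s/%s/rep%s kept uncorrected (non-melter)", pid, cond, rep)
        curves.append(curve)
    return curves


def melt_heatmap_matrix(curves: list[MeltCurve], clip: bool = True,
                        tm_by_protein: dict[str, float] | None = None) -> pd.DataFrame:
    """Replicate-averaged protein x temperature matrix for heatmap display.

    Values are clamped to [0, 1] when ``clip`` is set, matching the 0-1
    percentage display; rows can be ordered by fitted Tm via
    ``tm_by_protein``.  All curves must share one gradient.
    """
    if not curves:
        return pd.DataFrame()
    temps = curves[0].temperatures
    for c in curves:
        if c.temperatures.shape != temps.shape or not np.array_equal(c.temperatures, temps):
            raise ValidationError("curves with mixed temperature gradients")
    records = {}
    for c in curves:
        records.setdefault((c.protein_id, c.condition), []).append(c.fractions)
    rows = {key: np.mean(np.vstack(stack), axis=0) for key, stack in records.items()}
    conditions = {key[1] for key in rows}
    if len(conditions) > 1:
        index = pd.MultiIndex.from_tuples(rows.keys(), names=["protein_id", "condition"])
    else:
        index = pd.Index([key[0] for key in rows], name="protein_id")
    matrix = pd.DataFrame(np.vstack(list(rows.values())), index=index,
                          columns=[f"{t:g}" for t in temps])
    if clip:
        matrix = matrix.clip(0.0, 1.0)
    if tm_by_protein is not None:
        key = (matrix.index.get_level_values("protein_id")
               if isinstance(matrix.index, pd.MultiIndex) else matrix.index)
        order = np.argsort([tm_by_protein.get(p, np.inf) for p in key], kind="stable")
        matrix = matrix.iloc[order]
    return matrix
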