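"""Seeded synthetic CETSA-MS datasets with known ground truth.

In a thermal shift experiment, cells are heated across a temperature
gradient and the fraction of each protein remaining soluble decays
sigmoidally with temperature.  Drug binding stabilizes the target, moving
its melting midpoint to higher temperatures.  This generator emulates
exactly that readout: per-protein three-parameter logistic melting of the
soluble fraction over the gradient, a planted subset of stabilized
targets with a known positive Tm shift, multiplicative reporter-ion
noise, replicate runs, and optional channel cross-contamination by a
known impurity matrix.  Every dataset carries its true parameters so the
downstream fitting and hit-calling stages can be scored against a known
answer.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .io_tmt import (
    DEFAULT_TEMPERATURES,
    ImpurityMatrix,
    ReporterDataset,
    TemperatureGradient,
)
from .normalize import MeltCurve


@dataclass(frozen=True)
class MeltParams:
    """Parameters of the Boltzmann (three-parameter logistic) melt model.

    ``midpoint`` (degC) is the inflection temperature, ``slope`` (degC) the
    scale of the transition, and ``plateau`` the non-denaturing residual
    fraction remaining at high temperature.
    """

    midpoint: float
    slope: float
    plateau: float = 0.0

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ParameterError(f"slope must be > 0, got {self.slope}")
        if not (0.0 <= self.plateau < 1.0):
            raise ParameterError(f"plateau must be in [0, 1), got {self.plateau}")


def boltzmann(temperature, midpoint, slope, plateau):
    """Raw Boltzmann sigmoid f(T) = p + (1 - p) / (1 + exp((T - m)/s)).

    Array-friendly and unvalidated; broadcasting over any argument is
    supported.  Use :func:`melt_fraction` for the checked scalar-parameter
    form.
    """
    t = np.asarray(temperature, dtype=float)
    with np.errstate(over="ignore"):
        return plateau + (1.0 - plateau) / (1.0 + np.exp((t - midpoint) / slope))


def melt_fraction(temperature, params: MeltParams):
    """Soluble fraction predicted by the melt model at ``temperature``.

    Strictly decreasing in T; tends to 1 as T -> -inf and to the plateau
    as T -> +inf, with f(midpoint) = plateau + (1 - plateau)/2.
    """
    out = boltzmann(temperature, params.midpoint, params.slope, params.plateau)
    if np.isscalar(temperature):
        return float(out)
    return out


@dataclass
class SyntheticSpec:
    """Design of a synthetic CETSA experiment.

    Defaults encode the study conditions this generator emulates: 500
    proteins over the ten-temperature gradient in triplicate, 10% of
    proteins planted as drug targets with a +10 degC stabilization (the
    order of the headline target's shift), 5% multiplicative reporter
    noise, and a small replicate-to-replicate midpoint wobble.
    """

    n_proteins: int = 500
    n_replicates: int = 3
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    target_fraction: float = 0.1
    true_delta_tm_mean: float = 10.0
    true_delta_tm_sd: float = 0.0
    vehicle_tm_mean: float = 50.0
    vehicle_tm_sd: float = 4.0
    plateau_range: tuple[float, float] = (0.0, 0.3)
    slope_range: tuple[float, float] = (0.8, 4.0)
    replicate_tm_sd: float = 0.3
    noise_cv: float = 0.05
    abundance_logmean: float = 13.8
    abundance_logsd: float = 1.0
    psm_level: bool = False
    psms_per_protein_mean: float = 5.0
    impurity_matrix: ImpurityMatrix | None = None
    conditions: tuple[str, str] = ("vehicle", "treated")
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins <= 0 or self.n_replicates <= 0:
            raise ValidationError("n_proteins and n_replicates must be positive")
        if not (0.0 <= self.target_fraction <= 1.0):
            raise ValidationError("target_fraction must be in [0, 1]")
        if self.noise_cv < 0 or self.replicate_tm_sd < 0 or self.true_delta_tm_sd < 0:
            raise ValidationError("noise magnitudes must be non-negative")
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.size < 4 or not np.all(np.diff(temps) > 0):
            raise ValidationError("temperatures must be strictly increasing, length >= 4")
        for name, (lo, hi) in (("plateau_range", self.plateau_range),
                               ("slope_range", self.slope_range)):
            if lo > hi:
                raise ValidationError(f"{name} is inverted")
        if not (0.0 <= self.plateau_range[0] and self.plateau_range[1] < 1.0):
            raise ValidationError("plateau_range must lie in [0, 1)")
        if self.slope_range[0] <= 0:
            raise ValidationError("slopes must be positive")
        if self.psms_per_protein_mean <= 0:
            raise ValidationError("psms_per_protein_mean must be positive")
        if self.impurity_matrix is not None and self.impurity_matrix.n != temps.size:
            raise ValidationError("impurity matrix size does not match the gradient")


def mix_impurities(true_channel_intensities: np.ndarray,
                   impurity: ImpurityMatrix | np.ndarray) -> np.ndarray:
    """Forward channel cross-contamination: observed = impurity @ true.

    Inverse of the isotope-impurity correction; when the matrix columns sum
    to 1 the total signal is conserved.
    """
    a = impurity.values if isinstance(impurity, ImpurityMatrix) else np.asarray(impurity, float)
    x = np.asarray(true_channel_intensities, dtype=float)
    if x.shape[-1] != a.shape[1]:
        raise ValidationError(
            f"vector has {x.shape[-1]} channels, matrix expects {a.shape[1]}")
    return x @ a.T


def _long_frame(ids: np.ndarray, condition: str, replicate: int,
                gradient: TemperatureGradient, intensities: np.ndarray,
                psm_ids: np.ndarray | None = None) -> pd.DataFrame:
    n_rows, n_t = intensities.shape
    frame = {
        "protein_id": np.repeat(ids, n_t),
        "condition": condition,
        "replicate": replicate,
        "channel": np.tile(np.asarray(gradient.channels), n_rows),
        "temperature_c": np.tile(np.asarray(gradient.temperatures, float), n_rows),
        "intensity": intensities.ravel(),
    }
    df = pd.DataFrame(frame)
    if psm_ids is not None:
        df.insert(1, "psm_id", np.repeat(psm_ids, n_t))
    return df


def generate_cetsa_dataset(spec: SyntheticSpec) -> tuple[ReporterDataset, pd.DataFrame]:
    """Generate a seeded CETSA dataset and its ground-truth table.

    Intensities are abundance x melt_fraction x lognormal noise (unit-mean,
    CV = ``noise_cv``), optionally mixed through the impurity matrix.
    Non-targets have a true Tm shift of exactly 0 and identical parameters
    in both arms; slope and plateau are shared between arms, so the true
    shift equals the planted midpoint shift.  Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    temps = np.asarray(spec.temperatures, dtype=float)
    gradient = TemperatureGradient.for_temperatures(spec.temperatures)
    n = spec.n_proteins
    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    n_targets = int(round(n * spec.target_fraction))
    is_target = np.zeros(n, dtype=bool)
    if n_targets:
        is_target[rng.choice(n, size=n_targets, replace=False)] = True
    mid_vehicle = rng.normal(spec.vehicle_tm_mean, spec.vehicle_tm_sd, n)
    slope = rng.uniform(spec.slope_range[0], spec.slope_range[1], n)
    plateau = rng.uniform(spec.plateau_range[0], spec.plateau_range[1], n)
    shift = rng.normal(spec.true_delta_tm_mean, spec.true_delta_tm_sd, n)
    delta = np.where(is_target, shift, 0.0)
    mid_treated = mid_vehicle + delta

    truth = pd.DataFrame({
        "protein_id": ids,
        "midpoint_vehicle": mid_vehicle,
        "midpoint_treated": mid_treated,
        "slope": slope,
        "plateau": plateau,
        "true_delta_tm": delta,
        "is_target": is_target,
    })

    sigma = math.sqrt(math.log1p(spec.noise_cv ** 2))
    if spec.psm_level:
        n_psms = 1 + rng.poisson(max(spec.psms_per_protein_mean - 1.0, 0.0), n)
        protein_of_psm = np.repeat(np.arange(n), n_psms)
        psm_ids = np.array([f"{ids[i]}.psm{k + 1}"
                            for i in range(n)
                            for k in range(n_psms[i])])
        psm_logmean = spec.abundance_logmean - math.log(spec.psms_per_protein_mean)

    frames = []
    for condition, base_mid in zip(spec.conditions, (mid_vehicle, mid_treated)):
        for rep in range(1, spec.n_replicates + 1):
            mid_rep = base_mid + rng.normal(0.0, spec.replicate_tm_sd, n)
            fractions = boltzmann(temps[None, :], mid_rep[:, None],
                                  slope[:, None], plateau[:, None])
            if spec.psm_level:
                rows = fractions[protein_of_psm]
                abundance = rng.lognormal(psm_logmean, spec.abundance_logsd,
                                          rows.shape[0])
                noise = (rng.lognormal(-0.5 * sigma ** 2, sigma, rows.shape)
                         if sigma > 0 else 1.0)
                intensity = abundance[:, None] * rows * noise
                if spec.impurity_matrix is not None:
                    intensity = mix_impurities(intensity, spec.impurity_matrix)
                frames.append(_long_frame(ids[protein_of_psm], condition, rep,
                                          gradient, intensity, psm_ids=psm_ids))
            else:
                abundance = rng.lognormal(spec.abundance_logmean, spec.abundance_logsd, n)
                noise = (rng.lognormal(-0.5 * sigma ** 2, sigma, fractions.shape)
                         if sigma > 0 else 1.0)
                intensity = abundance[:, None] * fractions * noise
                if spec.impurity_matrix is not None:
                    intensity = mix_impurities(intensity, spec.impurity_matrix)
                frames.append(_long_frame(ids, condition, rep, gradient, intensity))
    data = pd.concat(frames, ignore_index=True)
    return ReporterDataset(data, gradient), truth


def sample_curves(n: int, seed: int, temperatures=DEFAULT_TEMPERATURES,
                  noise_cv: float = 0.0,
                  midpoint_range: tuple[float, float] = (40.0, 65.0),
                  slope_range: tuple[float, float] = (0.8, 6.0),
                  plateau_range: tuple[float, float] = (0.0, 0.4),
                  ) -> tuple[list[MeltCurve], list[MeltParams]]:
    """Sample standalone model curves spanning the parameter ranges.

    Returns noise-free (or multiplicatively noised) Boltzmann curves as
    MeltCurve objects together with their true parameters — the test bed
    for fitter validation, independent of the intensity/normalization path.
    """
    rng = np.random.default_rng(seed)
    temps = np.asarray(temperatures, dtype=float)
    sigma = math.sqrt(math.log1p(noise_cv ** 2)) if noise_cv > 0 else 0.0
    curves, params = [], []
    for i in range(n):
        p = MeltParams(rng.uniform(*midpoint_range), rng.uniform(*slope_range),
                       rng.uniform(*plateau_range))
        f = melt_fraction(temps, p)
        if sigma > 0:
            f = f * rng.lognormal(-0.5 * sigma ** 2, sigma, temps.size)
        curves.append(MeltCurve(f"S{i:04d}", "synthetic", 1, temps, f))
        params.append(p)
    return curves, params


def generate_global_proteome(n_proteins: int = 1000, n_control: int = 3,
                             n_treated: int = 3, de_fraction: float = 0.05,
                             effect_log2: float = 1.0,
                             spectra_per_protein_mean: float = 4.0,
                             spectrum_noise_sd: float = 0.3,
                             abundance_logmean: float = 13.8,
                             abundance_logsd: float = 1.0,
                             seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spectrum-level TMT table for the global differential-proteome path.

    One multiplexed run with ``n_control`` control and ``n_treated``
    treated channels; a ``de_fraction`` of proteins get a +/- ``effect_log2``
    treatment effect.  Spectrum noise is additive on the log2 scale.
    Returns the long spectrum table and the per-protein truth.
    """
    if n_proteins <= 0 or n_control < 2 or n_treated < 2:
        raise ValidationError("need >= 1 protein and >= 2 channels per group")
    rng = np.random.default_rng(seed)
    channels = ([f"ctrl{i+1}" for i in range(n_control)]
                + [f"trt{i+1}" for i in range(n_treated)])
    treated_mask = np.array([c.startswith("trt") for c in channels])
    ids = np.array([f"P{i:05d}" for i in range(1, n_proteins + 1)])
    n_de = int(round(n_proteins * de_fraction))
    is_de = np.zeros(n_proteins, dtype=bool)
    if n_de:
        is_de[rng.choice(n_proteins, n_de, replace=False)] = True
    direction = np.where(rng.random(n_proteins) < 0.5, -1.0, 1.0)
    effect = np.where(is_de, direction * effect_log2, 0.0)

    n_spectra = 1 + rng.poisson(max(spectra_per_protein_mean - 1.0, 0.0), n_proteins)
    protein_of = np.repeat(np.arange(n_proteins), n_spectra)
    spectrum_ids = np.array([f"spec{j:06d}" for j in range(protein_of.size)])
    log2_abund = rng.normal(abundance_logmean / math.log(2),
                            abundance_logsd / math.log(2), protein_of.size)
    log2_int = (log2_abund[:, None]
                + effect[protein_of][:, None] * treated_mask[None, :]
                + rng.normal(0.0, spectrum_noise_sd, (protein_of.size, len(channels))))
    intensity = np.exp2(log2_int)

    table = pd.DataFrame({
        "spectrum_id": np.repeat(spectrum_ids, len(channels)),
        "protein_id": np.repeat(ids[protein_of], len(channels)),
        "channel": np.tile(channels, protein_of.size),
        "intensity": intensity.ravel(),
    })
    truth = pd.DataFrame({"protein_id": ids, "true_log2_effect": effect, "is_de": is_de})
    return table, truth
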