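"""End-to-end pipelines and run configuration.

Two pipelines chain the library stages: the CETSA shift-calling pipeline
(read/simulate -> impurity-correct -> aggregate -> normalize -> fit ->
shift-call -> heatmap/density) and the global differential-proteome
pipeline (ratios -> weights -> aggregation -> z-scores -> t-tests ->
enrichment).  Every output table carries the manifest hash of the run
configuration in its header, and runs are deterministic for a fixed
config and seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import typing
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffprot import (
    aggregate_weighted,
    estimate_inverse_variance_weights,
    hypergeometric_enrichment,
    read_gmt,
    spectrum_ratio_table,
    standardize_zscores,
    ttest_proteins,
)
from .errors import NumericalError, ValidationError
from .fit import GridSpec, fit_dataset
from .io_tmt import (
    ImpurityMatrix,
    ReporterDataset,
    TemperatureGradient,
    aggregate_psms_to_protein,
    as_reporter_dataset,
    correct_dataset,
    read_reporter_table,
    write_table,
)
from .normalize import curves_from_dataset, melt_heatmap_matrix
from .shifts import HitThresholds, call_hits, shift_results, tm_shift_density
from .synthetic import SyntheticSpec, generate_cetsa_dataset, generate_global_proteome

logger = logging.getLogger(__name__)


def _from_dict(cls, data):
    """Build a (possibly nested) dataclass from a mapping, rejecting unknown keys."""
    if data is None:
        return None
    if isinstance(data, cls):
        return data
    if not isinstance(data, dict):
        raise ValidationError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for key, value in data.items():
        hint = hints.get(key)
        if (isinstance(hint, type) and dataclasses.is_dataclass(hint)
                and isinstance(value, dict)):
            value = _from_dict(hint, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


@dataclass
class DiffConfig:
    """Channel groups and options for the global-proteome comparison."""

    control_channels: tuple[str, ...] = ("ctrl1", "ctrl2", "ctrl3")
    treated_channels: tuple[str, ...] = ("trt1", "trt2", "trt3")
    weighting: str = "inverse_variance"  # or "uniform"
    welch: bool = False
    significance: float = 0.05
    gmt: str | None = None
    # synthetic input (used when no input table is given)
    n_proteins: int = 1000
    de_fraction: float = 0.05
    effect_log2: float = 1.0
    spectra_per_protein_mean: float = 4.0
    spectrum_noise_sd: float = 0.3

    def validate(self) -> None:
        if self.weighting not in ("uniform", "inverse_variance"):
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        if not (0 < self.significance < 1):
            raise ValidationError("significance must be in (0, 1)")
        if set(self.control_channels) & set(self.treated_channels):
            raise ValidationError("control and treated channel groups overlap")


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    input_table: str | None = None
    input_schema: str = "long"
    gradient: dict | None = None
    impurity_csv: str | None = None
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    grid: GridSpec = field(default_factory=GridSpec)
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    diff: DiffConfig = field(default_factory=DiffConfig)
    baseline_correct: bool = False
    clip_heatmap: bool = True
    shift_test: str = "t"
    n_bootstrap: int = 1000
    density_bandwidth: str | float = "auto"
    write_plots: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def manifest(self) -> dict:
        from . import __version__

        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: encode(getattr(obj, f.name)) for f in fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [encode(v) for v in obj]
            if isinstance(obj, ImpurityMatrix):
                return {"channels": list(obj.channels), "values": obj.values.tolist()}
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        manifest = encode(self)
        manifest["version"] = __version__
        return manifest

    def manifest_hash(self) -> str:
        manifest = self.manifest()
        manifest.pop("out_dir", None)  # where results land is not an analysis parameter
        payload = json.dumps(manifest, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _resolve_gradient(config: RunConfig) -> TemperatureGradient | None:
    if config.gradient is None:
        return None
    items = sorted(config.gradient.items(), key=lambda kv: float(kv[1]))
    return TemperatureGradient(tuple(str(k) for k, _ in items),
                               tuple(float(v) for _, v in items))


def run_cetsa_pipeline(config: RunConfig) -> dict:
    """Execute the CETSA shift-calling pipeline and write its result bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = config.manifest_hash()
    meta = {"manifest_hash": tag, "seed": config.seed}

    if config.input_table is not None:
        dataset = read_reporter_table(config.input_table, schema=config.input_schema,
                                      gradient=_resolve_gradient(config))
        truth = None
    else:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        dataset, truth = generate_cetsa_dataset(spec)
        write_table(truth, out_dir / "ground_truth.tsv", metadata=meta)

    if config.impurity_csv is not None:
        impurity = ImpurityMatrix.from_vendor_csv(config.impurity_csv,
                                                  channels=dataset.gradient.channels)
        dataset = correct_dataset(dataset, impurity)
    if dataset.is_psm_level:
        quant = aggregate_psms_to_protein(dataset, n_bootstrap=config.n_bootstrap,
                                          seed=config.seed)
        write_table(quant, out_dir / "protein_quant.tsv", metadata=meta)
        dataset = as_reporter_dataset(quant, dataset.gradient)

    curves = curves_from_dataset(dataset, apply_baseline=config.baseline_correct)
    if not curves:
        logger.warning("no valid melting curves; writing empty outputs")
        empty = pd.DataFrame()
        for name in ("fits.tsv", "hits.tsv", "heatmap.tsv"):
            write_table(empty, out_dir / name, metadata=meta)
        _write_manifest(config, out_dir)
        return {"fits": empty, "results": empty, "hits": empty, "heatmap": empty,
                "density": None, "truth": truth, "out_dir": out_dir}

    fits = fit_dataset(curves, config.grid)
    vehicle, treated = config.synthetic.conditions
    results = shift_results(fits, vehicle=vehicle, treated=treated,
                            method=config.shift_test)
    hits = call_hits(results, config.thresholds)

    tm_map = (fits[fits["tm_defined"]].groupby("protein_id")["tm"].mean().to_dict())
    heatmap = melt_heatmap_matrix(curves, clip=config.clip_heatmap, tm_by_protein=tm_map)
    shifts_finite = hits["mean_delta_tm"].dropna()
    density = (tm_shift_density(shifts_finite, bandwidth=config.density_bandwidth)
               if shifts_finite.size >= 2 else None)

    threshold_meta = dict(meta, r_threshold=config.thresholds.r_threshold,
                          p_threshold=config.thresholds.p_threshold)
    write_table(fits, out_dir / "fits.tsv", metadata=meta)
    write_table(hits, out_dir / "hits.tsv", metadata=threshold_meta)
    write_table(heatmap.reset_index(), out_dir / "heatmap.tsv", metadata=meta)
    if density is not None:
        density_df = pd.DataFrame({"delta_tm": density.grid, "density": density.density})
        write_table(density_df, out_dir / "density.tsv",
                    metadata=dict(meta, bandwidth=density.bandwidth))
    if config.write_plots:
        from . import plots
        plots.plot_heatmap(heatmap, out_dir / "heatmap.png")
        if density is not None:
            plots.plot_density(density, out_dir / "density.png")
    _write_manifest(config, out_dir)
    return {"fits": fits, "results": results, "hits": hits, "heatmap": heatmap,
            "density": density, "truth": truth, "out_dir": out_dir}


def run_diffprot_pipeline(config: RunConfig) -> dict:
    """Execute the global differential-proteome pipeline."""
    diff = config.diff
    diff.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"manifest_hash": config.manifest_hash(), "seed": config.seed}

    if config.input_table is not None:
        spectra = pd.read_csv(config.input_table, sep="\t", comment="#")
        truth = None
    else:
        spectra, truth = generate_global_proteome(
            n_proteins=diff.n_proteins, de_fraction=diff.de_fraction,
            effect_log2=diff.effect_log2,
            spectra_per_protein_mean=diff.spectra_per_protein_mean,
            spectrum_noise_sd=diff.spectrum_noise_sd,
            n_control=len(diff.control_channels), n_treated=len(diff.treated_channels),
            seed=config.seed)
        write_table(truth, out_dir / "diff_ground_truth.tsv", metadata=meta)

    records = spectrum_ratio_table(spectra, diff.control_channels, include_controls=True)
    if diff.weighting == "inverse_variance":
        records = estimate_inverse_variance_weights(records)
    protein_ratios = aggregate_weighted(records)

    wide = protein_ratios.pivot(index="protein_id", columns="channel", values="log2_ratio")
    z = pd.DataFrame(index=wide.index)
    for channel in wide.columns:
        z[channel] = standardize_zscores(wide[channel].to_numpy())

    ctrl = [c for c in diff.control_channels if c in z.columns]
    trt = [c for c in diff.treated_channels if c in z.columns]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValidationError("each channel group needs >= 2 quantified channels")
    stats_rows = []
    for pid, row in z.iterrows():
        t, p = ttest_proteins(row[ctrl].to_numpy(), row[trt].to_numpy(), welch=diff.welch)
        stats_rows.append((pid, float(row[trt].mean() - row[ctrl].mean()), t, p))
    table = pd.DataFrame(stats_rows, columns=["protein_id", "z_difference", "t", "p_value"])
    from statsmodels.stats.multitest import multipletests
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table = table.sort_values("p_value", kind="stable").reset_index(drop=True)

    enrichment = None
    significant = table.loc[table["p_value"] < diff.significance, "protein_id"]
    if diff.gmt is not None:
        collection = read_gmt(diff.gmt)
        enrichment = hypergeometric_enrichment(significant, collection,
                                               universe=table["protein_id"])
        write_table(enrichment, out_dir / "enrichment.tsv", metadata=meta)

    write_table(protein_ratios, out_dir / "protein_ratios.tsv", metadata=meta)
    write_table(z.reset_index(), out_dir / "zscores.tsv", metadata=meta)
    write_table(table, out_dir / "diff_stats.tsv", metadata=meta)
    _write_manifest(config, out_dir)
    return {"ratios": protein_ratios, "zscores": z, "stats": table,
            "enrichment": enrichment, "truth": truth, "out_dir": out_dir}


def _write_manifest(config: RunConfig, out_dir: Path) -> None:
    manifest = config.manifest()
    manifest["manifest_hash"] = config.manifest_hash()
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
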