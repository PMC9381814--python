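"""Configuration-driven orchestration of the full analysis.

The end-to-end flow mirrors how such a study is analyzed: ingest or
generate per-sample mean leaf spectra, smooth them, summarize the analyte
panel, evaluate full-spectrum PLSR models, partition the wavelength axis by
reflectance CV, evaluate the two range models, vote sensitive bands within
the low range, evaluate the sensitive-band models, and pick the winning
band set per analyte. Every run writes CSV artifacts plus a JSON manifest
recording the exact configuration, seed, and a config hash, so reruns are
byte-reproducible.

A single master seed fans out through ``numpy.random.SeedSequence`` into
independent child streams for generation, voting, and evaluation, so e.g.
changing the evaluation repetition count never perturbs the generated data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import band_selection, evaluation
from .exceptions import ConfigurationError
from .plsr import fit_pls, select_components
from .preprocessing import SmoothingConfig, savgol_smooth, standardize_fit_apply
from .synthetic_data import AnalytePanelConfig, OpticsConfig, StudyConfig, generate_study
from .tables import SampleTable

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("leafchem.pipeline")


@dataclass
class GeneratorSettings:
    enabled: bool = True
    n_exp1: int = 144
    n_exp2: int = 146
    n_bands: int = 300
    wl_min: float = 400.0
    wl_max: float = 1000.0


@dataclass
class DataSettings:
    spectra_csv: str | None = None


@dataclass
class SelectionSettings:
    R: int = 100
    threshold: int = 80
    boundary_nm: float = 717.08
    mode: str = "fixed"
    a_max: int = 15
    min_bands: int = 2


@dataclass
class EvaluationSettings:
    R: int = 100
    train_frac: float = 0.7
    a_max: int = 15
    stratify_by_experiment: bool = False


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "leafchem_out"
    analytes: list | None = None           # None -> all panel analytes
    generator: GeneratorSettings = field(default_factory=GeneratorSettings)
    data: DataSettings = field(default_factory=DataSettings)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    selection: SelectionSettings = field(default_factory=SelectionSettings)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)

    def validate(self) -> "PipelineConfig":
        if self.selection.threshold >= self.selection.R:
            raise ConfigurationError("selection.threshold must be < selection.R")
        if not 0 < self.evaluation.train_frac < 1:
            raise ConfigurationError("evaluation.train_frac must be in (0, 1)")
        if self.selection.mode not in ("fixed", "dynamic"):
            raise ConfigurationError("selection.mode must be 'fixed' or 'dynamic'")
        if not self.generator.enabled and self.data.spectra_csv is None:
            raise ConfigurationError(
                "generator disabled and no data.spectra_csv given: nothing to analyze"
            )
        return self

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "generator": GeneratorSettings,
    "data": DataSettings,
    "smoothing": SmoothingConfig,
    "selection": SelectionSettings,
    "evaluation": EvaluationSettings,
}


def validate_config(path) -> PipelineConfig:
    """Read a YAML config, fill defaults, reject unknown keys, validate."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    kwargs = {}
    top_known = {"seed", "output_dir", "analytes", *_SECTIONS}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("seed", "output_dir", "analytes"):
        if key in raw:
            kwargs[key] = raw[key]
    for section, cls in _SECTIONS.items():
        sub = raw.get(section, {}) or {}
        valid = {f for f in cls.__dataclass_fields__}
        bad = set(sub) - valid
        if bad:
            raise ConfigurationError(f"unknown keys in '{section}': {sorted(bad)}")
        kwargs[section] = cls(**sub)
    return PipelineConfig(**kwargs).validate()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _load_or_generate(config: PipelineConfig, seed: int) -> SampleTable:
    if config.data.spectra_csv is not None:
        log.info("loading sample table from %s", config.data.spectra_csv)
        return SampleTable.from_csv(config.data.spectra_csv)
    g = config.generator
    study = StudyConfig(n_exp1=g.n_exp1, n_exp2=g.n_exp2, n_bands=g.n_bands,
                        wl_min=g.wl_min, wl_max=g.wl_max, seed=seed)
    log.info("generating synthetic study: %d samples x %d bands",
             study.n_samples, study.n_bands)
    return generate_study(study, AnalytePanelConfig.default(), OpticsConfig())


def _scatter_records(samples: SampleTable, analyte: str, band_set, cfg: EvaluationSettings,
                     seed: int) -> pd.DataFrame:
    """Measured-vs-predicted pairs for one representative holdout split."""
    X = samples.spectra()
    if band_set is not None:
        X = X[:, np.asarray(band_set, dtype=int)]
    y = samples.concentrations(analyte)
    n = samples.n_samples
    rng = np.random.default_rng(seed)
    n_train = int(round(cfg.train_frac * n))
    perm = rng.permutation(n)
    train, test = perm[:n_train], perm[n_train:]
    z, scaler = standardize_fit_apply(y[train])
    model = fit_pls(X[train], z, select_components(X[train], z, cfg.a_max).a_star)
    pred = scaler.invert(model.predict(X[test]))
    return pd.DataFrame({
        "analyte": analyte,
        "sample_id": samples.frame["sample_id"].to_numpy()[test],
        "experiment": samples.frame["experiment"].to_numpy()[test],
        "measured": y[test],
        "predicted": pred,
    })


@dataclass
class PipelineResult:
    config: PipelineConfig
    samples: SampleTable
    partition: band_selection.RangePartition
    frequency_tables: dict
    summaries: dict
    choices: dict
    outputs: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the report bundle to ``output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    gen_seed, vote_seed, eval_seed, scatter_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )
    outputs: dict = {}

    def _stage(name):
        log.info("stage: %s", name)

    _stage("ingest/generate")
    samples = _load_or_generate(config, gen_seed)
    analytes = config.analytes or list(samples.analytes)
    bad = [a for a in analytes if a not in samples.analytes]
    if bad:
        raise ConfigurationError(f"unknown analytes requested: {bad}")

    _stage("smooth")
    smoothed = samples.with_spectra(savgol_smooth(samples.spectra(), config.smoothing))
    outputs["samples_csv"] = out / "samples.csv"
    smoothed.to_csv(outputs["samples_csv"])

    _stage("descriptives")
    desc = evaluation.descriptive_stats(smoothed)
    outputs["descriptives_csv"] = out / "descriptives.csv"
    desc.to_csv(outputs["descriptives_csv"], index=False)

    _stage("cv-partition")
    profile = band_selection.band_cv_profile(smoothed.spectra(), smoothed.wavelengths)
    partition = band_selection.partition_bands(smoothed.wavelengths,
                                               config.selection.boundary_nm)
    cv_frame = pd.DataFrame({
        "wavelength_nm": smoothed.wavelengths,
        "mean": profile.mean, "sd": profile.sd, "cv_percent": profile.cv_percent,
        "range": np.where(smoothed.wavelengths <= config.selection.boundary_nm,
                          "low", "high"),
    })
    outputs["cv_profile_csv"] = out / "cv_profile.csv"
    cv_frame.to_csv(outputs["cv_profile_csv"], index=False)

    sel, ev = config.selection, config.evaluation
    frequency_tables, summaries, choices = {}, {}, {}
    variant_rows, optimal_rows, scatter_frames = [], [], []

    for analyte in analytes:
        _stage(f"band-voting [{analyte}]")
        freq = band_selection.vote_sensitive_bands(
            smoothed, analyte, partition.low_range, R=sel.R, threshold=sel.threshold,
            train_frac=ev.train_frac, seed=vote_seed, a_max=sel.a_max,
            min_bands=sel.min_bands, mode=sel.mode,
        )
        frequency_tables[analyte] = freq
        freq.to_csv(out / f"frequency_{analyte}.csv")

        variants = {"all_bands": None,
                    "low_range": partition.low_range,
                    "high_range": partition.high_range}
        if freq.sensitive_bands.size >= 2:
            variants["sensitive_bands"] = freq.sensitive_bands
        else:
            log.warning("%s: fewer than two voted bands; variant skipped", analyte)

        _stage(f"evaluate [{analyte}]")
        summary, choice = evaluation.compare_variants(
            smoothed, analyte, variants, R=ev.R, train_frac=ev.train_frac,
            seed=eval_seed, a_max=ev.a_max,
            stratify_by_experiment=ev.stratify_by_experiment,
        )
        summaries[analyte] = summary
        choices[analyte] = choice
        frame = summary.summary_frame()
        frame.insert(0, "analyte", analyte)
        variant_rows.append(frame)
        optimal_rows.append({"analyte": analyte, "variant": choice.variant,
                             "n_bands": choice.n_bands, **choice.means})
        scatter_frames.append(_scatter_records(
            smoothed, analyte, variants.get(choice.variant), ev, scatter_seed))

    outputs["variant_metrics_csv"] = out / "variant_metrics.csv"
    pd.concat(variant_rows, ignore_index=True).to_csv(
        outputs["variant_metrics_csv"], index=False)
    outputs["optimal_csv"] = out / "optimal.csv"
    pd.DataFrame(optimal_rows).to_csv(outputs["optimal_csv"], index=False)
    outputs["scatter_csv"] = out / "scatter.csv"
    pd.concat(scatter_frames, ignore_index=True).to_csv(
        outputs["scatter_csv"], index=False)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "n_samples": smoothed.n_samples,
        "n_bands": smoothed.n_bands,
        "analytes": analytes,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    outputs["manifest_json"] = out / "manifest.json"
    outputs["manifest_json"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %d analytes, outputs in %s", len(analytes), out)

    return PipelineResult(config=config, samples=smoothed, partition=partition,
                          frequency_tables=frequency_tables, summaries=summaries,
                          choices=choices, outputs=outputs)
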