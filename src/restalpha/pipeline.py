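"""End-to-end orchestration: simulate → preprocess → spectra → reliability → models.

A :class:`PipelineConfig` (loadable from YAML) fixes cohort sizes,
generative parameters, preprocessing thresholds, spectral settings, the
model list and MCMC settings; a single master seed makes every stage
reproducible. Outputs are diff-able TSV/JSON files plus a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import (
    MODEL_FORMULAS,
    ModelSpec,
    build_design,
    gibbs_sample,
    marginal_slopes,
    summarize,
)
from .geometry import build_default_layout, nearest_neighbors
from .preprocessing import preprocess_recording
from .reliability import reliability_report, split_half_power
from .simulate import (
    GenerativeParams,
    cohort_covariates,
    generate_alpha_table,
    generate_cohort,
    generate_recording,
    inject_artifacts,
)
from .spectral import (
    CONDITIONS,
    SpectralConfig,
    build_long_table,
    clean_epochs_band_power,
    write_table,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger("restalpha")

#: The sleep-slope moderator each model stratifies over in the slope table.
MODEL_MODERATORS = {2: None, 3: None, 4: "Eyes", 5: "ML", 6: "AP", 7: "IS"}


@dataclass
class PipelineConfig:
    mode: str = "tabular"  # "tabular" | "waveform"
    n_abstinent: int = 15
    n_non_abstinent: int = 17
    generative: dict = field(default_factory=dict)  # GenerativeParams overrides
    abs_threshold_uV: float = 100.0
    step_threshold_uV: float = 50.0
    channel_frac: float = 0.40
    segment_frac: float = 0.10
    taper_fraction: float = 0.10
    band: tuple[float, float] = (8.0, 13.0)
    log_before_band_mean: bool = True
    inject_artifacts: bool = True
    models: list[int] = field(default_factory=lambda: [3])
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    neighbors_k: int = 4
    output_dir: str = "restalpha_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tabular", "waveform"):
            raise ValueError(f"mode must be 'tabular' or 'waveform', got {self.mode!r}")
        if self.n_abstinent < 1 or self.n_non_abstinent < 1:
            raise ValueError("both group sizes must be at least 1")
        if not self.models:
            raise ValueError("config must list at least one model to fit")
        for m in self.models:
            if m not in MODEL_FORMULAS:
                raise ValueError(f"unknown model id {m}; valid: {sorted(MODEL_FORMULAS)}")
        gp_fields = {f.name for f in dataclasses.fields(GenerativeParams)}
        unknown = set(self.generative) - gp_fields
        if unknown:
            raise ValueError(f"unknown generative parameters: {sorted(unknown)}")
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be smaller than iterations")

    def generative_params(self) -> GenerativeParams:
        kw = dict(self.generative)
        kw.setdefault("seed", self.seed)
        return GenerativeParams(**kw)

    def spectral_config(self) -> SpectralConfig:
        return SpectralConfig(
            taper_fraction=self.taper_fraction,
            band=tuple(self.band),
            log_before_band_mean=self.log_before_band_mean,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d


def load_config(path) -> PipelineConfig:
    """Read a YAML config, rejecting unknown keys before any computation."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "models" in raw and not raw["models"]:
        raise ValueError("config must list at least one model to fit")
    if "band" in raw:
        raw["band"] = tuple(raw["band"])
    return PipelineConfig(**raw)


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    version: str
    n_participants: int
    table_rows: int
    rows_per_participant: float
    retained_seconds: dict  # (participant-condition) -> s, waveform mode
    models_fit: list[int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("output_dir")  # where outputs land does not alter the computation
    blob = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _json_dump(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def simulate_table(config: PipelineConfig):
    """Run the simulation stage; returns (table, covariates, reliability or None)."""
    layout = build_default_layout()
    graph = nearest_neighbors(layout, config.neighbors_k)
    params = config.generative_params()
    cohort = generate_cohort(config.n_abstinent, config.n_non_abstinent, params)
    covariates = cohort_covariates(cohort)
    spectral_cfg = config.spectral_config()
    retained: dict[str, float] = {}
    if config.mode == "tabular":
        table = generate_alpha_table(cohort, layout, params)
        return table, covariates, None, retained
    band_powers = {}
    halves = {}
    for profile in cohort:
        for cond in CONDITIONS:
            rec = generate_recording(profile, cond, layout, params)
            if config.inject_artifacts and params.artifact_rate > 0:
                rec, _ = inject_artifacts(rec, params)
            clean = preprocess_recording(
                rec,
                layout,
                graph,
                abs_threshold_uV=config.abs_threshold_uV,
                step_threshold_uV=config.step_threshold_uV,
                channel_frac=config.channel_frac,
                segment_frac=config.segment_frac,
            )
            band_powers[(profile.id, cond)] = clean_epochs_band_power(clean, spectral_cfg)
            halves[(profile.id, cond)] = split_half_power(clean, spectral_cfg)
            retained[f"{profile.id}-{cond}"] = clean.retained_seconds
            log.info(
                "%s/%s: %d epochs retained (%.0f s), %d channels interpolated",
                profile.id,
                cond,
                len(clean.retained_indices),
                clean.retained_seconds,
                len(clean.interpolated_channels),
            )
    table = build_long_table(band_powers, covariates, layout)
    report = reliability_report(halves, layout.labels)
    return table, covariates, report, retained


def fit_models(
    table: pd.DataFrame, config: PipelineConfig
) -> tuple[dict[int, dict], pd.DataFrame]:
    """Fit the configured model suite; returns summaries and the slope table."""
    summaries: dict[int, dict] = {}
    slope_frames = []
    for mid in config.models:
        spec = ModelSpec.for_model(mid)
        design = build_design(table, spec)
        draws = gibbs_sample(
            design,
            spec,
            chains=config.chains,
            iterations=config.iterations,
            warmup=config.warmup,
            seed=config.seed + 1000 * mid,
        )
        summary = summarize(draws)
        summaries[mid] = summary.to_json_dict()
        log.info("model %d fit: %d fixed effects", mid, len(design.columns))
        if mid in MODEL_MODERATORS:
            st = marginal_slopes(draws, design, MODEL_MODERATORS[mid])
            st.insert(0, "model", mid)
            slope_frames.append(st)
    slopes = (
        pd.concat(slope_frames, ignore_index=True)
        if slope_frames
        else pd.DataFrame()
    )
    return summaries, slopes


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write outputs under ``config.output_dir``."""
    os.makedirs(config.output_dir, exist_ok=True)
    table, covariates, rel_report, retained = simulate_table(config)
    out = config.output_dir
    write_table(table, os.path.join(out, "alpha_table.tsv"))
    covariates.to_csv(os.path.join(out, "covariates.tsv"), sep="\t", index=False)
    if rel_report is not None:
        rel_report.to_tsv(os.path.join(out, "reliability.tsv"))
    summaries, slopes = fit_models(table, config)
    for mid, summary in summaries.items():
        _json_dump(summary, os.path.join(out, f"model_{mid}.json"))
    if not slopes.empty:
        slopes.to_csv(os.path.join(out, "marginal_slopes.tsv"), sep="\t", index=False)
    n_participants = covariates.shape[0]
    manifest = RunManifest(
        config_hash=_config_hash(config),
        seed=config.seed,
        version=__version__,
        n_participants=n_participants,
        table_rows=len(table),
        rows_per_participant=len(table) / n_participants,
        retained_seconds=retained,
        models_fit=list(config.models),
    )
    _json_dump(manifest.to_dict(), os.path.join(out, "manifest.json"))
    return manifest
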