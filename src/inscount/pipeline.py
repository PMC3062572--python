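"""Configuration and orchestration of end-to-end runs.

A run is described by a YAML config (unknown keys are rejected, every
effective parameter is echoed into the run manifest) and executes the
stage chain normalize -> background -> detect -> QC -> profile/classify,
writing each result as delimited text plus a JSON manifest that records
parameters, package version, seed and input checksums.  Identical
config + inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .background_detection import (
    BackgroundModel,
    Rounding,
    call_detection,
    detection_summary,
    negative_control_threshold,
)
from .codeset_io import (
    CountMatrix,
    NormState,
    read_codeset,
    read_counts,
    read_sample_meta,
    write_table,
)
from .errors import ConfigError
from .expression_profiling import classify_patterns, stage_profile
from .normalization import normalize_positive_controls, normalize_target_sum
from .qc_benchmark import replicate_cv, titration_summary
from .synthetic_data import SyntheticConfig, simulate_life_cycle, simulate_titration

log = logging.getLogger("inscount")

_PRESETS = ("titration", "lifecycle", "files")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated run configuration with explicit defaults."""

    preset: str = "lifecycle"
    seed: int = 0
    out_dir: str = "results"
    normalization: tuple[str, ...] = ("positive", "target_sum")
    background_method: str = "negctrl"  # "negctrl" | "fixed"
    background_k: float = 3.0
    background_rounding: str = "none"
    fixed_threshold: float | None = None
    detection_statistic: str = "group_mean"
    classification_threshold: float | None = None
    classification_min_fold: float = 3.0
    run_detection: bool = True
    codeset_path: str | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.preset not in _PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}; expected one of {_PRESETS}")
        allowed = [("positive",), ("positive", "target_sum"), ()]
        if tuple(self.normalization) not in allowed:
            raise ConfigError(
                "normalization must be a prefix of the chain ['positive', 'target_sum']"
            )
        if self.background_method not in ("negctrl", "fixed"):
            raise ConfigError(f"unknown background method {self.background_method!r}")
        if self.background_method == "fixed" and self.fixed_threshold is None:
            raise ConfigError("fixed background method requires fixed_threshold")
        Rounding(self.background_rounding)
        if self.detection_statistic not in ("group_mean", "per_sample"):
            raise ConfigError(f"unknown detection statistic {self.detection_statistic!r}")
        if self.preset == "files":
            for name in ("codeset_path", "counts_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"preset 'files' requires {name}")
                if not Path(p).exists():
                    raise ConfigError(f"{name}: no such file {p!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["normalization"] = list(d["normalization"])
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are
    rejected (all of them listed at once, never silently ignored)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = sorted(set(raw) - _FIELD_NAMES)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    if "normalization" in raw:
        raw["normalization"] = tuple(raw["normalization"])
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_counts(config: PipelineConfig) -> tuple[CountMatrix, dict]:
    """Produce the raw CountMatrix per preset, with provenance for the manifest."""
    if config.preset == "files":
        codeset = read_codeset(config.codeset_path)
        samples = read_sample_meta(config.samples_path) if config.samples_path else None
        cm = read_counts(config.counts_path, codeset, samples=samples)
        checksums = {
            name: _sha256(Path(p))
            for name, p in (
                ("codeset", config.codeset_path),
                ("counts", config.counts_path),
                ("samples", config.samples_path),
            )
            if p
        }
        return cm, {"inputs": checksums}
    sim = SyntheticConfig(seed=config.seed)
    if config.preset == "titration":
        cm = simulate_titration(sim)
        return cm, {"generator": dataclasses.asdict(sim) | {"spike_fmols": list(sim.spike_fmols)}}
    cm, labels, planted = simulate_life_cycle(sim)
    extra = {
        "generator": dataclasses.asdict(sim) | {"spike_fmols": list(sim.spike_fmols)},
        "planted_labels": labels.to_dict(),
    }
    return cm, extra


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stage chain and write all outputs.

    Returns a dict of in-memory results keyed by stage name; the same
    tables are written under ``config.out_dir`` along with
    ``manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "inscount",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
        "outputs": {},
    }
    results: dict = {}

    cm, provenance = _load_counts(config)
    manifest.update(provenance)
    log.info("loaded %d probes x %d samples (%s)", len(cm.codeset), len(cm.samples), config.preset)
    write_table(cm, out / "counts_raw.csv")
    manifest["outputs"]["counts_raw"] = "counts_raw.csv"
    results["raw"] = cm

    factor_tables = []
    if "positive" in config.normalization:
        cm, res = normalize_positive_controls(cm)
        factor_tables.append(res.factors.rename("positive_factor"))
        manifest["stages"].append({"stage": "normalize_positive_controls",
                                   "reference_value": res.reference_value})
    if "target_sum" in config.normalization:
        cm, res = normalize_target_sum(cm)
        factor_tables.append(res.factors.rename("target_sum_factor"))
        manifest["stages"].append({"stage": "normalize_target_sum",
                                   "reference_value": res.reference_value})
    if factor_tables:
        write_table(pd.concat(factor_tables, axis=1), out / "normalization_factors.csv")
        manifest["outputs"]["normalization_factors"] = "normalization_factors.csv"
    write_table(cm, out / "counts_normalized.csv")
    manifest["outputs"]["counts_normalized"] = "counts_normalized.csv"
    results["normalized"] = cm

    conditions = list(dict.fromkeys(s.condition for s in cm.samples))
    models: dict[str, BackgroundModel] = {}
    if config.run_detection:
        for cond in conditions:
            if config.background_method == "negctrl":
                models[cond] = negative_control_threshold(cm, scope=cond, k=config.background_k)
            else:
                models[cond] = BackgroundModel(
                    threshold=Rounding(config.background_rounding).apply(config.fixed_threshold),
                    method="fixed",
                    scope=cond,
                )
        calls = call_detection(cm, models, statistic=config.detection_statistic)
        summary = detection_summary(calls, cm.codeset)
        write_table(calls.calls.astype(int), out / "detection_calls.csv")
        thresholds = pd.Series({c: m.threshold for c, m in models.items()}, name="threshold")
        write_table(thresholds, out / "background_thresholds.csv")
        write_table(summary, out / "detection_summary.csv")
        manifest["outputs"].update(
            detection_calls="detection_calls.csv",
            background_thresholds="background_thresholds.csv",
            detection_summary="detection_summary.csv",
        )
        manifest["stages"].append(
            {"stage": "detection", "statistic": config.detection_statistic,
             "thresholds": {c: m.threshold for c, m in models.items()}}
        )
        results["detection"] = calls
        results["detection_summary"] = summary
        log.info("detection: %d scopes, thresholds %s", len(models),
                 {c: round(m.threshold, 2) for c, m in models.items()})
    else:
        manifest["stages"].append({"stage": "detection", "skipped": True})

    replicated = all(
        n >= 2
        for n in pd.Series([s.condition for s in cm.samples]).value_counts()
    )
    if replicated and len(conditions) > 1:
        cv = replicate_cv(cm, groups="condition")
        write_table(cv.median_cv.rename("median_cv_pct"), out / "median_cv.csv")
        manifest["outputs"]["median_cv"] = "median_cv.csv"
        results["cv"] = cv

    masses = {s.rna_mass for s in cm.samples}
    if config.preset == "titration" and len(masses) > 1:
        tit = titration_summary(cm)
        write_table(tit.table, out / "titration_summary.csv")
        manifest["outputs"]["titration_summary"] = "titration_summary.csv"
        manifest["stages"].append({"stage": "titration_summary", "masses": sorted(masses)})
        results["titration"] = tit

    if config.preset == "lifecycle" and cm.norm_state is NormState.TARGET_SUM_NORMALIZED:
        T = config.classification_threshold
        if T is None and models:
            T = max(m.threshold for m in models.values())
        profile = stage_profile(cm, threshold=T)
        flags = {
            p.gene_id: p.specificity_flag
            for p in cm.codeset.probes
            if p.specificity_flag
        }
        labels = classify_patterns(
            profile, background=T, min_fold=config.classification_min_fold,
            specificity_flags=flags,
        )
        write_table(profile, out / "stage_profile.csv")
        write_table(labels, out / "pattern_labels.csv")
        manifest["outputs"]["stage_profile"] = "stage_profile.csv"
        manifest["outputs"]["pattern_labels"] = "pattern_labels.csv"
        manifest["stages"].append(
            {"stage": "profile_classify", "threshold": T,
             "min_fold": config.classification_min_fold}
        )
        results["profile"] = profile
        results["labels"] = labels

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
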