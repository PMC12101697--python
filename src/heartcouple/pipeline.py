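"""Configuration, logging and the command-line interface.

One flat, sectioned config file (``section.key: value`` lines, YAML
syntax) drives the whole chain: simulate -> preprocess -> extract ->
select -> evaluate. Every stage writes its artifact (WAV recordings,
feature CSV, weights CSV, evaluation JSON) stamped with a hash of the
config that produced it, plus one log line with shapes, seed and wall
time, so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import click
import numpy as np
import yaml

from .classify import CnnConfig, EvalReport, evaluate
from .coupling import EmbeddingConfig, SpectralConfig, extract_features
from .preprocess import PreprocessConfig, preprocess_recording
from .records import MultiChannelRecording
from .selection import FeatureMatrix, relieff_weights, select_top
from .synthio import (
    SimParams,
    generate_cohort,
    read_recording,
    read_table_hash,
    read_feature_table,
    write_feature_table,
    write_recording,
)


@dataclass
class CohortConfig:
    n_normal: int = 30
    n_abnormal: int = 30

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("cohort counts must be >= 0")


@dataclass
class SelectionConfig:
    fraction: float = 0.6
    k_neighbors: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("selection.fraction must be in (0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("selection.k_neighbors must be >= 1")


@dataclass
class EvaluationConfig:
    n_repeats: int = 20
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("evaluation.n_repeats must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("evaluation.train_fraction must be in (0, 1)")


@dataclass
class RunConfig:
    """Fully-defaulted configuration for an end-to-end run."""

    sim: SimParams = field(default_factory=SimParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0
    outdir: str = "runs"

    def to_dict(self) -> dict:
        out: dict = {}
        for f in fields(self):
            val = getattr(self, f.name)
            if dataclasses.is_dataclass(val):
                out[f.name] = {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(val).items()
                }
            else:
                out[f.name] = val
        return out

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_SECTIONS = {
    "sim": SimParams,
    "cohort": CohortConfig,
    "preprocess": PreprocessConfig,
    "embedding": EmbeddingConfig,
    "spectral": SpectralConfig,
    "selection": SelectionConfig,
    "cnn": CnnConfig,
    "evaluation": EvaluationConfig,
}
_TOP_LEVEL = {"seed": int, "outdir": str}


def _coerce(value, target_type):
    if target_type is float and isinstance(value, int):
        return float(value)
    if target_type is tuple and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a flat ``section.key: value`` file.

    Unspecified keys take their documented defaults; unknown keys raise
    (typo protection), as do out-of-range values.
    """
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be flat 'section.key: value' lines")
        data.update(raw)
    if overrides:
        data.update(overrides)

    section_kwargs: dict[str, dict] = {name: {} for name in _SECTIONS}
    top: dict = {}
    for key, value in data.items():
        if key in _TOP_LEVEL:
            top[key] = _TOP_LEVEL[key](value)
            continue
        section, _, param = str(key).partition(".")
        if section not in _SECTIONS or not param:
            raise ValueError(f"unknown config key: {key}")
        cls = _SECTIONS[section]
        valid = {f.name: f for f in fields(cls)}
        if param not in valid:
            raise ValueError(f"unknown config key: {key}")
        default = getattr(cls(), param)
        if value is None:  # explicit null, e.g. preprocess.target_fs
            section_kwargs[section][param] = None
            continue
        if default is not None and not isinstance(value, type(default)):
            value = _coerce(value, type(default))
            if default is not None and not isinstance(value, type(default)):
                raise ValueError(
                    f"config key {key}: expected {type(default).__name__}, "
                    f"got {type(value).__name__}"
                )
        section_kwargs[section][param] = value

    try:
        sections = {name: cls(**section_kwargs[name]) for name, cls in _SECTIONS.items()}
    except (TypeError, ValueError) as err:
        raise ValueError(str(err)) from err
    return RunConfig(**sections, **top)


# ---------------------------------------------------------------------------
# stage functions (library surface; the CLI is a thin wrapper)
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> list[MultiChannelRecording]:
    sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
    return generate_cohort(cfg.cohort.n_normal, cfg.cohort.n_abnormal, sim)


def stage_extract(recordings: list[MultiChannelRecording], cfg: RunConfig) -> FeatureMatrix:
    rows = []
    names: list[str] | None = None
    labels = []
    for rec in recordings:
        pre = preprocess_recording(rec, cfg.preprocess)
        fv = extract_features(pre, cfg.embedding, cfg.spectral)
        if names is None:
            names = fv.names
        elif names != fv.names:
            raise ValueError("recordings yield inconsistent feature sets")
        rows.append(fv.values)
        labels.append(rec.label)
    if names is None:
        raise ValueError("no recordings to extract from")
    return FeatureMatrix(values=np.vstack(rows), names=names, labels=np.array(labels))


def stage_select(features: FeatureMatrix, cfg: RunConfig):
    weights = relieff_weights(features, k_neighbors=cfg.selection.k_neighbors, seed=cfg.seed)
    result = select_top(weights, cfg.selection.fraction)
    return weights, result


def stage_evaluate(features: FeatureMatrix, cfg: RunConfig) -> EvalReport:
    return evaluate(
        features,
        selection_fraction=cfg.selection.fraction,
        k_neighbors=cfg.selection.k_neighbors,
        cnn_cfg=cfg.cnn,
        n_repeats=cfg.evaluation.n_repeats,
        train_fraction=cfg.evaluation.train_fraction,
        seed=cfg.seed,
    )


class _RunLog:
    def __init__(self, outdir: Path, cfg: RunConfig):
        outdir.mkdir(parents=True, exist_ok=True)
        self.path = outdir / "run.log"
        self.cfg_hash = cfg.hash()
        self.seed = cfg.seed

    def stage(self, name: str, **info) -> None:
        parts = [f"stage={name}", f"config={self.cfg_hash}", f"seed={self.seed}"]
        parts += [f"{k}={v}" for k, v in info.items()]
        with open(self.path, "a") as fh:
            fh.write(" ".join(parts) + "\n")


def _check_hash(path: Path, cfg: RunConfig) -> None:
    stored = read_table_hash(path)
    if stored is not None and stored != cfg.hash():
        warnings.warn(
            f"{path} was produced by config {stored}, current config is {cfg.hash()}",
            UserWarning,
        )


def _write_weights(weights, names, path: Path, cfg_hash: str) -> None:
    order = np.argsort(-np.asarray(weights), kind="stable")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        fh.write("name,weight\n")
        for i in order:
            fh.write(f"{names[i]},{weights[i]:.10g}\n")


def run_all(cfg: RunConfig, outdir: str | Path | None = None) -> EvalReport:
    """Chain simulate -> preprocess+extract -> select -> evaluate, with artifacts."""
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    log = _RunLog(outdir, cfg)

    t0 = time.time()
    recs = stage_simulate(cfg)
    for i, rec in enumerate(recs):
        rec.meta["config_hash"] = cfg.hash()
        write_recording(rec, outdir / "recordings" / f"rec_{i:04d}")
    log.stage("simulate", n_recordings=len(recs), wall=f"{time.time() - t0:.2f}s")

    t0 = time.time()
    features = stage_extract(recs, cfg)
    write_feature_table(features, outdir / "features.csv", config_hash=cfg.hash())
    log.stage(
        "extract",
        n_samples=features.n_samples,
        n_features_per_sample=features.n_features,
        wall=f"{time.time() - t0:.2f}s",
    )

    t0 = time.time()
    weights, sel = stage_select(features, cfg)
    _write_weights(weights, features.names, outdir / "weights.csv", cfg.hash())
    log.stage("select", kept=len(sel.kept), of=features.n_features, wall=f"{time.time() - t0:.2f}s")

    t0 = time.time()
    report = stage_evaluate(features, cfg)
    report.to_json(outdir / "evaluation.json", config_hash=cfg.hash())
    log.stage(
        "evaluate",
        n_repeats=report.n_repeats,
        mean_acc=f"{report.acc:.2f}",
        wall=f"{time.time() - t0:.2f}s",
    )
    return report


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _cfg_from_options(config, seed) -> RunConfig:
    cfg = load_config(config)
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return cfg


_config_opt = click.option("--config", type=click.Path(exists=True), default=None,
                           help="Flat section.key config file.")
_seed_opt = click.option("--seed", type=int, default=None, help="Override the global seed.")


@click.group()
def cli() -> None:
    """Multi-channel heart-sound coupling-feature pipeline."""


@cli.command()
@_config_opt
@_seed_opt
@click.option("--out", type=click.Path(), required=True, help="Output directory.")
def simulate(config, seed, out) -> None:
    """Generate a synthetic labeled cohort of multi-channel recordings."""
    cfg = _cfg_from_options(config, seed)
    outdir = Path(out)
    log = _RunLog(outdir, cfg)
    recs = stage_simulate(cfg)
    for i, rec in enumerate(recs):
        rec.meta["config_hash"] = cfg.hash()
        write_recording(rec, outdir / f"rec_{i:04d}")
    log.stage("simulate", n_recordings=len(recs))
    click.echo(f"wrote {len(recs)} recordings to {outdir}")


def _load_recording_dirs(indir: Path) -> list[MultiChannelRecording]:
    rec_dirs = sorted(p for p in indir.iterdir() if p.is_dir())
    recs = [read_recording(p) for p in rec_dirs]
    if not recs:
        raise click.ClickException(f"no recording directories in {indir}")
    return recs


@cli.command("preprocess")
@_config_opt
@_seed_opt
@click.option("--in", "indir", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
def preprocess_cmd(config, seed, indir, out) -> None:
    """Denoise/detrend every recording in a directory."""
    cfg = _cfg_from_options(config, seed)
    outdir = Path(out)
    log = _RunLog(outdir, cfg)
    recs = _load_recording_dirs(Path(indir))
    for i, rec in enumerate(recs):
        pre = preprocess_recording(rec, cfg.preprocess)
        pre.meta["config_hash"] = cfg.hash()
        write_recording(pre, outdir / f"rec_{i:04d}")
    log.stage("preprocess", n_recordings=len(recs))
    click.echo(f"preprocessed {len(recs)} recordings into {outdir}")


@cli.command()
@_config_opt
@_seed_opt
@click.option("--in", "indir", type=click.Path(exists=True), required=True,
              help="Directory of recording subdirectories.")
@click.option("--out", type=click.Path(), required=True, help="Feature CSV path.")
def extract(config, seed, indir, out) -> None:
    """Preprocess and extract coupling features from a recording directory."""
    cfg = _cfg_from_options(config, seed)
    out = Path(out)
    log = _RunLog(out.parent, cfg)
    recs = _load_recording_dirs(Path(indir))
    features = stage_extract(recs, cfg)
    write_feature_table(features, out, config_hash=cfg.hash())
    log.stage("extract", n_samples=features.n_samples,
              n_features_per_sample=features.n_features)
    click.echo(f"wrote {features.n_samples} x {features.n_features} feature table to {out}")


@cli.command()
@_config_opt
@_seed_opt
@click.option("--in", "table", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True, help="Weights CSV path.")
def select(config, seed, table, out) -> None:
    """Rank features with ReliefF over the whole table (exploratory)."""
    cfg = _cfg_from_options(config, seed)
    _check_hash(Path(table), cfg)
    features = read_feature_table(table)
    weights, sel = stage_select(features, cfg)
    _write_weights(weights, features.names, Path(out), cfg.hash())
    click.echo(f"kept {len(sel.kept)} of {features.n_features} features; weights in {out}")


@cli.command("evaluate")
@_config_opt
@_seed_opt
@click.option("--in", "table", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True, help="Evaluation JSON path.")
def evaluate_cmd(config, seed, table, out) -> None:
    """Run the repeated-split selection + CNN evaluation protocol."""
    cfg = _cfg_from_options(config, seed)
    _check_hash(Path(table), cfg)
    features = read_feature_table(table)
    report = stage_evaluate(features, cfg)
    report.to_json(out, config_hash=cfg.hash())
    click.echo(report.confusion_table())
    click.echo(
        f"mean over {report.n_repeats} repeats: acc={report.acc:.2f}% pr={report.pr:.2f}% "
        f"se={report.se:.2f}% sp={report.sp:.2f}% f1={report.f1:.2f}%"
    )


@cli.command("run-all")
@_config_opt
@_seed_opt
@click.option("--out", type=click.Path(), default=None, help="Output directory.")
def run_all_cmd(config, seed, out) -> None:
    """Full chain: simulate, extract, select, evaluate."""
    try:
        cfg = _cfg_from_options(config, seed)
    except ValueError as err:
        raise click.ClickException(str(err)) from err
    report = run_all(cfg, out)
    click.echo(report.confusion_table())
    click.echo(
        f"mean over {report.n_repeats} repeats: acc={report.acc:.2f}% pr={report.pr:.2f}% "
        f"se={report.se:.2f}% sp={report.sp:.2f}% f1={report.f1:.2f}%"
    )


if __name__ == "__main__":
    cli()
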