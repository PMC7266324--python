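"""End-to-end orchestration: simulate -> extract -> fit -> validate.

Each stage reads/writes plain CSV/JSON artifacts under a results directory,
writes files atomically (temp-then-rename), and stamps a manifest with the
configuration hash and seed so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import agreement, features, keypoints_io, mixed_model, synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and stage options for a pipeline run."""

    keypoints_dir: str = "keypoints"
    results_dir: str = "results"
    ratings_csv: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    feature_config: features.FeatureConfig = field(default_factory=features.FeatureConfig)
    synthetic_config: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig
    )
    regularize_covariance: bool = True
    anova_type: str = "II"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ValueError(f"unparsable config file {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "feature_config" in kwargs:
            kwargs["feature_config"] = features.FeatureConfig(**kwargs["feature_config"])
        if "synthetic_config" in kwargs:
            kwargs["synthetic_config"] = synthetic.SyntheticConfig(**kwargs["synthetic_config"])
        return cls(**kwargs)

    def digest(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            return str(obj)

        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True).encode()
        ).hexdigest()[:16]


def atomic_write_text(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_csv(df: pd.DataFrame, path: Path) -> None:
    atomic_write_text(path, df.to_csv(index=True))


def _write_manifest(config: RunConfig, stage: str, outputs: list[str]) -> None:
    atomic_write_text(
        Path(config.results_dir) / f"{stage}_manifest.json",
        json.dumps(
            {"stage": stage, "config_hash": config.digest(), "seed": config.seed,
             "outputs": outputs},
            indent=2,
        ),
    )


def cmd_simulate(config: RunConfig) -> pd.DataFrame:
    """Generate the synthetic study into ``keypoints_dir``."""
    scfg = dataclasses.replace(config.synthetic_config, seed=config.seed)
    meta, _ = synthetic.generate_study(scfg, out_dir=config.keypoints_dir)
    _write_manifest(config, "simulate", [config.keypoints_dir])
    logger.info("simulated %d videos into %s", len(meta), config.keypoints_dir)
    return meta


def cmd_extract(config: RunConfig) -> pd.DataFrame:
    """Run the feature pipeline over every video directory listed in metadata."""
    kdir = Path(config.keypoints_dir)
    meta_path = kdir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata table at {meta_path}")
    meta = pd.read_csv(meta_path, dtype=str)
    summaries = []
    for _, row in meta.iterrows():
        md = synthetic.metadata_from_row(row)
        series = keypoints_io.load_video(kdir / md.video_id, md)
        summaries.append(features.extract_features(series, config.feature_config))
    table = features.summary_table(summaries)
    out = Path(config.results_dir) / "features.csv"
    atomic_write_text(out, table.to_csv(index=False))
    _write_manifest(config, "extract", [str(out)])
    logger.info("extracted %d video summaries (%d dropped)", len(table),
                int(table["dropped"].sum()))
    return table


def cmd_fit(config: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Fit both outcomes; write coefficient/anova tables and a JSON report."""
    if table is None:
        fpath = Path(config.results_dir) / "features.csv"
        if not fpath.exists():
            raise FileNotFoundError(f"no feature table at {fpath}")
        table = pd.read_csv(fpath, dtype={"sentence_id": str, "signer_id": str})
    results = {}
    outputs = []
    for outcome in ("internal", "external"):
        spec = mixed_model.ModelSpec(
            outcome=f"mean_{outcome}",
            regularize_covariance=config.regularize_covariance,
            anova_type=config.anova_type,
        )
        fit = mixed_model.fit_mixed_model(table, spec)
        anova = mixed_model.anova_wald(fit)
        effects = mixed_model.report_effects(fit)
        rdir = Path(config.results_dir)
        for name, df in (
            (f"coefficients_{outcome}.csv", fit.coefficients),
            (f"anova_{outcome}.csv", anova),
            (f"effects_{outcome}.csv", effects),
        ):
            atomic_write_csv(df, rdir / name)
            outputs.append(str(rdir / name))
        report = {
            "outcome": outcome,
            "n_obs": fit.n_obs,
            "converged": fit.converged,
            "singular": fit.singular,
            "sigma2": fit.sigma2,
            "variance_components": fit.variance_components,
            "reml_criterion": fit.reml_criterion,
        }
        rpath = rdir / f"fit_report_{outcome}.json"
        atomic_write_text(rpath, json.dumps(report, indent=2))
        outputs.append(str(rpath))
        results[outcome] = {"fit": fit, "anova": anova, "effects": effects}
    _write_manifest(config, "fit", outputs)
    return results


def cmd_validate(config: RunConfig) -> agreement.AgreementReport:
    """Compute agreement statistics from a ratings CSV (or a simulated one)."""
    if config.ratings_csv and Path(config.ratings_csv).exists():
        ratings = pd.read_csv(config.ratings_csv, dtype=str)
    else:
        ratings = synthetic.generate_ratings(seed=config.seed)
        logger.info("no ratings file configured; using a simulated rating table")
    report = agreement.agreement_report(ratings)
    out = Path(config.results_dir) / "agreement_report.json"
    atomic_write_text(out, json.dumps(report.to_dict(), indent=2))
    _write_manifest(config, "validate", [str(out)])
    return report


def cmd_run_all(config: RunConfig) -> dict:
    """simulate -> extract -> fit -> validate, plus a summary report."""
    cmd_simulate(config)
    table = cmd_extract(config)
    fits = cmd_fit(config, table)
    report = cmd_validate(config)
    summary = {
        "n_videos": len(table),
        "n_modelled": int((~table["dropped"]).sum()),
        "anova_internal": fits["internal"]["anova"].to_dict(),
        "anova_external": fits["external"]["anova"].to_dict(),
        "overall_accuracy": report.overall_accuracy,
        "light_kappa": report.light_kappa,
    }
    atomic_write_text(
        Path(config.results_dir) / "summary.json", json.dumps(summary, indent=2)
    )
    return {"features": table, "fits": fits, "agreement": report}
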