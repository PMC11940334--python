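"""End-to-end pipeline driver: config in, run directory out.

``run_pipeline`` reads a study directory (time series, phenotype,
parcellation), runs the full analysis through
:class:`~hemigrad.model.GradientAsymmetryAnalysis`, and writes every stage's
artifact into stage-named subfolders with a provenance record, so a rerun
with the same config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ParameterError
from .io import write_json, write_matrix
from .model import AnalysisParams, GradientAsymmetryAnalysis

log = logging.getLogger("hemigrad")


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    density: float = 0.10
    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 10
    n_gradients: int = 3
    mean_fd_max: float = 0.35
    max_fd_max: float = 3.0
    q_level: float = 0.05
    covariates: tuple = ("age", "sex", "mean_fd")
    harmonize: bool = True
    reference_group: str = "HC"
    n_repeats: int = 100
    parcellation_one_based: bool = False
    run_prediction: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ParameterError("density must be in (0, 1]")
        if not 0 <= self.alpha <= 1:
            raise ParameterError("alpha must be in [0, 1]")
        if self.n_components < self.n_gradients:
            raise ParameterError("n_components must be >= n_gradients")
        if not 0 < self.q_level < 1:
            raise ParameterError("q_level must be in (0, 1)")
        if self.n_repeats < 1 or self.seed < 0:
            raise ParameterError("n_repeats must be >= 1 and seed >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_params(self) -> AnalysisParams:
        return AnalysisParams(
            density=self.density, alpha=self.alpha,
            diffusion_time=self.diffusion_time, n_components=self.n_components,
            n_gradients=self.n_gradients, mean_fd_max=self.mean_fd_max,
            max_fd_max=self.max_fd_max, q_level=self.q_level,
            covariates=tuple(self.covariates), harmonize=self.harmonize,
        )

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig):
    """Execute every stage and write artifacts; returns the results object."""
    in_dir = Path(config.input_dir)
    if not in_dir.exists():
        raise ParameterError(f"input directory {in_dir} does not exist")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage config: echoing configuration")
    (out / "config.yaml").write_text(yaml.safe_dump(
        dataclasses.asdict(config), sort_keys=True, default_flow_style=False))
    write_json(out / "provenance.json", {
        "package_version": __version__, "config_hash": config.digest(),
        "seed": config.seed,
    })

    log.info("stage load: reading study from %s", in_dir)
    analysis = GradientAsymmetryAnalysis.from_directory(
        in_dir, params=config.to_params())

    log.info("stage fit: %d subjects", len(analysis.phenotype))
    results = analysis.fit(reference_group=config.reference_group)

    qc_dir = out / "qc"
    qc_dir.mkdir(exist_ok=True)
    pd.DataFrame([{"subject_id": e.subject_id, "reason": e.reason}
                  for e in results.exclusions]
                 or [], columns=["subject_id", "reason"]).to_csv(
        qc_dir / "exclusions.csv", index=False)

    grad_dir = out / "gradients"
    grad_dir.mkdir(exist_ok=True)
    for name, tmpl in (("intra", results.intra_template),
                       ("inter", results.inter_template)):
        write_matrix(grad_dir / f"template_{name}.tsv", tmpl.coordinates)
        write_json(grad_dir / f"template_{name}.json", {
            "provenance": tmpl.provenance, "reference": tmpl.reference,
            "eigenvalues": tmpl.eigenvalues,
            "explained_variance": tmpl.explained_variance,
        })

    ai_dir = out / "asymmetry"
    ai_dir.mkdir(exist_ok=True)
    results.region_features.to_csv(ai_dir / "region_ai.csv", float_format="%.17g")
    results.network_features.to_csv(ai_dir / "network_ai.csv", float_format="%.17g")
    results.region_features_harmonized.to_csv(
        ai_dir / "region_ai_harmonized.csv", float_format="%.17g")
    results.network_features_harmonized.to_csv(
        ai_dir / "network_ai_harmonized.csv", float_format="%.17g")

    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    results.network_results.table.to_csv(stats_dir / "network_comparison.csv",
                                         index=False, float_format="%.17g")
    results.region_results.table.to_csv(stats_dir / "region_comparison.csv",
                                        index=False, float_format="%.17g")
    results.cohens_d.table.to_csv(stats_dir / "cohens_d.csv", index=False,
                                  float_format="%.17g")
    results.demographics.to_csv(stats_dir / "demographics.csv", index=False,
                                float_format="%.17g")
    write_json(stats_dir / "selected_features.json",
               {"features": results.selected_features, "notes": results.notes})

    if config.run_prediction and results.selected_features:
        pred_dir = out / "prediction"
        pred_dir.mkdir(exist_ok=True)
        log.info("stage predict: classification over %d repeats", config.n_repeats)
        clf = results.predict_diagnosis(n_repeats=config.n_repeats,
                                        seed=config.seed)
        clf.per_repeat.to_csv(pred_dir / "classification.csv", index=False,
                              float_format="%.17g")
        summary = {"classification": clf.summary().to_dict()}
        pheno = results.phenotype
        for scale in ("panss_pos", "panss_neg", "panss_gen"):
            has = pheno.loc[pheno["group"] == "SZ", scale].notna()
            if has.sum() >= 20:
                reg = results.predict_panss(scale, n_repeats=config.n_repeats,
                                            seed=config.seed)
                reg.per_repeat.to_csv(pred_dir / f"{scale}.csv", index=False,
                                      float_format="%.17g")
                summary[scale] = reg.summary().to_dict()
        write_json(pred_dir / "summary.json", summary)

    (out / "summary.txt").write_text(results.summary() + "\n")
    log.info("pipeline complete: %s", out)
    return results
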