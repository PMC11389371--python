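"""End-to-end orchestration: preprocess, evaluate, stability, experiments,
accuracy model, report.

`run_pipeline` sequences the full analysis on either loaded feature tables
or the bundled synthetic cohort, isolating per-method failures so a fragile
estimator never aborts the comparison, and writes a manifest with seeds and
a config hash so reruns are reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .accuracy_model import InterpolationAccuracyModel, build_features
from .evaluation import (
    loo_evaluate,
    records_to_frame,
    subsample_experiment,
    summarize_accuracy,
)
from .interpolators import METHOD_NAMES, InterpolatorSpec
from .io import read_profile
from .profiles import LongitudinalProfile, select_top_taxa
from .stability import stability_series, taxon_bimodality_table
from .synthetic import SyntheticConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_METHOD_PARAMS"]

logger = logging.getLogger("mbinterp")

# Evaluation-scale parameters for the expensive estimators: LIMITS runs with
# a reduced bootstrap count and a support cap so the full 12-method
# comparison stays desk-scale.  Override per run via RunConfig.methods.
DEFAULT_METHOD_PARAMS: dict[str, dict] = {
    "knn": {"K": 5},
    "limits": {"n_bootstrap": 10, "max_terms": 5, "seed": 0},
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: str
    inputs: tuple[tuple[str, str, str], ...] = ()   # (table, metadata, individual)
    synthetic: SyntheticConfig | None = None
    methods: Mapping[str, Mapping] | Sequence[str] = METHOD_NAMES
    k_top_taxa: int = 30
    run_subsample: bool = False
    subsample_method: str = "knn"
    subsample_sizes: tuple[int, ...] = (10, 20, 30)
    subsample_replicates: int = 30
    run_accuracy_model: bool = True
    accuracy_model_method: str = "knn"
    seed: int = 0
    log_level: str = "INFO"

    def method_specs(self) -> list[InterpolatorSpec]:
        if isinstance(self.methods, Mapping):
            items = [(name, dict(p or {})) for name, p in self.methods.items()]
        else:
            items = [(name, {}) for name in self.methods]
        specs = []
        for name, params in items:
            merged = {**DEFAULT_METHOD_PARAMS.get(name, {}), **params}
            specs.append(InterpolatorSpec(name, merged))   # validates names
        return specs

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["methods"] = {s.method_name: s.parameters for s in self.method_specs()}
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_profiles(config: RunConfig) -> list[LongitudinalProfile]:
    if config.inputs:
        profiles = [
            read_profile(table, meta, individual_id=ident)
            for table, meta, ident in config.inputs
        ]
    else:
        cfg = config.synthetic or SyntheticConfig(seed=config.seed)
        profiles, _ = simulate_cohort(cfg)
    return [select_top_taxa(p, k=config.k_top_taxa) for p in profiles]


def _write(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> str:
    """Run the full analysis; returns the output directory path.

    Outputs: ``records.tsv`` (one row per method x target),
    ``summary_method.tsv`` / ``summary_individual.tsv``,
    ``stability_samples.tsv`` / ``stability_taxa.tsv``, optionally
    ``subsample.tsv``, ``accuracy_model_coefficients.tsv`` and
    ``accuracy_model_predictions.tsv``, and ``manifest.json``.
    """
    specs = config.method_specs()   # validate before any computation
    os.makedirs(config.output_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_jsonable(),
        "errors": {},
    }

    profiles = _load_profiles(config)
    manifest["n_individuals"] = len(profiles)

    all_records = []
    for spec in specs:
        for prof in profiles:
            try:
                all_records.extend(loo_evaluate(prof, spec))
            except Exception as exc:  # per-method isolation
                logger.exception("method %s failed on %s", spec.method_name,
                                 prof.individual_id)
                manifest["errors"][f"{spec.method_name}/{prof.individual_id}"] = str(exc)
    rec_df = records_to_frame(all_records).sort_values(
        ["method", "individual_id", "target_index"], kind="stable"
    )
    _write(rec_df, os.path.join(config.output_dir, "records.tsv"))
    _write(
        summarize_accuracy(all_records, "method").reset_index(),
        os.path.join(config.output_dir, "summary_method.tsv"),
    )
    _write(
        summarize_accuracy(all_records, "individual").reset_index(),
        os.path.join(config.output_dir, "summary_individual.tsv"),
    )

    stab = pd.concat([stability_series(p) for p in profiles], ignore_index=True)
    _write(stab, os.path.join(config.output_dir, "stability_samples.tsv"))
    _write(
        taxon_bimodality_table(profiles),
        os.path.join(config.output_dir, "stability_taxa.tsv"),
    )

    if config.run_subsample:
        sub_rows = []
        rng = np.random.default_rng(config.seed)
        for prof in profiles:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sizes = [s for s in config.subsample_sizes if s <= prof.n_samples]
            if not sizes:
                continue
            sub_rows.extend(
                subsample_experiment(
                    prof,
                    InterpolatorSpec(config.subsample_method,
                                     DEFAULT_METHOD_PARAMS.get(
                                         config.subsample_method, {})),
                    sizes=sizes,
                    replicates=config.subsample_replicates,
                    seed=sub_seed,
                )
            )
        _write(
            pd.DataFrame([dataclasses.asdict(r) for r in sub_rows]),
            os.path.join(config.output_dir, "subsample.tsv"),
        )

    if config.run_accuracy_model:
        recs = [r for r in all_records
                if r.method_name == config.accuracy_model_method]
        feats = build_features(recs)
        if len(feats) >= 10 and feats["individual_id"].nunique() >= 2:
            fit = InterpolationAccuracyModel(feats).fit()
            _write(
                fit.fixed_effects.reset_index(names="term"),
                os.path.join(config.output_dir, "accuracy_model_coefficients.tsv"),
            )
            pred = feats.assign(
                predicted_bc=fit.predict(feats, include_random=True)
            )
            _write(pred, os.path.join(config.output_dir,
                                      "accuracy_model_predictions.tsv"))
            mae, rho = fit.evaluate(feats)
            manifest["accuracy_model"] = {
                "method": config.accuracy_model_method,
                "in_sample_mae": mae,
                "in_sample_spearman": rho,
                "random_intercept_variance": fit.random_intercept_variance,
                "converged": fit.converged,
            }

    manifest["n_records"] = int(len(rec_df))
    with open(os.path.join(config.output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return config.output_dir
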