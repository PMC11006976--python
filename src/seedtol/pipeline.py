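"""End-to-end pipeline: indices -> descriptives -> gradients -> environment
-> mixed models -> path model, with a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .descriptives import summarize_table
from .environment import attribution_panel
from .germination import TreatmentScheme, compute_indices, indices_to_frame, trials_from_frame
from .gradients import gradient_panel
from .mixed import MORPHOLOGY_BLOCK, NUTRIENT_BLOCK, block_effect_decomposition, fit_random_intercept_lmm
from .pathmodel import PathModelSpec, composite_table, fit_path_model
from .tableio import SITES_SCHEMA, TRAITS_SCHEMA, TRIALS_SCHEMA, read_table, write_table

log = logging.getLogger("seedtol")

INDEX_COLUMNS = ["GDTI", "GCTI", "GSTI"]


@dataclass
class PipelineConfig:
    trials_path: str | Path = "trials.csv"
    traits_path: str | Path = "traits.csv"
    sites_path: str | Path = "sites.csv"
    out_dir: str | Path = "results"
    aggregation: str = "per_replicate"          # index replicate pairing
    gsti_interpretation: str = "symmetric"      # or "literal"
    decomposition_method: str = "commonality"   # or "abs_beta"
    regress_population_means: bool = True
    path_spec: PathModelSpec = field(default_factory=PathModelSpec)


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        k: str(v) for k, v in vars(config).items() if k != "path_spec"
    }
    payload["path_edges"] = list(map(list, config.path_spec.edges))
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the manifest dict.

    Any stage failure aborts with the stage name prepended to the cause.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seedtol_version": __version__,
        "config_hash": _config_hash(config),
        "stages": [],
    }

    def stage(name):
        def wrap(fn):
            log.info("stage %s", name)
            try:
                rows = fn()
            except Exception as exc:  # annotate and re-raise
                manifest["failed_stage"] = name
                (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise type(exc)(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append({"name": name, "rows": int(rows)})
        return wrap

    state: dict = {}

    @stage("indices")
    def _():
        trials_frame = read_table(config.trials_path, TRIALS_SCHEMA)
        trials = trials_from_frame(trials_frame)
        indices = compute_indices(
            trials,
            TreatmentScheme(),
            aggregation=config.aggregation,
            gsti_interpretation=config.gsti_interpretation,
        )
        state["indices"] = indices_to_frame(indices)
        write_table(state["indices"], out_dir / "indices.csv")
        traits = read_table(config.traits_path, TRAITS_SCHEMA)
        state["traits"] = traits.merge(state["indices"], on=["population_id", "replicate"])
        state["sites"] = read_table(config.sites_path, SITES_SCHEMA)
        return len(state["indices"])

    @stage("summarize")
    def _():
        summary = summarize_table(state["traits"])
        write_table(summary, out_dir / "summary.csv")
        return len(summary)

    @stage("gradients")
    def _():
        panel = gradient_panel(
            state["traits"], state["sites"], aggregate=config.regress_population_means
        )
        write_table(panel, out_dir / "gradients.csv")
        return len(panel)

    @stage("env")
    def _():
        panel = attribution_panel(state["traits"], state["sites"])
        write_table(panel, out_dir / "env_attribution.csv")
        return len(panel)

    for response in INDEX_COLUMNS:
        @stage(f"lmm_{response}")
        def _(response=response):
            fit = fit_random_intercept_lmm(
                state["traits"][response],
                state["traits"][MORPHOLOGY_BLOCK + NUTRIENT_BLOCK],
                state["traits"]["population_id"],
            )
            shares = block_effect_decomposition(fit, method=config.decomposition_method)
            payload = {
                "response": response,
                "fixed_effects": {
                    name: {"estimate": float(b), "se": float(s), "p": float(p)}
                    for name, b, s, p in zip(
                        fit.feature_names,
                        fit.fixed_effect_estimates,
                        fit.fixed_effect_se,
                        fit.fixed_effect_p_values,
                    )
                },
                "random_intercept_variance": fit.random_intercept_variance,
                "residual_variance": fit.residual_variance,
                "boundary_fit": fit.boundary_fit,
                "block_shares": shares,
            }
            (out_dir / f"lmm_{response}.json").write_text(json.dumps(payload, indent=2))
            return fit.n_obs

    @stage("sem")
    def _():
        composites = composite_table(
            state["traits"], state["sites"], state["indices"]
        )
        fit = fit_path_model(composites, config.path_spec)
        payload = {
            "coefficients": fit.coefficients.to_dict(orient="records"),
            "r_squared": fit.r_squared,
            "residual_variances": fit.residual_variances,
            "fit": {
                "chi_square": fit.chi_square,
                "df": fit.df,
                "gfi": fit.gfi,
                "cfi": fit.cfi,
                "rmsea": fit.rmsea,
                "n": fit.n,
            },
        }
        (out_dir / "sem_fit.json").write_text(json.dumps(payload, indent=2))
        write_table(fit.effects, out_dir / "sem_effects.csv")
        return len(fit.effects)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
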