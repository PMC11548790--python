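"""End-to-end sparse-testing experiment: data -> designs -> fits -> report.

``run_experiment`` executes, for each allocation method and each
cross-validation partition: the first-stage multi-response fit on the
masked wide table (when any CE method is requested), the construction of
the environment covariance per method, the single-response GBLUP on the
training cells, test-cell prediction (or across-TPE line scores for
GBLUP_TRN), and metric evaluation; results are aggregated into per-method
means, standard deviations and relative-efficiency tables and written as
CSV + JSON with a manifest of seeds and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from sparsemet.designs import cv_partitions
from sparsemet.engine import (
    METHOD_TAGS,
    MCMCConfig,
    PhenoTable,
    build_omega,
    fit_gblup,
    fit_multitrait_unstructured,
    gebv_across_tpe,
    predict_cells,
)
from sparsemet.markers import (
    KinshipMatrix,
    grm_vanraden,
    impute_missing,
    qc_filter,
    read_marker_csv,
)
from sparsemet.metrics import MetricsReport, aggregate, evaluate_partition
from sparsemet.synthetic import compound_symmetry, simulate_markers, simulate_met

logger = logging.getLogger("sparsemet")

_PKG_VERSION = "0.1.0"

__all__ = ["RunConfig", "SimulationBlock", "run_experiment", "prepare_inputs"]


class SimulationBlock(BaseModel):
    """Built-in data generator settings (used when no dataset paths given)."""

    J: int = 166
    I: int = 4
    p: int = 2000
    mu: float = 5.0
    sigma2_env: float = 1.0
    sigma2_gen: float = 1.0
    sigma2_gxe: float = 0.5
    sigma2_res: float = 0.5
    env_rho: float = 0.5


class MCMCBlock(BaseModel):
    n_iter: int = 20000
    burn_in: int = 10000
    thin: int = 1
    prior_df: float = 5.0
    prior_scale_fraction: float = 0.5


class RunConfig(BaseModel):
    """Validated configuration of a full sparse-testing experiment."""

    marker_csv: Optional[str] = None
    pheno_csv: Optional[str] = None
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    allocation_methods: list[str] = ["IBD", "Random"]
    methods: list[str] = list(METHOD_TAGS)
    n_partitions: int = 10
    train_frac: float = 0.5
    mcmc: MCMCBlock = Field(default_factory=MCMCBlock)
    nrmse_normalizer: str = "mean"
    maf_min: float = 0.05
    missing_max: float = 0.50
    out_dir: str = "sparsemet_out"
    seed: int = 0

    @field_validator("methods")
    @classmethod
    def _known_methods(cls, v):
        bad = set(v) - set(METHOD_TAGS)
        if bad:
            raise ValueError(f"unknown method tags {sorted(bad)}; valid: {METHOD_TAGS}")
        return v

    @field_validator("allocation_methods")
    @classmethod
    def _known_alloc(cls, v):
        bad = set(v) - {"IBD", "Random"}
        if bad:
            raise ValueError(f"unknown allocation methods {sorted(bad)}")
        return v

    @field_validator("train_frac")
    @classmethod
    def _frac(cls, v):
        if not 0.0 < v < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        return v


def prepare_inputs(config: RunConfig) -> tuple[KinshipMatrix, PhenoTable]:
    """Load or simulate markers and phenotypes; QC, impute, build G."""
    if config.marker_csv and config.pheno_csv:
        markers = read_marker_csv(config.marker_csv)
        from sparsemet.engine import read_pheno_csv

        pheno = read_pheno_csv(config.pheno_csv)
    elif config.marker_csv or config.pheno_csv:
        raise ValueError("provide both marker_csv and pheno_csv, or neither")
    else:
        sim = config.simulation
        markers = simulate_markers(sim.J, sim.p, seed=config.seed)
        kin0 = grm_vanraden(markers)
        pheno, _ = simulate_met(
            kin0,
            sim.I,
            mu=sim.mu,
            sigma2_env=sim.sigma2_env,
            sigma2_gen=sim.sigma2_gen,
            sigma2_gxe=sim.sigma2_gxe,
            sigma2_res=sim.sigma2_res,
            omega_true=compound_symmetry(sim.I, sim.env_rho),
            seed=config.seed + 1,
        )
    if np.isnan(markers.values).any():
        markers, _ = qc_filter(markers, config.maf_min, config.missing_max)
        markers = impute_missing(markers, seed=config.seed + 7)
    else:
        markers, _ = qc_filter(markers, config.maf_min, config.missing_max)
    kin = grm_vanraden(markers)
    pheno_lines = set(pheno.frame["line"])
    keep = [l for l in kin.line_ids if l in pheno_lines]
    kin = kin.reorder(keep)
    return kin, pheno


def _omega_cache_key(method: str) -> str:
    # GBLUP and GBLUP_TRN share the identity environment kernel, hence one fit
    return "identity" if method in ("GBLUP", "GBLUP_TRN") else method


def run_experiment(config: RunConfig, write: bool = True) -> MetricsReport:
    """Run the full experiment described by ``config``; see module docstring."""
    t0 = time.time()
    kin, pheno = prepare_inputs(config)
    line_ids = kin.line_ids
    env_order = sorted(set(pheno.frame["env"]), key=str)
    wide = pheno.to_wide(line_order=line_ids, env_order=env_order)
    if wide.isna().any().any():
        raise ValueError("the input phenotype grid must be complete before masking")
    env_ids = wide.columns.to_numpy(dtype=object)
    I = len(env_ids)

    needs_stage1 = any(m.startswith("GBLUP_CE") for m in config.methods)
    mcmc = MCMCConfig(
        n_iter=config.mcmc.n_iter,
        burn_in=config.mcmc.burn_in,
        thin=config.mcmc.thin,
        seed=config.seed,
        prior_df=config.mcmc.prior_df,
        prior_scale_fraction=config.mcmc.prior_scale_fraction,
    )

    records = []
    for alloc in config.allocation_methods:
        parts = cv_partitions(
            line_ids,
            env_ids,
            n_partitions=config.n_partitions,
            train_frac=config.train_frac,
            allocation_method=alloc,
            seed=config.seed + (0 if alloc == "IBD" else 100_000),
        )
        for part in parts:
            tag = f"{alloc}/partition {part.partition_index}"
            masked = wide.where(part.train)
            mt = None
            if needs_stage1:
                logger.info("%s: first-stage unstructured covariance fit", tag)
                mt = fit_multitrait_unstructured(
                    masked, kin, mcmc.replace(seed=part.seed + 1)
                )
            train_tbl = PhenoTable.from_wide(masked)
            test_tbl = PhenoTable.from_wide(wide.where(~part.train))

            fits = {}
            predictions, line_scores = {}, {}
            for method in config.methods:
                key = _omega_cache_key(method)
                if key not in fits:
                    omega = build_omega(method, mt, I=I, env_ids=env_ids)
                    logger.info("%s: fitting %s", tag, method)
                    fits[key] = fit_gblup(
                        train_tbl, kin, omega, mcmc.replace(seed=part.seed + 2)
                    )
                fit = fits[key]
                if method == "GBLUP_TRN":
                    line_scores[method] = gebv_across_tpe(fit)
                else:
                    cells = list(zip(test_tbl.frame["line"], test_tbl.frame["env"]))
                    predictions[method] = predict_cells(fit, cells)
            records.extend(
                evaluate_partition(
                    test_tbl.frame,
                    predictions,
                    line_scores,
                    allocation_tag=alloc,
                    partition_index=part.partition_index,
                    nrmse_normalizer=config.nrmse_normalizer,
                )
            )

    expected = len(config.allocation_methods) * config.n_partitions * len(config.methods)
    if len(records) != expected:
        raise RuntimeError(
            f"incomplete report: {len(records)} rows, expected {expected}"
        )
    report = aggregate(records)

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.per_partition.to_csv(out / "metrics_per_partition.csv", index=False)
        report.summary.to_csv(out / "metrics_summary.csv", index=False)
        report.relative_efficiencies.to_csv(out / "relative_efficiency.csv", index=False)
        payload = {
            "summary": report.summary.to_dict(orient="records"),
            "relative_efficiencies": report.relative_efficiencies.to_dict(
                orient="records"
            ),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        cfg_json = config.model_dump_json(indent=2)
        manifest = {
            "version": _PKG_VERSION,
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "runtime_seconds": round(time.time() - t0, 2),
            "n_records": len(records),
        }
        (out / "config.json").write_text(cfg_json)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
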