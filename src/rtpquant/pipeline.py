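"""End-to-end orchestration: bundle -> peptide ratios -> cell counts ->
copies per cell -> RTP model (-> optional CV curve), from one config.

Every run writes its result tables plus a JSON manifest carrying the config
hash, package version, per-stage filter counts and summary statistics, so a
run is a pure function of (input files, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

from rtpquant import __version__, cellcount, copies as copies_mod, io as qio, prm, robustness, rtp as rtp_mod
from rtpquant.errors import ConfigError
from rtpquant.simulate import SimConfig, simulate_bundle, write_bundle

log = logging.getLogger("rtpquant")

_DEFAULT_OPTIONS: dict[str, Any] = {
    "policy": "median_of_fragments",
    "min_fragments": 1,
    "gene_min_sample_fraction": 1.0,
    "cellcount_mode": "auto",          # auto | constant | calibrated
    "histones_per_cell": cellcount.DEFAULT_HISTONES_PER_CELL,
    "dna_pg_per_cell": cellcount.DEFAULT_DNA_PG_PER_CELL,
    "histone_genes": list(cellcount.DEFAULT_HISTONE_GENES),
    "allow_missing_histones": False,
    "rollup": "peptides-first",
    "min_samples": 2,
    "central": "median",
}

_DEFAULT_CV: dict[str, Any] = {
    "enabled": False,
    "sizes": None,
    "n_predictions_per_size": 500,
    "count": "predictions",
}


@dataclass
class RunConfig:
    """Validated top-level run configuration.

    Exactly one of ``inputs`` (paths to the four tables) or ``simulate``
    (a :class:`~rtpquant.simulate.SimConfig` mapping) must be given.
    """

    output_dir: str
    inputs: dict[str, str] | None = None
    simulate: dict[str, Any] | None = None
    options: dict[str, Any] = field(default_factory=dict)
    cv: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError("exactly one of 'inputs' or 'simulate' must be configured")
        if self.inputs is not None:
            required = {"transitions", "spikes", "samples", "tpm"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs block missing path(s): {sorted(missing)}")
            for key, path in self.inputs.items():
                if not os.path.exists(path):
                    raise ConfigError(f"input file for '{key}' not found: {path}")
        unknown = set(self.options) - set(_DEFAULT_OPTIONS)
        if unknown:
            raise ConfigError(f"unknown option(s): {sorted(unknown)}")
        unknown_cv = set(self.cv) - set(_DEFAULT_CV)
        if unknown_cv:
            raise ConfigError(f"unknown cv option(s): {sorted(unknown_cv)}")
        self.options = {**_DEFAULT_OPTIONS, **self.options}
        self.cv = {**_DEFAULT_CV, **self.cv}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        return cls(
            output_dir=raw["output_dir"],
            inputs=raw.get("inputs"),
            simulate=raw.get("simulate"),
            options=raw.get("options", {}),
            cv=raw.get("cv", {}),
            seed=int(raw.get("seed", 0)),
        )

    def to_jsonable(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "inputs": self.inputs,
            "simulate": self.simulate,
            "options": self.options,
            "cv": self.cv,
            "seed": self.seed,
        }


def analyze(transitions, spikes, samples, tpm, options: dict | None = None) -> dict:
    """In-memory run of quantify -> cell-count -> copy-number -> rtp.

    Returns a dict with the intermediate and final frames: ``peptide_ratios,
    exclusions, cells, cellcount_model, copy_numbers, rtp_ratios, rtp_table,
    gene_correlations, prediction``. Same option keys (and defaults) as the
    pipeline's ``options`` block.
    """
    opts = {**_DEFAULT_OPTIONS, **(options or {})}
    unknown = set(opts) - set(_DEFAULT_OPTIONS)
    if unknown:
        raise ConfigError(f"unknown option(s): {sorted(unknown)}")

    ratio_cfg = prm.RatioConfig(policy=opts["policy"], min_fragments=opts["min_fragments"])
    ratios = prm.peptide_ratios(transitions, ratio_cfg)
    histone_set = set(opts["histone_genes"])
    target_ratios = ratios[~ratios["gene_id"].isin(histone_set)]
    all_samples = list(samples["sample_id"])
    all_genes = sorted(set(transitions["gene_id"].unique()) - histone_set)
    kept, exclusions = prm.apply_quantifiability_filters(
        target_ratios, all_samples, all_genes,
        gene_min_sample_fraction=opts["gene_min_sample_fraction"],
    )

    mode = opts["cellcount_mode"]
    if mode == "auto":
        mode = "calibrated" if (samples["sample_class"] == "cell_line").any() else "constant"
    model = cellcount.CellCountModel(
        dna_pg_per_cell=opts["dna_pg_per_cell"],
        histones_per_cell=opts["histones_per_cell"],
        mode=mode,
        histone_genes=tuple(opts["histone_genes"]),
    )
    amounts = cellcount.histone_amounts(ratios, spikes, model.histone_genes)
    cells, fitted = cellcount.cells_from_histones(
        amounts, model, samples, allow_missing_histones=opts["allow_missing_histones"]
    )
    cells = cellcount.normalization_factors(cells, samples)

    pep_copies = copies_mod.peptide_copies(kept, spikes, cells)
    matrix, provenance = copies_mod.protein_copies(pep_copies, rollup=opts["rollup"])

    ratios_gs, tally = rtp_mod.rtp_ratios(matrix, tpm)
    gene_table = rtp_mod.gene_rtp(
        ratios_gs, min_samples=opts["min_samples"], central=opts["central"]
    )
    gene_corr = rtp_mod.gene_correlations(matrix, tpm)
    prediction = rtp_mod.predict_loo(matrix, tpm)
    return {
        "peptide_ratios": ratios,
        "exclusions": exclusions,
        "cells": cells,
        "cellcount_model": fitted,
        "copy_numbers": matrix,
        "copy_number_provenance": provenance,
        "rtp_ratios": ratios_gs,
        "rtp_tally": tally,
        "rtp_table": gene_table,
        "gene_correlations": gene_corr,
        "prediction": prediction,
    }


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_jsonable(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Any stage failure is re-raised with the failing stage named.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    chash = config_hash(config)
    meta = {"config_hash": chash}
    manifest: dict[str, Any] = {
        "tool": f"rtpquant/{__version__}",
        "config_hash": chash,
        "config": config.to_jsonable(),
        "stages": {},
    }
    opts = config.options
    stage = "load"
    try:
        truth = None
        if config.simulate is not None:
            stage = "simulate"
            sim_cfg = SimConfig.from_mapping({"seed": config.seed, **config.simulate})
            truth, bundle = simulate_bundle(sim_cfg)
            write_bundle(bundle, os.path.join(config.output_dir, "bundle"))
            transitions, spikes, samples, tpm = (
                bundle.transitions, bundle.spikes, bundle.samples, bundle.tpm,
            )
            manifest["stages"]["simulate"] = {
                "n_genes": len(truth.gene_ids),
                "n_samples": len(samples),
                "n_transition_rows": len(transitions),
                "n_removed_gene_sample_pairs": len(bundle.removed_pairs),
            }
        else:
            transitions = qio.read_transition_report(config.inputs["transitions"])
            spikes = qio.read_spike_table(config.inputs["spikes"])
            samples = qio.read_sample_sheet(config.inputs["samples"])
            tpm = qio.read_tpm_matrix(config.inputs["tpm"])

        stage = "validate"
        qio.validate_bundle(transitions, spikes, samples, tpm,
                            histone_genes=opts["histone_genes"])

        stage = "quantify-peptides"
        ratio_cfg = prm.RatioConfig(policy=opts["policy"], min_fragments=opts["min_fragments"])
        ratios = prm.peptide_ratios(transitions, ratio_cfg)
        histone_set = set(opts["histone_genes"])
        target_ratios = ratios[~ratios["gene_id"].isin(histone_set)]
        all_samples = list(samples["sample_id"])
        all_genes = sorted(set(transitions["gene_id"].unique()) - histone_set)
        kept, exclusions = prm.apply_quantifiability_filters(
            target_ratios, all_samples, all_genes,
            gene_min_sample_fraction=opts["gene_min_sample_fraction"],
        )
        qio.write_result_table(ratios, os.path.join(config.output_dir, "peptide_ratios.tsv"), meta)
        qio.write_result_table(exclusions, os.path.join(config.output_dir, "exclusions.tsv"), meta)
        manifest["stages"]["quantify-peptides"] = {
            "policy": opts["policy"],
            "n_peptide_ratios": len(ratios),
            "n_genes_in": len(all_genes),
            "n_genes_excluded": len(exclusions),
            "excluded_genes": exclusions["gene_id"].tolist(),
        }

        stage = "cell-count"
        mode = opts["cellcount_mode"]
        if mode == "auto":
            has_counted = (samples["sample_class"] == "cell_line").any()
            mode = "calibrated" if has_counted else "constant"
        model = cellcount.CellCountModel(
            dna_pg_per_cell=opts["dna_pg_per_cell"],
            histones_per_cell=opts["histones_per_cell"],
            mode=mode,
            histone_genes=tuple(opts["histone_genes"]),
        )
        amounts = cellcount.histone_amounts(ratios, spikes, model.histone_genes)
        cells, fitted = cellcount.cells_from_histones(
            amounts, model, samples, allow_missing_histones=opts["allow_missing_histones"]
        )
        cells = cellcount.normalization_factors(cells, samples)
        qio.write_result_table(cells, os.path.join(config.output_dir, "cell_counts.tsv"), meta)
        manifest["stages"]["cell-count"] = {
            "mode": mode,
            "calibration_factor": fitted.calibration_factor,
            "n_replicates": len(cells),
        }

        stage = "copy-number"
        pep_copies = copies_mod.peptide_copies(kept, spikes, cells)
        matrix, provenance = copies_mod.protein_copies(pep_copies, rollup=opts["rollup"])
        qio.write_result_table(
            matrix, os.path.join(config.output_dir, "copy_numbers.tsv"), meta, index=True
        )
        qio.write_result_table(
            provenance, os.path.join(config.output_dir, "copy_number_provenance.tsv"), meta
        )
        manifest["stages"]["copy-number"] = {
            "rollup": opts["rollup"],
            "n_genes": int(matrix.shape[0]),
            "n_samples": int(matrix.shape[1]),
            "n_defined_entries": int(np.isfinite(matrix.to_numpy()).sum()),
        }

        stage = "rtp"
        ratios_gs, tally = rtp_mod.rtp_ratios(matrix, tpm)
        gene_table = rtp_mod.gene_rtp(
            ratios_gs, min_samples=opts["min_samples"], central=opts["central"]
        )
        gene_corr = rtp_mod.gene_correlations(matrix, tpm)
        prediction = rtp_mod.predict_loo(matrix, tpm)
        qio.write_result_table(
            gene_table.join(gene_corr),
            os.path.join(config.output_dir, "rtp_table.tsv"), meta, index=True,
        )
        qio.write_result_table(
            prediction.predicted, os.path.join(config.output_dir, "predictions.tsv"),
            meta, index=True,
        )
        qio.write_result_table(
            prediction.sample_stats,
            os.path.join(config.output_dir, "sample_correlations.tsv"), meta, index=True,
        )
        manifest["stages"]["rtp"] = {"tally": tally, **prediction.summary}

        if truth is not None:
            est = gene_table.loc[gene_table["usable"], "rtp_central"]
            common = est.index.intersection(truth.true_rtp.index)
            err = np.abs(np.log10(est[common] / truth.true_rtp[common]))
            manifest["stages"]["rtp"]["recovery"] = {
                "n_genes": int(len(common)),
                "median_abs_log10_error": float(err.median()) if len(common) else None,
                "max_abs_log10_error": float(err.max()) if len(common) else None,
            }

        if config.cv["enabled"]:
            stage = "cv"
            result = robustness.cv_curve(
                matrix, tpm,
                sizes=config.cv["sizes"],
                n_predictions_per_size=config.cv["n_predictions_per_size"],
                seed=config.seed,
                count=config.cv["count"],
            )
            summary = robustness.summarize_cv(result)
            qio.write_result_table(
                summary, os.path.join(config.output_dir, "cv_summary.tsv"), meta, index=True
            )
            manifest["stages"]["cv"] = {
                "sizes": sorted(result.pearson_by_size),
                "n_predictions_per_size": config.cv["n_predictions_per_size"],
                "count": config.cv["count"],
                "median_at_max_k": float(summary["median"].iloc[-1]),
            }
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest_path = os.path.join(config.output_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    log.info("pipeline complete; manifest at %s", manifest_path)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
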