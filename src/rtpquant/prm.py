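"""Fragment -> peptide light/heavy ratio rollup and quantifiability filters.

A fragment yields a ratio only when both isotope labels were integrated and
the heavy area is positive; everything else is tallied as unusable, never
raised. Peptide ratios combine usable fragments either by the robust default
(median of per-fragment ratios) or by summed areas (sum light / sum heavy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rtpquant.errors import ConfigError

POLICIES = ("median_of_fragments", "sum_areas")

_KEY = ["gene_id", "peptide_seq", "sample_id", "replicate_id"]


@dataclass(frozen=True)
class RatioConfig:
    """Options for the fragment->peptide rollup."""

    policy: str = "median_of_fragments"
    min_fragments: int = 1

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ConfigError(f"policy must be one of {POLICIES}, got {self.policy!r}")
        if self.min_fragments < 1:
            raise ConfigError(f"min_fragments must be >= 1, got {self.min_fragments}")


def fragment_ratios(transitions: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fragment light/heavy ratios.

    Parameters
    ----------
    transitions : DataFrame
        Validated transition frame (see :mod:`rtpquant.io`).

    Returns
    -------
    ratios : DataFrame
        Columns ``gene_id, peptide_seq, sample_id, replicate_id,
        fragment_ion, light_area, heavy_area, ratio``.
    unusable : DataFrame
        Fragments skipped because a label was absent or the heavy area was
        zero; columns as above plus ``reason``.
    """
    wide = transitions.pivot_table(
        index=_KEY + ["fragment_ion"],
        columns="label",
        values="area",
        aggfunc="first",
    ).reindex(columns=["light", "heavy"]).reset_index()
    wide.columns.name = None
    wide = wide.rename(columns={"light": "light_area", "heavy": "heavy_area"})

    no_light = wide["light_area"].isna()
    no_heavy = wide["heavy_area"].isna()
    zero_heavy = wide["heavy_area"] == 0
    usable = ~(no_light | no_heavy | zero_heavy)

    unusable = wide[~usable].copy()
    unusable["reason"] = np.select(
        [no_heavy[~usable], zero_heavy[~usable].fillna(False)],
        ["heavy_absent", "heavy_zero"],
        default="light_absent",
    )

    ratios = wide[usable].copy()
    ratios["ratio"] = ratios["light_area"] / ratios["heavy_area"]
    return ratios.reset_index(drop=True), unusable.reset_index(drop=True)


def peptide_ratios(transitions: pd.DataFrame, config: RatioConfig | None = None) -> pd.DataFrame:
    """Roll fragment-level areas up to one light/heavy ratio per peptide
    per (sample, replicate).

    Under ``median_of_fragments`` the peptide ratio is the median of usable
    per-fragment ratios; under ``sum_areas`` it is the ratio of summed light
    to summed heavy areas over the same usable fragments. Peptides with fewer
    than ``min_fragments`` usable fragments are left unquantified (no row).

    Returns a DataFrame with columns ``gene_id, peptide_seq, sample_id,
    replicate_id, ratio, n_fragments_used``.
    """
    config = config or RatioConfig()
    ratios, _ = fragment_ratios(transitions)
    if ratios.empty:
        return pd.DataFrame(columns=_KEY + ["ratio", "n_fragments_used"])

    grouped = ratios.groupby(_KEY, sort=True)
    if config.policy == "median_of_fragments":
        agg = grouped.agg(
            ratio=("ratio", "median"), n_fragments_used=("ratio", "size")
        ).reset_index()
    else:  # sum_areas
        agg = grouped.agg(
            light=("light_area", "sum"),
            heavy=("heavy_area", "sum"),
            n_fragments_used=("ratio", "size"),
        ).reset_index()
        agg["ratio"] = agg["light"] / agg["heavy"]
        agg = agg.drop(columns=["light", "heavy"])

    agg = agg[agg["n_fragments_used"] >= config.min_fragments]
    return agg[_KEY + ["ratio", "n_fragments_used"]].reset_index(drop=True)


def apply_quantifiability_filters(
    ratios: pd.DataFrame,
    all_samples: list[str],
    all_genes: list[str] | None = None,
    gene_min_sample_fraction: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes that could not be quantified broadly enough.

    A gene counts as quantified in a sample if it has at least one peptide
    ratio there (any replicate). Genes quantified in fewer than
    ``gene_min_sample_fraction`` of ``all_samples`` are removed *globally* —
    the default fraction of 1.0 reproduces whole-gene exclusion on any
    unquantifiable sample.

    Parameters
    ----------
    ratios : peptide-ratio frame
    all_samples : the full sample universe the filter is judged against
    all_genes : gene universe; defaults to genes present in ``ratios``.
        Genes with zero ratios anywhere only show up in the exclusion report
        when listed here.

    Returns ``(kept_ratios, exclusion_report)`` where the report has columns
    ``gene_id, reason, missing_samples, n_missing``.
    """
    if not 0 < gene_min_sample_fraction <= 1:
        raise ConfigError(
            f"gene_min_sample_fraction must be in (0, 1], got {gene_min_sample_fraction}"
        )
    genes = list(all_genes) if all_genes is not None else sorted(ratios["gene_id"].unique())
    n_samples = len(all_samples)
    quantified = ratios.groupby("gene_id")["sample_id"].agg(set)

    records = []
    dropped = []
    for gene in genes:
        have = quantified.get(gene, set())
        if len(have) / n_samples < gene_min_sample_fraction:
            missing = sorted(set(all_samples) - have)
            dropped.append(gene)
            records.append(
                {
                    "gene_id": gene,
                    "reason": "unquantified_in_samples",
                    "missing_samples": ";".join(missing),
                    "n_missing": len(missing),
                }
            )
    report = pd.DataFrame(records, columns=["gene_id", "reason", "missing_samples", "n_missing"])
    kept = ratios[~ratios["gene_id"].isin(dropped)].reset_index(drop=True)
    return kept, report
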