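"""Absolute protein copies per cell from peptide ratios, spike amounts and
effective cell numbers.

copies/cell = (light/heavy ratio) x spiked heavy fmol x molecules-per-fmol
              / effective cells of that replicate

followed by a median rollup. Two rollup orders are provided because the
per-replicate and across-replicate medians commute only on symmetric data:

``peptides-first`` (default)
    per replicate take the median over peptides, then the median of those
    replicate values per sample;
``replicates-first``
    per peptide take the median over replicates, then the median over
    peptides.
"""

from __future__ import annotations

import pandas as pd

from rtpquant.errors import ConfigError, ValidationError
from rtpquant.units import MOLECULES_PER_FMOL

ROLLUP_ORDERS = ("peptides-first", "replicates-first")


def peptide_copies(
    ratios: pd.DataFrame,
    spikes: pd.DataFrame,
    cells: pd.DataFrame,
) -> pd.DataFrame:
    """Copies per cell for every quantified peptide in every replicate.

    Parameters
    ----------
    ratios : peptide-ratio frame (gene, peptide, sample, replicate, ratio)
    spikes : spike table with ``heavy_amount_fmol``
    cells : per-(sample, replicate) ``effective_cells``

    Raises :class:`ValidationError` naming the first offending
    (gene, peptide, sample) if a spike entry is missing, or the replicate if
    its cell number is missing or non-positive.
    """
    merged = ratios.merge(
        spikes[["gene_id", "peptide_seq", "sample_id", "heavy_amount_fmol"]],
        on=["gene_id", "peptide_seq", "sample_id"],
        how="left",
        validate="many_to_one",
    )
    if merged["heavy_amount_fmol"].isna().any():
        bad = merged.loc[
            merged["heavy_amount_fmol"].isna(), ["gene_id", "peptide_seq", "sample_id"]
        ].iloc[0]
        raise ValidationError(
            f"no spike amount for (gene={bad.gene_id}, peptide={bad.peptide_seq}, "
            f"sample={bad.sample_id})"
        )
    merged = merged.merge(
        cells[["sample_id", "replicate_id", "effective_cells"]],
        on=["sample_id", "replicate_id"],
        how="left",
        validate="many_to_one",
    )
    if merged["effective_cells"].isna().any() or (merged["effective_cells"] <= 0).any():
        bad = merged.loc[
            merged["effective_cells"].isna() | (merged["effective_cells"] <= 0),
            ["sample_id", "replicate_id"],
        ].iloc[0]
        raise ValidationError(
            f"no positive effective cell number for replicate "
            f"({bad.sample_id}, {bad.replicate_id})"
        )
    merged["copies_per_cell"] = (
        merged["ratio"] * merged["heavy_amount_fmol"] * MOLECULES_PER_FMOL
        / merged["effective_cells"]
    )
    return merged[
        ["gene_id", "peptide_seq", "sample_id", "replicate_id", "copies_per_cell"]
    ]


def protein_copies(
    peptide_level: pd.DataFrame, rollup: str = "peptides-first"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-rollup of peptide copies to a genes x samples matrix.

    Returns
    -------
    matrix : DataFrame
        genes (rows) x samples (columns); NaN where nothing was quantified.
        Genes removed upstream are simply absent.
    provenance : DataFrame
        per (gene, sample): ``n_peptides``, ``n_replicates`` that entered the
        rollup, plus the rollup order used.
    """
    if rollup not in ROLLUP_ORDERS:
        raise ConfigError(f"rollup must be one of {ROLLUP_ORDERS}, got {rollup!r}")

    if rollup == "peptides-first":
        per_rep = (
            peptide_level.groupby(["gene_id", "sample_id", "replicate_id"])["copies_per_cell"]
            .median()
            .reset_index()
        )
        per_sample = (
            per_rep.groupby(["gene_id", "sample_id"])["copies_per_cell"].median().reset_index()
        )
    else:
        per_pep = (
            peptide_level.groupby(["gene_id", "sample_id", "peptide_seq"])["copies_per_cell"]
            .median()
            .reset_index()
        )
        per_sample = (
            per_pep.groupby(["gene_id", "sample_id"])["copies_per_cell"].median().reset_index()
        )

    matrix = per_sample.pivot(index="gene_id", columns="sample_id", values="copies_per_cell")
    matrix.index.name = "gene_id"
    matrix.columns.name = None

    prov = (
        peptide_level.groupby(["gene_id", "sample_id"])
        .agg(
            n_peptides=("peptide_seq", "nunique"),
            n_replicates=("replicate_id", "nunique"),
        )
        .reset_index()
    )
    prov["rollup"] = rollup
    return matrix.sort_index(), prov
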