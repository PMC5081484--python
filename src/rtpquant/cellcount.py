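"""Histone-anchored effective cell numbers and normalization factors.

The four core histones (H2A, H2B, H3, H4) are quantified like any other
target; because their copy number per 2N cell tracks DNA content, their
summed abundance is a ruler for how many cells a replicate actually
contained. Two anchoring modes:

``constant``
    cells = histone copies / histones_per_cell, using a fixed
    histones-per-cell constant (default 6.4e7: diploid genome length over a
    200 bp nucleosome repeat, two copies of each core histone per
    nucleosome).
``calibrated``
    the same raw estimate rescaled by a factor fitted on cell-line
    replicates with counted cells, removing any dependence on the constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from rtpquant.errors import ConfigError, ValidationError
from rtpquant.units import fmol_to_molecules

DEFAULT_HISTONE_GENES = ("H2A", "H2B", "H3", "H4")

#: pg of DNA per diploid human cell, as used for the DNA-mass cell proxy.
DEFAULT_DNA_PG_PER_CELL = 3.59

DEFAULT_HISTONES_PER_CELL = 6.4e7


@dataclass
class CellCountModel:
    dna_pg_per_cell: float = DEFAULT_DNA_PG_PER_CELL
    histones_per_cell: float = DEFAULT_HISTONES_PER_CELL
    mode: str = "constant"
    calibration_factor: float | None = None
    histone_genes: tuple[str, ...] = field(default=DEFAULT_HISTONE_GENES)

    def __post_init__(self):
        if self.dna_pg_per_cell <= 0:
            raise ConfigError(f"dna_pg_per_cell must be > 0, got {self.dna_pg_per_cell}")
        if self.histones_per_cell <= 0:
            raise ConfigError(f"histones_per_cell must be > 0, got {self.histones_per_cell}")
        if self.mode not in ("constant", "calibrated"):
            raise ConfigError(f"mode must be 'constant' or 'calibrated', got {self.mode!r}")


def histone_amounts(
    peptide_ratios: pd.DataFrame,
    spikes: pd.DataFrame,
    histone_genes=DEFAULT_HISTONE_GENES,
) -> pd.DataFrame:
    """fmol of each histone per (sample, replicate).

    Per-peptide amount = light/heavy ratio x spiked heavy fmol; a histone's
    amount is the median over its peptides.

    Returns a DataFrame ``sample_id, replicate_id, gene_id, amount_fmol``.
    """
    hist = peptide_ratios[peptide_ratios["gene_id"].isin(histone_genes)]
    merged = hist.merge(
        spikes[["gene_id", "peptide_seq", "sample_id", "heavy_amount_fmol"]],
        on=["gene_id", "peptide_seq", "sample_id"],
        how="left",
        validate="many_to_one",
    )
    if merged["heavy_amount_fmol"].isna().any():
        bad = merged.loc[
            merged["heavy_amount_fmol"].isna(), ["gene_id", "peptide_seq", "sample_id"]
        ].drop_duplicates()
        raise ValidationError(
            f"missing spike amounts for histone peptides: {list(map(tuple, bad.values))[:5]}"
        )
    merged["amount_fmol"] = merged["ratio"] * merged["heavy_amount_fmol"]
    out = (
        merged.groupby(["sample_id", "replicate_id", "gene_id"], sort=True)["amount_fmol"]
        .median()
        .reset_index()
    )
    return out


def cells_from_dna(total_dna_mass_pg: float, model: CellCountModel | None = None) -> float:
    """Cell count implied by a total DNA mass (pg / pg-per-2N-cell)."""
    model = model or CellCountModel()
    if total_dna_mass_pg < 0:
        raise ValueError(f"DNA mass must be >= 0, got {total_dna_mass_pg}")
    return total_dna_mass_pg / model.dna_pg_per_cell


def cells_from_histones(
    amounts: pd.DataFrame,
    model: CellCountModel,
    samples: pd.DataFrame | None = None,
    allow_missing_histones: bool = False,
) -> tuple[pd.DataFrame, CellCountModel]:
    """Effective cell number per (sample, replicate) from histone amounts.

    The histone copy number of a replicate is the median over the four
    histones of fmol x molecules-per-fmol (robust to one aberrant histone).
    In ``constant`` mode cells = copies / histones_per_cell; in
    ``calibrated`` mode that raw estimate is multiplied by
    median(counted_cells / raw_estimate) over cell-line replicates, which
    requires ``samples`` with counted cells.

    By default every histone in ``model.histone_genes`` must be quantified
    in every replicate; pass ``allow_missing_histones=True`` to fall back to
    the median of whichever histones are present.

    Returns ``(cells, fitted_model)`` where ``cells`` has columns
    ``sample_id, replicate_id, histone_copies, effective_cells`` and
    ``fitted_model`` carries the calibration factor actually applied.
    """
    required = set(model.histone_genes)
    per_rep = amounts.groupby(["sample_id", "replicate_id"])

    rows = []
    for (sample, rep), grp in per_rep:
        present = set(grp["gene_id"])
        missing = required - present
        if missing and not allow_missing_histones:
            raise ValidationError(
                f"histone(s) {sorted(missing)} unquantified in replicate "
                f"({sample}, {rep}); pass allow_missing_histones to override"
            )
        if not present:
            raise ValidationError(f"no histones quantified in replicate ({sample}, {rep})")
        copies = float(np.median(fmol_to_molecules(grp["amount_fmol"].to_numpy())))
        rows.append({"sample_id": sample, "replicate_id": rep, "histone_copies": copies})
    cells = pd.DataFrame(rows)
    cells["raw_cells"] = cells["histone_copies"] / model.histones_per_cell

    factor = 1.0
    if model.mode == "calibrated":
        if samples is None:
            raise ConfigError("calibrated mode requires the sample sheet")
        counted = samples.loc[samples["sample_class"] == "cell_line",
                              ["sample_id", "counted_cells"]]
        merged = cells.merge(counted, on="sample_id", how="inner")
        if merged.empty:
            raise ConfigError(
                "calibrated mode requires at least one cell_line sample with counted cells"
            )
        factor = float(np.median(merged["counted_cells"] / merged["raw_cells"]))

    cells["effective_cells"] = cells["raw_cells"] * factor
    cells = cells.drop(columns="raw_cells")
    fitted = replace(model, calibration_factor=factor)
    return cells, fitted


def normalization_factors(cells: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Attach per-replicate normalization factors and tissue cells/mg.

    ``norm_factor`` is 1/effective_cells (the copies-per-cell divisor);
    ``cells_per_mg`` = effective_cells / lysate mass for tissue samples, NaN
    for cell lines. Replicates with zero effective cells are flagged in the
    boolean ``undefined`` column rather than raising.
    """
    out = cells.merge(
        samples[["sample_id", "sample_class", "lysate_mass_mg"]],
        on="sample_id",
        how="left",
        validate="many_to_one",
    )
    out["undefined"] = ~(out["effective_cells"] > 0)
    with np.errstate(divide="ignore"):
        out["norm_factor"] = np.where(
            out["undefined"], np.nan, 1.0 / out["effective_cells"]
        )
    out["cells_per_mg"] = np.where(
        out["sample_class"] == "tissue",
        out["effective_cells"] / out["lysate_mass_mg"],
        np.nan,
    )
    return out.drop(columns=["sample_class", "lysate_mass_mg"])
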