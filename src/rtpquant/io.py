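"""Readers and writers for the four tabular interfaces and for result tables.

External dialects (all plain text):

* transition report — CSV, columns ``Sample, Replicate, Gene, Peptide,
  Fragment, Label, Area`` (Skyline-style export names; remappable);
* spike table — TSV, ``Gene, Peptide, Sample, HeavyAmount_fmol``;
* sample sheet — TSV, ``Sample, Class, Replicates, CountedCells,
  LysateMass_mg`` with replicate ids ``;``-joined;
* TPM matrix — TSV, first column ``Gene``, one column per sample.

Internally everything is a pandas DataFrame with snake_case column names.
Missing endogenous measurements are absent rows, never zero areas; zeros in
TPM are legal and handled downstream. Identifiers are case-sensitive exact
strings.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from rtpquant.errors import SchemaError, ValidationError

#: Canonical internal column order of a transition frame.
TRANSITION_COLUMNS = [
    "sample_id",
    "replicate_id",
    "gene_id",
    "peptide_seq",
    "fragment_ion",
    "label",
    "area",
]

#: Default (Skyline-English-flavoured) header -> internal name mapping.
DEFAULT_TRANSITION_DIALECT: Mapping[str, str] = {
    "Sample": "sample_id",
    "Replicate": "replicate_id",
    "Gene": "gene_id",
    "Peptide": "peptide_seq",
    "Fragment": "fragment_ion",
    "Label": "label",
    "Area": "area",
}

SPIKE_COLUMNS = ["gene_id", "peptide_seq", "sample_id", "heavy_amount_fmol"]
_SPIKE_HEADER = ["Gene", "Peptide", "Sample", "HeavyAmount_fmol"]

SAMPLE_COLUMNS = [
    "sample_id",
    "sample_class",
    "replicate_ids",
    "counted_cells",
    "lysate_mass_mg",
]
_SAMPLE_HEADER = ["Sample", "Class", "Replicates", "CountedCells", "LysateMass_mg"]

_TRANSITION_KEY = TRANSITION_COLUMNS[:6]
LABELS = ("light", "heavy")
SAMPLE_CLASSES = ("cell_line", "tissue")


# ---------------------------------------------------------------------------
# transition report
# ---------------------------------------------------------------------------

def read_transition_report(path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a transition-level quant report (CSV).

    Parameters
    ----------
    path : path-like
    dialect : mapping, optional
        File-header -> internal-name mapping; defaults to
        :data:`DEFAULT_TRANSITION_DIALECT`.

    Returns
    -------
    DataFrame with :data:`TRANSITION_COLUMNS`; one row per integrated
    fragment-ion area.

    Raises
    ------
    SchemaError
        if a required column is missing (named in the message).
    ValidationError
        for non-numeric/negative areas, unknown labels, or duplicate
        (sample, replicate, gene, peptide, fragment, label) keys; messages
        cite 1-based data row numbers.
    """
    dialect = dict(dialect or DEFAULT_TRANSITION_DIALECT)
    raw = pd.read_csv(path, dtype=str)
    missing = [col for col in dialect if col not in raw.columns]
    if missing:
        raise SchemaError(
            f"transition report {path}: missing required column(s) {missing}"
        )
    df = raw.rename(columns=dialect)[TRANSITION_COLUMNS].copy()

    area = pd.to_numeric(df["area"], errors="coerce")
    bad = df.index[area.isna()]
    if len(bad):
        raise ValidationError(
            f"transition report {path}: non-numeric area on data row(s) "
            f"{[int(i) + 1 for i in bad[:10]]}"
        )
    neg = df.index[area < 0]
    if len(neg):
        raise ValidationError(
            f"transition report {path}: negative area on data row(s) "
            f"{[int(i) + 1 for i in neg[:10]]}"
        )
    df["area"] = area.astype(float)

    unknown = set(df["label"].unique()) - set(LABELS)
    if unknown:
        raise ValidationError(
            f"transition report {path}: unknown label(s) {sorted(unknown)}; "
            f"expected one of {list(LABELS)}"
        )
    _check_unique(df, _TRANSITION_KEY, f"transition report {path}")
    return df


def write_transition_report(df: pd.DataFrame, path, dialect: Mapping[str, str] | None = None) -> None:
    """Write a transition frame as CSV in the external dialect."""
    dialect = dict(dialect or DEFAULT_TRANSITION_DIALECT)
    inverse = {v: k for k, v in dialect.items()}
    out = df[TRANSITION_COLUMNS].rename(columns=inverse)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spike table
# ---------------------------------------------------------------------------

def read_spike_table(path) -> pd.DataFrame:
    """Read the heavy-standard spike table (TSV).

    One row per (gene, peptide, sample); ``heavy_amount_fmol`` must be > 0.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(raw, _SPIKE_HEADER, f"spike table {path}")
    df = raw.rename(columns=dict(zip(_SPIKE_HEADER, SPIKE_COLUMNS)))[SPIKE_COLUMNS].copy()
    amount = pd.to_numeric(df["heavy_amount_fmol"], errors="coerce")
    if amount.isna().any() or (amount <= 0).any():
        bad = df.index[amount.isna() | (amount <= 0)]
        raise ValidationError(
            f"spike table {path}: heavy amount must be a positive number "
            f"(data row(s) {[int(i) + 1 for i in bad[:10]]})"
        )
    df["heavy_amount_fmol"] = amount.astype(float)
    _check_unique(df, SPIKE_COLUMNS[:3], f"spike table {path}")
    return df


def write_spike_table(df: pd.DataFrame, path) -> None:
    out = df[SPIKE_COLUMNS].rename(columns=dict(zip(SPIKE_COLUMNS, _SPIKE_HEADER)))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet (TSV).

    ``replicate_ids`` is parsed from a ``;``-joined field. Cell-line entries
    must carry ``counted_cells``; tissue entries must carry
    ``lysate_mass_mg``. The unused field may be empty and reads as NaN.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(raw, _SAMPLE_HEADER, f"sample sheet {path}")
    df = raw.rename(columns=dict(zip(_SAMPLE_HEADER, SAMPLE_COLUMNS)))[SAMPLE_COLUMNS].copy()

    _check_unique(df, ["sample_id"], f"sample sheet {path}")
    unknown = set(df["sample_class"].unique()) - set(SAMPLE_CLASSES)
    if unknown:
        raise ValidationError(
            f"sample sheet {path}: unknown class(es) {sorted(unknown)}; "
            f"expected one of {list(SAMPLE_CLASSES)}"
        )
    df["replicate_ids"] = df["replicate_ids"].map(
        lambda s: tuple(x for x in str(s).split(";") if x) if pd.notna(s) else ()
    )
    if (df["replicate_ids"].map(len) == 0).any():
        bad = df.loc[df["replicate_ids"].map(len) == 0, "sample_id"].tolist()
        raise ValidationError(f"sample sheet {path}: sample(s) {bad} list no replicates")
    df["counted_cells"] = pd.to_numeric(df["counted_cells"], errors="coerce")
    df["lysate_mass_mg"] = pd.to_numeric(df["lysate_mass_mg"], errors="coerce")

    cl = df["sample_class"] == "cell_line"
    if df.loc[cl, "counted_cells"].isna().any():
        bad = df.loc[cl & df["counted_cells"].isna(), "sample_id"].tolist()
        raise ValidationError(
            f"sample sheet {path}: cell_line sample(s) {bad} lack CountedCells"
        )
    ts = df["sample_class"] == "tissue"
    if df.loc[ts, "lysate_mass_mg"].isna().any():
        bad = df.loc[ts & df["lysate_mass_mg"].isna(), "sample_id"].tolist()
        raise ValidationError(
            f"sample sheet {path}: tissue sample(s) {bad} lack LysateMass_mg"
        )
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    out = df[SAMPLE_COLUMNS].copy()
    out["replicate_ids"] = out["replicate_ids"].map(";".join)
    out = out.rename(columns=dict(zip(SAMPLE_COLUMNS, _SAMPLE_HEADER)))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TPM matrix
# ---------------------------------------------------------------------------

def read_tpm_matrix(path) -> pd.DataFrame:
    """Read a genes x samples TPM matrix (TSV, first column ``Gene``)."""
    df = pd.read_csv(path, sep="\t", dtype={"Gene": str})
    if df.columns[0] != "Gene":
        raise SchemaError(f"TPM matrix {path}: first column must be 'Gene'")
    df = df.set_index("Gene")
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"TPM matrix {path}: duplicate gene id(s) {dup}")
    values = df.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        raise ValidationError(f"TPM matrix {path}: non-numeric entries present")
    if (values < 0).any().any():
        raise ValidationError(f"TPM matrix {path}: negative TPM entries present")
    return values.astype(float)


def write_tpm_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "Gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# cross-file validation
# ---------------------------------------------------------------------------

def validate_bundle(
    transitions: pd.DataFrame,
    spikes: pd.DataFrame,
    samples: pd.DataFrame,
    tpm: pd.DataFrame,
    histone_genes: Iterable[str] = (),
) -> None:
    """Cross-check the four tables of a measurement bundle.

    Verifies that sample ids agree across files, that every measured
    (gene, peptide, sample) has a spike entry, that replicate ids are
    declared, and that every non-histone measured gene has a TPM row.
    Histone anchor genes are exempt from the TPM requirement.

    Raises :class:`ValidationError` listing the offending difference.
    """
    sheet_samples = set(samples["sample_id"])
    trans_samples = set(transitions["sample_id"].unique())
    if trans_samples - sheet_samples:
        raise ValidationError(
            "samples present in transitions but not in the sample sheet: "
            f"{sorted(trans_samples - sheet_samples)}"
        )
    tpm_samples = set(tpm.columns)
    if tpm_samples != sheet_samples:
        raise ValidationError(
            "sample sets differ between TPM matrix and sample sheet: "
            f"only in TPM {sorted(tpm_samples - sheet_samples)}, "
            f"only in sheet {sorted(sheet_samples - tpm_samples)}"
        )

    spike_keys = set(map(tuple, spikes[["gene_id", "peptide_seq", "sample_id"]].values))
    measured = transitions.loc[transitions["label"] == "heavy",
                               ["gene_id", "peptide_seq", "sample_id"]]
    missing_spikes = sorted(set(map(tuple, measured.values)) - spike_keys)
    if missing_spikes:
        raise ValidationError(
            f"no spike entry for measured (gene, peptide, sample): {missing_spikes[:10]}"
        )

    declared = {
        (row.sample_id, rep)
        for row in samples.itertuples()
        for rep in row.replicate_ids
    }
    used = set(map(tuple, transitions[["sample_id", "replicate_id"]].values))
    if used - declared:
        raise ValidationError(
            f"undeclared (sample, replicate) pairs in transitions: {sorted(used - declared)[:10]}"
        )

    histones = set(histone_genes)
    quant_genes = set(transitions["gene_id"].unique()) - histones
    no_tpm = sorted(quant_genes - set(tpm.index))
    if no_tpm:
        raise ValidationError(f"measured genes absent from TPM matrix: {no_tpm[:10]}")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_result_table(df: pd.DataFrame, path, meta: Mapping[str, str] | None = None,
                       index: bool = False) -> None:
    """Write a result TSV with a ``#``-commented provenance header line."""
    from rtpquant import __version__

    fields = {"tool": f"rtpquant/{__version__}"}
    fields.update(meta or {})
    header = "# " + " ".join(f"{k}={v}" for k, v in fields.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_result_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _check_unique(df: pd.DataFrame, key: list[str], what: str) -> None:
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValidationError(f"{what}: duplicate key {tuple(first)}")
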