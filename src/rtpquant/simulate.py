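"""Ground-truth parameters and synthetic measurement bundles.

The generator emits exactly the four tables the pipeline reads (transition
report, spike table, sample sheet, TPM matrix) with the statistical
structure the analysis assumes:

* gene-level true RTP factors drawn log-uniform over a ~3-decade range;
* per-gene TPM locations log-uniform, per-sample TPM log-normal around them;
* true copies per cell = RTP x TPM x multiplicative log-normal noise;
* heavy fragment areas proportional to the spiked fmol times a fixed
  per-fragment response factor, light areas = heavy x true light/heavy
  ratio x per-fragment log-normal noise;
* four histone anchor genes whose light signal tracks the true cell count
  of each replicate (never subject to missingness);
* whole-gene-in-sample missingness at a configurable rate.

All randomness flows from one integer seed fanned out into named
substreams, so identical (config, seed) gives a bit-identical bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from rtpquant import io as qio
from rtpquant.cellcount import DEFAULT_HISTONE_GENES
from rtpquant.errors import ConfigError
from rtpquant.units import MOLECULES_PER_FMOL

#: arbitrary instrument response: integrated area units per fmol on column
AREA_PER_FMOL = 1.0e4

_AMINO = "ACDEFGHILNPQSTVWY"  # no K/R/M interior: tryptic, methionine-free


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named deterministic substream of the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed)] + [ord(ch) for ch in stream])
    )


@dataclass
class SimConfig:
    """Shape and noise parameters of the synthetic study.

    Defaults emulate a 55-gene panel measured across nine cell lines and
    eleven tissues in triplicate, with 1-5 proteotypic peptides per gene.
    """

    n_genes: int = 55
    n_cell_lines: int = 9
    n_tissues: int = 11
    n_replicates: int = 3
    rtp_log10_range: tuple[float, float] = (math.log10(200.0), math.log10(220000.0))
    tpm_gene_mean_log10_range: tuple[float, float] = (0.0, 3.0)
    tpm_sample_sd_log10: float = 0.4
    copy_noise_sd_log10: float = 0.12
    fragment_noise_sd_log10: float = 0.05
    peptide_count_distribution: dict[int, int] = field(
        default_factory=lambda: {1: 24, 2: 13, 3: 11, 4: 5, 5: 2}
    )
    fragments_per_peptide: tuple[int, int] = (3, 6)
    missing_fraction: float = 0.02
    cells_per_cellline_sample: float = 1.0e6
    tissue_cell_range_fold: float = 30.0
    histones_per_cell: float = 6.4e7
    histone_genes: tuple[str, ...] = DEFAULT_HISTONE_GENES
    tissue_lysate_mass_mg: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigError(f"n_genes must be >= 0, got {self.n_genes}")
        if self.n_cell_lines + self.n_tissues < 1:
            raise ConfigError("n_cell_lines + n_tissues must be >= 1")
        if self.n_replicates < 1:
            raise ConfigError(f"n_replicates must be >= 1, got {self.n_replicates}")
        total = sum(self.peptide_count_distribution.values())
        if total != self.n_genes:
            raise ConfigError(
                "peptide_count_distribution sums to "
                f"{total}, expected n_genes={self.n_genes}"
            )
        if any(k < 1 for k in self.peptide_count_distribution):
            raise ConfigError("peptide_count_distribution keys must be >= 1")
        for name in ("tpm_sample_sd_log10", "copy_noise_sd_log10", "fragment_noise_sd_log10"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigError(
                f"missing_fraction must be in [0, 1), got {self.missing_fraction}"
            )
        lo, hi = self.fragments_per_peptide
        if not 1 <= lo <= hi:
            raise ConfigError(f"fragments_per_peptide invalid: {self.fragments_per_peptide}")
        for name in ("cells_per_cellline_sample", "tissue_cell_range_fold",
                     "histones_per_cell", "tissue_lysate_mass_mg"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown simulate option(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("rtp_log10_range", "tpm_gene_mean_log10_range",
                    "fragments_per_peptide", "histone_genes"):
            if key in kwargs and isinstance(kwargs[key], (list, tuple)):
                kwargs[key] = tuple(kwargs[key])
        if "peptide_count_distribution" in kwargs:
            kwargs["peptide_count_distribution"] = {
                int(k): int(v) for k, v in kwargs["peptide_count_distribution"].items()
            }
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Generative parameters behind one synthetic bundle."""

    gene_ids: list[str]
    peptides: pd.DataFrame            # gene_id, peptide_seq (histones included)
    samples: pd.DataFrame             # sample-sheet frame (io.SAMPLE_COLUMNS)
    true_rtp: pd.Series               # per gene, copies per TPM unit
    true_tpm: pd.DataFrame            # gene x sample
    true_copies: pd.DataFrame         # gene x sample, copies per cell
    true_cells: pd.DataFrame          # sample_id, replicate_id, cells
    spikes: pd.DataFrame              # spike table incl. histone peptides
    histone_genes: tuple[str, ...]


@dataclass
class Bundle:
    """One complete synthetic measurement set (the four pipeline inputs)."""

    transitions: pd.DataFrame
    spikes: pd.DataFrame
    samples: pd.DataFrame
    tpm: pd.DataFrame
    removed_pairs: pd.DataFrame       # gene_id, sample_id blanked by missingness


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _peptide_seq(rng: np.random.Generator, length: int = 9) -> str:
    body = "".join(rng.choice(list(_AMINO), size=length))
    return body + rng.choice(["K", "R"])


def generate_truth(config: SimConfig) -> GroundTruth:
    """Draw all generative parameters for one synthetic study."""
    config.validate()
    rng = _rng(config.seed, "truth")

    gene_ids = [f"GENE{i + 1:03d}" for i in range(config.n_genes)]
    cell_lines = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]
    tissues = [f"TS{i + 1:02d}" for i in range(config.n_tissues)]
    sample_ids = cell_lines + tissues
    replicate_ids = tuple(f"r{i + 1}" for i in range(config.n_replicates))

    # peptides per gene: expand the distribution, shuffle the assignment
    counts = []
    for n_pep, n_genes in sorted(config.peptide_count_distribution.items()):
        counts.extend([n_pep] * n_genes)
    counts = np.array(counts, dtype=int)
    rng.shuffle(counts)
    pep_rows = []
    for gene, n_pep in zip(gene_ids, counts):
        for _ in range(n_pep):
            pep_rows.append({"gene_id": gene, "peptide_seq": _peptide_seq(rng)})
    for hist in config.histone_genes:
        for _ in range(2):  # two peptides per histone anchor
            pep_rows.append({"gene_id": hist, "peptide_seq": _peptide_seq(rng)})
    peptides = pd.DataFrame(pep_rows, columns=["gene_id", "peptide_seq"])

    lo, hi = config.rtp_log10_range
    true_rtp = pd.Series(
        10.0 ** rng.uniform(lo, hi, size=config.n_genes), index=gene_ids, name="true_rtp"
    )

    mlo, mhi = config.tpm_gene_mean_log10_range
    gene_loc = rng.uniform(mlo, mhi, size=config.n_genes)
    tpm_log10 = gene_loc[:, None] + rng.normal(
        0.0, config.tpm_sample_sd_log10, size=(config.n_genes, len(sample_ids))
    )
    gene_index = pd.Index(gene_ids, name="gene_id")
    true_tpm = pd.DataFrame(10.0 ** tpm_log10, index=gene_index, columns=sample_ids)

    copy_noise = rng.normal(
        0.0, config.copy_noise_sd_log10, size=(config.n_genes, len(sample_ids))
    )
    true_copies = true_tpm.mul(true_rtp, axis=0) * 10.0 ** copy_noise

    # cells: counted aliquots for cell lines; tissues spread log-uniformly
    # over the configured fold range below the cell-line aliquot
    cell_rows = []
    fold_log10 = math.log10(config.tissue_cell_range_fold)
    for sample in sample_ids:
        if sample in cell_lines:
            cells = config.cells_per_cellline_sample
        else:
            cells = config.cells_per_cellline_sample * 10.0 ** rng.uniform(-fold_log10, 0.0)
        for rep in replicate_ids:
            cell_rows.append(
                {"sample_id": sample, "replicate_id": rep, "cells": float(cells)}
            )
    true_cells = pd.DataFrame(cell_rows)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sample_class": ["cell_line"] * len(cell_lines) + ["tissue"] * len(tissues),
            "replicate_ids": [replicate_ids] * len(sample_ids),
            "counted_cells": [config.cells_per_cellline_sample] * len(cell_lines)
            + [np.nan] * len(tissues),
            "lysate_mass_mg": [np.nan] * len(cell_lines)
            + [config.tissue_lysate_mass_mg] * len(tissues),
        }
    )

    # one mastermix: the spiked fmol of a peptide is identical in every
    # sample, pitched near the endogenous level in a counted cell aliquot
    ref_cells = config.cells_per_cellline_sample
    spike_rows = []
    for row in peptides.itertuples():
        if row.gene_id in config.histone_genes:
            level = config.histones_per_cell * ref_cells / MOLECULES_PER_FMOL
        else:
            med_copies = float(np.median(true_copies.loc[row.gene_id]))
            level = med_copies * ref_cells / MOLECULES_PER_FMOL
        amount = level * 10.0 ** rng.uniform(-0.3, 0.3)
        for sample in sample_ids:
            spike_rows.append(
                {
                    "gene_id": row.gene_id,
                    "peptide_seq": row.peptide_seq,
                    "sample_id": sample,
                    "heavy_amount_fmol": amount,
                }
            )
    spikes = pd.DataFrame(spike_rows, columns=qio.SPIKE_COLUMNS)

    return GroundTruth(
        gene_ids=gene_ids,
        peptides=peptides,
        samples=samples,
        true_rtp=true_rtp,
        true_tpm=true_tpm,
        true_copies=true_copies,
        true_cells=true_cells,
        spikes=spikes,
        histone_genes=tuple(config.histone_genes),
    )


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def generate_measurements(truth: GroundTruth, config: SimConfig) -> Bundle:
    """Emit the transition-level bundle implied by a ground truth.

    Heavy areas are spike fmol x a per-fragment response factor (fixed
    across samples and replicates, so it cancels in every ratio); light
    areas are heavy x the true light/heavy ratio x per-fragment log-normal
    noise. The true ratio of a target peptide in (sample, replicate) is
    copies x cells / (spike fmol x molecules-per-fmol); for histone anchors
    the copy term is ``histones_per_cell``.
    """
    config.validate()
    rng_frag = _rng(config.seed, "fragments")
    rng_noise = _rng(config.seed, "noise")
    rng_miss = _rng(config.seed, "missing")

    sample_ids = list(truth.samples["sample_id"])
    cells = truth.true_cells.set_index(["sample_id", "replicate_id"])["cells"]
    spike_lookup = truth.spikes.set_index(
        ["gene_id", "peptide_seq", "sample_id"]
    )["heavy_amount_fmol"]

    # fixed per-peptide fragment panels and response factors
    lo, hi = config.fragments_per_peptide
    panels: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for row in truth.peptides.itertuples():
        n_frag = int(rng_frag.integers(lo, hi + 1))
        factors = 10.0 ** rng_frag.uniform(-0.5, 0.5, size=n_frag)
        panels[(row.gene_id, row.peptide_seq)] = [
            (f"y{j + 3}", float(factors[j])) for j in range(n_frag)
        ]

    # whole-gene-in-sample missingness (histone anchors exempt)
    removed = []
    removed_set = set()
    for gene in truth.gene_ids:
        for sample in sample_ids:
            if rng_miss.uniform() < config.missing_fraction:
                removed.append({"gene_id": gene, "sample_id": sample})
                removed_set.add((gene, sample))
    removed_pairs = pd.DataFrame(removed, columns=["gene_id", "sample_id"])

    replicate_ids = {
        row.sample_id: row.replicate_ids for row in truth.samples.itertuples()
    }

    rows = []
    for (gene, peptide), panel in panels.items():
        is_histone = gene in truth.histone_genes
        for sample in sample_ids:
            spike = float(spike_lookup[(gene, peptide, sample)])
            drop_light = (gene, sample) in removed_set
            for rep in replicate_ids[sample]:
                n_cells = float(cells[(sample, rep)])
                if is_histone:
                    per_cell = config.histones_per_cell
                else:
                    per_cell = float(truth.true_copies.at[gene, sample])
                true_ratio = per_cell * n_cells / (spike * MOLECULES_PER_FMOL)
                noise = 10.0 ** rng_noise.normal(
                    0.0, config.fragment_noise_sd_log10, size=len(panel)
                )
                for (frag, response), eps in zip(panel, noise):
                    heavy = spike * response * AREA_PER_FMOL
                    rows.append((sample, rep, gene, peptide, frag, "heavy", heavy))
                    if not drop_light:
                        rows.append(
                            (sample, rep, gene, peptide, frag, "light",
                             heavy * true_ratio * eps)
                        )
    transitions = pd.DataFrame(rows, columns=qio.TRANSITION_COLUMNS)

    tpm = truth.true_tpm.copy()
    return Bundle(
        transitions=transitions,
        spikes=truth.spikes.copy(),
        samples=truth.samples.copy(),
        tpm=tpm,
        removed_pairs=removed_pairs,
    )


def simulate_bundle(config: SimConfig) -> tuple[GroundTruth, Bundle]:
    """Convenience: truth + measurements in one call."""
    truth = generate_truth(config)
    return truth, generate_measurements(truth, config)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_bundle(bundle: Bundle, directory) -> dict[str, str]:
    """Write the four tables into ``directory``; returns name -> path.

    Files round-trip losslessly through the :mod:`rtpquant.io` readers.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    paths = {
        "transitions": os.path.join(directory, "transitions.csv"),
        "spikes": os.path.join(directory, "spikes.tsv"),
        "samples": os.path.join(directory, "samples.tsv"),
        "tpm": os.path.join(directory, "tpm.tsv"),
    }
    qio.write_transition_report(bundle.transitions, paths["transitions"])
    qio.write_spike_table(bundle.spikes, paths["spikes"])
    qio.write_sample_sheet(bundle.samples, paths["samples"])
    qio.write_tpm_matrix(bundle.tpm, paths["tpm"])
    return paths
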