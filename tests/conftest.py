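import numpy as np
import pandas as pd
import pytest

from rtpquant.pipeline import analyze
from rtpquant.simulate import SimConfig, generate_truth, generate_measurements


@pytest.fixture(scope="session")
def noise_free():
    """Small noise-free study: exact round trips everywhere."""
    cfg = SimConfig(
        n_genes=12,
        n_cell_lines=3,
        n_tissues=3,
        n_replicates=2,
        peptide_count_distribution={1: 6, 2: 4, 3: 2},
        copy_noise_sd_log10=0.0,
        fragment_noise_sd_log10=0.0,
        tpm_sample_sd_log10=0.3,
        missing_fraction=0.0,
        seed=11,
    )
    truth = generate_truth(cfg)
    bundle = generate_measurements(truth, cfg)
    return cfg, truth, bundle


@pytest.fixture(scope="session")
def default_study():
    """Full-size noisy study (55 genes x 20 samples x 3 replicates)."""
    cfg = SimConfig(missing_fraction=0.0, seed=20160)
    truth = generate_truth(cfg)
    bundle = generate_measurements(truth, cfg)
    return cfg, truth, bundle


@pytest.fixture(scope="session")
def default_analysis(default_study):
    cfg, truth, bundle = default_study
    result = analyze(bundle.transitions, bundle.spikes, bundle.samples, bundle.tpm)
    return cfg, truth, bundle, result


def tiny_transitions(rows):
    """Build a transition frame from (sample, rep, gene, pep, frag, label, area) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "replicate_id", "gene_id", "peptide_seq",
            "fragment_ion", "label", "area",
        ],
    )
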