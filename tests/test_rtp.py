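import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rtpquant import rtp as rm
from rtpquant.errors import AlignmentError


def _mat(data, genes, samples):
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"), columns=samples)


# ---------------------------------------------------------------------------
# rtp_ratios
# ---------------------------------------------------------------------------

def test_rtp_simple_division():
    copies = _mat([[4000.0]], ["G1"], ["S1"])
    tpm = _mat([[20.0]], ["G1"], ["S1"])
    ratios, tally = rm.rtp_ratios(copies, tpm)
    assert ratios.loc["G1", "S1"] == 200.0
    assert tally == {"n_tpm_zero": 0, "n_copies_absent": 0, "n_defined": 1}


def test_rtp_elementwise_row():
    copies = _mat([[1000.0, 4000.0, 9000.0]], ["G1"], ["S1", "S2", "S3"])
    tpm = _mat([[10.0, 20.0, 30.0]], ["G1"], ["S1", "S2", "S3"])
    ratios, _ = rm.rtp_ratios(copies, tpm)
    assert list(ratios.loc["G1"]) == [100.0, 200.0, 300.0]


def test_rtp_zero_tpm_absent_and_tallied():
    copies = _mat([[100.0, 100.0]], ["G1"], ["S1", "S2"])
    tpm = _mat([[0.0, 10.0]], ["G1"], ["S1", "S2"])
    ratios, tally = rm.rtp_ratios(copies, tpm)
    assert np.isnan(ratios.loc["G1", "S1"])
    assert tally["n_tpm_zero"] == 1


def test_disjoint_genes_alignment_error():
    copies = _mat([[1.0]], ["G1"], ["S1"])
    tpm = _mat([[1.0]], ["G2"], ["S1"])
    with pytest.raises(AlignmentError):
        rm.rtp_ratios(copies, tpm)


# ---------------------------------------------------------------------------
# gene_rtp
# ---------------------------------------------------------------------------

def test_gene_rtp_median_and_cv():
    ratios = _mat([[100.0, 200.0, 300.0]], ["G1"], ["S1", "S2", "S3"])
    table = rm.gene_rtp(ratios)
    assert table.loc["G1", "rtp_central"] == 200.0
    assert table.loc["G1", "n_samples_used"] == 3


def test_gene_rtp_constant_has_zero_cv():
    ratios = _mat([[5.0, 5.0, 5.0]], ["G1"], ["S1", "S2", "S3"])
    table = rm.gene_rtp(ratios)
    assert table.loc["G1", "rtp_cv"] == 0.0


def test_gene_rtp_cv_oracle():
    vals = [100.0, 100.0, 400.0]
    ratios = _mat([vals], ["G1"], ["S1", "S2", "S3"])
    table = rm.gene_rtp(ratios)
    assert table.loc["G1", "rtp_central"] == 100.0
    expected_cv = np.std(vals, ddof=1) / np.mean(vals)
    assert table.loc["G1", "rtp_cv"] == pytest.approx(expected_cv)


def test_gene_rtp_central_attained_between_middle_order_stats():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(5, 1, size=8)
    ratios = _mat([vals], ["G1"], [f"S{i}" for i in range(8)])
    central = rm.gene_rtp(ratios).loc["G1", "rtp_central"]
    srt = np.sort(vals)
    assert srt[3] <= central <= srt[4]


def test_gene_rtp_min_samples_flags():
    ratios = _mat([[100.0, np.nan, np.nan]], ["G1"], ["S1", "S2", "S3"])
    table = rm.gene_rtp(ratios, min_samples=2)
    assert not table.loc["G1", "usable"]
    assert np.isnan(table.loc["G1", "rtp_central"])


# ---------------------------------------------------------------------------
# gene_correlations
# ---------------------------------------------------------------------------

def test_perfect_proportionality():
    tpm = _mat([[1.0, 2.0, 3.0, 4.0]], ["G1"], list("ABCD"))
    copies = tpm * 250.0
    corr = rm.gene_correlations(copies, tpm)
    assert corr.loc["G1", "pearson_loglog"] == pytest.approx(1.0)
    assert corr.loc["G1", "spearman"] == pytest.approx(1.0)
    assert corr.loc["G1", "r_squared"] == pytest.approx(1.0)


def test_power_law_is_loglog_linear():
    tpm = _mat([[1.0, 2.0, 5.0, 30.0]], ["G1"], list("ABCD"))
    copies = tpm ** 2
    corr = rm.gene_correlations(copies, tpm)
    assert corr.loc["G1", "pearson_loglog"] == pytest.approx(1.0)
    linear_r = np.corrcoef(tpm.loc["G1"], copies.loc["G1"])[0, 1]
    assert linear_r < 1.0 - 1e-9


def test_anti_ordered_spearman():
    tpm = _mat([[1.0, 2.0, 3.0, 4.0]], ["G1"], list("ABCD"))
    copies = _mat([[9.0, 7.0, 5.0, 3.0]], ["G1"], list("ABCD"))
    corr = rm.gene_correlations(copies, tpm)
    assert corr.loc["G1", "spearman"] == pytest.approx(-1.0)


def test_too_few_pairs_gives_nan():
    tpm = _mat([[1.0, 2.0]], ["G1"], ["A", "B"])
    copies = _mat([[1.0, 2.0]], ["G1"], ["A", "B"])
    corr = rm.gene_correlations(copies, tpm)
    assert np.isnan(corr.loc["G1", "pearson_loglog"])


# ---------------------------------------------------------------------------
# predict_loo
# ---------------------------------------------------------------------------

def _toy_study(n_genes=6, n_samples=5, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{j}" for j in range(n_samples)]
    rtp = 10.0 ** rng.uniform(2, 5, n_genes)
    tpm = 10.0 ** rng.uniform(0, 3, (n_genes, n_samples))
    noise = 10.0 ** rng.normal(0, noise_sd, (n_genes, n_samples))
    copies = (tpm * rtp[:, None]) * noise
    return _mat(copies, genes, samples), _mat(tpm, genes, samples)


def test_loo_median_construction():
    # per-sample RTP 100/200/300; the middle sample is predicted with
    # median(100, 300) = 200
    tpm = _mat([[1.0, 1.0, 1.0]], ["G1"], ["S1", "S2", "S3"])
    copies = _mat([[100.0, 200.0, 300.0]], ["G1"], ["S1", "S2", "S3"])
    result = rm.predict_loo(copies, tpm)
    assert result.predicted.loc["G1", "S2"] == 200.0
    assert result.predicted.loc["G1", "S1"] == 250.0  # median(200, 300)


def test_loo_exact_on_noise_free():
    copies, tpm = _toy_study(noise_sd=0.0)
    result = rm.predict_loo(copies, tpm)
    assert np.allclose(result.sample_stats["pearson_loglog"], 1.0)
    assert np.allclose(result.predicted.to_numpy(), copies.to_numpy(), rtol=1e-9)


def test_loo_single_sample_error():
    copies = _mat([[1.0]], ["G1"], ["S1"])
    tpm = _mat([[1.0]], ["G1"], ["S1"])
    with pytest.raises(ValueError):
        rm.predict_loo(copies, tpm)


def test_loo_hygiene_perturbation():
    """Perturbing sample s's copies never changes the factor used for s."""
    copies, tpm = _toy_study(noise_sd=0.1, seed=3)
    base = rm.predict_loo(copies, tpm)
    perturbed = copies.copy()
    perturbed["S0"] = perturbed["S0"] * 137.0
    after = rm.predict_loo(perturbed, tpm)
    pd.testing.assert_series_equal(base.predicted["S0"], after.predicted["S0"])
    # while every other sample's factor does see the perturbation
    assert not np.allclose(base.predicted["S1"], after.predicted["S1"])


def test_scale_equivariance_of_tpm():
    copies, tpm = _toy_study(noise_sd=0.05, seed=7)
    base = rm.predict_loo(copies, tpm)
    scaled = rm.predict_loo(copies, tpm * 7.5)
    pd.testing.assert_frame_equal(base.predicted, scaled.predicted)
    pd.testing.assert_frame_equal(base.sample_stats, scaled.sample_stats)
    r_base, _ = rm.rtp_ratios(copies, tpm)
    r_scaled, _ = rm.rtp_ratios(copies, tpm * 7.5)
    assert np.allclose(r_scaled.to_numpy() * 7.5, r_base.to_numpy())


def test_improvement_over_direct_on_noisy_data():
    copies, tpm = _toy_study(n_genes=25, n_samples=12, noise_sd=0.12, seed=5)
    result = rm.predict_loo(copies, tpm)
    assert (result.summary["median_pearson_loglog"]
            > result.summary["median_direct_pearson_loglog"])


# ---------------------------------------------------------------------------
# pearson test + Fisher Z
# ---------------------------------------------------------------------------

def _manual_pearson_test(x, y, conf=0.95):
    """Textbook oracle: t with n-2 df; CI via Fisher's Z."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    r = np.corrcoef(x, y)[0, 1]
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    z = 0.5 * math.log((1 + r) / (1 - r))
    zq = stats.norm.ppf(0.5 + conf / 2)
    se = 1 / math.sqrt(n - 3)
    return r, p, math.tanh(z - zq * se), math.tanh(z + zq * se)


def test_pearson_test_matches_textbook_formulas():
    rng = np.random.default_rng(12)
    x = rng.normal(size=10)
    y = 0.6 * x + rng.normal(scale=0.8, size=10)
    got = rm.pearson_test(x, y)
    r, p, lo, hi = _manual_pearson_test(x, y)
    assert got["r"] == pytest.approx(r)
    assert got["p"] == pytest.approx(p)
    assert got["ci_low"] == pytest.approx(lo)
    assert got["ci_high"] == pytest.approx(hi)
    assert got["n"] == 10


def test_pearson_test_degenerate_perfect():
    x = np.arange(5.0)
    got = rm.pearson_test(x, 2 * x + 1)
    assert got["r"] == pytest.approx(1.0)
    assert got["ci_low"] == got["ci_high"] == pytest.approx(1.0)


def test_rtp_length_analysis_flat_cv():
    table = pd.DataFrame({
        "rtp_central": [100.0, 200.0, 400.0, 800.0, 1600.0],
        "rtp_cv": [0.3, 0.3, 0.3, 0.3, 0.3],
        "n_samples_used": [5] * 5,
        "usable": [True] * 5,
    }, index=pd.Index([f"G{i}" for i in range(5)], name="gene_id"))
    lengths = pd.Series([100, 200, 300, 400, 500], index=table.index)
    out = rm.rtp_length_analysis(table, lengths)
    assert np.isnan(out["cv_vs_length"]["r"])  # zero variance -> undefined r
    assert out["rtp_vs_length"]["r"] == pytest.approx(1.0)


def test_rtp_length_analysis_skipped_when_sparse():
    table = pd.DataFrame({
        "rtp_central": [1.0, 2.0], "rtp_cv": [0.1, 0.2],
        "n_samples_used": [5, 5], "usable": [True, True],
    }, index=pd.Index(["G1", "G2"], name="gene_id"))
    lengths = pd.Series([10, 20], index=table.index)
    out = rm.rtp_length_analysis(table, lengths)
    assert out == {"cv_vs_length": None, "rtp_vs_length": None}


# ---------------------------------------------------------------------------
# compartment comparison
# ---------------------------------------------------------------------------

def _gene_table(log10_rtp):
    idx = pd.Index([f"G{i}" for i in range(len(log10_rtp))], name="gene_id")
    return pd.DataFrame({
        "rtp_central": 10.0 ** np.asarray(log10_rtp),
        "rtp_cv": 0.1, "n_samples_used": 5, "usable": True,
    }, index=idx)


def test_compartment_identical_groups():
    table = _gene_table([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    comp = pd.DataFrame({"gene_id": ["G0", "G1", "G2"], "compartment": ["nucleus"] * 3})
    out = rm.compartment_comparison(table, comp)
    assert out.loc["nucleus", "t"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc["nucleus", "p"] == pytest.approx(1.0)


def test_compartment_shifted_group_significant():
    rng = np.random.default_rng(4)
    vals = np.concatenate([rng.normal(2, 0.01, 5), rng.normal(3, 0.01, 5)])
    table = _gene_table(vals)
    comp = pd.DataFrame({"gene_id": [f"G{i}" for i in range(5, 10)],
                         "compartment": ["membrane"] * 5})
    out = rm.compartment_comparison(table, comp)
    assert out.loc["membrane", "p"] < 1e-6
    assert out.loc["membrane", "t"] > 0


def test_compartment_matches_manual_pooled_t():
    table = _gene_table([1.0, 1.5, 2.0, 2.2, 2.8, 3.1])
    comp = pd.DataFrame({"gene_id": ["G0", "G1", "G2"], "compartment": ["c"] * 3})
    out = rm.compartment_comparison(table, comp)

    a = np.array([1.0, 1.5, 2.0])
    b = np.array([2.2, 2.8, 3.1])
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    t_manual = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p_manual = 2 * stats.t.sf(abs(t_manual), len(a) + len(b) - 2)
    assert out.loc["c", "t"] == pytest.approx(t_manual)
    assert out.loc["c", "p"] == pytest.approx(p_manual)


def test_compartment_small_group_skipped():
    table = _gene_table([1.0, 2.0, 3.0])
    comp = pd.DataFrame({"gene_id": ["G0"], "compartment": ["lonely"]})
    out = rm.compartment_comparison(table, comp)
    assert bool(out.loc["lonely", "skipped"])
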