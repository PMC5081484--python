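"""Gene-specific RNA-to-protein (RTP) conversion factors and prediction.

The RTP factor of a gene in a sample is copies-per-cell / TPM; the gene's
central factor is the median over samples. Prediction multiplies a sample's
TPM by a factor estimated from the *other* samples (leave-one-out), so the
predicted sample never contributes to its own conversion factor.

Correlation conventions: Pearson between abundance-scale quantities is
computed on log10 values over pairwise-complete strictly positive pairs;
Spearman on raw values with average ranks for ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rtpquant.errors import AlignmentError, ConfigError


# ---------------------------------------------------------------------------
# correlation helpers
# ---------------------------------------------------------------------------

def loglog_pearson(x, y, min_pairs: int = 3) -> float:
    """Pearson r of log10(x) vs log10(y) over pairs where both are finite
    and strictly positive; NaN when fewer than ``min_pairs`` remain."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    if mask.sum() < min_pairs:
        return float("nan")
    lx, ly = np.log10(x[mask]), np.log10(y[mask])
    if lx.std() == 0 or ly.std() == 0:
        return float("nan")
    return float(np.corrcoef(lx, ly)[0, 1])


def rank_spearman(x, y, min_pairs: int = 3) -> float:
    """Spearman rho over pairwise-complete pairs (raw values, average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < min_pairs:
        return float("nan")
    rho = stats.spearmanr(x[mask], y[mask]).statistic
    return float(rho)


def _align(copies: pd.DataFrame, tpm: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = copies.index.intersection(tpm.index)
    if len(genes) == 0:
        raise AlignmentError("copy-number and TPM matrices share no genes")
    samples = copies.columns.intersection(tpm.columns)
    if len(samples) == 0:
        raise AlignmentError("copy-number and TPM matrices share no samples")
    return copies.loc[genes, samples], tpm.loc[genes, samples]


# ---------------------------------------------------------------------------
# RTP ratios
# ---------------------------------------------------------------------------

def rtp_ratios(copies: pd.DataFrame, tpm: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-gene, per-sample RTP = copies / TPM.

    Pairs with TPM == 0 or absent copies yield NaN and are tallied in the
    returned dict (keys ``n_tpm_zero``, ``n_copies_absent``, ``n_defined``).
    """
    c, t = _align(copies, tpm)
    tz = t.to_numpy() == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = c.to_numpy() / np.where(tz, np.nan, t.to_numpy())
    ratios = pd.DataFrame(r, index=c.index, columns=c.columns)
    tally = {
        "n_tpm_zero": int((tz & np.isfinite(c.to_numpy())).sum()),
        "n_copies_absent": int((~np.isfinite(c.to_numpy())).sum()),
        "n_defined": int(np.isfinite(r).sum()),
    }
    return ratios, tally


def gene_rtp(
    ratios: pd.DataFrame, min_samples: int = 2, central: str = "median"
) -> pd.DataFrame:
    """Central RTP and its variability per gene.

    ``rtp_central`` is the median (default) or mean over defined per-sample
    values; ``rtp_cv`` the linear-scale coefficient of variation (sd/mean,
    ddof=1). Genes with fewer than ``min_samples`` defined values are
    flagged (``usable=False``) and get NaN statistics.
    """
    if central not in ("median", "mean"):
        raise ConfigError(f"central must be 'median' or 'mean', got {central!r}")
    rows = []
    for gene, row in ratios.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        n = len(vals)
        if n >= min_samples:
            loc = float(np.median(vals)) if central == "median" else float(np.mean(vals))
            cv = float(np.std(vals, ddof=1) / np.mean(vals)) if n >= 2 else float("nan")
            rows.append((gene, loc, cv, n, True))
        else:
            rows.append((gene, np.nan, np.nan, n, False))
    return pd.DataFrame(
        rows, columns=["gene_id", "rtp_central", "rtp_cv", "n_samples_used", "usable"]
    ).set_index("gene_id")


def gene_correlations(copies: pd.DataFrame, tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene RNA-vs-protein correlation across samples.

    Pearson on log10 (positive pairwise-complete pairs), Spearman on raw
    values, and r^2; NaN with fewer than three usable pairs.
    """
    c, t = _align(copies, tpm)
    rows = []
    for gene in c.index:
        r = loglog_pearson(t.loc[gene], c.loc[gene])
        rho = rank_spearman(t.loc[gene], c.loc[gene])
        rows.append((gene, r, rho, r * r if np.isfinite(r) else np.nan))
    return pd.DataFrame(
        rows, columns=["gene_id", "pearson_loglog", "spearman", "r_squared"]
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# leave-one-out prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    predicted: pd.DataFrame          # gene x sample predicted copies per cell
    sample_stats: pd.DataFrame       # per sample: pearson_loglog, spearman, direct, n_genes
    summary: dict                    # medians across samples


def predict_loo(copies: pd.DataFrame, tpm: pd.DataFrame) -> PredictionResult:
    """Leave-one-out RNA-based prediction of protein copies per cell.

    For every sample ``s``, each gene's conversion factor is the median of
    its RTP values over all other samples; predicted[g, s] = TPM[g, s] x
    that factor. Per-sample statistics compare predictions with measured
    copies across genes; ``direct_pearson_loglog`` is the no-factor baseline
    (TPM vs copies). Genes with no out-of-sample RTP are omitted from that
    sample and tallied in ``n_genes_omitted``.
    """
    c, t = _align(copies, tpm)
    if c.shape[1] < 2:
        raise ValueError("leave-one-out prediction requires at least two samples")
    ratios, _ = rtp_ratios(c, t)
    rmat = ratios.to_numpy(dtype=float)

    predicted = pd.DataFrame(np.nan, index=c.index, columns=c.columns)
    rows = []
    for j, sample in enumerate(c.columns):
        others = np.delete(rmat, j, axis=1)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
            loo = np.nanmedian(others, axis=1)
        n_omitted = int(np.isnan(loo).sum())
        pred = t.iloc[:, j].to_numpy() * loo
        predicted[sample] = pred
        meas = c.iloc[:, j].to_numpy(dtype=float)
        rows.append(
            {
                "sample_id": sample,
                "pearson_loglog": loglog_pearson(pred, meas),
                "spearman": rank_spearman(pred, meas),
                "direct_pearson_loglog": loglog_pearson(t.iloc[:, j], meas),
                "direct_spearman": rank_spearman(t.iloc[:, j], meas),
                "n_genes": int(np.isfinite(pred).sum()),
                "n_genes_omitted": n_omitted,
            }
        )
    sample_stats = pd.DataFrame(rows).set_index("sample_id")
    summary = {
        "median_pearson_loglog": float(sample_stats["pearson_loglog"].median()),
        "median_spearman": float(sample_stats["spearman"].median()),
        "median_direct_pearson_loglog": float(
            sample_stats["direct_pearson_loglog"].median()
        ),
    }
    return PredictionResult(predicted=predicted, sample_stats=sample_stats, summary=summary)


# ---------------------------------------------------------------------------
# auxiliary analyses
# ---------------------------------------------------------------------------

def pearson_test(x, y, conf: float = 0.95) -> dict:
    """Pearson r with a two-sided t-test (n-2 df) and Fisher-Z interval.

    Returns keys ``r, p, ci_low, ci_high, n``. Degenerate r = +-1 yields a
    collapsed interval at r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 paired values, got {n}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)  # r undefined -> NaN
        res = stats.pearsonr(x, y)
    r = float(res.statistic)
    p = float(res.pvalue)
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        zq = stats.norm.ppf(0.5 + conf / 2)
        lo, hi = np.tanh(z - zq * se), np.tanh(z + zq * se)
    return {"r": r, "p": p, "ci_low": float(lo), "ci_high": float(hi), "n": n}


def rtp_length_analysis(gene_table: pd.DataFrame, lengths: pd.Series) -> dict:
    """Correlate per-gene RTP variability and central RTP with protein length.

    ``rtp_cv`` is tested on the linear scale, ``rtp_central`` on log10
    (abundance-scale). Returns ``{'cv_vs_length': ..., 'rtp_vs_length': ...}``
    with :func:`pearson_test` dicts, or ``None`` entries when fewer than
    four genes carry lengths.
    """
    tab = gene_table[gene_table["usable"]].join(lengths.rename("length"), how="inner")
    tab = tab.dropna(subset=["length"])
    out: dict = {"cv_vs_length": None, "rtp_vs_length": None}
    if len(tab) < 4:
        return out
    cv_tab = tab.dropna(subset=["rtp_cv"])
    if len(cv_tab) >= 4:
        out["cv_vs_length"] = pearson_test(cv_tab["rtp_cv"], cv_tab["length"])
    out["rtp_vs_length"] = pearson_test(np.log10(tab["rtp_central"]), tab["length"])
    return out


def compartment_comparison(
    gene_table: pd.DataFrame, compartments: pd.DataFrame
) -> pd.DataFrame:
    """Student's t-test of log10 central RTP: each compartment vs the rest.

    ``compartments`` has columns ``gene_id, compartment`` (a gene may appear
    under several). Equal-variance two-sided test; compartments whose
    in-group or out-group has fewer than two members are reported with
    ``skipped=True``.
    """
    usable = gene_table[gene_table["usable"]]
    logrtp = np.log10(usable["rtp_central"])
    rows = []
    for comp, grp in compartments.groupby("compartment"):
        members = set(grp["gene_id"]) & set(usable.index)
        inside = logrtp[logrtp.index.isin(members)]
        outside = logrtp[~logrtp.index.isin(members)]
        if len(inside) < 2 or len(outside) < 2:
            rows.append(
                {"compartment": comp, "n_in": len(inside), "n_out": len(outside),
                 "t": np.nan, "p": np.nan, "mean_in_log10": np.nan,
                 "mean_out_log10": np.nan, "skipped": True}
            )
            continue
        res = stats.ttest_ind(inside, outside, equal_var=True)
        rows.append(
            {"compartment": comp, "n_in": len(inside), "n_out": len(outside),
             "t": float(res.statistic), "p": float(res.pvalue),
             "mean_in_log10": float(inside.mean()),
             "mean_out_log10": float(outside.mean()), "skipped": False}
        )
    return pd.DataFrame(rows).set_index("compartment")
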