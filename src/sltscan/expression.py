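"""Per-gene TPM from expected counts, and the SL-vs-non-SL comparison.

TPM (transcripts per million) length-normalizes expected read counts:
``tpm_i = (c_i / L_i) / sum_j (c_j / L_j) * 1e6``.  Genes with and without
SL addition sites are compared on their mean TPM across replicates with a
two-sample t-test assuming unequal variances (Welch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def tpm(counts: dict[str, float] | pd.Series,
        lengths: dict[str, int] | pd.Series) -> pd.Series:
    """TPM per gene from expected counts and CDS lengths.

    Genes with zero length are excluded with a warning; all-zero counts are
    an error (no library to normalize).
    """
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing CDS lengths for genes {missing}")
    zero_len = lengths <= 0
    if zero_len.any():
        warnings.warn(f"excluding {int(zero_len.sum())} zero-length genes "
                      "from TPM")
        counts, lengths = counts[~zero_len], lengths[~zero_len]
    if (counts < 0).any():
        raise ValueError("negative expected counts")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        raise ValueError("all expected counts are zero")
    return rates / total * 1e6


def tpm_table(counts_df: pd.DataFrame,
              lengths: dict[str, int] | pd.Series) -> pd.DataFrame:
    """Long-format (gene_id, replicate_id, expected_count) -> wide TPM table
    (genes x replicates), normalized within each replicate."""
    wide = counts_df.pivot_table(index="gene_id", columns="replicate_id",
                                 values="expected_count", fill_value=0.0)
    return wide.apply(lambda col: tpm(col, lengths), axis=0)


def mean_tpm(counts_df: pd.DataFrame,
             lengths: dict[str, int] | pd.Series) -> pd.Series:
    """Arithmetic mean of per-replicate TPM for each gene."""
    return tpm_table(counts_df, lengths).mean(axis=1)


@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def welch_test(group_a, group_b) -> WelchResult:
    """Two-sample t-test assuming unequal variances.

    Computes the Welch statistic and Welch-Satterthwaite degrees of freedom
    in closed form; the two-tailed p-value comes from the t distribution.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0,
                               float(a.mean()), float(b.mean()),
                               a.size, b.size)
        raise ValueError("both groups have zero variance")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p),
                       float(a.mean()), float(b.mean()), a.size, b.size)


def compare_sl_expression(gene_mean_tpm: pd.Series,
                          sl_genes: set[str]) -> WelchResult:
    """Welch test of mean TPM: genes with SL addition sites (group A)
    against genes without (group B)."""
    mask = gene_mean_tpm.index.isin(sl_genes)
    return welch_test(gene_mean_tpm[mask].values,
                      gene_mean_tpm[~mask].values)
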