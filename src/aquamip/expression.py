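"""FPKM-matrix utilities: log transform, co-expression, abundance shares,
and threshold-based differential-expression flagging.

The conventions follow common RNA-seq summary practice for gene-family
surveys: expression heat maps show log2(FPKM+1); co-expressed pairs are
unordered gene pairs whose Pearson correlation across samples exceeds a
threshold (0.8 by convention); "abundance share" is the fraction of the
family's total FPKM contributed by a gene subset; and DE flags combine a
fold-change floor with raw-p and Benjamini-Hochberg FDR ceilings.  The
negative-binomial DE test itself is out of scope - p-values are inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class CoexpressionPair:
    gene_a: str
    gene_b: str
    pearson_r: float


def validate_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """An FPKM matrix is genes x samples, non-negative, unique sample ids."""
    if m.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    if (m.values < 0).any():
        raise ValueError("negative FPKM values")
    return m


def read_matrix(path: str | Path) -> pd.DataFrame:
    """TSV with a header row of sample ids and gene ids in the first column."""
    return validate_matrix(pd.read_csv(path, sep="\t", index_col=0))


def log_transform(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1)."""
    validate_matrix(m)
    return np.log2(m + 1.0)


def zscore_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score of log2(FPKM+1) (heat-map row normalisation)."""
    lm = log_transform(m)
    mu = lm.mean(axis=1)
    sd = lm.std(axis=1, ddof=1).replace(0.0, np.nan)
    return lm.sub(mu, axis=0).div(sd, axis=0)


def coexpression_pairs(m: pd.DataFrame, threshold: float = 0.8) -> list[CoexpressionPair]:
    """All unordered gene pairs with Pearson r strictly above ``threshold``.

    Requires at least 3 samples.  Zero-variance genes cannot carry a
    correlation and are excluded with a warning.
    """
    validate_matrix(m)
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    variances = m.var(axis=1, ddof=1)
    dropped = list(m.index[variances == 0.0])
    if dropped:
        warnings.warn(f"excluding zero-variance genes: {dropped}")
    kept = m.loc[variances > 0.0]
    if len(kept) < 2:
        return []
    r = np.corrcoef(kept.values)
    genes = list(kept.index)
    pairs = []
    for i, j in combinations(range(len(genes)), 2):
        if r[i, j] > threshold:
            pairs.append(CoexpressionPair(genes[i], genes[j], float(r[i, j])))
    return pairs


def abundance_share(
    m: pd.DataFrame,
    gene_subset: list[str],
    sample_subset: list[str] | None = None,
) -> float:
    """Fraction of total FPKM contributed by ``gene_subset`` over the samples."""
    validate_matrix(m)
    if not gene_subset:
        raise ValueError("empty gene subset")
    cols = list(m.columns) if sample_subset is None else list(sample_subset)
    if not cols:
        raise ValueError("empty sample subset")
    total = float(m[cols].values.sum())
    if total == 0.0:
        raise ValueError("all-zero denominator over the named samples")
    return float(m.loc[gene_subset, cols].values.sum()) / total


def de_flag(
    fold_changes: np.ndarray | pd.Series,
    p_values: np.ndarray | pd.Series,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Threshold-based differential-expression flags.

    A gene is flagged when \\|log2 FC\\| >= log2(fc_min), raw p <= fdr_max
    and Benjamini-Hochberg FDR <= fdr_max.  Fold changes are ratios
    (direction encoded by being above 1 or below 1).
    """
    fc = np.asarray(fold_changes, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if fc.shape != p.shape:
        raise ValueError("fold_changes and p_values must align")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values outside [0, 1]")
    if (fc <= 0).any():
        raise ValueError("fold changes must be positive ratios")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    log2fc = np.log2(fc)
    flag = (np.abs(log2fc) >= np.log2(fc_min)) & (p <= fdr_max) & (fdr <= fdr_max)
    index = fold_changes.index if isinstance(fold_changes, pd.Series) else None
    return pd.DataFrame(
        {"fold_change": fc, "log2_fc": log2fc, "p_value": p, "fdr": fdr, "flag": flag},
        index=index,
    )


def two_group_log_ttest(
    m: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Convenience Welch t-test on log2(FPKM+1) between two sample groups.

    Returns fold change (mean FPKM ratio, b over a) and p-value per gene.
    This is a simple screening statistic, not equivalent to a count-based
    negative-binomial test.
    """
    from scipy import stats

    validate_matrix(m)
    la, lb = np.log2(m[group_a] + 1.0), np.log2(m[group_b] + 1.0)
    t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    eps = 1e-9
    fc = (m[group_b].mean(axis=1) + eps) / (m[group_a].mean(axis=1) + eps)
    return pd.DataFrame({"fold_change": fc, "p_value": p}, index=m.index)


__all__ = [
    "CoexpressionPair",
    "abundance_share",
    "coexpression_pairs",
    "de_flag",
    "log_transform",
    "read_matrix",
    "two_group_log_ttest",
    "validate_matrix",
    "zscore_rows",
]
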