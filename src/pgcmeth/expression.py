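"""Differential expression on a gene-level FPKM matrix.

A gene is called differentially expressed between control and KO when

1. its mean FPKM is >= 1 in at least one of the two groups,
2. the group fold change exceeds 4 (strict), computed on group-mean FPKM
   with a 0.1 pseudocount, and
3. a two-sided Welch t-test on log2(FPKM + 0.1) across replicates gives
   p < 0.05.

The matrix is genes x samples; annotated small RNAs (microRNA, snRNA) are
expected to have been excluded upstream.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FPKM_MIN = 1.0
DEFAULT_FOLD_MIN = 4.0
DEFAULT_ALPHA = 0.05
FPKM_PSEUDOCOUNT = 0.1


def read_fpkm_matrix(path) -> pd.DataFrame:
    """Tab-delimited gene x sample FPKM table, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return df


def de_genes(
    matrix: pd.DataFrame,
    group_control: Sequence[str],
    group_ko: Sequence[str],
    fpkm_min: float = DEFAULT_FPKM_MIN,
    fold_min: float = DEFAULT_FOLD_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Genes passing the expression / fold-change / t-test filters.

    Returns one row per DE gene: mean_control, mean_ko, fold_change
    (always >= 1; see direction), p_value, direction ('up'/'down' in KO).
    Requires >= 2 replicates per group for the t-test.
    """
    missing = [s for s in (*group_control, *group_ko) if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    if len(group_control) < 2 or len(group_ko) < 2:
        raise ValueError("need >= 2 replicates per group for the t-test")

    ctrl = matrix[list(group_control)].to_numpy(dtype=float)
    ko = matrix[list(group_ko)].to_numpy(dtype=float)
    mean_c = ctrl.mean(axis=1)
    mean_k = ko.mean(axis=1)

    expressed = (mean_c >= fpkm_min) | (mean_k >= fpkm_min)

    ratio = (mean_k + FPKM_PSEUDOCOUNT) / (mean_c + FPKM_PSEUDOCOUNT)
    fold = np.where(ratio >= 1.0, ratio, 1.0 / ratio)
    big_change = fold > fold_min

    _, p = stats.ttest_ind(
        np.log2(ko + FPKM_PSEUDOCOUNT),
        np.log2(ctrl + FPKM_PSEUDOCOUNT),
        axis=1,
        equal_var=False,
    )
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups

    keep = expressed & big_change & (p < alpha)
    out = pd.DataFrame(
        {
            "gene": matrix.index[keep],
            "mean_control": mean_c[keep],
            "mean_ko": mean_k[keep],
            "fold_change": fold[keep],
            "p_value": p[keep],
            "direction": np.where(ratio[keep] >= 1.0, "up", "down"),
        }
    ).reset_index(drop=True)
    return out
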