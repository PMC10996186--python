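"""Calling differentially methylated 10-kb windows between control and KO.

A window is a DMR when its weighted-level difference (KO - control) exceeds
10 percentage points in magnitude (strict inequality) and a two-sided
Welch t-test across the per-CpG methylation fractions of the sites
informative in both samples gives p < 0.05.  Replicates are pooled before
windowing, so the CpG sites within a window are the replication unit of
the test.

The tested universe is every grid window informative (>= 5 CpGs) in both
samples with at least two shared informative sites; hyper and hypo calls
are disjoint subsets of that universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .regional_methylation import (
    DEFAULT_MIN_CPG,
    DEFAULT_WINDOW_SIZE,
    window_levels,
)

DEFAULT_DELTA_THRESHOLD = 10.0  # percentage points, strict
DEFAULT_ALPHA = 0.05


@dataclass
class DMRSet:
    """Hyper-/hypomethylated windows for one stage contrast.

    ``windows`` holds every tested window with its delta (pp, KO - control),
    p-value and direction ('hyper' / 'hypo' / '.').
    """

    label: str
    windows: pd.DataFrame
    window_size: int = DEFAULT_WINDOW_SIZE
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD
    alpha: float = DEFAULT_ALPHA

    @property
    def hyper(self) -> pd.DataFrame:
        return self.windows.loc[self.windows["direction"] == "hyper"]

    @property
    def hypo(self) -> pd.DataFrame:
        return self.windows.loc[self.windows["direction"] == "hypo"]

    @property
    def universe_size(self) -> int:
        return len(self.windows)

    def hyper_ids(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.hyper[["chrom", "start"]])


def _welch_by_window(merged: pd.DataFrame) -> pd.DataFrame:
    """Vectorized two-sided Welch t-test of per-site fractions, per window.

    Degenerate windows (zero pooled variance): equal means -> p = 1,
    unequal means -> p = 0.
    """
    g = merged.groupby(["chrom", "start"], sort=False)
    agg = g.agg(
        n=("frac_c", "size"),
        mean_c=("frac_c", "mean"),
        var_c=("frac_c", "var"),
        mean_k=("frac_k", "mean"),
        var_k=("frac_k", "var"),
    ).reset_index()
    n = agg["n"].to_numpy(dtype=float)
    vc = agg["var_c"].to_numpy()
    vk = agg["var_k"].to_numpy()
    diff = agg["mean_k"].to_numpy() - agg["mean_c"].to_numpy()
    se2 = vc / n + vk / n
    p = np.empty(len(agg))
    zero = se2 <= 0
    p[zero] = np.where(np.isclose(diff[zero], 0.0), 1.0, 0.0)
    ok = ~zero
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff[ok] / np.sqrt(se2[ok])
        # Welch-Satterthwaite degrees of freedom
        dof = se2[ok] ** 2 / (
            (vc[ok] / n[ok]) ** 2 / (n[ok] - 1) + (vk[ok] / n[ok]) ** 2 / (n[ok] - 1)
        )
    p[ok] = 2.0 * stats.t.sf(np.abs(t), dof)
    agg["p_value"] = p
    agg["n_shared"] = agg.pop("n").astype(int)
    return agg[["chrom", "start", "n_shared", "p_value"]]


def call_dmrs(
    control_calls: pd.DataFrame,
    ko_calls: pd.DataFrame,
    label: str = "KO_vs_control",
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_cpg: int = DEFAULT_MIN_CPG,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    exclude_contigs=(),
) -> DMRSet:
    """Call hyper-/hypomethylated windows between pooled, filtered samples.

    Both samples are windowed on the same fixed grid; a window is tested
    only if informative in both.  delta is the difference of the two
    window weighted levels x 100 (percentage points, KO - control).
    """
    wc = window_levels(control_calls, window_size, min_cpg, exclude_contigs)
    wk = window_levels(ko_calls, window_size, min_cpg, exclude_contigs)
    tested = wc.merge(wk, on=["chrom", "start", "end"], suffixes=("_control", "_ko"))

    # per-site fractions at sites informative in both samples
    shared = control_calls.merge(
        ko_calls, on=["chrom", "pos"], suffixes=("_c", "_k")
    )
    if exclude_contigs is not None and len(exclude_contigs):
        shared = shared.loc[~shared["chrom"].isin(exclude_contigs)]
    shared = shared.assign(
        start=(shared["pos"] - 1) // window_size * window_size,
        frac_c=shared["n_meth_c"] / (shared["n_meth_c"] + shared["n_unmeth_c"]),
        frac_k=shared["n_meth_k"] / (shared["n_meth_k"] + shared["n_unmeth_k"]),
    )
    in_universe = pd.MultiIndex.from_frame(shared[["chrom", "start"]]).isin(
        pd.MultiIndex.from_frame(tested[["chrom", "start"]])
    )
    shared = shared.loc[in_universe]

    if shared.empty:
        pvals = pd.DataFrame(
            {
                "chrom": pd.Series([], dtype=str),
                "start": pd.Series([], dtype=np.int64),
                "n_shared": pd.Series([], dtype=np.int64),
                "p_value": pd.Series([], dtype=float),
            }
        )
    else:
        pvals = _welch_by_window(shared)
    tested = tested.merge(pvals, on=["chrom", "start"], how="left")
    # windows with <2 shared informative sites fall out of the universe
    tested = tested.loc[tested["n_shared"].fillna(0) >= 2].reset_index(drop=True)

    tested["delta"] = (tested["level_ko"] - tested["level_control"]) * 100.0
    significant = tested["p_value"] < alpha
    tested["direction"] = "."
    tested.loc[(tested["delta"] > delta_threshold) & significant, "direction"] = "hyper"
    tested.loc[(tested["delta"] < -delta_threshold) & significant, "direction"] = "hypo"

    cols = [
        "chrom", "start", "end",
        "level_control", "level_ko", "delta",
        "n_cpg_control", "n_cpg_ko", "n_shared",
        "p_value", "direction",
    ]
    return DMRSet(
        label=label,
        windows=tested[cols],
        window_size=window_size,
        delta_threshold=delta_threshold,
        alpha=alpha,
    )


def summarize_dmrs(dmrset: DMRSet) -> dict:
    """Counts of hyper/hypo windows and the total genomic size they span.

    total_size_bp treats every window as a full grid window, so e.g.
    14,395 hypermethylated 10-kb windows span 143.95 Mb.
    """
    n_hyper = len(dmrset.hyper)
    n_hypo = len(dmrset.hypo)
    return {
        "label": dmrset.label,
        "n_total": n_hyper + n_hypo,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "universe_size": dmrset.universe_size,
        "hyper_size_bp": n_hyper * dmrset.window_size,
        "hypo_size_bp": n_hypo * dmrset.window_size,
        "total_size_bp": (n_hyper + n_hypo) * dmrset.window_size,
    }


def dmrset_from_counts(
    n_hyper: int, n_hypo: int, label: str = "", window_size: int = DEFAULT_WINDOW_SIZE
) -> DMRSet:
    """Build a placeholder DMRSet carrying only directions, for count
    arithmetic on published tallies (deltas/p-values are not available)."""
    n = n_hyper + n_hypo
    windows = pd.DataFrame(
        {
            "chrom": ["chrU"] * n,
            "start": np.arange(n, dtype=np.int64) * window_size,
            "end": (np.arange(n, dtype=np.int64) + 1) * window_size,
            "level_control": np.nan,
            "level_ko": np.nan,
            "delta": np.nan,
            "n_cpg_control": 0,
            "n_cpg_ko": 0,
            "n_shared": 0,
            "p_value": np.nan,
            "direction": ["hyper"] * n_hyper + ["hypo"] * n_hypo,
        }
    )
    return DMRSet(label=label, windows=windows, window_size=window_size)


def write_dmr_bed(dmrset: DMRSet, path) -> None:
    """BED6+ of called DMRs: chrom, start, end, direction, delta, p."""
    calls = dmrset.windows.loc[dmrset.windows["direction"] != "."]
    out = calls[["chrom", "start", "end", "direction", "delta", "p_value"]]
    out.to_csv(path, sep="\t", header=False, index=False)
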