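"""Global, fixed-grid windowed, and arbitrary-interval CG methylation levels.

All regional quantities are *weighted* methylation levels: summed methylated
read counts divided by summed total reads over the region's informative CpG
sites.  This is depth-robust, and makes every regional level an exact
count-weighted combination of its constituent sites, so concatenating all
grid windows reproduces the global level exactly.

Windows are a fixed tiling anchored at coordinate 0 of each chromosome,
half-open, identified by (chrom, start) — identical across samples and
stages, which is what makes cross-stage window set algebra meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: grid used throughout the analysis
DEFAULT_WINDOW_SIZE = 10_000
#: windows with fewer informative CpG sites than this are excluded
DEFAULT_MIN_CPG = 5

WINDOW_COLUMNS = ["chrom", "start", "end", "n_cpg", "meth_reads", "total_reads", "level"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) with 0-based coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def global_level(calls: pd.DataFrame, exclude_contigs: Sequence[str] = ()) -> float:
    """Genome-wide weighted CG methylation level.

    ``exclude_contigs`` is used to drop the spike-in conversion control;
    sex chromosomes are kept.
    """
    df = calls
    if exclude_contigs:
        df = df.loc[~df["chrom"].isin(exclude_contigs)]
    total = int((df["n_meth"] + df["n_unmeth"]).sum())
    if total == 0:
        raise ValueError("global methylation level undefined: no retained sites")
    return float(df["n_meth"].sum()) / total


def window_levels(
    calls: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_cpg: int = DEFAULT_MIN_CPG,
    exclude_contigs: Sequence[str] = (),
) -> pd.DataFrame:
    """Weighted methylation level in fixed tiling windows.

    Returns one row per window with >= min_cpg informative sites:
    chrom, start, end, n_cpg, meth_reads, total_reads, level.  The last
    partial window of a chromosome is retained if it passes min_cpg.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    df = calls
    if exclude_contigs:
        df = df.loc[~df["chrom"].isin(exclude_contigs)]
    if df.empty:
        return pd.DataFrame(
            {
                "chrom": pd.Series([], dtype=str),
                "start": pd.Series([], dtype=np.int64),
                "end": pd.Series([], dtype=np.int64),
                "n_cpg": pd.Series([], dtype=np.int64),
                "meth_reads": pd.Series([], dtype=np.int64),
                "total_reads": pd.Series([], dtype=np.int64),
                "level": pd.Series([], dtype=float),
            }
        )
    start = (df["pos"].to_numpy() - 1) // window_size * window_size
    grouped = (
        df.assign(start=start)
        .groupby(["chrom", "start"], as_index=False, sort=False)
        .agg(
            n_cpg=("pos", "size"),
            meth_reads=("n_meth", "sum"),
            total_reads_m=("n_meth", "sum"),
            total_reads_u=("n_unmeth", "sum"),
        )
    )
    grouped["total_reads"] = grouped.pop("total_reads_m") + grouped.pop("total_reads_u")
    grouped = grouped.loc[grouped["n_cpg"] >= min_cpg].copy()
    grouped["end"] = grouped["start"] + window_size
    grouped["level"] = grouped["meth_reads"] / grouped["total_reads"]
    return (
        grouped[WINDOW_COLUMNS]
        .sort_values(["chrom", "start"], kind="stable", ignore_index=True)
    )


def interval_level(
    calls: pd.DataFrame, interval: GenomicInterval, min_cpg: int = 1
) -> float:
    """Weighted level over CpGs falling in one arbitrary interval.

    A CpG at 1-based position pos lies in the 0-based half-open interval
    when pos-1 is in [start, end).  Returns NaN if fewer than ``min_cpg``
    informative sites fall inside.
    """
    sel = calls.loc[
        (calls["chrom"] == interval.chrom)
        & (calls["pos"] - 1 >= interval.start)
        & (calls["pos"] - 1 < interval.end)
    ]
    if len(sel) < min_cpg:
        return float("nan")
    total = int((sel["n_meth"] + sel["n_unmeth"]).sum())
    if total == 0:
        return float("nan")
    return float(sel["n_meth"].sum()) / total


def intersect_windows(*window_tables: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict each window table to the windows informative in all of them.

    Cross-sample comparisons (violin plots, scatterplots, DMR universes)
    use only windows informative in every sample; this applies that
    intersection after replicate pooling.
    """
    if not window_tables:
        return []
    keys = None
    for tab in window_tables:
        ids = pd.MultiIndex.from_frame(tab[["chrom", "start"]])
        keys = ids if keys is None else keys.intersection(ids)
    out = []
    for tab in window_tables:
        ids = pd.MultiIndex.from_frame(tab[["chrom", "start"]])
        out.append(tab.loc[ids.isin(keys)].reset_index(drop=True))
    return out


def write_window_table(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False)


def write_bedgraph(windows: pd.DataFrame, path) -> None:
    """Write window levels as a 4-column bedGraph."""
    windows[["chrom", "start", "end", "level"]].to_csv(
        path, sep="\t", header=False, index=False
    )
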