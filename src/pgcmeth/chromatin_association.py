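"""Histone-mark enrichment on the 10-kb grid and its relation to methylation.

A mark track is a per-window log2 IP/input enrichment score, computed from
library-size-normalized read counts with a pseudocount for stability:

    score_w = log2( (ip_w/IP_total + eps) / (input_w/Input_total + eps) )

where eps is the pseudocount rescaled to proportion units (pc averaged over
the two library sizes), so zero-count windows stay finite and exactly
proportional libraries score 0 everywhere.  Scores live on the same fixed grid as window methylation levels, so window
sets (top-quantile marked windows, DMRs, fate categories) can be compared
directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MARKS = ("H3K9me3", "H3K4me3", "H3K4me1", "H3K27ac", "H3K27me3")

DEFAULT_TOP_QUANTILE = 0.05


@dataclass
class MarkTrack:
    """Per-window enrichment for one histone mark."""

    mark: str
    scores: pd.DataFrame  # chrom, start, end, score

    def window_ids(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.scores[["chrom", "start"]])


def window_enrichment(
    counts: pd.DataFrame, mark: str = "H3K9me3", pseudocount: float = 1.0
) -> MarkTrack:
    """log2 IP/input enrichment per window from raw read counts.

    ``counts`` needs columns chrom, start, end, ip, input.  Both count
    vectors are normalized by their library totals (plus the pseudocount)
    before the ratio, so uniform IP/input coverage scores 0 everywhere.
    """
    for col in ("chrom", "start", "end", "ip", "input"):
        if col not in counts.columns:
            raise ValueError(f"counts table missing column {col!r}")
    ip = counts["ip"].to_numpy(dtype=float)
    inp = counts["input"].to_numpy(dtype=float)
    if ip.sum() <= 0 or inp.sum() <= 0:
        raise ValueError("library sizes must be positive")
    eps = pseudocount * 0.5 * (1.0 / ip.sum() + 1.0 / inp.sum())
    score = np.log2((ip / ip.sum() + eps) / (inp / inp.sum() + eps))
    out = counts[["chrom", "start", "end"]].copy()
    out["score"] = score
    out = out.sort_values(["chrom", "start"], kind="stable", ignore_index=True)
    return MarkTrack(mark=mark, scores=out)


def track_from_scores(scores: pd.DataFrame, mark: str) -> MarkTrack:
    """Wrap a precomputed bedGraph-style score table (chrom,start,end,score)."""
    out = scores[["chrom", "start", "end", "score"]].sort_values(
        ["chrom", "start"], kind="stable", ignore_index=True
    )
    return MarkTrack(mark=mark, scores=out)


def top_quantile_windows(track: MarkTrack, q: float = DEFAULT_TOP_QUANTILE) -> pd.DataFrame:
    """The ceil(q*N) highest-scoring windows of a track.

    Ties at the cutoff are broken by genomic order (the table is kept
    genomically sorted and the score sort is stable), so the selection is
    deterministic.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    n = len(track.scores)
    k = math.ceil(q * n)
    order = np.argsort(-track.scores["score"].to_numpy(), kind="stable")
    picked = track.scores.iloc[order[:k]]
    return picked.sort_values(["chrom", "start"], kind="stable", ignore_index=True)


def _summary(values: np.ndarray) -> dict:
    if values.size == 0:
        return {"n": 0, "median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    return {
        "n": int(values.size),
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
    }


def _subset(table: pd.DataFrame, window_set: pd.DataFrame, col: str) -> np.ndarray:
    ids = pd.MultiIndex.from_frame(table[["chrom", "start"]])
    want = pd.MultiIndex.from_frame(window_set[["chrom", "start"]])
    return table.loc[ids.isin(want), col].to_numpy()


def mark_vs_methylation(
    track: MarkTrack,
    region_set_a: pd.DataFrame,
    region_set_b: pd.DataFrame,
    window_levels_control: pd.DataFrame | None = None,
    window_levels_ko: pd.DataFrame | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Mark-score and methylation-level summaries of two window sets.

    Returns one row per set with n/median/quartiles of the mark score and,
    when window level tables are supplied, of the control and KO levels —
    the numbers a violin-plot comparison of marked vs unmarked regions
    summarizes.  Empty sets produce NaN summaries with a warning.
    """
    rows = []
    for label, wset in zip(labels, (region_set_a, region_set_b)):
        if len(wset) == 0:
            warnings.warn(f"window set {label!r} is empty; summaries undefined", stacklevel=2)
        row = {"set": label}
        row.update(
            {f"score_{k}": v for k, v in _summary(_subset(track.scores, wset, "score")).items()}
        )
        if window_levels_control is not None:
            row.update(
                {
                    f"level_control_{k}": v
                    for k, v in _summary(_subset(window_levels_control, wset, "level")).items()
                }
            )
        if window_levels_ko is not None:
            row.update(
                {
                    f"level_ko_{k}": v
                    for k, v in _summary(_subset(window_levels_ko, wset, "level")).items()
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
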