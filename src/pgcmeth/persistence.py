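"""Fate tracking of hypermethylated windows across developmental stages.

Windows hypermethylated in the KO are followed from E11.5 PGCs through
E13.5 and E16.5 female PGCs to fully grown oocytes (FGO).  Because every
stage's DMRs live on the identical fixed 10-kb grid, persistence is plain
set algebra on window identities (chrom, start): no interval-overlap
fractions are involved.

Each flagged window receives exactly one fate category:

    persistent_to_FGO   hyper at E13.5 and/or E16.5, and again in FGO
    PGC_only            hyper at E13.5 and/or E16.5, but not in FGO
    FGO_only            hyper only in FGO (never in PGCs)
    E11.5_and_FGO       hyper at E11.5 and FGO but at neither mid stage
    lost_after_E11.5    hyper at E11.5 only

Together these partition the union of all flagged windows.  Percentages are
always reported with their denominator; rounding to whole percent happens
only at display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .chromatin_association import MarkTrack, _summary, _subset
from .dmr_calling import DMRSet

STAGE_ORDER = ("E11.5", "E13.5", "E16.5", "FGO")

CATEGORIES = (
    "persistent_to_FGO",
    "PGC_only",
    "FGO_only",
    "E11.5_and_FGO",
    "lost_after_E11.5",
)


@dataclass
class FateTable:
    """Per-window hyper flags per stage, a derived category, and tallies."""

    windows: pd.DataFrame  # chrom, start, hyper@<stage>..., category
    stages: tuple[str, ...]
    counts: dict = field(default_factory=dict)
    percentages: dict = field(default_factory=dict)

    def category_windows(self, category: str) -> pd.DataFrame:
        return self.windows.loc[self.windows["category"] == category, ["chrom", "start"]]


def _hyper_ids(obj) -> pd.MultiIndex:
    if isinstance(obj, DMRSet):
        return obj.hyper_ids()
    return pd.MultiIndex.from_frame(pd.DataFrame(obj)[["chrom", "start"]])


def percentage(count: int, denominator: int) -> float:
    """100*count/denominator, exact; callers round only for display."""
    if denominator == 0:
        return float("nan")
    return 100.0 * count / denominator


def classify_fates(dmr_sets: Mapping[str, "DMRSet | pd.DataFrame"]) -> FateTable:
    """Partition hypermethylated windows by their cross-stage persistence.

    ``dmr_sets`` maps stage labels (subset of E11.5/E13.5/E16.5/FGO) to a
    DMRSet or to a window table with chrom/start columns.  Returns per-window
    flags and category, plus the count/percentage system: windows hyper at
    E11.5 that remained at E13.5 only / E16.5 only / both / were lost, all
    pairwise and triple stage intersections, and FGO-only gains, each with
    its explicit denominator.
    """
    stages = tuple(s for s in STAGE_ORDER if s in dmr_sets)
    extra = set(dmr_sets) - set(stages)
    if extra:
        raise ValueError(f"unknown stage labels: {sorted(extra)}")
    ids = {s: _hyper_ids(dmr_sets[s]) for s in stages}

    universe = None
    for s in stages:
        universe = ids[s] if universe is None else universe.union(ids[s])
    if universe is None or len(universe) == 0:
        windows = pd.DataFrame({"chrom": [], "start": []})
        for s in stages:
            windows[f"hyper@{s}"] = pd.Series([], dtype=bool)
        windows["category"] = pd.Series([], dtype=str)
        return FateTable(windows=windows, stages=stages)

    windows = universe.to_frame(index=False, name=["chrom", "start"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )
    uix = pd.MultiIndex.from_frame(windows[["chrom", "start"]])
    flags = {}
    for s in STAGE_ORDER:
        flags[s] = uix.isin(ids[s]) if s in stages else np.zeros(len(uix), dtype=bool)
        if s in stages:
            windows[f"hyper@{s}"] = flags[s]

    mid = flags["E13.5"] | flags["E16.5"]
    category = np.full(len(windows), "lost_after_E11.5", dtype=object)
    category[mid & flags["FGO"]] = "persistent_to_FGO"
    category[mid & ~flags["FGO"]] = "PGC_only"
    only_fgo = flags["FGO"] & ~mid
    category[only_fgo & flags["E11.5"]] = "E11.5_and_FGO"
    category[only_fgo & ~flags["E11.5"]] = "FGO_only"
    windows["category"] = category

    def n(mask) -> int:
        return int(np.count_nonzero(mask))

    counts = {f"hyper@{s}": n(flags[s]) for s in stages}
    counts.update({f"category:{c}": n(category == c) for c in CATEGORIES})
    counts["union"] = len(windows)
    percentages: dict[str, dict] = {}

    def pct(key, mask, denom_mask, denom_name):
        c, d = n(mask), n(denom_mask)
        counts[key] = c
        percentages[key] = {
            "count": c,
            "denominator": d,
            "denominator_set": denom_name,
            "percent": percentage(c, d),
        }

    e11 = flags["E11.5"]
    if "E11.5" in stages:
        rem13 = e11 & flags["E13.5"] & ~flags["E16.5"]
        rem16 = e11 & flags["E16.5"] & ~flags["E13.5"]
        both = e11 & flags["E13.5"] & flags["E16.5"]
        pct("E11.5_remained_E13.5_only", rem13, e11, "hyper@E11.5")
        pct("E11.5_remained_E16.5_only", rem16, e11, "hyper@E11.5")
        pct("E11.5_remained_both", both, e11, "hyper@E11.5")
        pct("E11.5_remained_total", rem13 | rem16 | both, e11, "hyper@E11.5")
        pct("E11.5_lost", e11 & ~mid, e11, "hyper@E11.5")
        if "FGO" in stages:
            pct("E11.5_also_FGO", e11 & flags["FGO"], e11, "hyper@E11.5")
    if "E13.5" in stages and "E16.5" in stages:
        pct(
            "E13.5_remained_E16.5",
            flags["E13.5"] & flags["E16.5"],
            flags["E13.5"],
            "hyper@E13.5",
        )
    if "FGO" in stages:
        for s in ("E13.5", "E16.5"):
            if s in stages:
                pct(f"{s}_also_FGO", flags[s] & flags["FGO"], flags[s], f"hyper@{s}")
        if "E13.5" in stages and "E16.5" in stages:
            persist = flags["E13.5"] & flags["E16.5"] & flags["FGO"]
            pct("persistent_E13.5_E16.5_FGO_vs_E13.5", persist, flags["E13.5"], "hyper@E13.5")
            pct("persistent_E13.5_E16.5_FGO_vs_E16.5", persist, flags["E16.5"], "hyper@E16.5")
        pct("FGO_only", only_fgo & ~flags["E11.5"], flags["FGO"], "hyper@FGO")

    return FateTable(windows=windows, stages=stages, counts=counts, percentages=percentages)


def delta_matrix(
    stage_levels: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    order_by: MarkTrack | None = None,
) -> pd.DataFrame:
    """Per-window ΔCG (KO - control, percentage points) matrix across stages.

    ``stage_levels`` maps a stage label to its (control, KO) window level
    tables.  Rows are windows (union over stages; NaN where a stage lacks
    the window), ordered by the ``order_by`` mark score descending when
    given — the table behind a heatmap of methylation gain sorted by
    H3K9me3.
    """
    per_stage = {}
    for stage, (ctrl, ko) in stage_levels.items():
        j = ctrl.merge(ko, on=["chrom", "start"], suffixes=("_c", "_k"))
        per_stage[stage] = j.set_index(["chrom", "start"]).eval(
            "(level_k - level_c) * 100"
        )
    mat = pd.DataFrame(per_stage)
    if order_by is not None:
        scores = order_by.scores.set_index(["chrom", "start"])["score"]
        mat = mat.assign(_score=scores.reindex(mat.index)).sort_values(
            "_score", ascending=False, kind="stable"
        )
        mat = mat.drop(columns="_score")
    return mat


def category_profiles(
    fate: FateTable,
    track: MarkTrack,
    fgo_levels_control: pd.DataFrame | None = None,
    fgo_levels_ko: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-fate-category medians/quartiles of mark score and FGO levels.

    Empty categories yield NaN summaries with a warning.
    """
    rows = []
    for cat in CATEGORIES:
        wset = fate.category_windows(cat)
        if len(wset) == 0:
            warnings.warn(f"fate category {cat!r} is empty", stacklevel=2)
        row = {"category": cat}
        row.update(
            {f"score_{k}": v for k, v in _summary(_subset(track.scores, wset, "score")).items()}
        )
        if fgo_levels_control is not None:
            row.update(
                {
                    f"fgo_control_{k}": v
                    for k, v in _summary(_subset(fgo_levels_control, wset, "level")).items()
                }
            )
        if fgo_levels_ko is not None:
            row.update(
                {
                    f"fgo_ko_{k}": v
                    for k, v in _summary(_subset(fgo_levels_ko, wset, "level")).items()
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
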