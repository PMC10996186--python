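"""Genomic-context, repeat-family and ICR characterization of DMRs.

Annotations are BED-backed interval tables:

* repeats — one row per repeat copy, with a family name (e.g. IAPEz-like)
  and a class (LTR / LINE / SINE / satellite / other);
* genes — gene spans plus exon sub-intervals (non-exonic gene bases are
  introns);
* icrs — the 15 named imprinting control regions.

Context categories partition every base of the genome with the precedence
repeat class > exon > intron > intergenic, so proportions over any region
set sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regional_methylation import GenomicInterval, interval_level

REPEAT_CLASSES = ("LTR", "LINE", "SINE", "satellite", "other")
CONTEXT_CATEGORIES = REPEAT_CLASSES + ("exon", "intron", "intergenic")

DEFAULT_MIN_COPIES = 50
DEFAULT_ICR_FOLD_THRESHOLD = 1.3

# per-base label codes; higher-precedence contexts painted last
_CODE = {name: i for i, name in enumerate(("intergenic", "intron", "exon") + REPEAT_CLASSES)}
_NAME = {i: name for name, i in _CODE.items()}


@dataclass
class AnnotationSet:
    """Repeat, gene/exon and ICR annotations on a genome of known sizes."""

    chrom_sizes: Mapping[str, int]
    repeats: pd.DataFrame  # chrom, start, end, family, cls
    genes: pd.DataFrame  # chrom, start, end, name
    exons: pd.DataFrame  # chrom, start, end, gene
    icrs: pd.DataFrame  # chrom, start, end, name

    def __post_init__(self):
        if self.icrs["name"].duplicated().any():
            raise ValueError("ICR names must be unique")

    def family_copy_counts(self) -> pd.Series:
        return self.repeats.groupby("family").size()


# ---------------------------------------------------------------------------
# BED I/O (repeats use name field "family|class"; ICRs/genes a plain name)

def _read_bed(path, names) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def read_repeat_bed(path) -> pd.DataFrame:
    df = _read_bed(path, ["chrom", "start", "end", "name"])
    fam_cls = df["name"].str.split("|", n=1, expand=True)
    df["family"] = fam_cls[0]
    df["cls"] = fam_cls[1].fillna("other")
    return df[["chrom", "start", "end", "family", "cls"]]


def read_named_bed(path) -> pd.DataFrame:
    return _read_bed(path, ["chrom", "start", "end", "name"])


def write_repeat_bed(repeats: pd.DataFrame, path) -> None:
    out = repeats.assign(name=repeats["family"] + "|" + repeats["cls"])
    out[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def write_named_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# genomic context

def _context_labels(annotation: AnnotationSet) -> dict[str, np.ndarray]:
    """Per-base context code arrays, painted in increasing precedence."""
    labels = {
        chrom: np.zeros(size, dtype=np.uint8)
        for chrom, size in annotation.chrom_sizes.items()
    }

    def paint(df: pd.DataFrame, code_of_row):
        for row in df.itertuples(index=False):
            arr = labels.get(row.chrom)
            if arr is None:
                continue
            arr[max(0, row.start): min(len(arr), row.end)] = code_of_row(row)

    paint(annotation.genes, lambda r: _CODE["intron"])
    paint(annotation.exons, lambda r: _CODE["exon"])
    paint(
        annotation.repeats,
        lambda r: _CODE[r.cls if r.cls in REPEAT_CLASSES else "other"],
    )
    return labels


def _category_bases(
    labels: dict[str, np.ndarray], regions: Iterable[GenomicInterval] | None
) -> pd.Series:
    counts = np.zeros(len(_CODE), dtype=np.int64)
    if regions is None:
        for arr in labels.values():
            counts += np.bincount(arr, minlength=len(_CODE))
    else:
        for iv in regions:
            arr = labels.get(iv.chrom)
            if arr is None:
                raise ValueError(f"unknown chromosome {iv.chrom!r}")
            counts += np.bincount(
                arr[iv.start: min(len(arr), iv.end)], minlength=len(_CODE)
            )
    return pd.Series({_NAME[i]: counts[i] for i in range(len(_CODE))})


def _as_intervals(regions) -> list[GenomicInterval]:
    if isinstance(regions, pd.DataFrame):
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in regions.itertuples(index=False)
        ]
    return list(regions)


def context_proportions(regions, annotation: AnnotationSet) -> pd.Series:
    """Base-pair fraction of each context category over a region set.

    ``regions`` is an iterable of GenomicInterval or a DataFrame with
    chrom/start/end columns.  Fractions sum to 1.
    """
    regions = _as_intervals(regions)
    if not regions:
        raise ValueError("context_proportions requires a non-empty region set")
    labels = _context_labels(annotation)
    bases = _category_bases(labels, regions)
    return bases / bases.sum()


def context_fold_enrichment(regions, annotation: AnnotationSet) -> pd.Series:
    """Per-category fold of region proportions over whole-genome proportions.

    Categories absent from the genome yield NaN.
    """
    labels = _context_labels(annotation)
    genome = _category_bases(labels, None)
    genome_prop = genome / genome.sum()
    region_prop = context_proportions(_as_intervals(regions), annotation)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = region_prop / genome_prop
    return fold.where(genome_prop > 0)


# ---------------------------------------------------------------------------
# repeat-family methylation

def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [], []
    for a, b in zip(s, e):
        if out_e and a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.asarray(out_s), np.asarray(out_e)


def _sites_in_intervals(calls: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Subset of call sites falling in any of the (possibly overlapping)
    intervals; each site counted once."""
    picks = []
    for chrom, grp in intervals.groupby("chrom", sort=False):
        sites = calls.loc[calls["chrom"] == chrom]
        if sites.empty:
            continue
        s, e = _merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
        pos0 = sites["pos"].to_numpy() - 1
        idx = np.searchsorted(s, pos0, side="right") - 1
        inside = (idx >= 0) & (pos0 < e[np.clip(idx, 0, None)])
        picks.append(sites.loc[inside])
    if not picks:
        return calls.iloc[0:0]
    return pd.concat(picks)


def _weighted_level(sites: pd.DataFrame) -> float:
    total = int((sites["n_meth"] + sites["n_unmeth"]).sum())
    if total == 0:
        return float("nan")
    return float(sites["n_meth"].sum()) / total


def repeat_family_methylation(
    control_calls: pd.DataFrame,
    ko_calls: pd.DataFrame,
    annotation: AnnotationSet,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> pd.DataFrame:
    """Per-family weighted methylation levels over all genomic copies.

    Families with fewer than ``min_copies`` annotated copies are excluded.
    Returns family, cls, n_copies, level_control, level_ko, delta_pp.
    """
    counts = annotation.family_copy_counts()
    rows = []
    for family, n_copies in counts.items():
        if n_copies < min_copies:
            continue
        fam = annotation.repeats.loc[annotation.repeats["family"] == family]
        lc = _weighted_level(_sites_in_intervals(control_calls, fam))
        lk = _weighted_level(_sites_in_intervals(ko_calls, fam))
        rows.append(
            {
                "family": family,
                "cls": fam["cls"].iloc[0],
                "n_copies": int(n_copies),
                "level_control": lc,
                "level_ko": lk,
                "delta_pp": (lk - lc) * 100.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["family", "cls", "n_copies", "level_control", "level_ko", "delta_pp"],
    )


def rank_hyper_families(
    summaries: pd.DataFrame, delta_threshold: float = 10.0
) -> pd.DataFrame:
    """Families hypermethylated beyond the threshold, ranked by delta descending."""
    hyper = summaries.loc[summaries["delta_pp"] > delta_threshold].copy()
    hyper = hyper.sort_values("delta_pp", ascending=False, kind="stable").reset_index(
        drop=True
    )
    hyper["rank"] = np.arange(1, len(hyper) + 1)
    return hyper


# ---------------------------------------------------------------------------
# imprinting control regions

def icr_methylation(
    control_calls: pd.DataFrame,
    ko_calls: pd.DataFrame,
    annotation: AnnotationSet,
    fold_threshold: float = DEFAULT_ICR_FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Per-ICR levels and KO/control fold increase.

    flagged is True when fold > threshold; the fold is undefined (NaN, with
    fold_defined False) when the control level is 0 or missing.
    """
    rows = []
    for row in annotation.icrs.itertuples(index=False):
        iv = GenomicInterval(row.chrom, int(row.start), int(row.end))
        lc = interval_level(control_calls, iv)
        lk = interval_level(ko_calls, iv)
        defined = np.isfinite(lc) and np.isfinite(lk) and lc > 0
        fold = lk / lc if defined else float("nan")
        rows.append(
            {
                "name": row.name,
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "level_control": lc,
                "level_ko": lk,
                "fold_increase": fold,
                "fold_defined": bool(defined),
                "flagged": bool(defined and fold > fold_threshold),
            }
        )
    return pd.DataFrame(rows)
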