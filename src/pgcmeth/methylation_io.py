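"""Reading, filtering, merging and QC of CpG-level bisulfite call data.

CpG calls are carried as pandas DataFrames with columns

    chrom    chromosome / contig name (str)
    pos      1-based position of the C of the plus strand of the CpG dyad
    n_meth   methylated read count
    n_unmeth unmethylated read count

("coverage-file dialect": the tab-delimited 6-column format
chrom / start / end / %meth / count-methylated / count-unmethylated with
1-based inclusive coordinates, as written by common bisulfite methylation
extractors).  The percent column of input files is never trusted; levels
are always recomputed from the counts.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CALL_COLUMNS = ["chrom", "pos", "n_meth", "n_unmeth"]

#: coverage filter bounds: sites covered by 3-100 reads (inclusive) are kept
DEFAULT_MIN_READS = 3
DEFAULT_MAX_READS = 100

#: replicate-correlation window size (bp)
QC_WINDOW_SIZE = 500_000

STAGES = ("epiblast", "E9.5", "E10.5", "E11.5", "E12.5", "E13.5", "E16.5", "GO", "FGO")
GENOTYPES = ("control", "KO", "WT")
SEXES = ("female", "male", "mixed")


class CoverageParseError(ValueError):
    """A malformed line in a coverage file."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one WGBS library: developmental stage, genotype, sex, replicate."""

    stage: str
    genotype: str
    sex: str = "mixed"
    replicate: str = "r1"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")

    @property
    def label(self) -> str:
        return f"{self.stage}_{self.genotype}_{self.replicate}"


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series([], dtype=str),
            "pos": pd.Series([], dtype=np.int64),
            "n_meth": pd.Series([], dtype=np.int64),
            "n_unmeth": pd.Series([], dtype=np.int64),
        }
    )


def sort_calls(calls: pd.DataFrame) -> pd.DataFrame:
    return calls.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)


def read_coverage_file(path) -> pd.DataFrame:
    """Read a 6-column coverage file (plain or gzipped) into a call table.

    Records are returned sorted by (chrom, pos).  The %meth column is
    discarded; methylation levels are recomputed from counts downstream.

    Raises
    ------
    CoverageParseError
        On a malformed line (wrong column count, non-numeric fields),
        naming the 1-based line number.
    ValueError
        On negative counts.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    chroms: list[str] = []
    pos: list[int] = []
    n_meth: list[int] = []
    n_unmeth: list[int] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CoverageParseError(
                    f"{path}: line {lineno}: expected 6 tab-delimited fields, got {len(fields)}"
                )
            try:
                p = int(fields[1])
                m = int(fields[4])
                u = int(fields[5])
            except ValueError as exc:
                raise CoverageParseError(f"{path}: line {lineno}: {exc}") from None
            if m < 0 or u < 0:
                raise ValueError(f"{path}: line {lineno}: negative read count")
            chroms.append(fields[0])
            pos.append(p)
            n_meth.append(m)
            n_unmeth.append(u)
    if not chroms:
        return _empty_calls()
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(pos, dtype=np.int64),
            "n_meth": np.asarray(n_meth, dtype=np.int64),
            "n_unmeth": np.asarray(n_unmeth, dtype=np.int64),
        }
    )
    return sort_calls(df)


def write_coverage_file(calls: pd.DataFrame, path) -> None:
    """Write a call table as a 6-column coverage file (gzip if path ends .gz)."""
    depth = calls["n_meth"] + calls["n_unmeth"]
    with np.errstate(invalid="ignore"):
        pct = np.where(depth > 0, 100.0 * calls["n_meth"] / depth, 0.0)
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos"],
            "end": calls["pos"],
            "pct": np.round(pct, 6),
            "n_meth": calls["n_meth"],
            "n_unmeth": calls["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def merge_strands(
    calls: pd.DataFrame, cpg_positions: Mapping[str, Sequence[int]]
) -> pd.DataFrame:
    """Collapse plus/minus strand records of each CpG dyad onto the plus strand.

    ``cpg_positions`` maps chromosome name to the sorted plus-strand (C)
    coordinates of known CpG dyads.  A record at position p+1 whose dyad C is
    at p has its counts added to the plus-strand record; records not matching
    any known dyad pass through unchanged.
    """
    if calls.empty:
        return calls.copy()
    parts = []
    for chrom, grp in calls.groupby("chrom", sort=False):
        plus = np.asarray(cpg_positions.get(chrom, ()), dtype=np.int64)
        p = grp["pos"].to_numpy()
        if plus.size:
            is_plus = np.isin(p, plus)
            is_minus = ~is_plus & np.isin(p - 1, plus)
            new_pos = np.where(is_minus, p - 1, p)
        else:
            new_pos = p
        parts.append(grp.assign(pos=new_pos))
    merged = (
        pd.concat(parts, ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=False)[["n_meth", "n_unmeth"]]
        .sum()
    )
    return sort_calls(merged)


def filter_coverage(
    calls: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    max_reads: int = DEFAULT_MAX_READS,
) -> pd.DataFrame:
    """Keep sites covered by min_reads..max_reads reads, bounds inclusive.

    The 3-100 defaults discard unreliable shallow sites and collapsed-repeat
    pileups.  Idempotent.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if max_reads < min_reads:
        raise ValueError("max_reads must be >= min_reads")
    depth = calls["n_meth"] + calls["n_unmeth"]
    return calls.loc[(depth >= min_reads) & (depth <= max_reads)].reset_index(drop=True)


def pool_replicates(
    samples: Iterable[pd.DataFrame],
    min_reads: int = DEFAULT_MIN_READS,
    max_reads: int = DEFAULT_MAX_READS,
) -> pd.DataFrame:
    """Sum per-site read counts across replicate libraries, then re-filter.

    Counts (not levels) are combined, so deep replicates weigh more; the
    coverage filter is re-applied because pooling changes site depths.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("pool_replicates requires at least one sample")
    pooled = (
        pd.concat(samples, ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False, sort=False)[["n_meth", "n_unmeth"]]
        .sum()
    )
    return filter_coverage(sort_calls(pooled), min_reads, max_reads)


def conversion_rate(calls: pd.DataFrame, spikein_contig: str) -> float:
    """Bisulfite conversion rate from the unmethylated spike-in contig.

    Returns 1 - sum(n_meth)/sum(depth) over spike-in sites.  Since the
    spike-in (lambda phage DNA) carries no methylation, every methylated
    call there is a conversion failure.  NaN with a warning if the contig
    has no covered sites.
    """
    spike = calls.loc[calls["chrom"] == spikein_contig]
    total = int((spike["n_meth"] + spike["n_unmeth"]).sum())
    if total == 0:
        warnings.warn(
            f"no covered sites on spike-in contig {spikein_contig!r}; "
            "conversion rate undefined",
            stacklevel=2,
        )
        return float("nan")
    return 1.0 - float(spike["n_meth"].sum()) / total


def replicate_correlation(
    sample_a: pd.DataFrame,
    sample_b: pd.DataFrame,
    window_size: int = QC_WINDOW_SIZE,
    min_cpg: int = 5,
) -> float:
    """Pearson R between two samples' regional methylation levels.

    Levels are weighted (read-count) means in fixed windows; only windows
    with at least ``min_cpg`` informative sites in *both* samples enter the
    correlation.  Symmetric in its arguments.
    """
    from .regional_methylation import window_levels  # local import avoids a cycle

    wa = window_levels(sample_a, window_size=window_size, min_cpg=min_cpg)
    wb = window_levels(sample_b, window_size=window_size, min_cpg=min_cpg)
    joined = wa.merge(wb, on=["chrom", "start"], suffixes=("_a", "_b"))
    if len(joined) < 2:
        raise ValueError(
            f"replicate correlation undefined: only {len(joined)} shared windows"
        )
    r, _ = stats.pearsonr(joined["level_a"], joined["level_b"])
    return float(r)
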