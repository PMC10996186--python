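"""Synthetic toy genome and WGBS/ChIP/RNA data with known planted truth.

The generator emulates the statistical structure the analysis relies on,
at desk scale:

* a toy genome (four 5-Mb chromosomes) with jittered CpG dyads (~1/100 bp)
  and an unmethylated 48.5-kb spike-in contig for conversion QC;
* repeat annotations including an IAP-like LTR family, a LINE-like family,
  a clustered satellite block and background families, plus genes/exons and
  15 imprinting control regions (ICRs);
* a stage trajectory of control methylation baselines tracking PGC
  demethylation (epiblast high -> E11.5-E16.5 near-complete erasure) and
  oocyte de novo methylation (FGO);
* a KO effect: hypermethylation planted preferentially at H3K9me3-marked
  windows (IAP-like + satellite), each planted window carrying a fate
  category (lost after E11.5 / PGC-only / persistent to FGO), plus
  FGO-only hypermethylation at unmarked windows and retention at 5 of the
  15 ICRs;
* beta-binomial read counts (biological overdispersion) at Poisson depths,
  with a bisulfite conversion error inflating apparent methylation.

Every product is deterministic under the master seed; per-sample streams
are derived hierarchically so adding a sample never perturbs another.
Truth tables (planted windows with categories, marked windows, flagged
ICRs) are exposed for end-to-end validation of the analysis modules.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_enrichment import (
    AnnotationSet,
    write_named_bed,
    write_repeat_bed,
)
from .methylation_io import write_coverage_file

# KO - control methylation delta planted per fate category per stage
FATE_SCHEDULE = {
    "lost_after_E11.5": {"E11.5": 0.30},
    "PGC_only": {"E11.5": 0.30, "E13.5": 0.25, "E16.5": 0.25},
    "persistent_to_FGO": {"E11.5": 0.30, "E13.5": 0.25, "E16.5": 0.25, "FGO": 0.30},
    "FGO_only": {"FGO": 0.35},
}


@dataclass(frozen=True)
class RepeatFamilyConfig:
    name: str
    cls: str
    n_copies: int
    copy_len: int
    clustered: bool = False


@dataclass
class SyntheticGenomeSpec:
    """Parameters of the toy genome and of the planted biology."""

    chrom_sizes: dict = field(
        default_factory=lambda: {f"chr{i}": 5_000_000 for i in range(1, 5)}
    )
    spikein_contig: str = "lambda_spikein"
    spikein_size: int = 48_502
    cpg_spacing: float = 100.0  # mean bp between CpG dyads
    window_size: int = 10_000
    repeat_families: tuple = (
        RepeatFamilyConfig("IAPEz_toy", "LTR", 200, 2_000),
        RepeatFamilyConfig("L1Md_toy", "LINE", 250, 3_000),
        RepeatFamilyConfig("B1_toy", "SINE", 400, 150),
        RepeatFamilyConfig("GSAT_toy", "satellite", 80, 1_000, clustered=True),
        RepeatFamilyConfig("MTA_toy", "LTR", 120, 500),
        RepeatFamilyConfig("MIR_toy", "SINE", 45, 150),  # below the 50-copy rule
    )
    n_genes: int = 60
    gene_len: int = 20_000
    exons_per_gene: int = 5
    exon_len: int = 300
    n_icrs: int = 15
    icr_len: int = 4_000
    n_flagged_icrs: int = 5
    # control weighted-methylation baselines per stage
    stage_baselines: dict = field(
        default_factory=lambda: {
            "epiblast": 0.70,
            "E9.5": 0.30,
            "E10.5": 0.15,
            "E11.5": 0.091,
            "E12.5": 0.05,
            "E13.5": 0.030,
            "E16.5": 0.022,
            "GO": 0.15,
            "FGO": 0.40,
        }
    )
    # fate mix of the H3K9me3-marked planted windows
    fate_fractions: dict = field(
        default_factory=lambda: {
            "lost_after_E11.5": 0.40,
            "PGC_only": 0.25,
            "persistent_to_FGO": 0.35,
        }
    )
    n_fgo_only_windows: int = 100
    icr_control_level: float = 0.10  # erasure-resistant remnant at PGC stages
    icr_ko_retained_level: float = 0.30
    # extra KO delta at sites inside the young-LTR family's copies, on top of
    # the window-level effect: makes the IAP-like family the single most
    # hypermethylated repeat family, ahead of the satellite
    boosted_family: str = "IAPEz_toy"
    boosted_extra_delta: float = 0.10
    overdispersion: float = 0.05  # beta-binomial rho
    mean_depth: float = 15.0
    conversion_error: float = 0.005
    replicates: int = 2
    chip_background: float = 100.0  # expected input reads per window
    chip_fold: float = 8.0
    knockout_gene: str = "gene_ko_target"
    derepressed_gene: str = "gene_derepressed"

    def validate(self) -> None:
        for stage, level in self.stage_baselines.items():
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"baseline for {stage} outside [0,1]")
        if not 0.0 <= self.conversion_error <= 1.0:
            raise ValueError("conversion_error outside [0,1]")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must be in [0,1)")
        if abs(sum(self.fate_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fate_fractions must sum to 1")
        for fam in self.repeat_families:
            if fam.n_copies < 50:
                warnings.warn(
                    f"repeat family {fam.name} has {fam.n_copies} copies; "
                    "families below 50 copies are excluded downstream",
                    stacklevel=2,
                )


@dataclass
class SyntheticGenome:
    """A built toy genome: annotations, CpG map, and planted truth."""

    spec: SyntheticGenomeSpec
    annotation: AnnotationSet
    cpg_positions: dict  # chrom -> sorted plus-strand dyad coordinates
    truth_windows: pd.DataFrame  # chrom, start, category, h3k9me3
    mark_windows: dict  # mark -> window DataFrame (chrom, start)
    flagged_icrs: tuple

    def all_windows(self) -> pd.DataFrame:
        """Every grid window of the autosomes (spike-in excluded)."""
        rows = []
        ws = self.spec.window_size
        for chrom, size in self.spec.chrom_sizes.items():
            starts = np.arange(0, size, ws, dtype=np.int64)
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": np.minimum(starts + ws, size)}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def write(self, outdir) -> None:
        """Write annotations and truth tables as plain-text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_repeat_bed(self.annotation.repeats, outdir / "repeats.bed")
        write_named_bed(self.annotation.genes, outdir / "genes.bed")
        write_named_bed(
            self.annotation.exons.rename(columns={"gene": "name"}), outdir / "exons.bed"
        )
        write_named_bed(self.annotation.icrs, outdir / "icrs.bed")
        sizes = pd.DataFrame(
            list(self.annotation.chrom_sizes.items()), columns=["chrom", "size"]
        )
        sizes.to_csv(outdir / "chrom.sizes", sep="\t", header=False, index=False)
        cpgs = pd.concat(
            pd.DataFrame({"chrom": c, "pos": p}) for c, p in self.cpg_positions.items()
        )
        cpgs.to_csv(outdir / "cpg_positions.tsv", sep="\t", index=False)
        self.truth_windows.to_csv(outdir / "truth_windows.tsv", sep="\t", index=False)
        with open(outdir / "truth_icrs.json", "w") as fh:
            json.dump({"flagged": list(self.flagged_icrs)}, fh, indent=1)


def _rng_for(seed: int, label: str) -> np.random.Generator:
    """Independent, order-insensitive child stream for a labelled task."""
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _place_nonoverlapping(rng, size: int, lengths, occupied: list) -> list:
    """Place intervals of the given lengths without overlap (rejection)."""
    placed = []
    for length in lengths:
        for _ in range(1000):
            start = int(rng.integers(0, size - length))
            end = start + length
            if all(end <= s or start >= e for s, e in occupied):
                occupied.append((start, end))
                placed.append((start, end))
                break
        else:
            raise RuntimeError("could not place interval; genome too crowded")
    return placed


def build_genome(spec: SyntheticGenomeSpec | None = None, seed: int = 0) -> SyntheticGenome:
    """Build the toy genome: annotations, CpG map and planted truth tables."""
    spec = spec or SyntheticGenomeSpec()
    spec.validate()
    rng = _rng_for(seed, "genome")
    chroms = list(spec.chrom_sizes)

    # --- CpG dyad coordinates (1-based plus-strand C), jittered spacing
    cpg_positions = {}
    for chrom, size in {**spec.chrom_sizes, spec.spikein_contig: spec.spikein_size}.items():
        gaps = rng.uniform(0.5 * spec.cpg_spacing, 1.5 * spec.cpg_spacing,
                           int(size / spec.cpg_spacing * 1.2) + 10)
        pos = np.unique(np.cumsum(gaps).astype(np.int64) + 1)
        cpg_positions[chrom] = pos[pos <= size - 1]

    # --- repeats (non-overlapping among themselves)
    occupied = {chrom: [] for chrom in chroms}
    repeat_rows = []
    for fam in spec.repeat_families:
        if fam.clustered:
            # one pericentromeric-style tandem block per chromosome
            per_chrom = np.array_split(np.arange(fam.n_copies), len(chroms))
            for chrom, idx in zip(chroms, per_chrom):
                if idx.size == 0:
                    continue
                block_len = fam.copy_len * idx.size
                (start, _), = _place_nonoverlapping(
                    rng, spec.chrom_sizes[chrom], [block_len], occupied[chrom]
                )
                for i in range(idx.size):
                    repeat_rows.append(
                        (chrom, start + i * fam.copy_len, start + (i + 1) * fam.copy_len,
                         fam.name, fam.cls)
                    )
        else:
            which = rng.integers(0, len(chroms), fam.n_copies)
            for ci in range(len(chroms)):
                n_here = int(np.sum(which == ci))
                chrom = chroms[ci]
                for start, end in _place_nonoverlapping(
                    rng, spec.chrom_sizes[chrom], [fam.copy_len] * n_here, occupied[chrom]
                ):
                    repeat_rows.append((chrom, start, end, fam.name, fam.cls))
    repeats = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "family", "cls"]
    ).sort_values(["chrom", "start"], ignore_index=True)

    # --- genes and exons (non-overlapping among themselves, may overlap repeats)
    gene_occupied = {chrom: [] for chrom in chroms}
    gene_rows, exon_rows = [], []
    names = [spec.knockout_gene, spec.derepressed_gene] + [
        f"gene{i:03d}" for i in range(spec.n_genes - 2)
    ]
    which = rng.integers(0, len(chroms), spec.n_genes)
    gi = 0
    for ci, chrom in enumerate(chroms):
        n_here = int(np.sum(which == ci))
        for start, end in _place_nonoverlapping(
            rng, spec.chrom_sizes[chrom], [spec.gene_len] * n_here, gene_occupied[chrom]
        ):
            name = names[gi]
            gi += 1
            gene_rows.append((chrom, start, end, name))
            exon_starts = np.linspace(
                start, end - spec.exon_len, spec.exons_per_gene
            ).astype(int)
            for es in exon_starts:
                exon_rows.append((chrom, int(es), int(es) + spec.exon_len, name))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name"])
    exons = pd.DataFrame(exon_rows, columns=["chrom", "start", "end", "gene"])

    # --- ICRs: non-overlapping, clear of repeats
    icr_rows = []
    for i in range(spec.n_icrs):
        chrom = chroms[i % len(chroms)]
        (start, end), = _place_nonoverlapping(
            rng, spec.chrom_sizes[chrom], [spec.icr_len], occupied[chrom]
        )
        icr_rows.append((chrom, start, end, f"ICR{i + 1:02d}"))
    icrs = pd.DataFrame(icr_rows, columns=["chrom", "start", "end", "name"])
    flagged = tuple(
        sorted(rng.choice(icrs["name"], size=spec.n_flagged_icrs, replace=False))
    )

    annotation = AnnotationSet(
        chrom_sizes=dict(spec.chrom_sizes),
        repeats=repeats,
        genes=genes,
        exons=exons,
        icrs=icrs,
    )

    # --- H3K9me3 truth: windows overlapping IAP-like or satellite copies
    ws = spec.window_size
    marked = repeats.loc[
        (repeats["family"] == "IAPEz_toy") | (repeats["cls"] == "satellite")
    ]
    mark_ids = set()
    for row in marked.itertuples(index=False):
        for w in range(row.start // ws, (row.end - 1) // ws + 1):
            mark_ids.add((row.chrom, w * ws))
    h3k9me3 = pd.DataFrame(sorted(mark_ids), columns=["chrom", "start"])

    # --- planted KO-hypermethylated windows with fate categories
    cats, fracs = zip(*sorted(spec.fate_fractions.items()))
    assigned = rng.choice(cats, size=len(h3k9me3), p=np.asarray(fracs))
    truth = h3k9me3.assign(category=assigned, h3k9me3=True)
    all_ids = pd.MultiIndex.from_frame(
        pd.DataFrame(
            [
                (c, s)
                for c, size in spec.chrom_sizes.items()
                for s in range(0, size, ws)
            ],
            columns=["chrom", "start"],
        )
    )
    unmarked = all_ids.difference(pd.MultiIndex.from_frame(h3k9me3))
    if spec.n_fgo_only_windows > len(unmarked):
        raise ValueError(
            "n_fgo_only_windows exceeds the number of unmarked grid windows"
        )
    pick = rng.choice(len(unmarked), size=spec.n_fgo_only_windows, replace=False)
    fgo_only = unmarked[np.sort(pick)].to_frame(index=False, name=["chrom", "start"])
    fgo_only = fgo_only.assign(category="FGO_only", h3k9me3=False)
    truth = pd.concat([truth, fgo_only], ignore_index=True).sort_values(
        ["chrom", "start"], ignore_index=True
    )

    # other histone marks: promoters / genic windows (no methylation linkage)
    promoter_ids = sorted(
        {(r.chrom, r.start // ws * ws) for r in genes.itertuples(index=False)}
    )
    mark_windows = {"H3K9me3": h3k9me3}
    promoters = pd.DataFrame(promoter_ids, columns=["chrom", "start"])
    for mark in ("H3K4me3", "H3K4me1", "H3K27ac"):
        mark_windows[mark] = promoters.copy()
    pick = rng.choice(len(unmarked), size=min(150, len(unmarked)), replace=False)
    mark_windows["H3K27me3"] = unmarked[np.sort(pick)].to_frame(
        index=False, name=["chrom", "start"]
    )

    return SyntheticGenome(
        spec=spec,
        annotation=annotation,
        cpg_positions=cpg_positions,
        truth_windows=truth,
        mark_windows=mark_windows,
        flagged_icrs=flagged,
    )


# ---------------------------------------------------------------------------
# per-site truth levels

def _site_table(genome: SyntheticGenome) -> pd.DataFrame:
    parts = []
    for chrom, pos in genome.cpg_positions.items():
        parts.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    df = pd.concat(parts, ignore_index=True)
    df["start"] = (df["pos"] - 1) // genome.spec.window_size * genome.spec.window_size
    return df


def site_truth_levels(genome: SyntheticGenome, stage: str, genotype: str) -> pd.DataFrame:
    """True methylation level of every CpG for one (stage, genotype).

    Baseline by stage; planted KO deltas by window fate category; ICR
    overrides at PGC stages; spike-in fixed at 0.
    """
    spec = genome.spec
    if stage not in spec.stage_baselines:
        raise ValueError(f"unknown stage {stage!r}")
    if genotype not in ("control", "KO", "WT"):
        raise ValueError(f"unknown genotype {genotype!r}")
    sites = _site_table(genome)
    level = np.full(len(sites), spec.stage_baselines[stage])

    if genotype == "KO":
        deltas = {
            cat: FATE_SCHEDULE[cat].get(stage, 0.0)
            for cat in genome.truth_windows["category"].unique()
        }
        planted = genome.truth_windows.assign(
            delta=genome.truth_windows["category"].map(deltas)
        )
        key = pd.MultiIndex.from_frame(sites[["chrom", "start"]])
        delta_by_win = planted.set_index(["chrom", "start"])["delta"]
        win_delta = delta_by_win.reindex(key).fillna(0.0).to_numpy()
        level = level + win_delta
        if spec.boosted_extra_delta > 0:
            from .annotation_enrichment import _sites_in_intervals

            fam = genome.annotation.repeats.loc[
                genome.annotation.repeats["family"] == spec.boosted_family
            ]
            if len(fam):
                in_fam = np.zeros(len(sites), dtype=bool)
                hits = _sites_in_intervals(sites.reset_index(drop=True), fam)
                in_fam[hits.index.to_numpy()] = True
                # the boost follows the window's fate schedule
                level = level + np.where(
                    in_fam & (win_delta > 0), spec.boosted_extra_delta, 0.0
                )

    # ICR override during PGC stages (erasure remnant; KO retention at flagged)
    if stage in ("E9.5", "E10.5", "E11.5", "E12.5", "E13.5", "E16.5"):
        retained = (
            genome.flagged_icrs if genotype == "KO" else ()
        )
        for row in genome.annotation.icrs.itertuples(index=False):
            inside = (
                (sites["chrom"] == row.chrom)
                & (sites["pos"] - 1 >= row.start)
                & (sites["pos"] - 1 < row.end)
            ).to_numpy()
            level[inside] = (
                spec.icr_ko_retained_level
                if row.name in retained
                else spec.icr_control_level
            )

    level[(sites["chrom"] == spec.spikein_contig).to_numpy()] = 0.0
    sites["level"] = np.clip(level, 0.0, 1.0)
    return sites


# ---------------------------------------------------------------------------
# samplers

def simulate_sample(
    genome: SyntheticGenome,
    stage: str,
    genotype: str,
    replicate: int = 1,
    seed: int = 0,
    depth: float | None = None,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Draw one WGBS library as a CpG call table.

    Read counts are beta-binomial around the per-site truth level (biological
    overdispersion), at Poisson depths truncated to >= 1, with the bisulfite
    conversion error inflating apparent methylation:
    p_obs = p + (1-p)*error.  ``noiseless=True`` replaces sampling by
    deterministic rounding at a fixed depth (default 200), for oracle runs.
    """
    spec = genome.spec
    rng = _rng_for(seed, f"wgbs/{stage}/{genotype}/{replicate}")
    sites = site_truth_levels(genome, stage, genotype)
    p = sites["level"].to_numpy()
    p_obs = p + (1.0 - p) * spec.conversion_error
    n = len(sites)

    if noiseless:
        d = np.full(n, int(depth if depth is not None else 200), dtype=np.int64)
        m = np.rint(p_obs * d).astype(np.int64)
    else:
        lam = depth if depth is not None else spec.mean_depth
        d = np.maximum(rng.poisson(lam, n), 1).astype(np.int64)
        rho = spec.overdispersion
        if rho > 0:
            conc = (1.0 - rho) / rho
            interior = (p_obs > 0) & (p_obs < 1)
            p_site = p_obs.copy()
            p_site[interior] = rng.beta(
                p_obs[interior] * conc, (1.0 - p_obs[interior]) * conc
            )
        else:
            p_site = p_obs
        m = rng.binomial(d, p_site)

    return pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "n_meth": m,
            "n_unmeth": d - m,
        }
    )


def simulate_strand_split(calls: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Split each dyad's counts randomly onto plus (pos) and minus (pos+1)
    strand records, for exercising strand merging."""
    rng = _rng_for(seed, "strandsplit")
    m_plus = rng.binomial(calls["n_meth"], 0.5)
    u_plus = rng.binomial(calls["n_unmeth"], 0.5)
    plus = calls.assign(n_meth=m_plus, n_unmeth=u_plus)
    minus = calls.assign(
        pos=calls["pos"] + 1,
        n_meth=calls["n_meth"] - m_plus,
        n_unmeth=calls["n_unmeth"] - u_plus,
    )
    both = pd.concat([plus, minus], ignore_index=True)
    both = both.loc[both["n_meth"] + both["n_unmeth"] > 0]
    return both.sort_values(["chrom", "pos"], ignore_index=True)


def simulate_chip(
    genome: SyntheticGenome, mark: str = "H3K9me3", seed: int = 0
) -> pd.DataFrame:
    """IP and input read counts per grid window for one histone mark.

    input ~ Poisson(background); IP ~ Poisson(background * fold), with
    fold > 1 only at the mark's truth windows.
    """
    if mark not in genome.mark_windows:
        raise ValueError(f"mark {mark!r} not defined for this genome")
    rng = _rng_for(seed, f"chip/{mark}")
    windows = genome.all_windows()
    truth = pd.MultiIndex.from_frame(genome.mark_windows[mark][["chrom", "start"]])
    enriched = pd.MultiIndex.from_frame(windows[["chrom", "start"]]).isin(truth)
    lam_in = genome.spec.chip_background
    lam_ip = np.where(enriched, lam_in * genome.spec.chip_fold, lam_in)
    windows = windows.assign(
        input=rng.poisson(lam_in, len(windows)),
        ip=rng.poisson(lam_ip),
    )
    return windows


def simulate_expression(genome: SyntheticGenome, seed: int = 0) -> pd.DataFrame:
    """Gene-level FPKM matrix: control and KO replicates, log-normal noise.

    The knocked-out gene collapses to ~0 FPKM in KO; the derepressed gene
    rises 8-fold; all other genes have truth fold change 1.
    """
    spec = genome.spec
    rng = _rng_for(seed, "rnaseq")
    gene_names = genome.annotation.genes["name"].tolist()
    base = rng.lognormal(mean=2.0, sigma=1.0, size=len(gene_names))
    cols = {}
    for genotype in ("control", "KO"):
        for rep in range(1, spec.replicates + 1):
            mu = base.copy()
            if genotype == "KO":
                ko_i = gene_names.index(spec.knockout_gene)
                de_i = gene_names.index(spec.derepressed_gene)
                mu[ko_i] = 0.01
                mu[de_i] = base[de_i] * 8.0
            noise = rng.lognormal(mean=0.0, sigma=0.1, size=len(gene_names))
            cols[f"{genotype}_r{rep}"] = mu * noise
    return pd.DataFrame(cols, index=pd.Index(gene_names, name="gene"))


def simulate_null_pair(
    n_windows: int = 10_000,
    cpgs_per_window: int = 20,
    depth: float = 20.0,
    level: float = 0.30,
    overdispersion: float = 0.05,
    window_size: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two independent samples drawn from one identical truth.

    A dedicated null construction for type-I calibration of the DMR caller:
    every window has the same true level in both samples, so any called DMR
    is a false positive.
    """
    rng = _rng_for(seed, "nullpair")
    spacing = window_size // (cpgs_per_window + 1)
    pos = np.concatenate(
        [
            w * window_size + spacing * np.arange(1, cpgs_per_window + 1)
            for w in range(n_windows)
        ]
    ).astype(np.int64) + 1
    out = []
    conc = (1.0 - overdispersion) / overdispersion
    for _ in range(2):
        d = np.maximum(rng.poisson(depth, pos.size), 1)
        p_site = rng.beta(level * conc, (1.0 - level) * conc, pos.size)
        m = rng.binomial(d, p_site)
        out.append(
            pd.DataFrame(
                {"chrom": "chrN", "pos": pos, "n_meth": m, "n_unmeth": d - m}
            )
        )
    return out[0], out[1]


def write_sample(calls: pd.DataFrame, path) -> None:
    write_coverage_file(calls, path)
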