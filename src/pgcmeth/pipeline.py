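"""End-to-end orchestration: simulate -> QC -> windows -> DMRs -> annotation
-> chromatin -> fate -> expression, with a reproducibility manifest.

Every stage hands off through files in the output directory; the manifest
records parameters, input checksums and outputs, so a run is fully
reconstructable.  Under a fixed seed the whole run is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    annotation_enrichment,
    chromatin_association,
    dmr_calling,
    expression,
    methylation_io,
    persistence,
    regional_methylation,
    synthetic_data,
)

log = logging.getLogger("pgcmeth")

CONTRAST_STAGES = ("E11.5", "E13.5", "E16.5", "FGO")


@dataclass
class RunConfig:
    """Parameters of one full synthetic-data analysis run."""

    outdir: str = "pgcmeth_run"
    seed: int = 0
    window_size: int = 10_000
    min_cpg: int = 5
    min_reads: int = 3
    max_reads: int = 100
    delta_threshold: float = 10.0
    alpha: float = 0.05
    top_quantile: float = 0.05
    stages: tuple = CONTRAST_STAGES
    genome_spec: synthetic_data.SyntheticGenomeSpec = field(
        default_factory=synthetic_data.SyntheticGenomeSpec
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute all analysis stages in dependency order; return the manifest."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.genome_spec
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "window_size": config.window_size,
            "min_cpg": config.min_cpg,
            "coverage_filter": [config.min_reads, config.max_reads],
            "delta_threshold": config.delta_threshold,
            "alpha": config.alpha,
            "top_quantile": config.top_quantile,
        },
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        def deco(fn):
            t = time.time()
            log.info("stage %s ...", name)
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t, 3),
            }
            return result

        return deco

    # 1. genome + annotations + truth
    @stage("simulate_genome")
    def genome():
        g = synthetic_data.build_genome(spec, seed=config.seed)
        g.write(out / "genome")
        return g

    spike = spec.spikein_contig

    # 2. WGBS samples, replicate QC, pooling
    @stage("simulate_wgbs")
    def samples():
        reps: dict = {}
        for st in config.stages:
            for gt in ("control", "KO"):
                reps[(st, gt)] = [
                    synthetic_data.simulate_sample(
                        genome, st, gt, replicate=r, seed=config.seed
                    )
                    for r in range(1, spec.replicates + 1)
                ]
        return reps

    @stage("qc_and_pool")
    def pooled():
        qc_rows = []
        pools: dict = {}
        for (st, gt), reps in samples.items():
            filtered = [
                methylation_io.filter_coverage(r, config.min_reads, config.max_reads)
                for r in reps
            ]
            if len(filtered) >= 2:
                r = methylation_io.replicate_correlation(filtered[0], filtered[1])
            else:
                r = float("nan")
            pool = methylation_io.pool_replicates(
                filtered, config.min_reads, config.max_reads
            )
            conv = methylation_io.conversion_rate(pool, spike)
            glob = regional_methylation.global_level(pool, exclude_contigs=[spike])
            qc_rows.append(
                {
                    "stage": st,
                    "genotype": gt,
                    "replicate_R": r,
                    "conversion_rate": conv,
                    "global_level": glob,
                }
            )
            synthetic_data.write_sample(pool, out / f"pooled_{st}_{gt}.cov")
            pools[(st, gt)] = pool
        pd.DataFrame(qc_rows).to_csv(out / "qc_summary.tsv", sep="\t", index=False)
        return pools

    # 3. windowed levels
    @stage("window_levels")
    def windows():
        w = {}
        for (st, gt), pool in pooled.items():
            tab = regional_methylation.window_levels(
                pool, config.window_size, config.min_cpg, exclude_contigs=[spike]
            )
            regional_methylation.write_window_table(
                tab, out / f"windows_{st}_{gt}.tsv"
            )
            w[(st, gt)] = tab
        return w

    # 4. DMRs per stage
    @stage("dmr_calling")
    def dmrsets():
        sets = {}
        summaries = []
        for st in config.stages:
            ds = dmr_calling.call_dmrs(
                pooled[(st, "control")],
                pooled[(st, "KO")],
                label=f"{st}_KO_vs_control",
                window_size=config.window_size,
                min_cpg=config.min_cpg,
                delta_threshold=config.delta_threshold,
                alpha=config.alpha,
                exclude_contigs=[spike],
            )
            dmr_calling.write_dmr_bed(ds, out / f"dmrs_{st}.bed")
            summaries.append(dmr_calling.summarize_dmrs(ds))
            sets[st] = ds
        pd.DataFrame(summaries).to_csv(out / "dmr_summary.tsv", sep="\t", index=False)
        return sets

    # 5. annotation: context, repeats, ICRs (at E13.5, the reference contrast)
    @stage("annotation")
    def annot_results():
        ref = "E13.5" if "E13.5" in config.stages else config.stages[0]
        hyper = dmrsets[ref].hyper
        res = {}
        if len(hyper):
            res["context_proportions"] = annotation_enrichment.context_proportions(
                hyper, genome.annotation
            )
            res["context_fold"] = annotation_enrichment.context_fold_enrichment(
                hyper, genome.annotation
            )
            res["context_proportions"].rename("proportion").to_csv(
                out / "context_proportions.tsv", sep="\t"
            )
            res["context_fold"].rename("fold").to_csv(
                out / "context_fold.tsv", sep="\t"
            )
        fams = annotation_enrichment.repeat_family_methylation(
            pooled[(ref, "control")], pooled[(ref, "KO")], genome.annotation
        )
        fams.to_csv(out / "repeat_families.tsv", sep="\t", index=False)
        res["families"] = fams
        res["family_ranks"] = annotation_enrichment.rank_hyper_families(
            fams, config.delta_threshold
        )
        icr = annotation_enrichment.icr_methylation(
            pooled[(ref, "control")], pooled[(ref, "KO")], genome.annotation
        )
        icr.to_csv(out / "icr_methylation.tsv", sep="\t", index=False)
        res["icrs"] = icr
        return res

    # 6. chromatin association
    @stage("chromatin")
    def chrom_results():
        ref = "E13.5" if "E13.5" in config.stages else config.stages[0]
        counts = synthetic_data.simulate_chip(genome, "H3K9me3", seed=config.seed)
        track = chromatin_association.window_enrichment(counts, "H3K9me3")
        track.scores.to_csv(out / "h3k9me3_scores.tsv", sep="\t", index=False)
        hyper = dmrsets[ref].hyper
        others = dmrsets[ref].windows.loc[dmrsets[ref].windows["direction"] == "."]
        comparison = chromatin_association.mark_vs_methylation(
            track,
            hyper,
            others,
            windows[(ref, "control")],
            windows[(ref, "KO")],
            labels=("hyper_dmr", "non_dmr"),
        )
        comparison.to_csv(out / "mark_vs_methylation.tsv", sep="\t", index=False)
        return {"track": track, "comparison": comparison}

    # 7. fate classification
    @stage("fate")
    def fate_results():
        fate = persistence.classify_fates(dmrsets)
        fate.windows.to_csv(out / "fate_table.tsv", sep="\t", index=False)
        with open(out / "fate_counts.json", "w") as fh:
            json.dump(
                {"counts": fate.counts, "percentages": fate.percentages}, fh, indent=1
            )
        track = chrom_results["track"]
        profiles = persistence.category_profiles(
            fate,
            track,
            windows.get(("FGO", "control")),
            windows.get(("FGO", "KO")),
        )
        profiles.to_csv(out / "category_profiles.tsv", sep="\t", index=False)
        mat = persistence.delta_matrix(
            {st: (windows[(st, "control")], windows[(st, "KO")]) for st in config.stages},
            order_by=track,
        )
        mat.to_csv(out / "delta_matrix.tsv", sep="\t")
        return {"fate": fate, "profiles": profiles}

    # 8. expression
    @stage("expression")
    def de_results():
        fpkm = synthetic_data.simulate_expression(genome, seed=config.seed)
        fpkm.to_csv(out / "fpkm_matrix.tsv", sep="\t")
        ctrl = [c for c in fpkm.columns if c.startswith("control")]
        ko = [c for c in fpkm.columns if c.startswith("KO")]
        de = expression.de_genes(fpkm, ctrl, ko)
        de.to_csv(out / "de_genes.tsv", sep="\t", index=False)
        return de

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    manifest["total_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run complete in %.1fs", manifest["total_seconds"])
    return manifest
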