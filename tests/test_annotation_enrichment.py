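import numpy as np
import pandas as pd
import pytest

import pgcmeth
from pgcmeth.annotation_enrichment import AnnotationSet, CONTEXT_CATEGORIES
from pgcmeth.regional_methylation import GenomicInterval


@pytest.fixture()
def toy_annotation():
    """1-Mb single-chromosome annotation with known overlaps."""
    repeats = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "start": [100_000, 300_000, 500_000, 700_000],
            "end": [110_000, 320_000, 505_000, 701_000],
            "family": ["IAP_x", "L1_x", "IAP_x", "SAT_x"],
            "cls": ["LTR", "LINE", "LTR", "satellite"],
        }
    )
    genes = pd.DataFrame(
        {"chrom": ["chr1"], "start": [200_000], "end": [260_000], "name": ["geneA"]}
    )
    exons = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [200_000, 250_000],
            "end": [210_000, 255_000],
            "gene": ["geneA", "geneA"],
        }
    )
    icrs = pd.DataFrame(
        {"chrom": ["chr1"], "start": [800_000], "end": [804_000], "name": ["ICRx"]}
    )
    return AnnotationSet(
        chrom_sizes={"chr1": 1_000_000},
        repeats=repeats,
        genes=genes,
        exons=exons,
        icrs=icrs,
    )


class TestContextProportions:
    def test_region_inside_one_ltr(self, toy_annotation):
        prop = pgcmeth.context_proportions(
            [GenomicInterval("chr1", 101_000, 105_000)], toy_annotation
        )
        assert prop["LTR"] == 1.0

    def test_half_line_half_intergenic(self, toy_annotation):
        prop = pgcmeth.context_proportions(
            [GenomicInterval("chr1", 310_000, 330_000)], toy_annotation
        )
        assert prop["LINE"] == pytest.approx(0.5)
        assert prop["intergenic"] == pytest.approx(0.5)

    def test_sums_to_one(self, toy_annotation):
        rng = np.random.default_rng(3)
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 10_000)
            for s in rng.integers(0, 990_000, 25)
        ]
        prop = pgcmeth.context_proportions(regions, toy_annotation)
        assert prop.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_per_base_brute_force(self, toy_annotation):
        # independent oracle: label every base with explicit precedence rules
        labels = np.full(1_000_000, "intergenic", dtype=object)
        g = toy_annotation.genes.iloc[0]
        labels[g.start: g.end] = "intron"
        for e in toy_annotation.exons.itertuples(index=False):
            labels[e.start: e.end] = "exon"
        for r in toy_annotation.repeats.itertuples(index=False):
            labels[r.start: r.end] = r.cls
        rng = np.random.default_rng(7)
        regions = [
            GenomicInterval("chr1", int(s), int(s) + 20_000)
            for s in rng.integers(0, 980_000, 15)
        ]
        expected = pd.Series(
            np.concatenate([labels[iv.start: iv.end] for iv in regions])
        ).value_counts(normalize=True)
        prop = pgcmeth.context_proportions(regions, toy_annotation)
        for cat in CONTEXT_CATEGORIES:
            assert prop[cat] == pytest.approx(expected.get(cat, 0.0), abs=1e-12)

    def test_empty_region_set_rejected(self, toy_annotation):
        with pytest.raises(ValueError):
            pgcmeth.context_proportions([], toy_annotation)


class TestContextFold:
    def test_whole_genome_folds_are_one(self, toy_annotation):
        whole = [GenomicInterval("chr1", 0, 1_000_000)]
        fold = pgcmeth.context_fold_enrichment(whole, toy_annotation)
        present = fold.dropna()
        assert np.allclose(present, 1.0)

    def test_double_share_gives_fold_two(self):
        # LTR occupies 10% of the genome; pick regions where it is 20%
        ann = AnnotationSet(
            chrom_sizes={"chr1": 100_000},
            repeats=pd.DataFrame(
                {
                    "chrom": ["chr1"],
                    "start": [0],
                    "end": [10_000],
                    "family": ["IAP_x"],
                    "cls": ["LTR"],
                }
            ),
            genes=pd.DataFrame(columns=["chrom", "start", "end", "name"]),
            exons=pd.DataFrame(columns=["chrom", "start", "end", "gene"]),
            icrs=pd.DataFrame(columns=["chrom", "start", "end", "name"]),
        )
        regions = [GenomicInterval("chr1", 0, 50_000)]  # 10k of 50k = 20% LTR
        fold = pgcmeth.context_fold_enrichment(regions, ann)
        assert fold["LTR"] == pytest.approx(2.0)

    def test_planted_enrichment_recovered(self, genome, e13_dmrs):
        fold = pgcmeth.context_fold_enrichment(e13_dmrs.hyper, genome.annotation)
        # hypermethylation is planted at IAP-like (LTR) and satellite windows
        assert fold["LTR"] > 1.5
        assert fold["satellite"] > 1.5
        assert fold["intergenic"] < 1.1


class TestRepeatFamilies:
    def _calls(self, level, ann, depth=20):
        pos = np.arange(1, 1_000_000, 500)
        m = int(round(level * depth))
        return pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "n_meth": m, "n_unmeth": depth - m}
        )

    def test_family_below_copy_threshold_excluded(self, toy_annotation):
        c = self._calls(0.1, toy_annotation)
        out = pgcmeth.repeat_family_methylation(c, c, toy_annotation, min_copies=3)
        assert set(out["family"]) == set()  # no family has 3 copies
        out = pgcmeth.repeat_family_methylation(c, c, toy_annotation, min_copies=2)
        assert set(out["family"]) == {"IAP_x"}

    def test_identical_samples_zero_delta(self, toy_annotation):
        c = self._calls(0.3, toy_annotation)
        out = pgcmeth.repeat_family_methylation(c, c, toy_annotation, min_copies=1)
        assert np.allclose(out["delta_pp"], 0.0)

    def test_family_level_equals_per_copy_pooling(self, toy_annotation):
        rng = np.random.default_rng(13)
        pos = np.arange(1, 1_000_000, 333)
        d = rng.integers(3, 50, pos.size)
        m = rng.binomial(d, 0.25)
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "n_meth": m, "n_unmeth": d - m}
        )
        out = pgcmeth.repeat_family_methylation(
            calls, calls, toy_annotation, min_copies=1
        )
        # brute force: pool counts over each copy's interval separately
        fam = toy_annotation.repeats.query("family == 'IAP_x'")
        tm = tt = 0
        for row in fam.itertuples(index=False):
            inside = (pos - 1 >= row.start) & (pos - 1 < row.end)
            tm += m[inside].sum()
            tt += d[inside].sum()
        got = out.set_index("family").loc["IAP_x", "level_control"]
        assert got == pytest.approx(tm / tt, abs=1e-12)

    def test_split_batch_invariance(self, toy_annotation):
        c = self._calls(0.2, toy_annotation)
        k = self._calls(0.5, toy_annotation)
        whole = pgcmeth.repeat_family_methylation(c, k, toy_annotation, min_copies=1)
        # recombining each family's copies in two batches changes nothing
        again = pgcmeth.repeat_family_methylation(
            c, k, toy_annotation.__class__(
                chrom_sizes=toy_annotation.chrom_sizes,
                repeats=pd.concat(
                    [toy_annotation.repeats.iloc[:2], toy_annotation.repeats.iloc[2:]]
                ).reset_index(drop=True),
                genes=toy_annotation.genes,
                exons=toy_annotation.exons,
                icrs=toy_annotation.icrs,
            ),
            min_copies=1,
        )
        pd.testing.assert_frame_equal(whole, again)


class TestRankHyperFamilies:
    def test_no_family_above_threshold(self):
        s = pd.DataFrame({"family": ["a"], "cls": ["LTR"], "n_copies": [60],
                          "level_control": [0.1], "level_ko": [0.15], "delta_pp": [5.0]})
        assert len(pgcmeth.rank_hyper_families(s)) == 0

    def test_ranking_and_cutoff(self):
        s = pd.DataFrame(
            {
                "family": ["a", "b", "c"],
                "cls": ["LTR"] * 3,
                "n_copies": [60] * 3,
                "level_control": [0.1] * 3,
                "level_ko": [0.4, 0.22, 0.19],
                "delta_pp": [30.0, 12.0, 9.0],
            }
        )
        out = pgcmeth.rank_hyper_families(s)
        assert out["family"].tolist() == ["a", "b"]
        assert out["rank"].tolist() == [1, 2]

    def test_planted_iap_family_ranks_first(self, genome, pooled_samples):
        fams = pgcmeth.repeat_family_methylation(
            pooled_samples[("E13.5", "control")],
            pooled_samples[("E13.5", "KO")],
            genome.annotation,
        )
        ranked = pgcmeth.rank_hyper_families(fams)
        assert ranked.iloc[0]["family"] == genome.spec.boosted_family


class TestIcrMethylation:
    def _ann_one_icr(self):
        return AnnotationSet(
            chrom_sizes={"chr1": 100_000},
            repeats=pd.DataFrame(columns=["chrom", "start", "end", "family", "cls"]),
            genes=pd.DataFrame(columns=["chrom", "start", "end", "name"]),
            exons=pd.DataFrame(columns=["chrom", "start", "end", "gene"]),
            icrs=pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [10_000], "name": ["I1"]}
            ),
        )

    def _icr_calls(self, level, depth=100):
        m = int(round(level * depth))
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, 10_000, 200),
                "n_meth": m,
                "n_unmeth": depth - m,
            }
        )

    @pytest.mark.parametrize("ko_level,flagged", [(0.14, True), (0.12, False)])
    def test_fold_threshold(self, ko_level, flagged):
        ann = self._ann_one_icr()
        out = pgcmeth.icr_methylation(
            self._icr_calls(0.10), self._icr_calls(ko_level), ann
        )
        assert out.iloc[0]["fold_increase"] == pytest.approx(ko_level / 0.10)
        assert bool(out.iloc[0]["flagged"]) is flagged

    def test_zero_control_fold_undefined(self):
        ann = self._ann_one_icr()
        out = pgcmeth.icr_methylation(
            self._icr_calls(0.0), self._icr_calls(0.5), ann
        )
        assert not out.iloc[0]["fold_defined"]
        assert np.isnan(out.iloc[0]["fold_increase"])
        assert not out.iloc[0]["flagged"]

    def test_planted_icr_retention_recovered(self, genome, pooled_samples):
        out = pgcmeth.icr_methylation(
            pooled_samples[("E13.5", "control")],
            pooled_samples[("E13.5", "KO")],
            genome.annotation,
        )
        assert len(out) == 15
        assert set(out.loc[out["flagged"], "name"]) == set(genome.flagged_icrs)
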