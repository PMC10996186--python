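import gzip

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pgcmeth
from pgcmeth.methylation_io import CoverageParseError


def _calls(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"])


class TestReadCoverageFile:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "a.cov"
        p.write_text("chr1\t3001\t3001\t100.0\t5\t0\n")
        out = pgcmeth.read_coverage_file(p)
        assert out.iloc[0].tolist() == ["chr1", 3001, 5, 0]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.cov"
        p.write_text("")
        assert len(pgcmeth.read_coverage_file(p)) == 0

    def test_out_of_order_lines_are_sorted(self, tmp_path):
        p = tmp_path / "a.cov"
        p.write_text("chr1\t500\t500\t0.0\t0\t5\nchr1\t100\t100\t0.0\t1\t4\n")
        out = pgcmeth.read_coverage_file(p)
        # oracle: independently re-sort the parsed records
        assert out["pos"].tolist() == sorted(out["pos"].tolist()) == [100, 500]

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.cov"
        p.write_text("chr1\t1\t1\t0.0\t1\t1\nchr1\t2\t2\tbroken\n")
        with pytest.raises(CoverageParseError, match="line 2"):
            pgcmeth.read_coverage_file(p)

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "neg.cov"
        p.write_text("chr1\t1\t1\t0.0\t-1\t3\n")
        with pytest.raises(ValueError, match="negative"):
            pgcmeth.read_coverage_file(p)

    def test_gzip_roundtrip(self, tmp_path):
        calls = _calls([("chr1", 10, 3, 2), ("chr2", 5, 0, 7)])
        p = tmp_path / "a.cov.gz"
        pgcmeth.write_coverage_file(calls, p)
        with gzip.open(p, "rt"):
            pass  # file really is gzipped
        out = pgcmeth.read_coverage_file(p)
        pd.testing.assert_frame_equal(out, calls)

    def test_percent_column_ignored(self, tmp_path):
        # deliberately inconsistent %meth: counts win
        p = tmp_path / "a.cov"
        p.write_text("chr1\t10\t10\t99.9\t1\t9\n")
        out = pgcmeth.read_coverage_file(p)
        assert out.loc[0, "n_meth"] == 1 and out.loc[0, "n_unmeth"] == 9


class TestMergeStrands:
    def test_dyad_counts_are_additive(self):
        calls = _calls([("chr1", 100, 3, 1), ("chr1", 101, 2, 2)])
        out = pgcmeth.merge_strands(calls, {"chr1": [100]})
        assert out.to_numpy().tolist() == [["chr1", 100, 5, 3]]

    def test_lone_plus_record_unchanged(self):
        calls = _calls([("chr1", 100, 3, 1)])
        out = pgcmeth.merge_strands(calls, {"chr1": [100]})
        pd.testing.assert_frame_equal(out, calls)

    def test_unknown_site_passes_through(self):
        calls = _calls([("chr1", 555, 1, 1)])
        out = pgcmeth.merge_strands(calls, {"chr1": [100]})
        pd.testing.assert_frame_equal(out, calls)

    def test_random_strand_split_recovers_totals(self, genome):
        from pgcmeth.synthetic_data import simulate_strand_split

        calls = pgcmeth.simulate_sample(genome, "E11.5", "control", seed=3)
        split = simulate_strand_split(calls, seed=3)
        merged = pgcmeth.merge_strands(split, genome.cpg_positions)
        nonzero = calls.loc[calls["n_meth"] + calls["n_unmeth"] > 0].reset_index(
            drop=True
        )
        pd.testing.assert_frame_equal(merged, nonzero, check_dtype=False)

    def test_merge_then_pool_equals_pool_then_merge(self, genome):
        from pgcmeth.synthetic_data import simulate_strand_split

        a = simulate_strand_split(
            pgcmeth.simulate_sample(genome, "E13.5", "control", 1, seed=5), seed=5
        )
        b = simulate_strand_split(
            pgcmeth.simulate_sample(genome, "E13.5", "control", 2, seed=5), seed=6
        )
        cpgs = genome.cpg_positions
        route1 = pgcmeth.pool_replicates(
            [pgcmeth.merge_strands(a, cpgs), pgcmeth.merge_strands(b, cpgs)]
        )
        route2 = pgcmeth.merge_strands(pgcmeth.pool_replicates([a, b], 1, 10**9), cpgs)
        route2 = pgcmeth.filter_coverage(route2)
        pd.testing.assert_frame_equal(route1, route2)


class TestFilterCoverage:
    @pytest.mark.parametrize(
        "depth,kept",
        [(2, False), (3, True), (100, True), (101, False)],
    )
    def test_inclusive_bounds(self, depth, kept):
        calls = _calls([("chr1", 1, depth, 0)])
        assert (len(pgcmeth.filter_coverage(calls)) == 1) is kept

    def test_zero_depth_input_empties(self):
        calls = _calls([("chr1", i, 0, 0) for i in range(1, 5)])
        assert len(pgcmeth.filter_coverage(calls)) == 0

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 60), st.integers(0, 60)), min_size=0, max_size=30
        )
    )
    def test_idempotent_and_depths_in_range(self, counts):
        calls = _calls([("chr1", i + 1, m, u) for i, (m, u) in enumerate(counts)])
        once = pgcmeth.filter_coverage(calls)
        twice = pgcmeth.filter_coverage(once)
        pd.testing.assert_frame_equal(once, twice)
        depth = once["n_meth"] + once["n_unmeth"]
        assert ((depth >= 3) & (depth <= 100)).all()


class TestPoolReplicates:
    def test_single_sample_identity(self):
        calls = pgcmeth.filter_coverage(_calls([("chr1", 1, 5, 5)]))
        pd.testing.assert_frame_equal(pgcmeth.pool_replicates([calls]), calls)

    def test_counts_sum_per_site(self):
        a = _calls([("chr1", 1, 5, 0)])
        b = _calls([("chr1", 1, 0, 5)])
        out = pgcmeth.pool_replicates([a, b])
        assert out.iloc[0].tolist() == ["chr1", 1, 5, 5]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pgcmeth.pool_replicates([])

    def test_pooled_global_is_depth_weighted_mean(self):
        rng = np.random.default_rng(11)
        samples = []
        for _ in range(3):
            d = rng.integers(3, 50, 100)
            m = rng.binomial(d, 0.3)
            samples.append(
                _calls(
                    [("chr1", i + 1, int(mm), int(dd - mm)) for i, (mm, dd) in enumerate(zip(m, d))]
                )
            )
        pooled = pgcmeth.pool_replicates(samples, 1, 10**9)
        # brute-force oracle: total counts over all sites of all samples
        tot_m = sum(s["n_meth"].sum() for s in samples)
        tot = sum((s["n_meth"] + s["n_unmeth"]).sum() for s in samples)
        assert pgcmeth.global_level(pooled) == pytest.approx(tot_m / tot, abs=1e-12)


class TestConversionRate:
    def test_fully_converted(self):
        calls = _calls([("lambda_spikein", i, 0, 10) for i in range(1, 21)])
        assert pgcmeth.conversion_rate(calls, "lambda_spikein") == 1.0

    def test_two_failures_in_200(self):
        calls = _calls([("lambda_spikein", 1, 2, 98), ("lambda_spikein", 2, 0, 100)])
        assert pgcmeth.conversion_rate(calls, "lambda_spikein") == pytest.approx(0.99)

    def test_no_spikein_sites_warns_nan(self):
        calls = _calls([("chr1", 1, 1, 1)])
        with pytest.warns(UserWarning, match="spike-in"):
            assert np.isnan(pgcmeth.conversion_rate(calls, "lambda_spikein"))

    def test_binomial_simulation_near_truth(self):
        rng = np.random.default_rng(2)
        m = rng.binomial(2000, 0.005)
        calls = _calls([("lambda_spikein", 1, int(m), int(2000 - m))])
        assert pgcmeth.conversion_rate(calls, "lambda_spikein") == pytest.approx(
            0.995, abs=0.005
        )


class TestReplicateCorrelation:
    def test_sample_vs_itself(self, genome):
        s = pgcmeth.filter_coverage(
            pgcmeth.simulate_sample(genome, "E9.5", "control", seed=4)
        )
        assert pgcmeth.replicate_correlation(s, s) == pytest.approx(1.0)

    def test_level_inverted_copy_anticorrelates(self, genome):
        s = pgcmeth.filter_coverage(
            pgcmeth.simulate_sample(genome, "E9.5", "control", seed=4)
        )
        inverted = s.rename(columns={"n_meth": "n_unmeth", "n_unmeth": "n_meth"})
        r = pgcmeth.replicate_correlation(s, inverted[s.columns])
        assert r == pytest.approx(-1.0)

    def test_symmetric(self, genome):
        a = pgcmeth.filter_coverage(pgcmeth.simulate_sample(genome, "FGO", "control", 1, seed=4))
        b = pgcmeth.filter_coverage(pgcmeth.simulate_sample(genome, "FGO", "control", 2, seed=4))
        assert pgcmeth.replicate_correlation(a, b) == pytest.approx(
            pgcmeth.replicate_correlation(b, a), abs=1e-12
        )

    def test_replicates_of_one_truth_correlate(self, genome):
        a = pgcmeth.filter_coverage(
            pgcmeth.simulate_sample(genome, "FGO", "KO", 1, seed=4, depth=15)
        )
        b = pgcmeth.filter_coverage(
            pgcmeth.simulate_sample(genome, "FGO", "KO", 2, seed=4, depth=15)
        )
        assert pgcmeth.replicate_correlation(a, b) >= 0.9

    def test_too_few_shared_windows(self):
        a = _calls([("chr1", i, 3, 3) for i in range(1, 10)])
        with pytest.raises(ValueError, match="shared windows"):
            pgcmeth.replicate_correlation(a, a)
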