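import warnings

import pytest

import pgcmeth


@pytest.fixture(scope="session")
def genome():
    """Default toy genome, shared across the suite (seed fixed)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pgcmeth.build_genome(seed=1)


def _pooled(genome, stage, genotype, seed=1, depth=None):
    reps = [
        pgcmeth.simulate_sample(genome, stage, genotype, replicate=r, seed=seed, depth=depth)
        for r in (1, 2)
    ]
    return pgcmeth.pool_replicates([pgcmeth.filter_coverage(r) for r in reps])


@pytest.fixture(scope="session")
def pooled_samples(genome):
    """Pooled, filtered control/KO calls for the four contrast stages."""
    return {
        (st, gt): _pooled(genome, st, gt)
        for st in ("E11.5", "E13.5", "E16.5", "FGO")
        for gt in ("control", "KO")
    }


@pytest.fixture(scope="session")
def e13_dmrs(genome, pooled_samples):
    return pgcmeth.call_dmrs(
        pooled_samples[("E13.5", "control")],
        pooled_samples[("E13.5", "KO")],
        label="E13.5",
        exclude_contigs=[genome.spec.spikein_contig],
    )


@pytest.fixture(scope="session")
def h3k9me3_track(genome):
    counts = pgcmeth.simulate_chip(genome, "H3K9me3", seed=1)
    return pgcmeth.window_enrichment(counts, "H3K9me3")
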