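import numpy as np
import pytest

from divscan.table import MISSING, GenotypeTable


def build_table(site_genotypes, populations, outgroup=(), chrom="chr1",
                depth=None, quality=None, start_pos=1, alts=None):
    """Hand-build a GenotypeTable.

    ``site_genotypes``: list of per-site lists of (a, b) tuples or None
    (missing); ``populations``: list of population labels per sample
    (label None marks an outgroup sample when combined with ``outgroup``).
    """
    n_sites = len(site_genotypes)
    n_samples = len(populations)
    g = np.full((n_sites, n_samples, 2), MISSING, dtype=np.int8)
    for s, row in enumerate(site_genotypes):
        for j, gt in enumerate(row):
            if gt is not None:
                g[s, j] = gt
    samples = [f"s{j + 1}" for j in range(n_samples)]
    population_of = {s: p for s, p in zip(samples, populations) if p is not None}
    og = {samples[j] for j in outgroup}
    if alts is None:
        alt_arr = np.empty(n_sites, dtype=object)
        alt_arr[:] = [("T",) if (g[s][g[s] >= 0] > 0).any() else () for s in range(n_sites)]
    else:
        alt_arr = np.empty(n_sites, dtype=object)
        alt_arr[:] = [tuple(a) for a in alts]
    return GenotypeTable(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.arange(start_pos, start_pos + n_sites, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alts=alt_arr,
        genotypes=g,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        quality=None if quality is None else np.asarray(quality, dtype=np.int16),
        samples=samples,
        population_of=population_of,
        outgroup=og,
    )


@pytest.fixture
def two_pop_table():
    """Two populations x two diploids, four sites incl. one invariant and
    one with a missing genotype."""
    return build_table(
        [
            [(0, 0), (0, 1), (0, 0), (1, 1)],
            [(0, 0), (0, 0), (0, 0), (0, 0)],
            [(0, 1), None, (1, 1), (0, 1)],
            [(1, 1), (1, 1), (0, 0), (0, 0)],
        ],
        populations=["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def small_sim():
    """A seeded three-population simulation reused across tests."""
    from divscan import SimulationConfig, simulate_genotypes

    cfg = SimulationConfig(
        n_populations=3, samples_per_population=(4, 3, 3),
        branch_lengths=(0.0003, 0.0004, 0.0005),
        n_regions=6, n_nongenic=2, region_length_bp=2000,
        window_length_bp=1000, missing_rate=0.08, expansion=False, seed=42,
    )
    table, truth = simulate_genotypes(cfg)
    return cfg, table, truth
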