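"""Degenerate-site classes, coverage gates, fixed differences, outliers."""

import numpy as np
import pandas as pd
import pytest

import divscan as dv
from divscan.config import DnDsConfig
from divscan.dnds import EXCLUDED, NONSYN, SYN

from .conftest import build_table


class TestCodonClasses:
    def test_nine_bp_frame0(self):
        labels = dv.codon_site_classes(9, 0)
        assert list(labels) == [NONSYN, NONSYN, SYN] * 3

    def test_trailing_partial_codon_dropped(self):
        labels = dv.codon_site_classes(10, 0)
        assert labels[9] == EXCLUDED

    def test_frame_offset_skips_leading_bases(self):
        labels = dv.codon_site_classes(10, 1)
        assert labels[0] == EXCLUDED
        assert list(labels[1:10]) == [NONSYN, NONSYN, SYN] * 3

    def test_missing_frame_rejected(self):
        with pytest.raises(dv.ConfigurationError):
            dv.codon_site_classes(9, ".")


class TestFixedDifference:
    @pytest.mark.parametrize("pop,og,expected", [
        ({"A"}, {"G"}, True),
        ({"A", "G"}, {"G"}, False),
        ({"A"}, {"A"}, False),
        ({"A"}, set(), False),
    ])
    def test_allele_set_disjointness(self, pop, og, expected):
        assert dv.is_fixed_difference(pop, og) is expected

    def test_disjoint_and_strict_rules_agree_on_biallelic(self):
        t, reg = dv.simulate_coding_gene(40, n_fixed_syn=3, n_fixed_nonsyn=5,
                                         missingness=0.1, seed=8)
        a = dv.gene_dnds(t, reg.iloc[0], "pop1", DnDsConfig(fixed_rule="disjoint"))
        b = dv.gene_dnds(t, reg.iloc[0], "pop1", DnDsConfig(fixed_rule="strict"))
        assert (a["fixed_nonsyn"], a["fixed_syn"]) == (b["fixed_nonsyn"], b["fixed_syn"])


class TestCoverageGate:
    def _gene_with_missing(self, n_missing):
        """One-codon gene; the synonymous site has ``n_missing`` of 10
        population genotypes missing and a genotyped outgroup."""
        pop_rows = lambda miss: [None] * miss + [(0, 0)] * (10 - miss)
        sites = [
            pop_rows(0) + [(1, 1)],          # codon pos 1 (nonsyn), fixed diff
            pop_rows(0) + [(0, 0)],          # codon pos 2
            pop_rows(n_missing) + [(1, 1)],  # codon pos 3 (syn), fixed diff
        ]
        t = build_table(sites, populations=["A"] * 10 + [None], outgroup=(10,))
        reg = dict(region_id="g", chrom="chr1", start=0, end=3, genic=1, frame=0)
        return t, reg

    def test_fifty_percent_missing_retained(self):
        t, reg = self._gene_with_missing(5)
        rec = dv.gene_dnds(t, reg, "A")
        assert rec["covered_syn_sites"] == 1 and rec["fixed_syn"] == 1

    def test_sixty_percent_missing_dropped(self):
        t, reg = self._gene_with_missing(6)
        rec = dv.gene_dnds(t, reg, "A")
        assert rec["covered_syn_sites"] == 0

    def test_outgroup_fully_missing_site_dropped(self):
        sites = [
            [(0, 0)] * 10 + [(1, 1)],
            [(0, 0)] * 10 + [(0, 0)],
            [(1, 1)] * 10 + [None],  # syn site, outgroup missing
        ]
        t = build_table(sites, populations=["A"] * 10 + [None], outgroup=(10,))
        reg = dict(region_id="g", chrom="chr1", start=0, end=3, genic=1, frame=0)
        rec = dv.gene_dnds(t, reg, "A")
        assert rec["covered_syn_sites"] == 0


class TestMissingnessMonotonicity:
    def test_masking_never_increases_fixed_counts(self):
        t, reg = dv.simulate_coding_gene(60, n_fixed_syn=4, n_fixed_nonsyn=7, seed=2)
        base = dv.gene_dnds(t, reg.iloc[0], "pop1")
        rng = np.random.default_rng(0)
        for frac in (0.1, 0.3, 0.6):
            t2 = t.copy()
            mask = rng.random((t.n_sites, t.n_samples)) < frac
            t2.genotypes[mask] = dv.MISSING
            rec = dv.gene_dnds(t2, reg.iloc[0], "pop1")
            assert rec["fixed_nonsyn"] <= base["fixed_nonsyn"]
            assert rec["fixed_syn"] <= base["fixed_syn"]


class TestOutliers:
    def test_hand_arithmetic_no_outliers(self):
        genes = pd.DataFrame(dict(
            gene=["g1", "g2", "g3", "g4"], population="A",
            ratio=[1.0, 1.0, 1.0, 10.0],
        ))
        out = dv.dnds_outliers(genes)
        pp = out["per_population"]["A"]
        assert pp["mean"] == pytest.approx(3.25)
        assert pp["sd"] == pytest.approx(3.897, abs=1e-3)
        assert pp["threshold"] == pytest.approx(14.94, abs=0.01)
        assert pp["outliers"] == set()

    def test_constructed_outlier_detected(self):
        rng = np.random.default_rng(1)
        ratios = list(rng.normal(1.0, 0.1, 50)) + [3.0]
        genes = pd.DataFrame(dict(gene=[f"g{i}" for i in range(51)],
                                  population="A", ratio=ratios))
        out = dv.dnds_outliers(genes)
        assert "g50" in out["per_population"]["A"]["outliers"]

    def test_cross_population_overlap(self):
        genes = pd.DataFrame(dict(
            gene=["g1"] * 21 + ["g1"] * 21,
            population=["A"] * 21 + ["B"] * 21,
            ratio=list(np.r_[np.full(20, 1.0) + np.arange(20) * 1e-3, 9.0]) * 2,
        ))
        genes["gene"] = [f"g{i}" for i in range(21)] * 2
        out = dv.dnds_outliers(genes)
        assert out["overlap"].loc["A", "B"] == 1
        assert out["union"] == {"g20"}

    def test_zero_sd_flagged(self):
        genes = pd.DataFrame(dict(gene=["g1", "g2"], population="A", ratio=[1.0, 1.0]))
        out = dv.dnds_outliers(genes)
        assert out["per_population"]["A"]["flagged"]


def test_injected_high_dnds_genes_recovered_as_outliers():
    """Genes injected with ~5x the neutral mean ratio are recovered as
    per-population outliers with recall >= 0.8 at fixed seed."""
    n_genes, n_inj = 300, 6
    cinj = [dv.CodingInjection(i * 45, "pop1", n_fixed_syn=0, n_fixed_nonsyn=200)
            for i in range(n_inj)]
    cfg = dv.SimulationConfig(
        n_populations=1, samples_per_population=(6,), branch_lengths=(0.0,),
        n_regions=n_genes, n_nongenic=0, region_length_bp=1500,
        window_length_bp=1500, missing_rate=0.0, expansion=False,
        with_depth=False, outgroup_divergence=0.04,
        coding_injections=cinj, seed=1007,
    )
    t, truth = dv.simulate_genotypes(cfg)
    genes = dv.gene_dnds_table(t, dv.regions_from_truth(truth, cfg))
    out = dv.dnds_outliers(genes)
    inj_ids = set(truth.genes["region_id"])
    bg_mean = genes.loc[~genes["gene"].isin(inj_ids), "ratio"].mean()
    inj_mean = genes.loc[genes["gene"].isin(inj_ids), "ratio"].mean()
    assert inj_mean >= 5 * bg_mean  # the signal really is strong
    recall = len(out["per_population"]["pop1"]["outliers"] & inj_ids) / n_inj
    assert recall >= 0.8


class TestDivergentSelection:
    def test_intersection_semantics(self):
        assert dv.divergent_selection_genes({"A", "B", "C"}, {"B", "D"}) == ["B"]
        assert dv.divergent_selection_genes({"A"}, {"B"}) == []

    def test_end_to_end_doubly_injected_gene_recovered(self):
        """A gene given both strong allele-frequency divergence (gene-flow
        window injection) and excess non-synonymous fixation must appear in
        the divergent-selection intersection."""
        inj_region = 0
        cfg = dv.SimulationConfig(
            n_populations=2, samples_per_population=(6, 6),
            branch_lengths=(0.0005, 0.0005),
            n_regions=40, n_nongenic=0, region_length_bp=900,
            window_length_bp=900, missing_rate=0.0, expansion=False,
            with_depth=False, outgroup_divergence=0.02,
            scenario_injections=[dv.ScenarioInjection(inj_region, "gene_flow")],
            coding_injections=[dv.CodingInjection(inj_region, "pop1",
                                                  n_fixed_syn=0, n_fixed_nonsyn=60)],
            seed=33,
        )
        table, truth = dv.simulate_genotypes(cfg)
        regions = dv.regions_from_truth(truth, cfg)
        assignment = dv.assign_windows(table, regions, cfg.window_length_bp)
        stats = dv.compute_window_stats(table, assignment, with_tajima=False)
        calls = dv.classify_pair(stats, ("pop1", "pop2"))
        fst_out = dv.fst_outlier_windows(calls, regions)
        fst_genes = set().union(*fst_out["genes"]) if len(fst_out) else set()
        genes = dv.gene_dnds_table(table, regions)
        dnds_out = dv.dnds_outliers(genes)
        hits = dv.divergent_selection_genes(fst_genes, dnds_out["union"])
        assert "r00001" in hits
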