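"""Unit and property tests for the windowed diversity estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import divscan as dv
from divscan.table import MISSING

from .conftest import build_table
from . import oracles


class TestSiteEstimators:
    def test_site_pi_enumerates_pairs(self):
        # alleles {0,0,0,1}: 3 of the 6 haplotype pairs differ
        assert dv.site_pi(1, 4) == (3, 6)

    def test_site_pi_invariant(self):
        assert dv.site_pi(0, 10) == (0, 45)

    def test_site_pi_requires_two_haplotypes(self):
        with pytest.raises(dv.ConfigurationError):
            dv.site_pi(0, 1)

    def test_site_dxy_cross_pairs(self):
        # A={0,0}, B={0,1}: 2 of 4 cross pairs differ
        assert dv.site_dxy(0, 2, 1, 2) == (2, 4)

    def test_site_dxy_complete_divergence(self):
        assert dv.site_dxy(0, 4, 4, 4) == (16, 16)

    def test_site_dxy_invariant(self):
        assert dv.site_dxy(0, 3, 0, 5) == (0, 15)

    def test_hudson_fixed_difference(self):
        num, den = dv.hudson_fst_site(1.0, 10, 0.0, 10)
        assert num == pytest.approx(1.0) and den == pytest.approx(1.0)

    def test_hudson_equal_frequencies_negative_numerator(self):
        num, den = dv.hudson_fst_site(0.5, 10, 0.5, 10)
        assert num == pytest.approx(-0.0556, abs=1e-4)
        assert den == pytest.approx(0.5)
        assert num / den == pytest.approx(-0.111, abs=1e-3)

    def test_hudson_invariant_contributes_nothing(self):
        assert dv.hudson_fst_site(0.0, 10, 0.0, 10) == (0.0, 0.0)


class TestWindowAggregation:
    def test_window_pi_ratio_of_sums(self):
        # one variant site ({0,1} in 2 haplotypes) + 9 invariant sites:
        # Pi = 1 / (1 + 9) = 0.1, NOT the mean of per-site ratios
        sites = [[(0, 1)]] + [[(0, 0)]] * 9
        t = build_table(sites, populations=["A"])
        c1, n = t.allele_counts(np.array([0]))
        pi, ns, nv = dv.window_pi(c1, n, np.zeros(10, dtype=int), 1)
        assert pi[0] == pytest.approx(0.1)
        assert ns[0] == 10 and nv[0] == 1

    def test_all_invariant_window_pi_zero(self):
        t = build_table([[(0, 0), (0, 0)]] * 5, populations=["A", "A"])
        c1, n = t.allele_counts(np.array([0, 1]))
        pi, _, _ = dv.window_pi(c1, n, np.zeros(5, dtype=int), 1)
        assert pi[0] == 0.0

    def test_window_fst_single_fixed_site(self):
        t = build_table([[(0, 0), (0, 0), (1, 1), (1, 1)]], populations=["A", "A", "B", "B"])
        c1a, na = t.allele_counts(np.array([0, 1]))
        c1b, nb = t.allele_counts(np.array([2, 3]))
        fst, _, _ = dv.window_fst(c1a, na, c1b, nb, np.zeros(1, dtype=int), 1)
        assert fst[0] == pytest.approx(1.0)

    def test_zero_comparison_window_is_nan(self):
        t = build_table([[None, None]], populations=["A", "A"])
        c1, n = t.allele_counts(np.array([0, 1]))
        pi, ns, _ = dv.window_pi(c1, n, np.zeros(1, dtype=int), 1)
        assert np.isnan(pi[0]) and ns[0] == 0


SEED_TABLES = st.integers(min_value=0, max_value=10_000)


class TestOracleEquivalence:
    """Estimators must match exhaustive pair enumeration exactly."""

    @staticmethod
    def _random_table(seed, n_sites=25, na=4, nb=5, missing=0.15):
        rng = np.random.default_rng(seed)
        sites = []
        for _ in range(n_sites):
            row = []
            for _ in range(na + nb):
                if rng.random() < missing:
                    row.append(None)
                else:
                    row.append(tuple(rng.integers(0, 2, size=2)))
            sites.append(row)
        return build_table(sites, populations=["A"] * na + ["B"] * nb)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=SEED_TABLES)
    def test_pi_dxy_fst_match_enumeration(self, seed):
        t = self._random_table(seed)
        ia, ib = t.population_indices("A"), t.population_indices("B")
        c1a, na = t.allele_counts(ia)
        c1b, nb = t.allele_counts(ib)
        widx = np.zeros(t.n_sites, dtype=int)
        pi, _, _ = dv.window_pi(c1a, na, widx, 1)
        dxy, _, _ = dv.window_dxy(c1a, na, c1b, nb, widx, 1)
        fst, _, _ = dv.window_fst(c1a, na, c1b, nb, widx, 1)
        assert pi[0] == pytest.approx(oracles.enum_pi(t, ia), abs=1e-12)
        assert dxy[0] == pytest.approx(oracles.enum_dxy(t, ia, ib), abs=1e-12)
        ofst = oracles.enum_hudson_fst(t, ia, ib)
        if np.isnan(ofst):
            assert np.isnan(fst[0])
        else:
            assert fst[0] == pytest.approx(ofst, abs=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=SEED_TABLES)
    def test_symmetry_and_bounds(self, seed):
        t = self._random_table(seed)
        ia, ib = t.population_indices("A"), t.population_indices("B")
        c1a, na = t.allele_counts(ia)
        c1b, nb = t.allele_counts(ib)
        widx = np.zeros(t.n_sites, dtype=int)
        dxy_ab, _, _ = dv.window_dxy(c1a, na, c1b, nb, widx, 1)
        dxy_ba, _, _ = dv.window_dxy(c1b, nb, c1a, na, widx, 1)
        fst_ab, _, _ = dv.window_fst(c1a, na, c1b, nb, widx, 1)
        fst_ba, _, _ = dv.window_fst(c1b, nb, c1a, na, widx, 1)
        assert dxy_ab[0] == pytest.approx(dxy_ba[0], abs=1e-15)
        np.testing.assert_allclose(fst_ab, fst_ba, atol=1e-15)
        pi, _, _ = dv.window_pi(c1a, na, widx, 1)
        assert 0.0 <= pi[0] <= 1.0
        assert 0.0 <= dxy_ab[0] <= 1.0
        if np.isfinite(fst_ab[0]):
            assert fst_ab[0] <= 1.0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=SEED_TABLES)
    def test_fully_missing_genotypes_change_nothing(self, seed):
        """Adding fully-missing genotypes must leave every statistic alone."""
        t = self._random_table(seed, missing=0.1)
        # append one all-missing sample to each population
        import numpy as _np
        g = _np.full((t.n_sites, t.n_samples + 2, 2), MISSING, dtype=_np.int8)
        g[:, : t.n_samples] = t.genotypes
        from divscan.table import GenotypeTable
        t3 = GenotypeTable(
            chrom=t.chrom, pos=t.pos, ref=t.ref, alts=t.alts, genotypes=g,
            samples=t.samples + ["x1", "x2"],
            population_of={**t.population_of, "x1": "A", "x2": "B"},
            outgroup=set(),
        )
        widx = _np.zeros(t.n_sites, dtype=int)
        for tab in (t, t3):
            ia, ib = tab.population_indices("A"), tab.population_indices("B")
            c1a, na = tab.allele_counts(ia)
            c1b, nb = tab.allele_counts(ib)
            tab._pi = dv.window_pi(c1a, na, widx, 1)[0][0]
            tab._dxy = dv.window_dxy(c1a, na, c1b, nb, widx, 1)[0][0]
            tab._fst = dv.window_fst(c1a, na, c1b, nb, widx, 1)[0][0]
        assert t._pi == pytest.approx(t3._pi, abs=1e-15)
        assert t._dxy == pytest.approx(t3._dxy, abs=1e-15)
        np.testing.assert_allclose(t._fst, t3._fst, atol=1e-15)


class TestTajimasD:
    def test_singleton_window_matches_rational_oracle(self):
        # n=4 haplotypes, one singleton site
        d = dv.tajimas_d(S=1, theta_pi=0.5, n=4)
        assert d == pytest.approx(oracles.exact_tajimas_d([1], 4), abs=1e-12)
        assert d == pytest.approx(-0.612, abs=1e-3)

    def test_balanced_window_matches_rational_oracle(self):
        d = dv.tajimas_d(S=1, theta_pi=2 / 3, n=4)
        assert d == pytest.approx(oracles.exact_tajimas_d([2], 4), abs=1e-12)
        assert d == pytest.approx(1.633, abs=1e-3)

    def test_monomorphic_window_undefined(self):
        assert np.isnan(dv.tajimas_d(S=0, theta_pi=0.0, n=4))

    @pytest.mark.parametrize("counts,n", [([1, 2, 3], 8), ([1, 1, 1, 5], 6), ([3], 10)])
    def test_vectorized_window_matches_scalar_oracle(self, counts, n):
        c1 = np.array(counts)
        nn = np.full(len(counts), n)
        d, n_complete, S = dv.window_tajimas_d(c1, nn, n, np.zeros(len(counts), dtype=int), 1)
        assert d[0] == pytest.approx(oracles.exact_tajimas_d(counts, n), abs=1e-12)
        assert S[0] == len(counts)

    def test_complete_case_excludes_sites_with_missing(self):
        """A site missing one genotype in the population is excluded and n
        stays at the full haplotype count."""
        sites = [
            [(0, 1), (0, 0)],   # complete, singleton
            [(0, 1), None],     # incomplete -> excluded
        ]
        t = build_table(sites, populations=["A", "A"])
        c1, n = t.allele_counts(np.array([0, 1]))
        d, n_complete, S = dv.window_tajimas_d(c1, n, 4, np.zeros(2, dtype=int), 1)
        assert n_complete[0] == 1 and S[0] == 1
        assert d[0] == pytest.approx(oracles.exact_tajimas_d([1], 4), abs=1e-12)


def test_compute_window_stats_tidy_schema(small_sim):
    cfg, table, truth = small_sim
    assignment = dv.assign_windows(table, None, cfg.window_length_bp)
    stats = dv.compute_window_stats(table, assignment)
    assert set(stats["stat"]) == {"pi", "dxy", "fst", "tajima_d"}
    assert set(stats.columns) == {"chrom", "window_start", "window_end", "pop",
                                  "stat", "value", "n_sites", "n_variant_sites"}
    # 3 populations -> 3 pairs
    assert stats.loc[stats["stat"] == "fst", "pop"].nunique() == 3
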