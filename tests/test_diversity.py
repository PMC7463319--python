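"""Diversity and structure statistics: closed forms, oracles, permutation nulls."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from fragdrift.diversity import (
    allelic_richness,
    bh_fdr,
    brookfield_null_freq,
    expected_het,
    haversine_km,
    ibd_test,
    observed_het,
    pairwise_fst,
    wc_fstatistics,
    _mantel,
)
from fragdrift.genotypes import GenotypeMatrix, SiteInfo
from fragdrift.synthetic import MetapopSpec, generate_metapopulation, generate_population

from conftest import random_matrix


def _single_locus(genotypes, pops=None):
    n = len(genotypes)
    pops = pops or ["P"] * n
    return GenotypeMatrix(
        [f"i{i}" for i in range(n)], pops, ["L1"], np.array(genotypes)[:, None, :]
    )


class TestHeterozygosities:
    def test_observed_het_hand_case(self):
        g = _single_locus([[100, 100], [100, 102], [102, 102]])
        assert observed_het(g).loc["P", "L1"] == pytest.approx(1 / 3)

    def test_all_homozygotes(self):
        g = _single_locus([[100, 100], [102, 102]])
        assert observed_het(g).loc["P", "mean"] == 0.0

    def test_observed_het_brute_force(self):
        rng = np.random.default_rng(4)
        g = random_matrix(rng, n=50, n_loci=10, missing_rate=0.1)
        table = observed_het(g)
        for pop in g.populations:
            sub = g.by_population(pop)
            for j, name in enumerate(g.locus_names):
                calls = [c for c in sub.calls[:, j, :] if c[0] != -1]
                want = np.mean([a != b for a, b in calls]) if calls else np.nan
                got = table.loc[pop, name]
                assert got == pytest.approx(want) or (np.isnan(got) and np.isnan(want))

    def test_expected_het_closed_form(self):
        # n = 2 diploids, p = (0.5, 0.5): (2n/(2n-1)) * 0.5 = 2/3
        g = _single_locus([[100, 102], [100, 102]])
        assert expected_het(g).loc["P", "L1"] == pytest.approx(2 / 3)

    def test_monomorphic_he_zero(self):
        g = _single_locus([[100, 100], [100, 100]])
        assert expected_het(g).loc["P", "L1"] == 0.0

    def test_expected_het_brute_force_unbiased(self):
        rng = np.random.default_rng(5)
        g = random_matrix(rng, n=18, n_loci=6, missing_rate=0.1)
        table = expected_het(g)
        for pop in g.populations:
            sub = g.by_population(pop)
            for j, name in enumerate(g.locus_names):
                genes = [int(a) for c in sub.calls[:, j, :] for a in c if a != -1]
                if len(genes) < 2:
                    continue
                n = len(genes)
                p = np.array([genes.count(a) for a in set(genes)]) / n
                want = n / (n - 1) * (1 - np.sum(p**2))
                assert table.loc[pop, name] == pytest.approx(want)

    def test_large_sample_matches_spectrum(self, spectra10):
        g = generate_population(2000, spectra10, seed=6)
        he = expected_het(g).loc["pop1", "mean"]
        want = np.mean([1 - s @ s for s in spectra10])
        assert abs(he - want) < 0.01


class TestAllelicRichness:
    def test_binomial_coefficient_hand_oracle(self):
        # allele counts (2, 2) in 4 genes, G = 2: 2 * (1 - C(2,2)/C(4,2)) = 5/3
        g = _single_locus([[100, 102], [100, 102]])
        r = allelic_richness(g, rarefaction_genes=2).loc["P", "L1"]
        assert r == pytest.approx(2 * (1 - comb(2, 2) / comb(4, 2)))
        assert r == pytest.approx(5 / 3)

    def test_full_sample_rarefaction_equals_count(self):
        g = _single_locus([[100, 102], [104, 104], [100, 106]])
        r = allelic_richness(g, rarefaction_genes=6).loc["P", "L1"]
        assert r == pytest.approx(4.0)

    def test_monomorphic_richness_one(self):
        g = _single_locus([[100, 100], [100, 100]])
        assert allelic_richness(g).loc["P", "L1"] == pytest.approx(1.0)

    def test_monotone_in_rarefaction_size(self, spectra5):
        g = generate_population(20, spectra5, seed=7)
        vals = [
            allelic_richness(g, rarefaction_genes=G).loc["pop1", "mean"]
            for G in (2, 10, 20, 40)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_oversized_rarefaction_names_population(self, spectra5):
        g = generate_population(10, spectra5, seed=8)
        with pytest.raises(ValueError, match="pop1"):
            allelic_richness(g, rarefaction_genes=21)


class TestWcFstatistics:
    def test_fixed_difference_theta_one(self):
        g = _single_locus(
            [[100, 100], [100, 100], [200, 200], [200, 200]],
            pops=["A", "A", "B", "B"],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert wc_fstatistics(g, n_bootstrap=10).theta == pytest.approx(1.0)

    def test_identical_populations_theta_near_zero(self, spectra10):
        g = generate_population(400, spectra10, seed=9)
        pops = np.array(["A"] * 200 + ["B"] * 200, dtype=object)
        g2 = GenotypeMatrix(g.ids, pops, g.locus_names, g.calls)
        assert abs(wc_fstatistics(g2, n_bootstrap=50).theta) < 0.01

    def test_single_polymorphic_locus_warns_degenerate_ci(self):
        g = _single_locus(
            [[100, 102], [100, 100], [102, 102], [100, 102]],
            pops=["A", "A", "B", "B"],
        )
        with pytest.warns(UserWarning, match="degenerate"):
            res = wc_fstatistics(g)
        assert res.ci_low == res.ci_high == pytest.approx(res.theta)

    def test_ci_brackets_estimate(self, spectra10):
        g = generate_metapopulation(
            MetapopSpec(n_pops=8, n_per_pop=25, fst=0.1,
                        spectra=tuple(map(tuple, spectra10)), seed=10)
        )
        res = wc_fstatistics(g, seed=1)
        assert res.ci_low <= res.theta <= res.ci_high

    def test_requires_two_populations(self, spectra5):
        g = generate_population(10, spectra5, seed=1)
        with pytest.raises(ValueError, match="two populations"):
            wc_fstatistics(g)


class TestPairwiseFst:
    def test_fixed_difference_minimum_p(self):
        # 10 + 10 individuals: only 2 of C(20,10) label assignments keep the
        # perfect separation, so the observed ordering is essentially forced
        g = _single_locus(
            [[100, 100]] * 10 + [[200, 200]] * 10,
            pops=["A"] * 10 + ["B"] * 10,
        )
        theta, p = pairwise_fst(g, permutations=99, seed=1)
        assert theta.loc["A", "B"] == pytest.approx(1.0)
        assert p.loc["A", "B"] == pytest.approx(1 / 100)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # 2 + 2 individuals: only C(4,2) = 6 distinct label assignments
        g = _single_locus(
            [[100, 102], [100, 100], [102, 102], [100, 102]],
            pops=["A", "A", "B", "B"],
        )
        from fragdrift.diversity import _locus_codes, _theta_only

        codes = _locus_codes(g)
        obs = _theta_only(codes, np.array([0, 0, 1, 1]), 2)
        thetas = []
        for combo in itertools.combinations(range(4), 2):
            lab = np.zeros(4, dtype=int)
            lab[list(combo)] = 1
            thetas.append(_theta_only(codes, lab, 2))
        exhaustive = np.mean([t >= obs for t in thetas if not np.isnan(t)])
        _, p = pairwise_fst(g, permutations=3000, seed=2)
        assert abs(p.loc["A", "B"] - exhaustive) < 0.05


class TestBrookfield:
    def test_closed_form(self):
        assert brookfield_null_freq(0.5, 0.4) == pytest.approx(0.1 / 1.5)

    def test_equal_heterozygosities(self):
        assert brookfield_null_freq(0.6, 0.6) == 0.0

    def test_heterozygote_excess_floored(self):
        assert brookfield_null_freq(0.4, 0.6) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            brookfield_null_freq(1.2, 0.5)


class TestIbd:
    @staticmethod
    def _sites(n=5, spacing=0.5):
        return [SiteInfo(f"S{i}", -37.0 - spacing * i, 143.0 + spacing * i) for i in range(n)]

    def test_perfect_distance_decay_mantel_r_one(self):
        sites = self._sites()
        lat = np.array([s.latitude for s in sites])
        lon = np.array([s.longitude for s in sites])
        d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        x = np.log(np.where(d > 0, d, 1.0))
        theta = x / (1.0 + x)  # linearised theta equals log distance
        m = pd.DataFrame(theta, index=[s.code for s in sites], columns=[s.code for s in sites])
        res = ibd_test(m, sites, permutations=200, seed=1)
        assert res.mantel_r == pytest.approx(1.0, abs=1e-9)
        assert res.slope > 0 and res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_mantel_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        n = 5
        x = rng.uniform(size=(n, n)); x = (x + x.T) / 2; np.fill_diagonal(x, 0)
        y = rng.uniform(size=(n, n)); y = (y + y.T) / 2; np.fill_diagonal(y, 0)
        iu = np.triu_indices(n, 1)

        def corr(m):
            a, b = x[iu], m[iu]
            return np.corrcoef(a, b)[0, 1]

        obs = corr(y)
        hits = sum(
            abs(corr(y[np.ix_(p, p)])) >= abs(obs)
            for p in itertools.permutations(range(n))
        )
        exhaustive = hits / 120
        _, p_hat = _mantel(x, y, permutations=4000, rng=np.random.default_rng(3))
        assert abs(p_hat - exhaustive) < 0.05

    def test_mantel_cross_checked_against_skbio(self):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        rng = np.random.default_rng(13)
        n = 8
        x = rng.uniform(0.1, 1, size=(n, n)); x = (x + x.T) / 2; np.fill_diagonal(x, 0)
        y = x + rng.normal(0, 0.1, size=(n, n)); y = (y + y.T) / 2
        np.fill_diagonal(y, 0); y = np.abs(y)
        r_ours, p_ours = _mantel(x, y, permutations=999, rng=np.random.default_rng(4))
        r_sk, p_sk, _ = skbio_mantel(
            DistanceMatrix(x), DistanceMatrix(y), method="pearson",
            permutations=999, alternative="two-sided",
        )
        assert r_ours == pytest.approx(r_sk, abs=1e-10)
        assert abs(p_ours - p_sk) < 0.08

    def test_requires_three_sites(self):
        sites = self._sites(2)
        m = pd.DataFrame(np.zeros((2, 2)), index=["S0", "S1"], columns=["S0", "S1"])
        with pytest.raises(ValueError, match="three sites"):
            ibd_test(m, sites)


class TestBhFdr:
    def test_hand_step_up(self):
        reject, _ = bh_fdr([0.01, 0.02, 0.9], q=0.05)
        assert reject.tolist() == [True, True, False]

    def test_all_ones_none_rejected(self):
        reject, _ = bh_fdr([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_single_small_p_rejected(self):
        reject, _ = bh_fdr([0.04], q=0.05)
        assert reject.tolist() == [True]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.4])
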