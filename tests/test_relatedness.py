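"""Relatedness estimators, ML relationship classification, spatial structure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from fragdrift.genotypes import GenotypeMatrix
from fragdrift.relatedness import (
    ClassDiagnosticsError,
    class_relatedness_profile,
    loiselle_kinship,
    lr_relatedness,
    ml_relationship,
    qg_relatedness,
    reference_frequencies,
    relatedness_matrix,
    site_relatedness_summary,
    spatial_autocorrelogram,
)
from fragdrift.synthetic import (
    generate_pedigreed_pairs,
    generate_population,
    generate_spatial_population,
)


def _pair_matrix(gx, gy, pops=("P", "P")):
    calls = np.stack([np.asarray(gx), np.asarray(gy)])
    return GenotypeMatrix(["x", "y"], list(pops), [f"L{j}" for j in range(calls.shape[1])], calls)


class TestQuellerGoodnight:
    def test_identical_homozygotes_r_one(self):
        # hand evaluation at p = 0.5 biallelic loci: num = den = 1 per locus
        g = _pair_matrix([[100, 100]] * 4, [[100, 100]] * 4)
        ref = [({100: 0.5, 102: 0.5}, 40)] * 4
        assert qg_relatedness(g, (0, 1), ref) == pytest.approx(1.0)

    def test_mean_over_unrelated_pairs_near_zero(self, spectra10):
        g, _ = generate_pedigreed_pairs("U", 600, spectra10, seed=1)
        ref = reference_frequencies(g)
        r = np.mean([qg_relatedness(g, (2 * i, 2 * i + 1), ref) for i in range(600)])
        assert abs(r) < 0.04

    def test_mean_over_full_sib_pairs_near_half(self, spectra10):
        g, _ = generate_pedigreed_pairs("FS", 600, spectra10, seed=2)
        ref = reference_frequencies(g)
        r = np.mean([qg_relatedness(g, (2 * i, 2 * i + 1), ref) for i in range(600)])
        assert abs(r - 0.5) < 0.04

    def test_monomorphic_locus_skipped(self):
        # the monomorphic first locus must not poison the estimate: only the
        # informative homozygous-shared locus contributes, giving r = 1
        g = _pair_matrix([[100, 100], [200, 200]], [[100, 100], [200, 200]])
        ref = [({100: 1.0}, 40), ({200: 0.5, 202: 0.5}, 40)]
        assert qg_relatedness(g, (0, 1), ref) == pytest.approx(1.0)


class TestLynchRitlandAndLoiselle:
    def test_po_pairs_mean_lr_near_half(self, spectra10):
        g, _ = generate_pedigreed_pairs("PO", 600, spectra10, seed=3)
        ref = reference_frequencies(g)
        r = np.mean([lr_relatedness(g, (2 * i, 2 * i + 1), ref) for i in range(600)])
        assert abs(r - 0.5) < 0.04

    def test_unrelated_loiselle_kinship_near_zero(self, spectra10):
        g, _ = generate_pedigreed_pairs("U", 600, spectra10, seed=4)
        ref = reference_frequencies(g)
        f = np.mean([loiselle_kinship(g, (2 * i, 2 * i + 1), ref) for i in range(600)])
        assert abs(f) < 0.02

    def test_estimators_rank_agree_on_mixed_pedigrees(self, spectra10):
        parts, qg, lr = [], [], []
        for rel, seed in (("U", 5), ("HS", 6), ("FS", 7), ("PO", 8)):
            g, _ = generate_pedigreed_pairs(rel, 100, spectra10, seed=seed)
            parts.append(g)
        g = GenotypeMatrix.concat(parts)
        ref = reference_frequencies(g)
        for i in range(400):
            qg.append(qg_relatedness(g, (2 * i, 2 * i + 1), ref))
            lr.append(lr_relatedness(g, (2 * i, 2 * i + 1), ref))
        rho = spearmanr(qg, lr).statistic
        assert rho > 0.8

    def test_matrix_fast_path_matches_pairwise(self, spectra10):
        g, _ = generate_pedigreed_pairs("FS", 15, spectra10, seed=9)
        ref = reference_frequencies(g)
        for est, fn in (
            ("qg", qg_relatedness),
            ("lr", lr_relatedness),
            ("loiselle", loiselle_kinship),
        ):
            m = relatedness_matrix(g, est)
            for i, j in [(0, 1), (2, 9), (5, 11)]:
                assert m[i, j] == pytest.approx(fn(g, (i, j), ref), abs=1e-10)


class TestMlRelationship:
    def test_no_shared_alleles_excludes_po(self):
        g = _pair_matrix([[100, 102]], [[104, 106]])
        ref = [({100: 0.25, 102: 0.25, 104: 0.25, 106: 0.25}, 40)]
        label, logl = ml_relationship(g, (0, 1), ref)
        assert logl["PO"] == -np.inf
        assert label != "PO"

    def test_po_pairs_classified_as_close_kin(self, spectra10):
        g, _ = generate_pedigreed_pairs("PO", 500, spectra10, seed=10)
        ref = reference_frequencies(g)
        labels = [ml_relationship(g, (2 * i, 2 * i + 1), ref)[0] for i in range(500)]
        assert np.mean([l in ("PO", "FS") for l in labels]) >= 0.8

    def test_unrelated_pairs_mostly_unrelated(self, spectra10):
        g, _ = generate_pedigreed_pairs("U", 500, spectra10, seed=11)
        ref = reference_frequencies(g)
        labels = [ml_relationship(g, (2 * i, 2 * i + 1), ref)[0] for i in range(500)]
        assert np.mean([l == "U" for l in labels]) >= 0.7

    def test_confusion_matrix_diagonally_dominant(self, spectra10):
        # at 10 informative loci each truth class is most often given its own label,
        # with PO/FS confusion allowed to merge into "close kin"
        counts = {}
        for rel, seed in (("U", 12), ("FS", 13), ("PO", 14)):
            g, _ = generate_pedigreed_pairs(rel, 300, spectra10, seed=seed)
            ref = reference_frequencies(g)
            labels = [ml_relationship(g, (2 * i, 2 * i + 1), ref)[0] for i in range(300)]
            counts[rel] = labels
        assert np.mean([l == "U" for l in counts["U"]]) > 0.5
        assert np.mean([l in ("FS", "PO") for l in counts["FS"]]) > 0.5
        assert np.mean([l == "PO" for l in counts["PO"]]) > 0.5

    def test_ties_break_toward_less_related(self):
        # a pair of identical homozygotes for the only allele seen gives equal
        # likelihood under every hypothesis at an uninformative locus
        g = _pair_matrix([[100, 100]], [[100, 100]])
        ref = [({100: 1.0, 102: 1e-9}, 40)]
        label, _ = ml_relationship(g, (0, 1), ref)
        assert label == "U"


class TestSiteRelatednessSummary:
    def test_identical_twins_fully_related(self):
        calls = np.repeat([[[100, 102], [200, 204], [300, 302], [400, 404]]], 2, axis=0)
        g = GenotypeMatrix(["t1", "t2"], ["P", "P"], ["L1", "L2", "L3", "L4"], calls)
        table = site_relatedness_summary(g)
        assert table.loc["P", "U"] == 0.0
        assert table.loc["P", "related"] == 100.0

    def test_percentages_sum_to_hundred(self, spectra10):
        g = generate_population(15, spectra10, seed=15)
        table = site_relatedness_summary(g)
        assert table.loc["pop1", ["U", "HS", "FS", "PO"]].sum() == pytest.approx(100.0)

    def test_single_individual_population_empty(self, spectra5):
        g = generate_population(1, spectra5, seed=16)
        assert site_relatedness_summary(g).loc["pop1"].isna().all()

    def test_unrelated_population_low_related_fraction(self, spectra10):
        g = generate_population(25, spectra10, seed=17)
        table = site_relatedness_summary(g)
        # related calls reflect only the classifier's false-positive rate
        assert table.loc["pop1", "related"] < 45.0


class TestSpatialAutocorrelogram:
    def test_clone_pairs_at_zero_distance_positive(self, spectra10):
        g = generate_population(30, spectra10, seed=18)
        calls = np.vstack([g.calls, g.calls[:10]])  # 10 planted clones
        g2 = GenotypeMatrix([f"i{i}" for i in range(40)], ["P"] * 40, g.loci, calls)
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 500, size=(40, 2))
        xy[30:] = xy[:10]  # clones co-located with their originals
        res = spatial_autocorrelogram(g2, xy, n_classes=4, permutations=199, seed=2)
        first = res.table.iloc[0]
        assert first["d_min"] == 0.0 and first["d_max"] == 0.0
        assert first["r"] > first["null_high"]

    def test_family_layout_shape(self, spectra10):
        centers = [(300.0 * i, 0.0) for i in range(8)]
        g, xy = generate_spatial_population(centers, 20.0, 10, spectra10, seed=19)
        res = spatial_autocorrelogram(g, xy, n_classes=8, permutations=199, seed=3)
        t = res.table
        assert t.iloc[0]["r"] > t.iloc[0]["null_high"]  # within-family class
        # signal crosses zero once classes reach the inter-family scale
        beyond = t[t["d_min"] > 300.0]
        assert (beyond["r"] < t.iloc[0]["r"] / 2).all()

    def test_pair_counts_partition_all_pairs(self, spectra5):
        g = generate_population(25, spectra5, seed=20)
        xy = np.random.default_rng(4).uniform(0, 100, size=(25, 2))
        res = spatial_autocorrelogram(g, xy, n_classes=5, permutations=19, seed=5)
        assert res.table["n_pairs"].sum() == 25 * 24 // 2

    def test_multi_location_mode_uses_within_location_pairs(self, spectra5):
        g1 = generate_population(10, spectra5, seed=21, pop="A")
        g2 = generate_population(10, spectra5, seed=22, pop="B")
        g = GenotypeMatrix.concat([g1, g2])
        xy = np.random.default_rng(6).uniform(0, 100, size=(20, 2))
        res = spatial_autocorrelogram(
            g, xy, n_classes=3, permutations=19, seed=7, locations=np.asarray(g.pops)
        )
        assert res.table["n_pairs"].sum() == 2 * (10 * 9 // 2)


class TestClassRelatednessProfile:
    def test_family_layout_first_class_above_null(self, spectra10):
        centers = [(250.0 * i, 0.0) for i in range(10)]
        g, xy = generate_spatial_population(centers, 15.0, 10, spectra10, seed=23)
        table = class_relatedness_profile(
            g, xy, n_classes=8, permutations=199, estimators=("qg",), seed=8
        )
        first = table.iloc[0]
        assert first["qg_mean"] > first["qg_null_high"]
        assert first["qg_p"] < 0.05

    def test_diagnostics_verified_by_direct_count(self, spectra10):
        centers = [(200.0 * i, 100.0 * (i % 2)) for i in range(10)]
        g, xy = generate_spatial_population(centers, 25.0, 10, spectra10, seed=24)
        table = class_relatedness_profile(
            g, xy, n_classes=8, permutations=49, estimators=("qg",), seed=9
        )
        assert (table["n_pairs"] > 100).all()
        assert table["n_pairs"].sum() == 100 * 99 // 2
        assert (table["participation"] > 0.5).all()
        assert (table["cv_participation"] < 1.0).all()

    def test_violated_diagnostics_refused_with_report(self, spectra5):
        g = generate_population(10, spectra5, seed=25)
        xy = np.random.default_rng(10).uniform(0, 100, size=(10, 2))
        with pytest.raises(ClassDiagnosticsError, match="pairs"):
            class_relatedness_profile(g, xy, n_classes=3, permutations=9, seed=11)
        table = class_relatedness_profile(
            g, xy, n_classes=3, permutations=9, seed=11, override_diagnostics=True
        )
        assert len(table) >= 1

    def test_exchangeable_layout_no_signal(self, spectra10):
        # all families co-located: distance carries no relatedness information
        g, _ = generate_spatial_population([(0.0, 0.0)] * 6, 10.0, 10, spectra10, seed=26)
        xy = np.random.default_rng(12).uniform(0, 50, size=(60, 2))
        table = class_relatedness_profile(
            g, xy, n_classes=4, permutations=199, estimators=("qg",), seed=13,
            override_diagnostics=True,
        )
        assert (table["qg_p"] > 0.01).all()
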