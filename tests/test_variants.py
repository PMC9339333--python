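"""SNP filter cascade, effect classes, diversity and mutation load."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triadkit.variants import (
    CATEGORIES,
    classify_effect,
    classify_effects,
    compare_loads,
    family_snp_proportions,
    filter_snps,
    flag_extreme_individuals,
    mutation_load,
    site_pi,
    site_pi_all,
)

from conftest import make_variants


class TestFilterCascade:
    def test_empty_input(self):
        v, g = make_variants([])
        g = g.reshape(0, 0)
        out, gout, stages = filter_snps(v, g, set())
        assert len(out) == 0
        assert all(c == 0 for c in stages.values())

    def test_missingness_boundary_is_strict(self):
        # exactly 25% missing calls is retained (rule is "> 25%")
        v, g = make_variants(
            [
                {"genotypes": [-1, 1, 1, 1]},
                {"genotypes": [-1, -1, 1, 1]},
            ]
        )
        out, _, stages = filter_snps(v, g, {"g1"})
        assert stages["missingness"] == 1
        assert list(out["snp_id"]) == ["s0"]

    def test_hand_traced_toy_table(self):
        # 12 SNPs, each stage removes exactly the ones traced by hand
        specs = [
            {"snp_id": "keep1", "consequence": "synonymous", "genotypes": [1, 1, 0, 0]},
            {"snp_id": "noncoding", "consequence": "other", "in_canonical_cds": False,
             "genotypes": [1, 1, 0, 0]},
            {"snp_id": "splice", "consequence": "missense", "sift": 0.3, "splice_region": True,
             "genotypes": [1, 1, 0, 0]},
            {"snp_id": "nosift", "consequence": "missense", "genotypes": [1, 1, 0, 0]},
            {"snp_id": "gappy", "consequence": "synonymous", "genotypes": [-1, -1, 1, 0]},
            {"snp_id": "rare", "consequence": "synonymous", "genotypes": [0, 0, 0, 0]},
            {"snp_id": "unexpressed", "gene_id": "g_off", "consequence": "synonymous",
             "genotypes": [1, 1, 0, 0]},
            {"snp_id": "swept", "consequence": "synonymous", "flag_sweep": True,
             "genotypes": [1, 1, 0, 0]},
            {"snp_id": "introgressed", "consequence": "missense", "sift": 0.01,
             "flag_introgression": True, "genotypes": [1, 1, 0, 0]},
            {"snp_id": "multisyn", "consequence": "synonymous", "n_annotations": 2,
             "genotypes": [1, 1, 0, 0]},
            {"snp_id": "keep2", "consequence": "missense", "sift": 0.04, "genotypes": [2, 1, 0, 0]},
            {"snp_id": "keep3", "consequence": "stop_gained", "genotypes": [1, 0, 1, 0]},
        ]
        v, g = make_variants(specs)
        out, gout, stages = filter_snps(v, g, {"g1"})
        assert sorted(out["snp_id"]) == ["keep1", "keep2", "keep3"]
        assert stages["input"] == 12
        assert stages["canonical_cds"] == 11
        assert stages["no_splice_region"] == 10
        assert stages["missense_has_sift"] == 9
        assert stages["missingness"] == 8
        assert stages["maf"] == 7
        assert stages["expressed_gene"] == 6
        assert stages["region_exclusion"] == 4
        assert stages["single_annotation_synonymous"] == 3
        assert gout.shape == (3, 4)

    def test_monotone_on_random_tables(self):
        rng = np.random.default_rng(14)
        consequences = ["synonymous", "missense", "stop_gained", "other", "splice_region"]
        for _ in range(50):
            n = int(rng.integers(1, 40))
            specs = []
            for i in range(n):
                cons = rng.choice(consequences)
                specs.append(
                    {
                        "consequence": cons,
                        "sift": float(rng.uniform()) if (cons == "missense" and rng.random() < 0.8) else np.nan,
                        "in_canonical_cds": bool(rng.random() < 0.9),
                        "splice_region": bool(rng.random() < 0.1),
                        "n_annotations": int(rng.integers(1, 3)),
                        "gene_id": rng.choice(["g1", "g2"]),
                        "flag_sweep": bool(rng.random() < 0.1),
                        "genotypes": rng.choice([-1, 0, 1, 2], size=8).tolist(),
                    }
                )
            v, g = make_variants(specs)
            _, _, stages = filter_snps(v, g, {"g1"})
            counts = list(stages.values())
            assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_unknown_consequence_rejected(self):
        v, g = make_variants([{"consequence": "frameshift", "genotypes": [0, 0]}])
        with pytest.raises(ValueError, match="frameshift"):
            filter_snps(v, g, set())


class TestClassifyEffect:
    def test_sift_boundary_is_deleterious(self):
        assert classify_effect("missense", 0.05) == "deleterious_missense"

    def test_tolerated(self):
        assert classify_effect("missense", 0.2) == "tolerated_missense"

    def test_stop_gained_precedence(self):
        assert classify_effect("stop_gained", 0.01) == "stop_gained"

    def test_synonymous(self):
        assert classify_effect("synonymous") == "synonymous"

    def test_missense_without_sift_rejected(self):
        with pytest.raises(ValueError):
            classify_effect("missense", np.nan)

    def test_partition_is_exhaustive_and_disjoint(self):
        v, _ = make_variants(
            [
                {"consequence": "synonymous", "genotypes": [0]},
                {"consequence": "missense", "sift": 0.01, "genotypes": [0]},
                {"consequence": "missense", "sift": 0.5, "genotypes": [0]},
                {"consequence": "stop_gained", "genotypes": [0]},
            ]
        )
        cats = classify_effects(v)
        assert sorted(cats) == sorted(CATEGORIES)


class TestSitePi:
    def test_monomorphic(self):
        assert site_pi([0, 0, 0]) == 0.0

    def test_two_homozygotes(self):
        # {0/0, 1/1}: 4 of the 6 allele pairs differ
        assert site_pi([0, 2]) == pytest.approx(2 / 3)

    def test_undefined_below_two_alleles(self):
        assert np.isnan(site_pi([-1, -1]))
        assert np.isnan(site_pi([]))

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(1000):
            n = int(rng.integers(1, 11))
            gt = rng.choice([-1, 0, 1, 2], size=n, p=[0.1, 0.5, 0.25, 0.15])
            alleles = []
            for g in gt:
                if g >= 0:
                    alleles += [1] * g + [0] * (2 - g)
            if len(alleles) < 2:
                assert np.isnan(site_pi(gt))
                continue
            diffs = sum(a != b for a, b in itertools.combinations(alleles, 2))
            total = len(alleles) * (len(alleles) - 1) / 2
            assert site_pi(gt) == pytest.approx(diffs / total)

    def test_vectorised_agrees(self):
        rng = np.random.default_rng(16)
        gt = rng.choice([-1, 0, 1, 2], size=(50, 9)).astype(np.int8)
        vec = site_pi_all(gt)
        for i in range(50):
            scalar = site_pi(gt[i])
            if np.isnan(scalar):
                assert np.isnan(vec[i])
            else:
                assert vec[i] == pytest.approx(scalar)


def _load_inputs(genos, cats, groups):
    v = pd.DataFrame({"snp_id": [f"s{i}" for i in range(len(genos))]})
    g = np.array(genos, dtype=np.int8)
    return v, g, pd.Series(cats), pd.Series(groups)


class TestMutationLoad:
    def test_forced_arithmetic(self):
        v, g, cats, grp = _load_inputs(
            [[2, 0], [2, 1]], ["deleterious_missense"] * 2, ["TF"] * 2
        )
        load = mutation_load(v, g, cats, grp, {"TF": 10_000}, ["i1", "i2"])
        row = load[(load["individual"] == "i1") & (load["category"] == "deleterious_missense")]
        assert row["load_per_kb"].iloc[0] == pytest.approx(0.2)

    def test_heterozygous_only_zero_load(self):
        v, g, cats, grp = _load_inputs([[1, 1], [1, 1]], ["synonymous"] * 2, ["TF"] * 2)
        load = mutation_load(v, g, cats, grp, {"TF": 5000}, ["i1", "i2"])
        assert (load["load_per_kb"] == 0).all()

    def test_zero_length_rejected(self):
        v, g, cats, grp = _load_inputs([[2]], ["synonymous"], ["TF"])
        with pytest.raises(ValueError, match="zero total"):
            mutation_load(v, g, cats, grp, {"TF": 0}, ["i1"])

    def test_count_identity_over_sites_and_individuals(self):
        rng = np.random.default_rng(17)
        genos = rng.choice([-1, 0, 1, 2], size=(30, 12))
        cats = rng.choice(list(CATEGORIES), size=30)
        grp = rng.choice(["TF", "non-TF"], size=30)
        v = pd.DataFrame({"snp_id": [f"s{i}" for i in range(30)]})
        load = mutation_load(
            v, genos.astype(np.int8), pd.Series(cats), pd.Series(grp),
            {"TF": 1000, "non-TF": 1000},
        )
        for cat in CATEGORIES:
            by_ind = load[load["category"] == cat]["hom_alt_count"].sum()
            by_site = int((genos[np.asarray(cats) == cat] == 2).sum())
            assert by_ind == by_site

    def test_invariant_to_individual_order(self):
        rng = np.random.default_rng(18)
        genos = rng.choice([0, 1, 2], size=(10, 6)).astype(np.int8)
        v = pd.DataFrame({"snp_id": [f"s{i}" for i in range(10)]})
        cats = pd.Series(["synonymous"] * 10)
        grp = pd.Series(["TF"] * 10)
        names = [f"i{k}" for k in range(6)]
        a = mutation_load(v, genos, cats, grp, {"TF": 1000}, names)
        perm = rng.permutation(6)
        b = mutation_load(v, genos[:, perm], cats, grp, {"TF": 1000}, [names[k] for k in perm])
        merged = a.merge(b, on=["individual", "group", "category"], suffixes=("_a", "_b"))
        assert (merged["hom_alt_count_a"] == merged["hom_alt_count_b"]).all()

    def test_hardy_weinberg_expectation(self):
        # homozygous-alt count per individual per site approximates q^2
        rng = np.random.default_rng(19)
        q = 0.3
        n_sites, n_ind = 400, 200
        genos = ((rng.random((n_sites, n_ind)) < q).astype(int)
                 + (rng.random((n_sites, n_ind)) < q).astype(int)).astype(np.int8)
        v = pd.DataFrame({"snp_id": [f"s{i}" for i in range(n_sites)]})
        load = mutation_load(
            v, genos, pd.Series(["synonymous"] * n_sites), pd.Series(["TF"] * n_sites),
            {"TF": 1000},
        )
        syn = load[load["category"] == "synonymous"]
        mean_per_site = syn["hom_alt_count"].mean() / n_sites
        se = np.sqrt(q**2 * (1 - q**2) / (n_sites * n_ind))
        assert abs(mean_per_site - q**2) < 4 * se


class TestExtremeIndividuals:
    def _table(self, loads, group="TF", category="synonymous"):
        return pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(len(loads))],
                "group": group,
                "category": category,
                "hom_alt_count": 0,
                "load_per_kb": loads,
            }
        )

    def test_degenerate_distribution_flags_nobody(self):
        assert flag_extreme_individuals(self._table([1.0] * 50)) == set()

    def test_two_hundred_distinct_loads_flag_ten(self):
        flagged = flag_extreme_individuals(self._table(list(range(200))))
        # strict 2.5% tails of 200 distinct values: 5 per side
        assert len(flagged) == 10
        assert {"i0", "i1", "i2", "i3", "i4", "i195", "i196", "i197", "i198", "i199"} == flagged

    def test_extreme_in_any_distribution_flags(self):
        t1 = self._table([1.0] * 41, category="synonymous")
        t2 = self._table(list(range(40)) + [1000], category="stop_gained")
        flagged = flag_extreme_individuals(pd.concat([t1, t2], ignore_index=True))
        assert "i40" in flagged


class TestFamilyProportions:
    def _inputs(self):
        specs = []
        fams, cats = [], []
        # family NAC: 5 SNPs; family TCP: 4 SNPs (excluded); non-TF: 2
        layout = [("NAC", 5), ("TCP", 4), ("non-TF", 2)]
        for fam, k in layout:
            for i in range(k):
                specs.append({"consequence": "synonymous", "genotypes": [1, 1, 0, 0]})
                fams.append(fam)
                cats.append("synonymous")
        v, g = make_variants(specs)
        return v, g, pd.Series(cats), pd.Series(fams)

    def test_family_thresholds(self):
        v, g, cats, fams = self._inputs()
        out = family_snp_proportions(
            v, g, cats, fams, {"NAC": 20, "TCP": 20}, set(), ["i1", "i2", "i3", "i4"]
        )
        assert set(out["family"]) == {"NAC", "non-TF"}

    def test_triad_threshold(self):
        v, g, cats, fams = self._inputs()
        out = family_snp_proportions(
            v, g, cats, fams, {"NAC": 10, "TCP": 20}, set(), ["i1", "i2", "i3", "i4"]
        )
        assert "NAC" not in set(out["family"])  # needs MORE than 10 triads

    def test_extreme_only_snps_dropped(self):
        specs = [
            {"consequence": "synonymous", "genotypes": [1, 0, 0, 0]},  # only carrier i1
            {"consequence": "synonymous", "genotypes": [1, 2, 0, 0]},
        ]
        v, g = make_variants(specs)
        cats = pd.Series(["synonymous", "synonymous"])
        fams = pd.Series(["non-TF", "non-TF"])
        out = family_snp_proportions(
            v, g, cats, fams, {}, {"i1"}, ["i1", "i2", "i3", "i4"]
        )
        assert out.loc[out["family"] == "non-TF", "n_snps"].iloc[0] == 1


class TestCompareLoads:
    def _table(self, tf_shift=0.0, seed=20):
        rng = np.random.default_rng(seed)
        rows = []
        for group in ("TF", "non-TF"):
            for cat in ("synonymous", "deleterious_missense"):
                base = rng.uniform(1, 2, size=30)
                if group == "TF":
                    base = base + tf_shift
                for k, val in enumerate(base):
                    rows.append(
                        {
                            "individual": f"i{k}",
                            "group": group,
                            "category": cat,
                            "hom_alt_count": 0,
                            "load_per_kb": val,
                        }
                    )
        return pd.DataFrame(rows)

    def test_no_difference(self):
        out = compare_loads(self._table(0.0))
        assert out["anova"].loc["C(group)", "PR(>F)"] > 0.01
        assert np.allclose(out["percent_difference"].abs() < 25, True)

    def test_strong_group_effect_detected(self):
        out = compare_loads(self._table(-1.0))
        assert out["anova"].loc["C(group)", "PR(>F)"] < 1e-6
        assert (out["tukey"]["p-adj"] < 0.01).all()
        assert (out["percent_difference"] > 0).all()

    def test_requires_two_levels(self):
        t = self._table()
        with pytest.raises(ValueError):
            compare_loads(t[t["group"] == "TF"])
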