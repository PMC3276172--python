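"""Trait-profile construction, clustering, similarity and deviation tests."""

import numpy as np
import pandas as pd
import pytest

from pombepop.synthetic import (
    TraitMatrixParams,
    simulate_trait_matrix,
    simulate_trait_replicates,
)
from pombepop.traits import (
    TraitMatrix,
    atypicality_ranking,
    build_trait_matrix,
    cluster_profiles,
    deviant_trait_fraction,
    group_similarity,
)


def _long_components(values: dict[str, dict[str, float]]):
    rows = []
    for strain, traits in values.items():
        for trait, v in traits.items():
            comp, env = trait.split(":")
            rows.append((strain, env, comp, v))
    return pd.DataFrame(rows, columns=["strain", "environment", "component",
                                       "value"])


class TestBuildTraitMatrix:
    def test_log2_ratio_entries(self):
        df = _long_components({
            "ref": {"rate:YES": 1.0, "lag:YES": 2.0},
            "a": {"rate:YES": 2.0, "lag:YES": 2.0},
        })
        tm = build_trait_matrix(df, reference="ref")
        assert tm.values.loc["a", "rate:YES"] == pytest.approx(1.0)
        assert tm.values.loc["a", "lag:YES"] == pytest.approx(0.0)
        assert np.allclose(tm.values.loc["ref"], 0.0)

    def test_three_components_by_42_environments(self):
        rows = []
        for comp in ("lag", "rate", "efficiency"):
            for e in range(42):
                rows.append(("ref", f"env{e}", comp, 1.0))
                rows.append(("a", f"env{e}", comp, 2.0))
        df = pd.DataFrame(rows, columns=["strain", "environment", "component",
                                         "value"])
        tm = build_trait_matrix(df, reference="ref")
        assert len(tm.traits) == 126

    def test_missing_reference_rejected(self):
        df = _long_components({"a": {"rate:YES": 2.0}})
        with pytest.raises(ValueError):
            build_trait_matrix(df, reference="ref")

    def test_missing_strain_value_becomes_nan(self):
        df = _long_components({
            "ref": {"rate:A": 1.0, "rate:B": 1.0},
            "a": {"rate:A": 2.0},
        })
        tm = build_trait_matrix(df, reference="ref")
        assert np.isnan(tm.values.loc["a", "rate:B"])


class TestClustering:
    def test_planted_bipartition_recovered(self):
        tm = simulate_trait_matrix(TraitMatrixParams(
            n_strains=20, n_traits=40, n_groups=2, group_effect_sd=1.0,
            noise_sd=0.05, seed=11))
        tree = cluster_profiles(tm)
        cut = pd.Series(tree.cut(2))
        truth = tm.annotations["group"]
        # the 2-cluster cut must equal the planted labels up to renaming
        tab = pd.crosstab(cut[truth.index], truth)
        assert (tab.to_numpy() > 0).sum() == 2

    def test_duplicated_strains_merge_at_height_zero(self):
        rng = np.random.default_rng(2)
        row = rng.normal(size=12)
        values = pd.DataFrame(
            [row, row, rng.normal(size=12)],
            index=["a", "b", "c"],
            columns=[f"t{i}" for i in range(12)])
        tree = cluster_profiles(TraitMatrix(values=values))
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_distance_two(self):
        x = np.linspace(-1, 1, 10)
        values = pd.DataFrame([x, -x, x + 0.001],
                              index=["a", "b", "c"],
                              columns=[f"t{i}" for i in range(10)])
        tree = cluster_profiles(TraitMatrix(values=values))
        assert tree.linkage[:, 2].max() == pytest.approx(2.0, abs=1e-6)

    def test_invariant_to_trait_and_strain_order(self):
        tm = simulate_trait_matrix(TraitMatrixParams(
            n_strains=12, n_traits=20, n_groups=3, seed=4))
        tree1 = cluster_profiles(tm)
        rng = np.random.default_rng(0)
        values = tm.values.sample(frac=1, axis=1, random_state=1)
        values = values.sample(frac=1, axis=0, random_state=2)
        tree2 = cluster_profiles(TraitMatrix(values=values))
        part1 = {frozenset(s for s, c in tree1.cut(3).items() if c == k)
                 for k in (1, 2, 3)}
        part2 = {frozenset(s for s, c in tree2.cut(3).items() if c == k)
                 for k in (1, 2, 3)}
        assert part1 == part2

    def test_too_few_shared_traits_is_an_error(self):
        values = pd.DataFrame(
            [[1.0, 2.0, np.nan, np.nan, 1.0],
             [np.nan, np.nan, 1.0, 2.0, np.nan],
             [1.0, 2.0, 1.0, 2.0, 1.0]],
            index=["a", "b", "c"], columns=list("vwxyz"))
        with pytest.raises(ValueError, match="share"):
            cluster_profiles(TraitMatrix(values=values))

    def test_newick_roundtrip_contains_all_leaves(self):
        tm = simulate_trait_matrix(TraitMatrixParams(
            n_strains=6, n_traits=15, seed=9))
        nwk = cluster_profiles(tm).to_newick()
        for s in tm.strains:
            assert s in nwk
        assert nwk.endswith(";")


class TestGroupSimilarity:
    def test_noise_free_groups_within_one(self):
        tm = simulate_trait_matrix(TraitMatrixParams(
            n_strains=12, n_traits=30, n_groups=3, noise_sd=0.0, seed=5))
        rep = group_similarity(tm, "group")
        assert rep.within_mean == pytest.approx(1.0)
        assert rep.within_mean > rep.between_mean

    def test_planted_structure_is_highly_significant(self):
        tm = simulate_trait_matrix(TraitMatrixParams(
            n_strains=40, n_traits=60, n_groups=4, group_effect_sd=1.0,
            noise_sd=0.1, seed=6))
        rep = group_similarity(tm, "group")
        assert rep.p_value < 1e-3
        assert rep.within_mean > rep.between_mean

    def test_single_group_has_no_between_pairs(self):
        tm = simulate_trait_matrix(TraitMatrixParams(
            n_strains=6, n_traits=10, n_groups=1, seed=1))
        with pytest.raises(ValueError, match="different-group"):
            group_similarity(tm, "group")

    def test_pooled_and_welch_variants_agree_on_balanced_data(self):
        tm = simulate_trait_matrix(TraitMatrixParams(
            n_strains=20, n_traits=30, n_groups=2, seed=12))
        welch = group_similarity(tm, "group", equal_var=False)
        pooled = group_similarity(tm, "group", equal_var=True)
        assert welch.within_mean == pooled.within_mean
        assert np.sign(welch.t_statistic) == np.sign(pooled.t_statistic)


class TestAtypicality:
    def test_mean_profile_strain_is_most_typical(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        values = pd.DataFrame(
            [base, base + rng.normal(0, 0.5, 20), base + rng.normal(0, 0.5, 20),
             rng.normal(size=20)],
            index=["mean_like", "a", "b", "weird"],
            columns=[f"t{i}" for i in range(20)])
        out = atypicality_ranking(TraitMatrix(values=values))
        assert out.iloc[-1]["strain"] == "mean_like"
        assert out.iloc[0]["strain"] == "weird"

    def test_planted_outlier_is_bottom_ranked(self):
        # few groups so that shared structure dominates the mean profile;
        # with many equal groups the mean correlates weakly with every
        # strain and the ranking is dominated by group-level luck
        tm = simulate_trait_matrix(TraitMatrixParams(
            n_strains=30, n_traits=60, n_groups=2, group_effect_sd=1.0,
            noise_sd=0.1, outlier_ids=(12,), outlier_fraction=0.5,
            outlier_shift=10.0, seed=21))
        out = atypicality_ranking(tm)
        assert out.iloc[0]["strain"] == "strain13"


class TestDeviantTraits:
    def test_planted_fraction_recovered(self):
        p = TraitMatrixParams(
            n_strains=25, n_traits=50, n_groups=1, group_effect_sd=0.0,
            noise_sd=0.1, outlier_ids=(0,), outlier_fraction=0.2,
            outlier_shift=5.0, seed=31)
        reps = simulate_trait_replicates(p, n_replicates=4)
        frac = deviant_trait_fraction(reps, "strain1", fdr=0.05)
        assert frac == pytest.approx(0.20, abs=0.06)

    def test_null_fraction_bounded_by_fdr(self):
        fracs = []
        for seed in range(15):
            p = TraitMatrixParams(
                n_strains=20, n_traits=40, n_groups=1, group_effect_sd=0.0,
                noise_sd=1.0, seed=seed)
            reps = simulate_trait_replicates(p, n_replicates=3)
            fracs.append(deviant_trait_fraction(reps, "strain5", fdr=0.05))
        assert np.mean(fracs) <= 0.05 + 0.02

    def test_zero_variance_identical_strain(self):
        rows = []
        for s in ("a", "b", "c"):
            for trait in ("t1", "t2"):
                for r in range(3):
                    rows.append((s, trait, 1.0))
        reps = pd.DataFrame(rows, columns=["strain", "trait", "value"])
        assert deviant_trait_fraction(reps, "a") == 0.0

    def test_thin_replicates_warn_and_skip(self):
        rows = [("a", "t1", 1.0)] + [("b", "t1", v) for v in (1.0, 1.1, 0.9)]
        reps = pd.DataFrame(rows, columns=["strain", "trait", "value"])
        with pytest.warns(UserWarning, match="skipped"):
            frac = deviant_trait_fraction(reps, "a")
        assert frac == 0.0
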