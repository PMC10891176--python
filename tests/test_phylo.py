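"""Phylogenetic ANOVA machinery: VCV, F, eta squared, Holm, null simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from mottle.phylo import (
    GroupFactor,
    anova_F,
    eta_squared,
    holm_adjust,
    phyl_anova,
    read_newick,
    simulate_bm_tips,
    validate_ultrametric,
)


class TestNewickAndVcv:
    def test_cherry_vcv_is_identity(self):
        tree = read_newick("(A:1,B:1);")
        assert validate_ultrametric(tree)
        labels, C = tree.vcv()
        np.testing.assert_allclose(C, np.eye(2))
        assert sorted(labels) == ["A", "B"]

    def test_nested_tree_shared_paths(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        assert validate_ultrametric(tree)
        labels, C = tree.vcv()
        i = {lab: k for k, lab in enumerate(labels)}
        assert C[i["A"], i["B"]] == pytest.approx(1.0)
        assert C[i["A"], i["C"]] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(C), 2.0)

    def test_unequal_depths_fail_validation_naming_tips(self):
        tree = read_newick("(A:1,B:2);")
        assert not validate_ultrametric(tree)
        with pytest.raises(ValueError, match="'B'.*'A'|'A'.*'B'"):
            tree.require_ultrametric()

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            read_newick("(A,B);")

    def test_vcv_symmetric_psd_with_depth_diagonal(self):
        tree = read_newick("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);")
        _, C = tree.vcv()
        np.testing.assert_allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > -1e-12
        np.testing.assert_allclose(np.diag(C), tree.depth)


class TestAnova:
    def test_hand_computed_two_group_example(self):
        stats = anova_F([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert stats.SSB == pytest.approx(13.5)
        assert stats.SSW == pytest.approx(4.0)
        assert stats.F == pytest.approx(13.5)

    def test_identical_group_means_give_zero_F(self):
        stats = anova_F([1, 3, 1, 3], ["a", "a", "b", "b"])
        assert stats.F == 0.0
        assert not stats.degenerate

    def test_constant_response_is_zero_with_flag(self):
        stats = anova_F([5.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert stats.F == 0.0
        assert stats.degenerate

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            anova_F([1, 2, 3], ["a", "a", "a"])


class TestEtaSquared:
    def test_direct_division(self):
        assert eta_squared(13.5, 4.0) == pytest.approx(27 / 35)

    def test_boundary_cases(self):
        assert eta_squared(0.0, 3.0) == 0.0
        assert eta_squared(2.0, 0.0) == 1.0
        assert np.isnan(eta_squared(0.0, 0.0))


class TestHolm:
    def test_hand_executed_examples(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )
        np.testing.assert_allclose(holm_adjust([1.0]), [1.0])
        np.testing.assert_allclose(holm_adjust([0.02, 0.02, 0.02]), [0.06] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.1, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_statsmodels_holm(self, pvals):
        ours = holm_adjust(pvals)
        _, theirs, _, _ = multipletests(pvals, method="holm")
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert (ours >= np.asarray(pvals) - 1e-15).all()


def balanced_factor(tree, name="g"):
    tips = tree.tip_labels
    half = len(tips) // 2
    return GroupFactor(name, {t: ("A" if i < half else "B") for i, t in enumerate(tips)})


class TestPhylAnova:
    def test_constant_trait_gives_p_one(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        factor = balanced_factor(tree)
        res = phyl_anova(tree, factor, {t: 2.0 for t in tree.tip_labels},
                         nsim=199, seed=1)
        assert res.F_obs == 0.0
        assert res.p_phylo == 1.0
        assert res.degenerate

    def test_bit_reproducible_given_seed(self):
        from mottle.synth import generate_phylogeny

        tree = generate_phylogeny(12, seed=5)
        factor = balanced_factor(tree)
        trait = {t: float(i) for i, t in enumerate(tree.tip_labels)}
        a = phyl_anova(tree, factor, trait, nsim=300, seed=42)
        b = phyl_anova(tree, factor, trait, nsim=300, seed=42)
        assert a.p_phylo == b.p_phylo
        pd.testing.assert_frame_equal(a.posthoc, b.posthoc)

    def test_affine_invariance_of_F_and_p(self):
        from mottle.synth import generate_phylogeny

        tree = generate_phylogeny(12, seed=5)
        factor = balanced_factor(tree)
        trait = {t: float(i) for i, t in enumerate(tree.tip_labels)}
        shifted = {t: 3.7 * v - 11.0 for t, v in trait.items()}
        a = phyl_anova(tree, factor, trait, nsim=300, seed=42)
        b = phyl_anova(tree, factor, shifted, nsim=300, seed=42)
        assert b.F_obs == pytest.approx(a.F_obs, rel=1e-9)
        assert b.p_phylo == a.p_phylo

    def test_trait_species_missing_from_tree_is_an_error(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        factor = GroupFactor("g", {"A": "x", "B": "x", "C": "y", "Z": "y"})
        trait = {"A": 1.0, "B": 2.0, "C": 3.0, "Z": 4.0}
        with pytest.raises(ValueError, match="Z"):
            phyl_anova(tree, factor, trait, nsim=199, seed=0)

    def test_species_without_factor_level_are_dropped(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        factor = GroupFactor("g", {"A": "x", "B": "x", "C": "y"})
        trait = {t: float(i) for i, t in enumerate(tree.tip_labels)}
        res = phyl_anova(tree, factor, trait, nsim=199, seed=0)
        assert res.n_species == 3
        assert res.n_dropped == 1

    def test_small_nsim_warns(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        factor = balanced_factor(tree)
        trait = {t: float(i) for i, t in enumerate(tree.tip_labels)}
        with pytest.warns(UserWarning, match="nsim"):
            phyl_anova(tree, factor, trait, nsim=50, seed=0)

    def test_posthoc_pairs_and_holm_monotone(self):
        star = "(" + ",".join(f"t{i}:1" for i in range(12)) + ");"
        tree = read_newick(star)
        mapping = {f"t{i}": ["A", "B", "C"][i % 3] for i in range(12)}
        trait = {f"t{i}": float(i % 3) * 5 + 0.01 * i for i in range(12)}
        res = phyl_anova(tree, GroupFactor("g", mapping), trait, nsim=400, seed=3)
        assert len(res.posthoc) == 3
        assert (res.posthoc["p_holm"] >= res.posthoc["p"] - 1e-12).all()
        assert (res.posthoc["p_holm"] <= 1.0).all()

    def test_power_under_true_group_effect(self):
        # effect of 2 BM standard deviations, balanced groups of 20
        from mottle.synth import generate_phylogeny

        tree = generate_phylogeny(40, seed=9)
        labels, C = tree.vcv()
        rng = np.random.default_rng(17)
        group_of = {t: ("A" if i % 2 == 0 else "B") for i, t in enumerate(labels)}
        factor = GroupFactor("g", group_of)
        effect = np.array([2.0 if group_of[t] == "B" else 0.0 for t in labels])
        hits = 0
        nrep = 200
        base = simulate_bm_tips(C, 1.0, nrep, rng)
        for r in range(nrep):
            trait = dict(zip(labels, base[r] + effect))
            res = phyl_anova(tree, factor, trait, nsim=200, seed=1000 + r,
                             posthoc=False)
            hits += res.p_phylo < 0.05
        assert hits / nrep > 0.8


class TestBmSimulation:
    def test_zero_rate_gives_constant_tips(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        _, C = tree.vcv()
        draws = simulate_bm_tips(C, 0.0, 5, np.random.default_rng(0))
        assert np.all(draws == 0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="sigma2"):
            simulate_bm_tips(np.eye(2), -1.0, 1, np.random.default_rng(0))
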