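import warnings

import numpy as np
import pytest

from oracles import brute_dollo_min_events, brute_mk_loglik, brute_mk_marginal
from plastdeg._model import CharacterMatrix
from plastdeg.ancestral import (
    binarize,
    dollo_reconstruct,
    fit_mk_er,
    marginal_ancestral,
    mk_er_loglik,
    summarize_losses,
)
from plastdeg.fixtures import NDH_GENES, SECT_CYATHOPHORA, SERIES_REGES
from plastdeg.synthetic import simulate_tree
from plastdeg.tree import Tree


class TestBinarize:
    @pytest.mark.parametrize(
        "scheme,expected",
        [
            ("functional", {0: 0, 1: 1, 2: 1, 3: 1}),
            ("complete", {0: 0, 1: 0, 2: 1, 3: 1}),
            ("existing", {0: 0, 1: 0, 2: 0, 3: 1}),
        ],
    )
    def test_scheme_mappings(self, study_matrix, scheme, expected):
        out = binarize(study_matrix, scheme)
        for taxon in study_matrix.taxa:
            for gene in study_matrix.genes:
                assert out.data.loc[taxon, gene] == expected[study_matrix.data.loc[taxon, gene]]

    def test_unknown_scheme_rejected(self, study_matrix):
        with pytest.raises(ValueError, match="scheme"):
            binarize(study_matrix, "strict")


class TestPruningLikelihood:
    def test_zero_branch_lengths_give_log_prior(self):
        tree = Tree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        for k in (2, 3, 4):
            ll = mk_er_loglik(tree, {t: 1 % k for t in "ABCD"}, mu=0.7, k=k)
            assert ll == pytest.approx(np.log(1 / k))

    def test_large_rate_reaches_independence_limit(self):
        tree = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        ll = mk_er_loglik(tree, {"A": 0, "B": 1, "C": 0, "D": 1}, mu=200.0, k=2)
        assert ll == pytest.approx(4 * np.log(0.5), abs=1e-6)

    def test_invalid_rate_and_taxa_rejected(self):
        tree = Tree.from_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            mk_er_loglik(tree, {"A": 0, "B": 0, "C": 0}, mu=0.0, k=2)
        with pytest.raises(ValueError, match="mismatch"):
            mk_er_loglik(tree, {"A": 0, "B": 0}, mu=1.0, k=2)

    def test_matches_exhaustive_enumeration(self):
        """Pruning equals summation over all internal assignments."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            k = int(rng.integers(2, 5))
            tree = simulate_tree(int(rng.integers(3, 6)), int(rng.integers(0, 2**31)))
            char = {t: int(rng.integers(0, k)) for t in tree.tip_labels()}
            mu = float(rng.uniform(0.05, 3.0))
            assert mk_er_loglik(tree, char, mu, k=k) == pytest.approx(
                brute_mk_loglik(tree, char, mu, k), abs=1e-10
            )


class TestMarginal:
    def test_probabilities_sum_to_one_and_tips_are_observed(self):
        tree = simulate_tree(12, 3)
        rng = np.random.default_rng(0)
        char = {t: int(rng.integers(0, 4)) for t in tree.tip_labels()}
        res = marginal_ancestral(tree, char, mu=0.4, k=4)
        for node, p in res.probabilities.items():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            if node.is_leaf:
                assert p[char[node.name]] == pytest.approx(1.0)

    def test_star_tree_data_dominance(self):
        tree = Tree.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        char = {t: 1 for t in "ABCDE"}
        res = marginal_ancestral(tree, char, mu=0.3, k=4)
        assert res.probabilities[tree.root][1] > 1 / 4

    def test_matches_exhaustive_conditional(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            k = int(rng.integers(2, 5))
            tree = simulate_tree(4, int(rng.integers(0, 2**31)))
            char = {t: int(rng.integers(0, k)) for t in tree.tip_labels()}
            mu = float(rng.uniform(0.1, 2.0))
            res = marginal_ancestral(tree, char, mu, k=k)
            for node in tree.postorder():
                if node.is_leaf:
                    continue
                expected = brute_mk_marginal(tree, char, mu, k, node)
                assert np.abs(res.probabilities[node] - expected).max() < 1e-10


class TestFit:
    def test_invariant_character_flagged_at_bound(self):
        tree = simulate_tree(8, 1)
        with pytest.warns(UserWarning, match="bound"):
            fit = fit_mk_er(tree, {t: 0 for t in tree.tip_labels()}, k=2)
        assert fit.at_bound

    def test_fitted_rate_beats_grid(self):
        tree = simulate_tree(10, 5)
        rng = np.random.default_rng(5)
        char = {t: int(rng.integers(0, 2)) for t in tree.tip_labels()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mk_er(tree, char, k=2)
        grid = np.geomspace(1e-6, 100, 100)
        best_grid = max(mk_er_loglik(tree, char, m, k=2) for m in grid)
        assert fit.log_likelihood >= best_grid - 1e-6


class TestDollo:
    def test_no_derived_tips_means_no_events(self):
        tree = simulate_tree(6, 2)
        res = dollo_reconstruct(tree, {t: 0 for t in tree.tip_labels()})
        assert res.origin is None and res.reversals == [] and res.n_events == 0

    def test_non_binary_input_rejected(self):
        tree = simulate_tree(4, 2)
        char = {t: 2 for t in tree.tip_labels()}
        with pytest.raises(ValueError, match="binary"):
            dollo_reconstruct(tree, char)

    def test_events_match_exhaustive_minimum(self):
        """Origin-at-MRCA with stem reversals attains the single-origin
        minimum event count on random 6-taxon cases."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            tree = simulate_tree(6, int(rng.integers(0, 2**31)))
            char = {t: int(rng.integers(0, 2)) for t in tree.tip_labels()}
            res = dollo_reconstruct(tree, char)
            assert res.n_events == brute_dollo_min_events(tree, char)

    def test_result_invariant_to_tip_relabelling_order(self, study_matrix, study_tree):
        b = binarize(study_matrix, "functional")
        res1 = dollo_reconstruct(study_tree, b.column("ndhG"))
        shuffled = dict(reversed(list(b.column("ndhG").items())))
        res2 = dollo_reconstruct(study_tree, shuffled)
        assert res1.event_branches() == res2.event_branches()

    def test_forward_simulating_events_reproduces_tips(self, study_matrix, study_tree):
        """Replaying each gene's reconstructed event script regenerates the
        observed derived tip set exactly."""
        b = binarize(study_matrix, "functional")
        for gene in b.genes:
            res = dollo_reconstruct(study_tree, b.column(gene))
            states = {n: 0 for n in study_tree.postorder()}
            for node in study_tree.preorder():
                if res.origin is not None and node is res.origin:
                    states[node] = 1
                elif node.parent is not None and states[node.parent] == 1:
                    states[node] = 0 if node in res.reversals else 1
            derived = {n.name for n in study_tree.leaves() if states[n] == 1}
            observed = {t for t, s in b.column(gene).items() if s == 1}
            assert derived == observed, gene


class TestStudyReconstruction:
    def test_nine_ndh_genes_lost_in_section_ancestor(self, study_matrix, study_tree):
        b = binarize(study_matrix, "functional")
        results = {g: dollo_reconstruct(study_tree, b.column(g)) for g in NDH_GENES}
        assert summarize_losses(results, study_tree, SECT_CYATHOPHORA) == 9

    def test_ndhg_reverses_three_times_in_series_reges(self, study_matrix, study_tree):
        b = binarize(study_matrix, "functional")
        res = dollo_reconstruct(study_tree, b.column("ndhG"))
        reges = set(SERIES_REGES)
        tipsets = [ts for kind, ts in res.event_branches() if kind == "reversal"]
        assert len(tipsets) == 3
        assert all(ts <= reges for ts in tipsets)
        assert frozenset({"P_rex_var_rex"}) in tipsets
        assert frozenset({"P_rex_var_rockii"}) in tipsets
        assert frozenset({"P_thamnophila", "P_aff_thamnophila"}) in tipsets

    def test_ccsa_reversal_signal_concentrates_in_clade_iii(self, study_matrix, study_tree):
        """The likelihood reconstruction puts far more functional probability
        at the clade-III ancestor than at the section ancestor (the published
        support value itself depends on unpublished branch lengths)."""
        b = binarize(study_matrix, "functional")
        char = b.column("ccsA")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_mk_er(study_tree, char, k=2)
        res = marginal_ancestral(study_tree, char, fit.mu, k=2)
        clade_iii = [t for t in SECT_CYATHOPHORA if "cyathophylloides" in t or "superba" in t]
        p_iii = res.at(clade_iii)[0]
        p_sect = res.at(SECT_CYATHOPHORA)[0]
        assert p_iii > 5 * p_sect
        assert p_iii > 0.25


class TestSummaries:
    def test_all_functional_matrix_counts_zero_everywhere(self, study_tree):
        import pandas as pd

        df = pd.DataFrame(0, index=study_tree.tip_labels(), columns=list(NDH_GENES))
        matrix = CharacterMatrix(df, alphabet=(0, 1))
        results = {g: dollo_reconstruct(study_tree, matrix.column(g)) for g in NDH_GENES}
        assert summarize_losses(results, study_tree, SECT_CYATHOPHORA) == 0

    def test_unknown_tips_in_selector_rejected(self, study_matrix, study_tree):
        b = binarize(study_matrix, "functional")
        results = {"ndhA": dollo_reconstruct(study_tree, b.column("ndhA"))}
        with pytest.raises(KeyError):
            summarize_losses(results, study_tree, ["not_a_taxon"])
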