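"""Likelihood engine: pruning oracle, optimization, simulation, congruence."""

import itertools
import math

import numpy as np
import pytest

from rhizogeo import (
    LocusAlignment,
    SubstitutionModel,
    congruence_test,
    log_likelihood,
    model_select,
    nni_search,
    optimize,
    parse_newick,
    simulate_alignment,
)
from rhizogeo.errors import ParameterError
from rhizogeo.likelihood_engine import LikTree
from rhizogeo.msa_core import p_distance
from rhizogeo.tree_infer import bipartitions, neighbor_joining


# ---------------------------------------------------------------------------
# Brute-force oracle: sum over all internal-state assignments
# ---------------------------------------------------------------------------

def brute_force_log_likelihood(tree, aln, model):
    lt = LikTree.from_dendropy(tree) if not isinstance(tree, LikTree) else tree
    rates, probs = model.rate_categories()
    pi = np.asarray(model.base_frequencies)
    internal = [nd for nd in lt.postorder if nd.children]
    leaves = {nd.name: nd for nd in lt.postorder if not nd.children}
    from rhizogeo.likelihood_engine import _AMBIG_PARTIAL
    from rhizogeo.msa_core import _CHAR_TO_CODE

    total = 0.0
    for col in range(aln.n_columns):
        site = 0.0
        for rate, prob in zip(rates, probs):
            pmats = {nd.index: model.transition_matrices(
                np.array([nd.length * rate]))[0]
                for nd in lt.postorder if nd.parent is not None}
            cat_lik = 0.0
            for states in itertools.product(range(4), repeat=len(internal)):
                smap = dict(zip((nd.index for nd in internal), states))
                term = pi[smap[lt.root.index]]
                for nd in lt.postorder:
                    if nd.parent is None:
                        continue
                    ps = smap[nd.parent.index]
                    if nd.children:
                        term *= pmats[nd.index][ps, smap[nd.index]]
                    else:
                        code = _CHAR_TO_CODE[aln.rows[nd.name][col]]
                        ind = _AMBIG_PARTIAL[code]
                        term *= float(pmats[nd.index][ps] @ ind) if rate > 0 \
                            else float(ind[ps])
                cat_lik += term
            site += prob * cat_lik
        total += math.log(site)
    return total


class TestPruningLikelihood:
    def test_single_column_identical_pair_at_t0(self):
        aln = LocusAlignment("x", {"a": "A", "b": "A"})
        tree = parse_newick("(a:0.0,b:0.0);")
        lnl = log_likelihood(tree, aln, SubstitutionModel.jc69())
        assert lnl == pytest.approx(math.log(0.25))

    def test_two_sequence_closed_form(self):
        # JC69 pair likelihood: match prob 1/4+3/4 e^{-4t/3}; mismatch (1-..)/3
        t = 0.17
        n_match, n_mis = 60, 15
        aln = LocusAlignment("x", {"a": "A" * (n_match + n_mis),
                                   "b": "A" * n_match + "C" * n_mis})
        tree = parse_newick(f"(a:{t / 2},b:{t / 2});")
        lnl = log_likelihood(tree, aln, SubstitutionModel.jc69())
        p_same = 0.25 + 0.75 * math.exp(-4 * t / 3)
        p_diff = (1 - p_same) / 3
        expected = n_match * math.log(0.25 * p_same) \
            + n_mis * math.log(0.25 * p_diff)
        assert lnl == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("model", [
        SubstitutionModel.jc69(),
        SubstitutionModel.k2p(kappa=3.0),
        SubstitutionModel.t92(gc=0.4, kappa=2.5),
        SubstitutionModel.gtr((1, 2, 0.5, 0.8, 3, 1),
                              (0.3, 0.2, 0.3, 0.2), gamma_shape=0.7),
        SubstitutionModel.k2p(kappa=2.0, gamma_shape=0.5, p_invariant=0.3),
    ], ids=["jc69", "k2p", "t92", "gtr+g", "k2p+g+i"])
    def test_matches_brute_force_enumeration(self, model, rng):
        tree = parse_newick(
            "((a:0.12,b:0.30):0.08,(c:0.25,d:0.05):0.11,e:0.4);")
        aln = simulate_alignment(tree, SubstitutionModel.jc69(), 8, seed=rng)
        # add gaps/ambiguity to exercise partial-likelihood handling
        rows = dict(aln.rows)
        rows["a"] = "-" + rows["a"][1:]
        rows["b"] = rows["b"][:2] + "R" + rows["b"][3:]
        aln = LocusAlignment("x", rows)
        fast = log_likelihood(tree, aln, model)
        slow = brute_force_log_likelihood(tree, aln, model)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_invariant_to_rerooting(self, rng):
        model = SubstitutionModel.k2p(kappa=2.0, gamma_shape=0.6)
        tree = parse_newick(
            "((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.07,e:0.3);")
        aln = simulate_alignment(tree, model, 200, seed=rng)
        lnl = log_likelihood(tree, aln, model)
        from rhizogeo.tree_infer import root_tree
        for og in ("a", "c", "e"):
            rerooted = root_tree(tree, outgroup=og)
            assert log_likelihood(rerooted, aln, model) == \
                pytest.approx(lnl, abs=1e-6)

    def test_one_gamma_category_reduces_to_rate_one(self, rng):
        tree = parse_newick("((a:0.1,b:0.2):0.1,c:0.3);")
        aln = simulate_alignment(tree, SubstitutionModel.jc69(), 100, seed=rng)
        with_g1 = SubstitutionModel.jc69(gamma_shape=0.5, n_rate_categories=1)
        plain = SubstitutionModel.jc69()
        assert log_likelihood(tree, aln, with_g1) == \
            pytest.approx(log_likelihood(tree, aln, plain), rel=1e-12)

    def test_leaf_without_sequence_raises(self):
        aln = LocusAlignment("x", {"a": "A", "b": "A"})
        tree = parse_newick("((a:1,b:1):1,c:1);")
        with pytest.raises(ParameterError):
            log_likelihood(tree, aln, SubstitutionModel.jc69())


class TestOptimize:
    def test_frozen_fit_returns_input_lnl(self, rng):
        tree = parse_newick("((a:0.1,b:0.2):0.1,c:0.3);")
        model = SubstitutionModel.k2p()
        aln = simulate_alignment(tree, model, 150, seed=rng)
        fit = optimize(tree, aln, model, free=())
        assert fit.log_likelihood == pytest.approx(
            log_likelihood(tree, aln, model))

    def test_lnl_never_decreases_and_improves(self, rng):
        model = SubstitutionModel.k2p(kappa=3.0, gamma_shape=0.5)
        tree = parse_newick(
            "((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.07,e:0.3);")
        aln = simulate_alignment(tree, model, 800, seed=rng)
        start = parse_newick(
            "((a:0.5,b:0.5):0.5,(c:0.5,d:0.5):0.5,e:0.5);")
        lnl0 = log_likelihood(start, aln, SubstitutionModel.k2p(gamma_shape=1.0))
        fit = optimize(start, aln, SubstitutionModel.k2p(gamma_shape=1.0))
        assert fit.log_likelihood >= lnl0
        assert fit.converged

    def test_branch_length_recovery(self, rng):
        """Simulated data on a known 6-taxon tree; lengths back within 15%."""
        model = SubstitutionModel.jc69(gamma_shape=0.5)
        true = parse_newick("((a:0.12,b:0.3):0.09,(c:0.25,d:0.08):0.11,"
                            "(e:0.2,f:0.15):0.05);")
        aln = simulate_alignment(true, model, 5000, seed=rng)
        fit = optimize(true, aln, model)
        got = {nd.name: nd.length for nd in fit.tree.leaves}
        for name, want in (("a", 0.12), ("b", 0.3), ("c", 0.25),
                           ("d", 0.08), ("e", 0.2), ("f", 0.15)):
            assert got[name] == pytest.approx(want, rel=0.15)

    def test_information_criteria_formulas(self, rng):
        tree = parse_newick("((a:0.1,b:0.2):0.1,c:0.3);")
        aln = simulate_alignment(tree, SubstitutionModel.jc69(), 120, seed=rng)
        fit = optimize(tree, aln, SubstitutionModel.jc69(),
                       free=("branch_lengths",))
        k, n, lnl = fit.n_free_parameters, 120, fit.log_likelihood
        assert k == 4  # JC69 on a fixed 3-taxon tree: 4 branches
        assert fit.bic == pytest.approx(-2 * lnl + k * math.log(n))
        assert fit.aicc == pytest.approx(
            -2 * lnl + 2 * k + 2 * k * (k + 1) / (n - k - 1))


class TestModelSelect:
    def test_nested_models_lnl_ordering(self, rng):
        tree = parse_newick("((a:0.1,b:0.2):0.1,(c:0.2,d:0.1):0.1);")
        aln = simulate_alignment(tree, SubstitutionModel.k2p(3.0), 600,
                                 seed=rng)
        fits = {f.model.name: f for f in model_select(
            aln, tree, [SubstitutionModel.jc69(), SubstitutionModel.gtr()])}
        assert fits["GTR"].log_likelihood >= fits["JC69"].log_likelihood - 1e-6

    def test_bic_prefers_generating_simple_model(self, rng):
        tree = parse_newick("((a:0.1,b:0.2):0.1,(c:0.2,d:0.1):0.1);")
        wins = 0
        for _ in range(5):
            aln = simulate_alignment(tree, SubstitutionModel.jc69(), 2000,
                                     seed=rng)
            ranked = model_select(aln, tree, [
                SubstitutionModel.jc69(),
                SubstitutionModel.gtr(gamma_shape=0.5)])
            wins += ranked[0].model.name == "JC69"
        assert wins >= 4


class TestNniSearch:
    def test_true_topology_is_local_optimum(self, rng):
        model = SubstitutionModel.jc69()
        true = parse_newick("((a:0.1,b:0.1):0.15,(c:0.1,d:0.1):0.15,e:0.2);")
        aln = simulate_alignment(true, model, 2000, seed=rng)
        fit = nni_search(true, aln, model, optimize_model=False)
        assert bipartitions(fit.tree.to_dendropy()) == bipartitions(true)

    def test_recovers_topology_from_wrong_start(self, rng):
        model = SubstitutionModel.jc69()
        true = parse_newick("((a:0.1,b:0.1):0.3,(c:0.1,d:0.1):0.3);")
        aln = simulate_alignment(true, model, 2000, seed=rng)
        wrong = parse_newick("((a:0.1,c:0.1):0.1,(b:0.1,d:0.1):0.1);")
        start_lnl = log_likelihood(wrong, aln, model)
        fit = nni_search(wrong, aln, model, optimize_model=False)
        assert fit.log_likelihood >= start_lnl
        assert bipartitions(fit.tree.to_dendropy()) == bipartitions(true)


class TestSimulate:
    def test_zero_lengths_give_identical_rows(self, rng):
        tree = parse_newick("((a:0,b:0):0,c:0);")
        aln = simulate_alignment(tree, SubstitutionModel.jc69(), 50, seed=rng)
        assert len(set(aln.rows.values())) == 1

    def test_seed_determinism(self):
        tree = parse_newick("((a:0.1,b:0.2):0.1,c:0.3);")
        m = SubstitutionModel.k2p(gamma_shape=0.5)
        a1 = simulate_alignment(tree, m, 300, seed=5)
        a2 = simulate_alignment(tree, m, 300, seed=5)
        assert a1.rows == a2.rows

    def test_base_frequencies_recovered(self, rng):
        freqs = (0.4, 0.1, 0.2, 0.3)
        model = SubstitutionModel.gtr(base_frequencies=freqs)
        tree = parse_newick("((a:0.05,b:0.05):0.02,c:0.05);")
        aln = simulate_alignment(tree, model, 10000, seed=rng)
        counts = np.zeros(4)
        for s in aln.rows.values():
            for i, b in enumerate("ACGT"):
                counts[i] += s.count(b)
        obs = counts / counts.sum()
        n = counts.sum()
        for o, e in zip(obs, freqs):
            assert abs(o - e) < 3 * math.sqrt(e * (1 - e) / n)

    def test_pairwise_divergence_matches_jc_expectation(self, rng):
        t = 0.2
        tree = parse_newick(f"(a:{t / 2},b:{t / 2});")
        aln = simulate_alignment(tree, SubstitutionModel.jc69(), 10000,
                                 seed=rng)
        p_obs = p_distance(aln).get("a", "b")
        p_exp = 0.75 * (1 - math.exp(-4 * t / 3))
        assert abs(p_obs - p_exp) < 3 * math.sqrt(p_exp * (1 - p_exp) / 10000)

    def test_column_count_validated(self):
        tree = parse_newick("(a:0.1,b:0.1);")
        with pytest.raises(ParameterError):
            simulate_alignment(tree, SubstitutionModel.jc69(), 0)


class TestCongruence:
    def test_delta_nonnegative_and_p_valid_under_null(self, small_study, rng):
        local = list(small_study.truth["strain_id"])
        from rhizogeo.msa_core import concatenate, harmonize
        hk = concatenate(harmonize(
            [a.subset(local) for a in small_study.hk_loci()]))
        ref = neighbor_joining(p_distance(hk.as_locus_alignment()))
        res = congruence_test(small_study.hk_loci()[2].subset(local), ref,
                              SubstitutionModel.k2p(gamma_shape=0.5),
                              n_bootstrap=19, seed=1)
        assert res.delta >= 0
        assert 0 < res.p_value <= 1
        assert res.p_value > 0.05  # clonal locus: congruent with MLSA tree

    def test_hgt_locus_flagged(self, small_study):
        local = list(small_study.truth["strain_id"])
        from rhizogeo.msa_core import concatenate, harmonize
        hk = concatenate(harmonize(
            [a.subset(local) for a in small_study.hk_loci()]))
        ref = neighbor_joining(p_distance(hk.as_locus_alignment()))
        res = congruence_test(small_study.sym_locus().subset(local), ref,
                              SubstitutionModel.k2p(gamma_shape=0.5),
                              n_bootstrap=19, seed=2)
        assert res.delta > 10  # transferred strains force a big lnL gain
        assert res.p_value <= 0.05

    def test_minimum_bootstrap_enforced(self, small_study):
        ref = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        with pytest.raises(ParameterError):
            congruence_test(small_study.hk_loci()[0], ref,
                            SubstitutionModel.jc69(), n_bootstrap=5)
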