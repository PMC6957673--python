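"""GTR+Γ+I likelihood, NJ, ML optimization, bootstrap and the rate test."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy import integrate, stats

from mitodate.mlphylo import (SubstitutionModel, TreeLikelihood,
                              bootstrap_branch_lengths, branch_keys,
                              discrete_gamma_rates, fit_ml,
                              jc_distance_matrix, log_likelihood, nj_tree,
                              rate_equality_test)
from mitodate.seqio import Alignment, SequenceRecord, parse_newick, newick_string
from mitodate.simgen import simulate_alignment, SimScenario

from .conftest import jc_pair_alignment

GTR = SubstitutionModel(
    exchangeabilities=(1.5, 4.0, 0.8, 1.2, 5.0, 1.0),
    base_frequencies=(0.3, 0.2, 0.26, 0.24),
    alpha=0.4, p_inv=0.3, n_categories=4,
)


class TestDiscreteGamma:
    def test_single_category_is_unit_rate(self):
        assert discrete_gamma_rates(0.37, 1).tolist() == [1.0]

    def test_large_alpha_limit(self):
        rates = discrete_gamma_rates(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 2.0])
    def test_matches_quadrature_oracle(self, alpha):
        """Category means agree with numerical integration of the gamma."""
        n = 4
        edges = [stats.gamma.ppf(i / n, a=alpha, scale=1 / alpha)
                 for i in range(n + 1)]
        oracle = [
            n * integrate.quad(
                lambda x: x * stats.gamma.pdf(x, a=alpha, scale=1 / alpha),
                edges[i], edges[i + 1])[0]
            for i in range(n)
        ]
        assert np.allclose(discrete_gamma_rates(alpha, n), oracle, atol=1e-6)

    def test_mean_is_one(self):
        for alpha in (0.05, 0.3, 1.0, 7.0):
            assert abs(discrete_gamma_rates(alpha, 8).mean() - 1) < 1e-10

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            discrete_gamma_rates(0.0, 4)


class TestModel:
    def test_rate_matrix_rows_sum_to_zero_and_unit_rate(self):
        q = GTR.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
        pi = np.asarray(GTR.base_frequencies)
        assert abs(-(pi @ np.diag(q)) - 1.0) < 1e-12

    def test_transition_matrices_are_stochastic(self):
        p = GTR.transition_matrices(np.array([0.01, 0.5, 3.0]))
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-10)
        assert (p >= 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionModel(base_frequencies=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ValueError):
            SubstitutionModel(p_inv=1.0)


class TestLogLikelihood:
    def test_zero_length_star_tree_identical_sequences(self):
        aln = Alignment([SequenceRecord(t, "ACGT") for t in "abc"])
        tree = parse_newick("(a:0,b:0,c:0);")
        model = SubstitutionModel(base_frequencies=(0.1, 0.2, 0.3, 0.4),
                                  alpha=0.7)
        expected = sum(np.log([0.1, 0.2, 0.3, 0.4]))
        assert log_likelihood(aln, tree, model) == pytest.approx(
            expected, abs=1e-5)

    def test_two_taxon_jc_closed_form(self):
        aln = Alignment([SequenceRecord("a", "ACGTAC"),
                         SequenceRecord("b", "ACGAAC")])
        tree = parse_newick("(a:0.05,b:0.05);")
        t = 0.1
        p_same = 0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3))
        p_diff = 0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3))
        expected = 5 * np.log(p_same) + np.log(p_diff)
        assert log_likelihood(aln, tree, SubstitutionModel.jc()) == \
            pytest.approx(expected, abs=1e-10)

    def test_matches_exhaustive_enumeration(self, rng, quartet_tree):
        """Pruning equals the brute-force sum over ancestral states."""
        seqs = ["".join(rng.choice(list("ACGT-N"), 20,
                                   p=[.22, .24, .24, .2, .05, .05]))
                for _ in range(4)]
        aln = Alignment([SequenceRecord(t, s) for t, s in zip("abcd", seqs)])
        got = log_likelihood(aln, quartet_tree, GTR)

        pi = np.asarray(GTR.base_frequencies)
        rates = GTR.site_rates()
        lam, left, right = GTR.eigensystem()

        def pmat(t):
            return left @ np.diag(np.exp(lam * t)) @ right

        def allow(ch):
            v = np.zeros(4)
            if ch in "ACGT":
                v["ACGT".index(ch)] = 1
            else:
                v[:] = 1
            return v

        lengths = dict(a=0.1, b=0.23, ab=0.07, c=0.4, d=0.02)
        total = 0.0
        for site in range(20):
            tips = {t: allow(seqs[i][site]) for i, t in enumerate("abcd")}
            mean_cat = 0.0
            for r in rates:
                p = {k: pmat(v * r) for k, v in lengths.items()}
                site_l = 0.0
                for root_state, anc in itertools.product(range(4), range(4)):
                    term = pi[root_state] * p["ab"][root_state, anc]
                    term *= p["a"][anc] @ tips["a"]
                    term *= p["b"][anc] @ tips["b"]
                    term *= p["c"][root_state] @ tips["c"]
                    term *= p["d"][root_state] @ tips["d"]
                    site_l += term
                mean_cat += site_l / len(rates)
            l_inv = sum(pi[x] * np.prod([tips[t][x] for t in "abcd"])
                        for x in range(4))
            total += np.log(GTR.p_inv * l_inv + (1 - GTR.p_inv) * mean_cat)
        assert got == pytest.approx(total, abs=1e-8)

    def test_invariant_to_rerooting_and_tip_order(self, rng):
        seqs = {t: "".join(rng.choice(list("ACGT"), 40)) for t in "abcde"}
        aln1 = Alignment([SequenceRecord(t, seqs[t]) for t in "abcde"])
        aln2 = Alignment([SequenceRecord(t, seqs[t]) for t in "edcba"])
        t1 = parse_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.02,e:0.4);")
        # same unrooted tree, different basal arrangement
        t2 = parse_newick("((c:0.3,d:0.1):0.02,(a:0.1,b:0.2):0.05,e:0.4);")
        l1 = log_likelihood(aln1, t1, GTR)
        l2 = log_likelihood(aln2, t2, GTR)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_pattern_compression_matches_sitewise_sum(self, rng):
        """Weighted pattern likelihood equals the uncompressed total."""
        seqs = {t: "".join(rng.choice(list("ACG"), 60)) for t in "abc"}
        aln = Alignment([SequenceRecord(t, s) for t, s in seqs.items()])
        tree = parse_newick("(a:0.1,b:0.2,c:0.15);")
        engine = TreeLikelihood(aln, tree, GTR)
        assert engine.codes.shape[1] < 60  # compression happened
        total = engine.log_likelihood()
        sitewise = 0.0
        for col in range(1, 61):
            sub = Alignment([
                SequenceRecord(t, s[col - 1] + "") for t, s in seqs.items()
            ])
            # single-column alignments are valid (length 1)
            sitewise += log_likelihood(sub, parse_newick(
                "(a:0.1,b:0.2,c:0.15);"), GTR)
        assert total == pytest.approx(sitewise, abs=1e-6)

    def test_missing_tip_sequence_rejected(self, quartet_tree):
        aln = Alignment([SequenceRecord("a", "ACGT"),
                         SequenceRecord("b", "ACGT")])
        with pytest.raises(ValueError, match="without sequence"):
            log_likelihood(aln, quartet_tree, GTR)

    def test_edge_local_likelihood_matches_full_recompute(self, rng,
                                                          quartet_tree):
        seqs = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(4)]
        aln = Alignment([SequenceRecord(t, s) for t, s in zip("abcd", seqs)])
        engine = TreeLikelihood(aln, quartet_tree, GTR)
        D, scal, pmats = engine._down_pass(engine.lengths)
        for v in engine.edges:
            G, gs, dv, ds = engine._edge_vectors(v, D, scal, pmats)
            for t in (0.01, 0.2, 1.0):
                lengths = engine.lengths.copy()
                lengths[v] = t
                assert engine._edge_loglik(t, G, gs, dv, ds) == \
                    pytest.approx(engine.log_likelihood(lengths), abs=1e-8)


class TestNeighborJoining:
    def test_additive_matrix_recovered_exactly(self):
        labels = list("abcd")
        d = np.array([[0, 5, 7, 8],
                      [5, 0, 8, 9],
                      [7, 8, 0, 7],
                      [8, 9, 7, 0]], float)
        tree = nj_tree(d, labels)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == \
                        pytest.approx(d[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
        tree = nj_tree(d, list("abc"))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, list("abc"))

    def test_ultrametric_truth_topology_recovered(self, rng):
        from mitodate.simgen import dated_vertebrate_scenario

        scenario = dated_vertebrate_scenario(2, n_sites=8000, clocklike=True)
        aln, _ = simulate_alignment(scenario)
        ids, d = jc_distance_matrix(aln)
        tree = nj_tree(d, ids)
        ns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=newick_string(tree), schema="newick",
                               taxon_namespace=ns)
        t2 = dendropy.Tree.get(data=newick_string(scenario.tree),
                               schema="newick", taxon_namespace=ns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0


class TestFitMl:
    def test_refit_at_optimum_is_fixed_point(self, rng):
        aln, _ = _quartet_data(rng, n=1500)
        fit = fit_ml(aln, search="fixed_topology",
                     model=SubstitutionModel.jc(), optimize_model=False)
        engine = TreeLikelihood(aln, fit.tree, fit.model)
        refit = engine.optimize_branch_lengths(sweeps=3)
        assert refit - fit.log_likelihood < 1e-5 * abs(fit.log_likelihood)

    def test_nni_recovers_true_topology(self, rng):
        aln, true_tree = _quartet_data(rng, n=2000)
        # start from a deliberately wrong topology
        wrong = parse_newick("((a:0.1,c:0.1):0.05,b:0.1,d:0.1);")
        fit = fit_ml(aln, start_tree=wrong, search="nni",
                     model=SubstitutionModel.jc(), optimize_model=False)
        ns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=newick_string(fit.tree), schema="newick",
                               taxon_namespace=ns)
        t2 = dendropy.Tree.get(data=newick_string(true_tree),
                               schema="newick", taxon_namespace=ns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(
            t1, t2) == 0

    def test_invalid_search_mode_rejected(self, toy_alignment):
        with pytest.raises(ValueError):
            fit_ml(toy_alignment, search="spr")


def _quartet_data(rng, n=2000):
    tree = parse_newick("((a:0.1,b:0.2):0.08,c:0.3,d:0.05);")
    scenario = SimScenario(tree=tree, model=SubstitutionModel.jc(),
                           n_sites=n, seed=int(rng.integers(2**31)))
    aln, _ = simulate_alignment(scenario)
    return aln, tree


class TestBootstrap:
    def test_fixed_seed_is_reproducible(self, rng):
        aln, tree = _quartet_data(rng, n=400)
        fit = fit_ml(aln, start_tree=tree, search="fixed_topology",
                     model=SubstitutionModel.jc(), optimize_model=False)
        bs1 = bootstrap_branch_lengths(aln, fit.tree, fit.model, n=20,
                                       seed=77)
        bs2 = bootstrap_branch_lengths(aln, fit.tree, fit.model, n=20,
                                       seed=77)
        for key in bs1.branch_lengths:
            assert np.array_equal(bs1.branch_lengths[key],
                                  bs2.branch_lengths[key])

    def test_zero_variation_alignment_gives_null_intervals(self):
        aln = Alignment([SequenceRecord(t, "ACGT" * 50) for t in "abc"])
        tree = parse_newick("(a:0.01,b:0.01,c:0.01);")
        fit = fit_ml(aln, start_tree=tree, search="fixed_topology",
                     model=SubstitutionModel.jc(), optimize_model=False)
        bs = bootstrap_branch_lengths(aln, fit.tree, fit.model, n=10, seed=1)
        for key in bs.branch_lengths:
            lo, hi = bs.ci(key)
            assert hi < 1e-6  # at the effectively-zero lower bound

    def test_branch_keys_name_tips_and_bipartitions(self):
        tree = parse_newick("((a:1,b:1):1,c:1,d:1);")
        keys = set(branch_keys(tree).values())
        assert ("a",) in keys and ("b",) in keys
        assert ("b",) in keys or ("a", "b") in keys  # internal edge side


class TestRateEqualityTest:
    def test_identical_replicates_not_rejected(self):
        from mitodate.mlphylo import BootstrapResult

        lengths = {("a",): np.full(50, 0.1), ("b",): np.full(50, 0.1)}
        bs = BootstrapResult(n_replicates=50, seed=0,
                             branch_lengths=lengths)
        res = rate_equality_test(bs, ("a",), ("b",))
        assert res.tail_fraction == 1.0 and not res.reject

    def test_unknown_branch_rejected(self):
        from mitodate.mlphylo import BootstrapResult

        bs = BootstrapResult(n_replicates=5, seed=0,
                             branch_lengths={("a",): np.ones(5)})
        with pytest.raises(KeyError):
            rate_equality_test(bs, ("a",), ("zz",))

    def test_detects_threefold_rate_difference(self, rng):
        """Simulated 3x rate difference on one branch is detected."""
        tree = parse_newick("((a:0.15,b:0.05):0.05,c:0.1,d:0.1);")
        scenario = SimScenario(tree=tree, model=SubstitutionModel.jc(),
                               n_sites=5000, seed=4242)
        aln, _ = simulate_alignment(scenario)
        fit = fit_ml(aln, start_tree=tree, search="fixed_topology",
                     model=SubstitutionModel.jc(), optimize_model=False)
        bs = bootstrap_branch_lengths(aln, fit.tree, fit.model, n=200,
                                      seed=99)
        res = rate_equality_test(bs, ("a",), ("b",))
        assert res.reject

    def test_equal_rates_usually_not_rejected(self, rng):
        tree = parse_newick("((a:0.1,b:0.1):0.05,c:0.1,d:0.1);")
        scenario = SimScenario(tree=tree, model=SubstitutionModel.jc(),
                               n_sites=5000, seed=77)
        aln, _ = simulate_alignment(scenario)
        fit = fit_ml(aln, start_tree=tree, search="fixed_topology",
                     model=SubstitutionModel.jc(), optimize_model=False)
        bs = bootstrap_branch_lengths(aln, fit.tree, fit.model, n=200,
                                      seed=98)
        res = rate_equality_test(bs, ("a",), ("b",))
        assert not res.reject
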