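import itertools

import numpy as np
import pytest

from pbstyper.models import SubstitutionModel, discrete_gamma_rates
from pbstyper.msa import Alignment
from pbstyper.phylo import (TreeLikelihood, aic_score, bootstrap_support,
                            build_reference_tree, nj_tree,
                            optimize_branch_lengths, select_model,
                            site_loglikelihood, topology_test)
from pbstyper.seqio import PROTEIN, SequenceRecord
from pbstyper.synthetic import AA20, simulate_protein_alignment
from pbstyper.tree import ReferenceTree, _leafset


def brute_force_loglikelihood(aln, tree, model):
    """Exhaustive sum over all internal-state assignments and rate
    categories; independent of the pruning engine."""
    X = aln.to_matrix()
    row = {t: i for i, t in enumerate(aln.taxa)}
    internals = [n for n in tree.postorder() if not n.is_leaf]
    rates = model.category_rates
    pi = model.freqs
    total = 0.0
    for s in range(X.shape[1]):
        site_lik = 0.0
        for r in rates:
            P = {id(n): model.transition_matrix(n.length, r)
                 for n in tree.postorder() if n is not tree.root}
            for states in itertools.product(range(20), repeat=len(internals)):
                assign = {id(n): st for n, st in zip(internals, states)}
                term = pi[assign[id(tree.root)]]
                for n in tree.postorder():
                    if n is tree.root:
                        continue
                    parent_state = assign[id(n.parent)]
                    child_state = (X[row[n.name], s] if n.is_leaf
                                   else assign[id(n)])
                    term *= P[id(n)][parent_state, child_state]
                site_lik += term
        total += np.log(site_lik / len(rates))
    return total


class TestModels:
    def test_gamma_category_rates_average_to_one(self):
        for alpha in (0.1, 0.5, 1.0, 5.0, 50.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(rates) > 0)

    def test_transition_matrix_is_stochastic_and_reversible(self):
        m = SubstitutionModel("LG", alpha=0.8)
        P = m.transition_matrix(0.37)
        assert np.allclose(P.sum(axis=1), 1.0)
        flux = m.freqs[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError):
            SubstitutionModel("GTR20")


class TestPruningLikelihood:
    def test_zero_distance_limit(self):
        # two identical residues at vanishing distance: P -> pi_A
        model = SubstitutionModel("WAG")
        aln = Alignment([SequenceRecord("x", "A", PROTEIN),
                         SequenceRecord("y", "A", PROTEIN)])
        tree = ReferenceTree.from_newick("(x:1e-9,y:1e-9);")
        _, total = site_loglikelihood(aln, tree, model)
        assert total == pytest.approx(np.log(model.freqs[0]), abs=1e-6)

    def test_infinite_distance_limit(self):
        model = SubstitutionModel("WAG")
        aln = Alignment([SequenceRecord("x", "A", PROTEIN),
                         SequenceRecord("y", "A", PROTEIN)])
        tree = ReferenceTree.from_newick("(x:10,y:10);")
        _, total = site_loglikelihood(aln, tree, model)
        assert total == pytest.approx(2 * np.log(model.freqs[0]), rel=1e-3)

    def test_matches_enumeration_oracle(self, rng):
        model = SubstitutionModel("WAG", alpha=0.7)
        taxa = ["A", "B", "C", "D"]
        aln = Alignment([
            SequenceRecord(t, "".join(rng.choice(list(AA20), size=10)),
                           PROTEIN) for t in taxa])
        tree = ReferenceTree.from_newick(
            "((A:0.1,B:0.23):0.15,(C:0.4,D:0.05):0.02);")
        _, total = site_loglikelihood(aln, tree, model)
        brute = brute_force_loglikelihood(aln, tree, model)
        assert total == pytest.approx(brute, rel=1e-9)

    def test_rerooting_invariance(self, small_alignment, six_taxon_tree,
                                  wag_gamma):
        _, t1 = site_loglikelihood(small_alignment, six_taxon_tree, wag_gamma)
        _, t2 = site_loglikelihood(small_alignment,
                                   six_taxon_tree.reroot_at("D"), wag_gamma)
        assert t1 == pytest.approx(t2, rel=1e-9)

    def test_leaf_order_permutation_invariance(self, small_alignment,
                                               six_taxon_tree, wag_gamma):
        shuffled = Alignment(list(reversed(small_alignment.records)))
        _, t1 = site_loglikelihood(small_alignment, six_taxon_tree, wag_gamma)
        _, t2 = site_loglikelihood(shuffled, six_taxon_tree, wag_gamma)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_missing_taxon_rejected(self, small_alignment, wag_gamma):
        tree = ReferenceTree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,Z:0.1):0.1);")
        with pytest.raises(ValueError):
            site_loglikelihood(small_alignment, tree, wag_gamma)


class TestOptimizeBranchLengths:
    def test_identical_sequences_collapse_to_clamp(self):
        model = SubstitutionModel("WAG")
        aln = Alignment([SequenceRecord(t, "MKLVAWGHEE" * 5, PROTEIN)
                         for t in "ABC"])
        tree = ReferenceTree.from_newick("(A:0.2,B:0.3,C:0.1);")
        tree, _, _, _ = optimize_branch_lengths(aln, tree, model,
                                                optimize_alpha=False,
                                                max_sweeps=5)
        assert all(e.length < 1e-4 for e in tree.edges())

    def test_ascent_across_sweeps(self, small_alignment, six_taxon_tree,
                                  wag_gamma):
        tree = six_taxon_tree.copy()
        for e in tree.edges():
            e.length = 0.3
        engine = TreeLikelihood(small_alignment, tree, wag_gamma)
        before = engine.total()
        tree, fitted, after, _ = optimize_branch_lengths(
            small_alignment, tree, wag_gamma, max_sweeps=3)
        assert after >= before


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = nj_tree(d, ["a", "b", "c"])
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_matrix_recovers_topology(self, rng):
        from tests.conftest import random_binary_tree
        taxa = [f"t{i}" for i in range(5)]
        true = random_binary_tree(taxa, rng)
        # exact additive distances from the generating tree
        d = np.zeros((5, 5))
        paths = {}
        for node in true.postorder():
            if node.is_leaf:
                paths[id(node)] = {node.name: 0.0}
            else:
                paths[id(node)] = {}
                for c in node.children:
                    for t, dist in paths[id(c)].items():
                        paths[id(node)][t] = dist + c.length
        def dist(a, b):
            best = None
            for node in true.postorder():
                p = paths[id(node)]
                if a in p and b in p:
                    cand = p[a] + p[b]
                    best = cand if best is None else min(best, cand)
            return best
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    d[i, j] = d[j, i] = dist(a, b)
        recovered = nj_tree(d, taxa)
        # oracle: exhaustive least-squares over all 15 unrooted topologies
        best_sse, best_bips = None, None
        leafsets = taxa
        for topo in _all_unrooted_5taxon(taxa):
            sse, bips = _ls_fit(topo, d, taxa)
            if best_sse is None or sse < best_sse - 1e-12:
                best_sse, best_bips = sse, bips
        assert recovered.bipartitions() == best_bips == true.bipartitions()

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(d, list("abc"))


def _all_unrooted_5taxon(taxa):
    """All 15 unrooted binary topologies on 5 taxa as newick strings."""
    a, rest = taxa[0], taxa[1:]
    out = []
    # unrooted 5-taxon trees = rooted 4-taxon trees grafted to leaf a
    for quartet in _rooted_trees(rest):
        out.append(f"({a},{quartet});")
    return out


def _rooted_trees(taxa):
    if len(taxa) == 1:
        yield taxa[0]
        return
    first, rest = taxa[0], taxa[1:]
    for sub in _rooted_trees(rest):
        # insert `first` on every edge of the shape string
        yield from _insert_everywhere(sub, first)


def _insert_everywhere(shape, leaf):
    # represent shapes as nested tuples via eval-free parsing is overkill;
    # operate recursively on (left, right) tuples encoded as strings
    yield f"({shape},{leaf})"
    if shape.startswith("("):
        left, right = _split(shape)
        for ins in _insert_everywhere(left, leaf):
            yield f"({ins},{right})"
        for ins in _insert_everywhere(right, leaf):
            yield f"({left},{ins})"


def _split(shape):
    inner = shape[1:-1]
    depth = 0
    for i, c in enumerate(inner):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
        elif c == "," and depth == 0:
            return inner[:i], inner[i + 1:]
    raise ValueError(shape)


def _ls_fit(newick, d, taxa):
    """Least-squares branch lengths for a fixed topology; returns
    (sse, bipartitions)."""
    tree = ReferenceTree.from_newick(newick)
    edges = tree.edges()
    pairs = [(i, j) for i in range(len(taxa)) for j in range(len(taxa))
             if i < j]
    A = np.zeros((len(pairs), len(edges)))
    for k, (i, j) in enumerate(pairs):
        for m, e in enumerate(edges):
            side = set(_leafset(e))
            if (taxa[i] in side) != (taxa[j] in side):
                A[k, m] = 1.0
    y = np.array([d[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    sse = float(((A @ x - y) ** 2).sum())
    return sse, tree.bipartitions()


class TestBootstrap:
    def _builder(self, model):
        return lambda a: build_reference_tree(a, model, refine=False)[0]

    def test_single_replicate_supports_binary(self, small_alignment,
                                              six_taxon_tree, wag_gamma):
        support = bootstrap_support(small_alignment, self._builder(wag_gamma),
                                    1, rng_seed=5, target_tree=six_taxon_tree)
        assert set(support.values()) <= {0.0, 1.0}

    def test_fixed_seed_reproducible(self, small_alignment, six_taxon_tree,
                                     wag_gamma):
        kw = dict(n_replicates=10, rng_seed=11, target_tree=six_taxon_tree)
        s1 = bootstrap_support(small_alignment, self._builder(wag_gamma), **kw)
        s2 = bootstrap_support(small_alignment, self._builder(wag_gamma), **kw)
        assert s1 == s2

    def test_saturated_signal_full_support(self, six_taxon_tree, wag_gamma):
        aln = simulate_protein_alignment(six_taxon_tree, wag_gamma, 5000,
                                         rng_seed=21)
        support = bootstrap_support(aln, self._builder(wag_gamma), 20,
                                    rng_seed=3, target_tree=six_taxon_tree)
        assert all(v >= 0.99 for v in support.values())


class TestModelSelection:
    def test_aic_formula(self):
        assert aic_score(-100.0, 2) == pytest.approx(204.0)

    def test_single_candidate_selected(self, small_alignment,
                                       six_taxon_tree, wag_gamma):
        res = select_model(small_alignment, six_taxon_tree, [wag_gamma],
                           max_sweeps=1)
        assert res.selected == "WAG"
        name, lnl, k, aic = res.table[0]
        assert aic == pytest.approx(2 * k - 2 * lnl, abs=1e-9)


class TestTopologyTest:
    def test_duplicate_best_topology_ties_at_one(self, six_taxon_tree,
                                                 wag_gamma):
        aln = simulate_protein_alignment(six_taxon_tree, wag_gamma, 300,
                                         rng_seed=8)
        alt = ReferenceTree.from_newick(
            "((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1,(E:0.1,F:0.1):0.1);")
        rows = topology_test(aln, [six_taxon_tree.copy(), alt,
                                   six_taxon_tree.copy()],
                             wag_gamma, n_rell=2000, rng_seed=5, max_sweeps=3)
        assert rows[0]["p_value"] == 1.0 and rows[2]["p_value"] == 1.0
        assert rows[0]["delta_lnl"] == pytest.approx(0.0, abs=1e-4)

    def test_input_order_invariance(self, six_taxon_tree, wag_gamma):
        aln = simulate_protein_alignment(six_taxon_tree, wag_gamma, 200,
                                         rng_seed=9)
        alt = ReferenceTree.from_newick(
            "((A:0.1,C:0.1):0.1,(B:0.1,D:0.1):0.1,(E:0.1,F:0.1):0.1);")
        r1 = topology_test(aln, [six_taxon_tree.copy(), alt], wag_gamma,
                           n_rell=4000, rng_seed=7, max_sweeps=3)
        r2 = topology_test(aln, [alt, six_taxon_tree.copy()], wag_gamma,
                           n_rell=4000, rng_seed=7, max_sweeps=3)
        assert r1[1]["p_value"] == pytest.approx(r2[0]["p_value"], abs=0.03)

    def test_mismatched_leaf_sets_rejected(self, six_taxon_tree, wag_gamma,
                                           small_alignment):
        bad = ReferenceTree.from_newick("((A:1,B:1):1,(C:1,Z:1):1);")
        with pytest.raises(ValueError):
            topology_test(small_alignment, [six_taxon_tree, bad], wag_gamma)
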