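"""Tree likelihood, model selection, bootstrap and topology tests.

The likelihood engine is Felsenstein pruning over a discrete-gamma rate
mixture, vectorized across sites.  Topology comes from neighbor-joining
on maximum-likelihood pairwise distances, after which branch lengths and
the gamma shape are refitted by coordinate-wise Brent ascent — a
deterministic stand-in for a full ML topology search that is exact for
the likelihood itself.  Bootstrap support resamples alignment columns
within partitions; model choice is by AIC; alternative topologies are
compared with a RELL-resampling Shimodaira-Hasegawa-style test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .models import SubstitutionModel
from .msa import Alignment
from .tree import Node, ReferenceTree

MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0


# ---------------------------------------------------------------------------
# pruning engine

class TreeLikelihood:
    """Pruning likelihood of one alignment on one tree under one model.

    Keeps per-node conditional likelihood arrays of shape
    ``(ncat, nsites, 20)`` with shared per-site log-scalers, so a single
    branch can be re-evaluated in O(1) matrix products.
    """

    def __init__(self, aln: Alignment, tree: ReferenceTree,
                 model: SubstitutionModel):
        taxa = set(aln.taxa)
        missing = [n.name for n in tree.leaves() if n.name not in taxa]
        if missing:
            raise ValueError(f"taxa in tree but not alignment: {missing}")
        self.aln = aln
        self.tree = tree
        self.model = model
        X = aln.to_matrix()
        row = {t: i for i, t in enumerate(aln.taxa)}
        self.nsites = X.shape[1]
        ns = model.n_states
        self._leaf = {}
        for leaf in tree.leaves():
            codes = X[row[leaf.name]]
            part = np.zeros((self.nsites, ns))
            known = codes < ns
            part[np.arange(self.nsites)[known], codes[known]] = 1.0
            part[~known, :] = 1.0
            self._leaf[leaf.name] = part

    # -- messages ------------------------------------------------------

    def _edge_matrices(self, t: float) -> np.ndarray:
        return self.model.transition_matrices(max(t, 0.0))

    def _message(self, partial: np.ndarray, t: float) -> np.ndarray:
        """Evolve a partial through a branch: msg_p(i) = sum_j P_ij L(j)."""
        P = self._edge_matrices(t)
        return np.matmul(partial, P.transpose(0, 2, 1))

    def below_partials(self):
        """Postorder conditional likelihoods and per-site log-scalers."""
        ncat = len(self.model.category_rates)
        below, scal = {}, {}
        for node in self.tree.postorder():
            if node.is_leaf:
                part = np.broadcast_to(self._leaf[node.name],
                                       (ncat, self.nsites,
                                        self.model.n_states)).copy()
                below[id(node)] = part
                scal[id(node)] = np.zeros(self.nsites)
            else:
                part = np.ones((ncat, self.nsites, self.model.n_states))
                sc = np.zeros(self.nsites)
                for c in node.children:
                    part = part * self._message(below[id(c)], c.length)
                    sc += scal[id(c)]
                m = part.max(axis=(0, 2))
                m[m == 0] = 1.0
                part /= m[None, :, None]
                below[id(node)] = part
                scal[id(node)] = sc + np.log(m)
        return below, scal

    def above_partials(self, below, below_scal):
        """Preorder 'rest of tree' conditionals, indexed by non-root node:
        ``above[id(c)](s_p)`` is the likelihood of all data outside the
        subtree of ``c`` given the state at c's parent."""
        ncat = len(self.model.category_rates)
        above, scal = {}, {}
        order = self.tree.postorder()[::-1]  # preorder
        for node in order:
            for c in node.children:
                if node is self.tree.root:
                    part = np.ones((ncat, self.nsites, self.model.n_states))
                    sc = np.zeros(self.nsites)
                else:
                    part = self._message(above[id(node)], node.length)
                    sc = scal[id(node)].copy()
                for sib in node.children:
                    if sib is c:
                        continue
                    part = part * self._message(below[id(sib)], sib.length)
                    sc += below_scal[id(sib)]
                m = part.max(axis=(0, 2))
                m[m == 0] = 1.0
                part /= m[None, :, None]
                above[id(c)] = part
                scal[id(c)] = sc + np.log(m)
        return above, scal

    # -- likelihoods ---------------------------------------------------

    def site_loglikelihoods(self) -> np.ndarray:
        below, scal = self.below_partials()
        root = self.tree.root
        lik = np.einsum("csj,j->cs", below[id(root)], self.model.freqs).mean(axis=0)
        return np.log(lik) + scal[id(root)]

    def total(self) -> float:
        return float(self.site_loglikelihoods().sum())

    def edge_loglikelihood(self, edge: Node, t: float,
                           below, below_scal, above, above_scal) -> float:
        """Total lnL as a function of one branch length, all else fixed."""
        msg = self._message(below[id(edge)], t)
        lik = np.einsum("csj,csj,j->cs", msg, above[id(edge)],
                        self.model.freqs, optimize=True).mean(axis=0)
        lik = np.maximum(lik, 1e-300)
        return float((np.log(lik) + below_scal[id(edge)]
                      + above_scal[id(edge)]).sum())


def site_loglikelihood(aln: Alignment, tree: ReferenceTree, model):
    """Per-site log-likelihood vector and total.

    ``model`` may be a single :class:`SubstitutionModel` or a mapping
    from partition name to model (partitioned concatenation).
    """
    if isinstance(model, dict):
        pieces = []
        for name, start, end in aln.partition_map:
            if name not in model:
                raise ValueError(f"no model bound for partition {name!r}")
            sub = Alignment(
                [type(r)(r.id, r.residues[start:end], r.alphabet, r.description)
                 for r in aln.records])
            pieces.append(TreeLikelihood(sub, tree, model[name]).site_loglikelihoods())
        per_site = np.concatenate(pieces)
    else:
        per_site = TreeLikelihood(aln, tree, model).site_loglikelihoods()
    return per_site, float(per_site.sum())


# ---------------------------------------------------------------------------
# branch-length and shape optimization

def optimize_branch_lengths(aln: Alignment, tree: ReferenceTree,
                            model: SubstitutionModel,
                            optimize_alpha: bool = True,
                            tol: float = 1e-6, max_sweeps: int = 100):
    """Coordinate-wise Brent refinement of branch lengths (and gamma
    shape).  Returns ``(tree, model, lnL, converged)``; the input tree is
    modified in place."""
    engine = TreeLikelihood(aln, tree, model)
    lnL = engine.total()
    converged = False
    for _ in range(max_sweeps):
        previous = lnL
        for edge in tree.edges():
            below, bscal = engine.below_partials()
            above, ascal = engine.above_partials(below, bscal)

            def neg(t, e=edge):
                return -engine.edge_loglikelihood(e, t, below, bscal,
                                                  above, ascal)

            res = minimize_scalar(neg, bounds=(MIN_BRANCH, MAX_BRANCH),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            if -res.fun >= -neg(edge.length):
                edge.length = float(np.clip(res.x, MIN_BRANCH, MAX_BRANCH))
        if optimize_alpha and model.alpha is not None:
            def neg_alpha(log_a):
                engine.model = model.with_alpha(float(np.exp(log_a)))
                return -engine.total()

            res = minimize_scalar(neg_alpha, bounds=(np.log(0.02), np.log(50)),
                                  method="bounded", options={"xatol": 1e-4})
            if -res.fun >= lnL:
                model = model.with_alpha(float(np.exp(res.x)))
            engine.model = model
        lnL = engine.total()
        if lnL - previous < tol:
            converged = True
            break
    if not converged:
        warnings.warn("branch-length optimization did not converge "
                      f"within {max_sweeps} sweeps")
    return tree, model, lnL, converged


# ---------------------------------------------------------------------------
# distances and neighbor-joining

def ml_pairwise_distances(aln: Alignment, model: SubstitutionModel) -> np.ndarray:
    """ML distance for every pair under the model (gamma mixture included)."""
    X = aln.to_matrix()
    n, nsites = X.shape
    ns = model.n_states
    rates = model.category_rates
    pi = model.freqs
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (X[i] < ns) & (X[j] < ns)
            counts = np.zeros((ns, ns))
            np.add.at(counts, (X[i][ok], X[j][ok]), 1.0)

            def neg(t):
                mix = np.mean([model.transition_matrix(t, r) for r in rates],
                              axis=0)
                jp = np.maximum(pi[:, None] * mix, 1e-300)
                return -float((counts * np.log(jp)).sum())

            res = minimize_scalar(neg, bounds=(MIN_BRANCH, MAX_BRANCH),
                                  method="bounded", options={"xatol": 1e-7})
            dist[i, j] = dist[j, i] = float(res.x)
    return dist


def nj_tree(distances: np.ndarray, labels: list[str]) -> ReferenceTree:
    """Neighbor-joining topology with non-negative branch lengths."""
    d = np.asarray(distances, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if d.shape[0] < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj
    dm = DistanceMatrix(d, ids=list(labels))
    newick = str(_skbio_nj(dm))
    tree = ReferenceTree.from_newick(newick)
    for node in tree.postorder():
        if node is not tree.root and node.length < 0:
            node.length = 0.0
    return tree


def build_reference_tree(aln: Alignment, model: SubstitutionModel,
                         refine: bool = True):
    """NJ on ML distances, then (optionally) ML branch-length refit."""
    dist = ml_pairwise_distances(aln, model)
    tree = nj_tree(dist, aln.taxa)
    if refine:
        tree, model, lnL, _ = optimize_branch_lengths(aln, tree, model,
                                                      max_sweeps=10)
        return tree, model, lnL
    _, lnL = site_loglikelihood(aln, tree, model)
    return tree, model, lnL


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(aln: Alignment, tree_builder, n_replicates: int,
                      rng_seed: int, target_tree: ReferenceTree | None = None):
    """Column-resampling bootstrap; support per canonical bipartition.

    ``tree_builder(Alignment) -> ReferenceTree``.  Resampling is done
    within each partition so partitioned concatenations keep their
    per-gene column counts.  If ``target_tree`` is given, only its
    bipartitions are reported.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(rng_seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = []
        for _, start, end in aln.partition_map:
            cols.extend(rng.integers(start, end, size=end - start))
        rep = Alignment(
            [type(r)(r.id, "".join(r.residues[c] for c in cols), r.alphabet)
             for r in aln.records],
            list(aln.partition_map))  # per-partition widths are preserved
        for bp in tree_builder(rep).bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    support = {bp: c / n_replicates for bp, c in counts.items()}
    if target_tree is not None:
        support = {bp: support.get(bp, 0.0)
                   for bp in target_tree.bipartitions()}
    return support


# ---------------------------------------------------------------------------
# model selection

@dataclass
class ModelSelectionResult:
    table: list[tuple[str, float, int, float]]  # (name, lnL, k, AIC)
    selected: str

    def aic(self, name: str) -> float:
        for nm, _, _, a in self.table:
            if nm == name:
                return a
        raise KeyError(name)


def aic_score(log_likelihood: float, k: int) -> float:
    return 2.0 * k - 2.0 * log_likelihood


def select_model(aln: Alignment, tree: ReferenceTree,
                 candidates: list[SubstitutionModel],
                 max_sweeps: int = 6) -> ModelSelectionResult:
    """Fit each candidate (branch lengths + shape) and rank by AIC;
    ties go to the earlier candidate."""
    if not candidates:
        raise ValueError("need at least one candidate model")
    table = []
    for cand in candidates:
        t = tree.copy()
        _, fitted, lnL, _ = optimize_branch_lengths(
            aln, t, cand, max_sweeps=max_sweeps)
        k = len(t.edges()) + fitted.n_free_parameters
        table.append((cand.name, lnL, k, aic_score(lnL, k)))
    best = min(range(len(table)), key=lambda i: (table[i][3], i))
    return ModelSelectionResult(table, table[best][0])


# ---------------------------------------------------------------------------
# topology test (RELL / SH-style)

def topology_test(aln: Alignment, topologies: list[ReferenceTree],
                  model: SubstitutionModel, n_rell: int = 10000,
                  rng_seed: int = 0, max_sweeps: int = 8):
    """RELL-resampling topology comparison (Shimodaira-Hasegawa style).

    Branch lengths of each fixed topology are refitted, per-site lnL
    vectors collected, and site sums bootstrap-resampled (RELL).  Each
    topology's resampled sums are centered on their own mean; the
    p-value is the fraction of resamples in which the centered deficit
    to the best topology reaches the observed deficit.
    """
    if len(topologies) < 2:
        raise ValueError("need at least two topologies")
    leafsets = {frozenset(t.leaf_names()) for t in topologies}
    if len(leafsets) != 1:
        raise ValueError("topologies must share one leaf set")
    vectors = []
    for topo in topologies:
        t = topo.copy()
        _, fitted, _, _ = optimize_branch_lengths(aln, t, model.with_alpha(
            model.alpha) if model.alpha else model, max_sweeps=max_sweeps)
        per_site, _ = site_loglikelihood(aln, t, fitted)
        vectors.append(per_site)
    V = np.vstack(vectors)                      # (ntopo, nsites)
    totals = V.sum(axis=1)
    best = totals.max()
    deltas = best - totals                      # observed deficits, >= 0
    rng = np.random.default_rng(rng_seed)
    nsites = V.shape[1]
    idx = rng.integers(0, nsites, size=(n_rell, nsites))
    sums = V[:, idx].sum(axis=2)                # (ntopo, n_rell)
    centered = sums - sums.mean(axis=1, keepdims=True)
    D = centered.max(axis=0) - centered         # (ntopo, n_rell)
    pvals = (D >= deltas[:, None]).mean(axis=1)
    return [{"delta_lnl": float(d), "p_value": float(p), "lnl": float(t)}
            for d, p, t in zip(deltas, pvals, totals)]
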