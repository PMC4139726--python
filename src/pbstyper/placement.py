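"""Likelihood-based placement of sequence fragments on fixed reference
trees (evolutionary placement).

Each query is profile-aligned against the reference alignment, then
attached in turn to every edge of the reference tree through a new node;
the attachment position along the edge and the pendant branch length are
optimized while the reference topology and branch lengths stay fixed.
Per-edge log-likelihoods are reported as likelihood weight ratios
(LWR), normalized over edges.

A cheap vectorized pre-scan over a small grid of candidate attachments
ranks the edges first; only the leading edges are then polished with
Brent optimization.  This keeps placement of thousands of metagenomic
fragments tractable without re-estimating anything on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .models import SubstitutionModel
from .msa import Alignment, align_to_profile
from .phylo import TreeLikelihood, MIN_BRANCH
from .seqio import SequenceRecord
from .tree import ReferenceTree

MAX_PENDANT = 5.0
DEFAULT_LWR_CUTOFF = 0.001
DEFAULT_MIN_QUERY_AA = 60


@dataclass
class EdgePlacement:
    edge_id: int
    log_likelihood: float
    pendant_length: float
    distal_position: float
    lwr: float = 0.0


@dataclass
class PlacementResult:
    query_id: str
    placements: list[EdgePlacement] = field(default_factory=list)

    @property
    def best(self) -> EdgePlacement:
        return max(self.placements, key=lambda p: p.log_likelihood)

    @property
    def best_edge(self) -> int:
        return self.best.edge_id


class EdgePlacer:
    """Places queries on a fixed reference (alignment, tree, model).

    Edge ids index ``tree.edges()`` (postorder, node-below-edge
    convention) and stay stable for the lifetime of the placer.
    """

    def __init__(self, ref_aln: Alignment, tree: ReferenceTree,
                 model: SubstitutionModel, refine_top: int = 3):
        self.ref_aln = ref_aln
        self.tree = tree
        self.model = model
        self.refine_top = refine_top
        self.engine = TreeLikelihood(ref_aln, tree, model)
        self.edges = tree.edges()
        below, bscal = self.engine.below_partials()
        above, ascal = self.engine.above_partials(below, bscal)
        ncat = len(model.category_rates)
        # Pre-evolved edge-side arrays: for edge e with length b and split
        # x, the insertion likelihood is sum_s pi_s * [P(x) L_below](s)
        #   * [P(b-x) U_above](s) * [P(pendant) q](s).
        self._below = [below[id(e)] for e in self.edges]
        self._above = [above[id(e)] for e in self.edges]
        self._scal = [bscal[id(e)] + ascal[id(e)] for e in self.edges]
        self._ncat = ncat
        self._ref_site_lnl = self.engine.site_loglikelihoods()

    # -- per-edge likelihood -------------------------------------------

    def _query_partial(self, aligned_query: str) -> np.ndarray:
        from .msa import _AA2I
        ns = self.model.n_states
        nsites = self.engine.nsites
        part = np.ones((nsites, ns))
        for j, c in enumerate(aligned_query.upper()):
            i = _AA2I.get(c)
            if i is not None:
                part[j, :] = 0.0
                part[j, i] = 1.0
        return part

    def _context(self, qpart: np.ndarray) -> dict:
        """Restrict per-edge arrays to query-covered columns.

        Columns the query does not cover contribute the reference
        likelihood unchanged, for any edge and attachment, so they fold
        into one constant.
        """
        covered = ~np.all(qpart == 1.0, axis=1)
        if not covered.any():
            raise ValueError("no alignable columns")
        idx = np.where(covered)[0]
        return {
            "below": [b[:, idx, :] for b in self._below],
            "above": [a[:, idx, :] for a in self._above],
            "scal": [s[idx] for s in self._scal],
            "q": qpart[idx],
            "rest": float(self._ref_site_lnl[~covered].sum()),
        }

    def _edge_lnl(self, ctx: dict, eidx: int, x: float, pendant: float) -> float:
        e = self.edges[eidx]
        msg_down = self.engine._message(ctx["below"][eidx], x)
        msg_up = self.engine._message(ctx["above"][eidx],
                                      max(e.length - x, 0.0))
        msg_q = self.engine._message(
            np.broadcast_to(ctx["q"], msg_down.shape), pendant)
        lik = ((msg_down * msg_up * msg_q) @ self.model.freqs).mean(axis=0)
        lik = np.maximum(lik, 1e-300)
        return float((np.log(lik) + ctx["scal"][eidx]).sum()) + ctx["rest"]

    # -- placement ------------------------------------------------------

    def place_aligned(self, query_id: str, aligned_query: str,
                      lwr_cutoff: float = DEFAULT_LWR_CUTOFF,
                      prescan: bool = True) -> PlacementResult:
        qpart = self._query_partial(aligned_query)
        try:
            ctx = self._context(qpart)
        except ValueError as exc:
            raise ValueError(f"{query_id}: {exc}") from exc
        n = len(self.edges)
        results: dict[int, tuple[float, float, float]] = {}

        if prescan and n > self.refine_top:
            grid = [(0.5, 0.01), (0.5, 0.1), (0.5, 0.4)]
            coarse = np.full(n, -np.inf)
            grids = {}
            for eidx, e in enumerate(self.edges):
                best = max(((self._edge_lnl(ctx, eidx, f * e.length, p),
                             f * e.length, p) for f, p in grid))
                coarse[eidx] = best[0]
                grids[eidx] = best
            order = np.argsort(-coarse)
            refine = set(order[:self.refine_top].tolist())
            for eidx in range(n):
                if eidx not in refine:
                    lnl, x, pend = grids[eidx]
                    results[eidx] = (lnl, pend, x)
        else:
            refine = set(range(n))

        for eidx in refine:
            lnl, x, pend = self._optimize_edge(ctx, eidx)
            results[eidx] = (lnl, pend, x)

        lnls = np.array([results[i][0] for i in range(n)])
        lwr = np.exp(lnls - lnls.max())
        lwr /= lwr.sum()
        placements = [
            EdgePlacement(i, results[i][0], results[i][1], results[i][2],
                          float(lwr[i]))
            for i in range(n)
            if lwr[i] >= lwr_cutoff or i == int(np.argmax(lnls))
        ]
        placements.sort(key=lambda p: -p.log_likelihood)
        return PlacementResult(query_id, placements)

    def _optimize_edge(self, ctx: dict, eidx: int, sweeps: int = 3):
        e = self.edges[eidx]
        x, pend = 0.5 * e.length, 0.05
        lnl = self._edge_lnl(ctx, eidx, x, pend)
        for _ in range(sweeps):
            if e.length > MIN_BRANCH:
                res = minimize_scalar(
                    lambda v: -self._edge_lnl(ctx, eidx, v, pend),
                    bounds=(0.0, e.length), method="bounded",
                    options={"xatol": 1e-6})
                x = float(res.x)
            res = minimize_scalar(
                lambda v: -self._edge_lnl(ctx, eidx, x, v),
                bounds=(MIN_BRANCH, MAX_PENDANT), method="bounded",
                options={"xatol": 1e-6})
            new_lnl, pend = -res.fun, float(res.x)
            if new_lnl - lnl < 1e-6:
                lnl = max(lnl, new_lnl)
                break
            lnl = new_lnl
        return lnl, x, pend

    def place_fragment(self, query: SequenceRecord,
                       lwr_cutoff: float = DEFAULT_LWR_CUTOFF,
                       prescan: bool = True) -> PlacementResult:
        """Profile-align a raw protein fragment, then place it."""
        aligned, _ = align_to_profile(query.residues, self.ref_aln)
        return self.place_aligned(query.id, aligned, lwr_cutoff, prescan)

    # -- reporting ------------------------------------------------------

    def edge_label(self, edge_id: int) -> str:
        """Human-readable edge name: the sorted leaf set below the edge."""
        node = self.edges[edge_id]
        if node.is_leaf:
            return node.name
        from .tree import _leafset
        return "|".join(sorted(_leafset(node)))

    def jplace_tree(self) -> str:
        """Newick with {edge_num} annotations, jplace style."""
        ids = {id(e): i for i, e in enumerate(self.edges)}

        def fmt(node):
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node is self.tree.root:
                return body
            return f"{body}:{node.length:.10g}{{{ids[id(node)]}}}"

        return fmt(self.tree.root) + ";"


@dataclass
class ReferenceBundle:
    """Everything needed to place one category of fragments."""

    category: str
    alignment: Alignment
    tree: ReferenceTree
    model: SubstitutionModel

    def placer(self, **kw) -> EdgePlacer:
        return EdgePlacer(self.alignment, self.tree, self.model, **kw)


def place_all(queries: list[tuple[str, SequenceRecord]],
              bundles: dict[str, ReferenceBundle],
              min_query_aa: int = DEFAULT_MIN_QUERY_AA,
              lwr_cutoff: float = DEFAULT_LWR_CUTOFF):
    """Place category-routed fragments on their reference bundles.

    ``queries`` rows are ``(category, fragment)``.  Returns
    ``(results, skipped)`` where ``results`` maps category to a list of
    :class:`PlacementResult` and ``skipped`` counts queries without a
    bundle or shorter than ``min_query_aa``.
    """
    placers = {}
    results: dict[str, list[PlacementResult]] = {c: [] for c in bundles}
    skipped = {"no_bundle": 0, "too_short": 0, "unalignable": 0}
    for category, frag in queries:
        if category not in bundles:
            skipped["no_bundle"] += 1
            continue
        if len(frag.residues) < min_query_aa:
            skipped["too_short"] += 1
            continue
        if category not in placers:
            placers[category] = bundles[category].placer()
        try:
            res = placers[category].place_fragment(frag, lwr_cutoff)
        except ValueError:
            skipped["unalignable"] += 1
            continue
        results[category].append(res)
    return results, skipped


def to_jplace(placer: EdgePlacer, results: list[PlacementResult]):
    """Rows for :func:`pbstyper.seqio.write_jplace`."""
    rows = []
    for res in results:
        rows.append((res.query_id,
                     [(p.edge_id, p.log_likelihood, p.lwr,
                       p.distal_position, p.pendant_length)
                      for p in res.placements]))
    return rows, placer.jplace_tree()
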