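"""Per-sample abundance tables: RecA normalization and placement tallies.

Subunit counts are divided by each sample's single-copy RecA count to
correct for differing sequencing effort and community size, then turned
into within-sample proportions.  Proportions are invariant to the RecA
divisor within a sample; the normalized values are what make samples
comparable to each other.  Placement tallies count each placed query at
its best edge, mapped to a clade label; an LWR-weighted mode spreads
each query over its reported edges instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class AbundanceTable:
    counts: pd.DataFrame          # samples x categories, raw counts
    reca: pd.Series | None        # per-sample RecA count (None for tallies)
    normalized: pd.DataFrame
    proportions: pd.DataFrame
    empty_samples: list
    sample_meta: pd.DataFrame | None = None

    def to_tsv(self, path):
        out = self.counts.add_prefix("count_")
        if self.reca is not None:
            out["recA"] = self.reca
            out = out.join(self.normalized.add_prefix("norm_"))
        out = out.join(self.proportions.add_prefix("prop_"))
        if self.sample_meta is not None:
            out = out.join(self.sample_meta)
        out.to_csv(path, sep="\t")
        return path


def normalize_subunits(counts: pd.DataFrame,
                       reca: pd.Series,
                       sample_meta: pd.DataFrame | None = None) -> AbundanceTable:
    """RecA-normalize per-sample subunit counts.

    ``counts`` rows are samples, columns subunit categories (PC, PEI,
    PEII).  Samples with zero RecA keep raw proportions but are flagged;
    samples with no subunit counts at all have undefined proportions.
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    reca = reca.reindex(counts.index).fillna(0).astype(float)
    norm = counts.div(reca.where(reca > 0), axis=0)
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0), axis=0)
    empty = totals[totals == 0].index.tolist()
    return AbundanceTable(counts, reca, norm, props, empty, sample_meta)


def tally_placements(placements, clade_map: dict[int, str],
                     sample_of: dict[str, str],
                     sample_meta: pd.DataFrame | None = None,
                     weighted: bool = False) -> AbundanceTable:
    """Tally placement results per sample and clade.

    ``placements`` is an iterable of
    :class:`pbstyper.placement.PlacementResult`; ``clade_map`` maps edge
    ids to clade labels (edges absent from the map raise, so build the
    map over every edge of the reference); ``sample_of`` maps query ids
    to sample ids.  ``weighted=True`` spreads each query over its
    reported edges by likelihood weight ratio instead of counting only
    the best edge.
    """
    rows: dict[tuple[str, str], float] = {}
    known_samples = set(sample_of.values())
    if sample_meta is not None:
        known_samples |= set(sample_meta.index)
    for res in placements:
        if res.query_id not in sample_of:
            raise ValueError(f"placement for unknown query {res.query_id!r}")
        sample = sample_of[res.query_id]
        if sample not in known_samples:
            raise ValueError(f"unknown sample {sample!r}")
        if weighted:
            for p in res.placements:
                clade = _clade(clade_map, p.edge_id)
                rows[(sample, clade)] = rows.get((sample, clade), 0.0) + p.lwr
        else:
            clade = _clade(clade_map, res.best_edge)
            rows[(sample, clade)] = rows.get((sample, clade), 0.0) + 1.0
    samples = sorted({s for s, _ in rows} | known_samples)
    clades = sorted({c for _, c in rows} | set(clade_map.values()))
    counts = pd.DataFrame(0.0, index=samples, columns=clades)
    for (s, c), v in rows.items():
        counts.loc[s, c] = v
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0), axis=0)
    empty = totals[totals == 0].index.tolist()
    return AbundanceTable(counts, None, counts.copy(), props, empty,
                          sample_meta)


def _clade(clade_map: dict[int, str], edge_id: int) -> str:
    if edge_id not in clade_map:
        raise KeyError(f"edge {edge_id} missing from clade map")
    return clade_map[edge_id]


def collapse_clades(table: AbundanceTable,
                    groups: dict[str, list[str]]) -> AbundanceTable:
    """Sum sibling clades into named groups; unlisted clades pass through."""
    mapping = {}
    for group, members in groups.items():
        for m in members:
            mapping[m] = group
    counts = table.counts.T.groupby(
        lambda c: mapping.get(c, c)).sum().T
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0), axis=0)
    return AbundanceTable(counts, table.reca, counts.copy(), props,
                          table.empty_samples, table.sample_meta)


def clade_map_by_type(placer, community) -> dict[int, str]:
    """Map every edge of a placer's reference tree to a pigment type.

    Each edge bipartitions the leaves; the edge takes the type of
    whichever side is type-unanimous (so the rooting of the reference
    tree is immaterial).  Edges between type clades, where neither side
    is unanimous, are labelled "mixed".
    """
    from .tree import _leafset
    all_leaves = set(placer.tree.leaf_names())
    out = {}
    for eid, node in enumerate(placer.edges):
        below = set(_leafset(node))
        for side in (below, all_leaves - below):
            types = {community.type_of(t) for t in side}
            if len(types) == 1:
                out[eid] = types.pop()
                break
        else:
            out[eid] = "mixed"
    return out
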