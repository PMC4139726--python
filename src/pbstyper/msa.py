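"""Multiple alignment of subunit proteins and partitioned concatenation.

The aligner is deliberately simple and deterministic: a guide tree from
k-mer distances (k=3, UPGMA clustering with index-ordered tie-breaks)
followed by profile-profile Needleman-Wunsch merges under BLOSUM62 with
a linear gap penalty.  For the highly conserved phycobiliprotein
subunits this is adequate, and determinism makes every downstream tree
reproducible.

Column filtering replaces manual curation: columns whose gap fraction
exceeds a threshold are dropped, with the partition map remapped.
Concatenation unions taxa across genes, gap-filling missing ones
(a ``require_complete`` switch keeps only taxa present in every gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import PROTEIN, SequenceRecord

GAP = "-"
_B62 = substitution_matrices.load("BLOSUM62")
_ALPHA = "ARNDCQEGHILKMFPSTWYV"
_AA2I = {a: i for i, a in enumerate(_ALPHA)}
_S = np.array([[_B62[a, b] for b in _ALPHA] for a in _ALPHA], float)

DEFAULT_GAP_PENALTY = 8.0


@dataclass
class Alignment:
    """Equal-length protein rows plus a named column partition map."""

    records: list[SequenceRecord]
    partition_map: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment needs at least one row")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"rows differ in length: {sorted(lengths)}")
        if not self.partition_map:
            self.partition_map = [("all", 0, self.n_columns)]
        self._check_partitions()

    def _check_partitions(self):
        pos = 0
        for name, start, end in self.partition_map:
            if start != pos or end <= start:
                raise ValueError(f"partition {name!r} does not tile columns")
            pos = end
        if pos != self.n_columns:
            raise ValueError("partitions do not cover all columns")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def taxa(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, taxon: str) -> str:
        for r in self.records:
            if r.id == taxon:
                return r.residues
        raise KeyError(taxon)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    def to_matrix(self) -> np.ndarray:
        """Integer matrix, 0..19 for residues and 20 for gap/ambiguous."""
        out = np.full((len(self.records), self.n_columns), 20, dtype=np.int8)
        for i, r in enumerate(self.records):
            for j, c in enumerate(r.residues.upper()):
                out[i, j] = _AA2I.get(c, 20)
        return out

    def subset(self, taxa: list[str]) -> "Alignment":
        recs = [r for r in self.records if r.id in set(taxa)]
        return Alignment(recs, list(self.partition_map))


# ---------------------------------------------------------------------------
# guide tree from k-mer distances

def kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _upgma_order(dist: np.ndarray):
    """UPGMA join order as a nested tuple of input indices; ties break
    toward the smallest (i, j) pair."""
    n = dist.shape[0]
    clusters = {i: (i, 1) for i in range(n)}  # id -> (subtree, size)
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        (i, j) = min(d, key=lambda p: (d[p], p))
        (ti, si), (tj, sj) = clusters.pop(i), clusters.pop(j)
        for k in list(clusters):
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        del d[(i, j)]
        clusters[next_id] = ((ti, tj), si + sj)
        next_id += 1
    (tree, _), = clusters.values()
    return tree


# ---------------------------------------------------------------------------
# profile-profile Needleman-Wunsch

def _profile_counts(rows: list[str]) -> np.ndarray:
    ncol = len(rows[0])
    counts = np.zeros((ncol, 20))
    for row in rows:
        for j, c in enumerate(row.upper()):
            i = _AA2I.get(c)
            if i is not None:
                counts[j, i] += 1
    return counts


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    gap_penalty: float) -> tuple[list[str], list[str], float]:
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    na = np.maximum(ca.sum(axis=1), 1e-9)
    nb = np.maximum(cb.sum(axis=1), 1e-9)
    M = (ca @ _S @ cb.T) / np.outer(na, nb)
    la, lb = M.shape
    D = np.full((la + 1, lb + 1), -np.inf)
    D[0, :] = -gap_penalty * np.arange(lb + 1)
    D[:, 0] = -gap_penalty * np.arange(la + 1)
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, la + 1):
        diag = D[i - 1, :-1] + M[i - 1]
        up = D[i - 1, 1:] - gap_penalty
        for j in range(1, lb + 1):
            left = D[i, j - 1] - gap_penalty
            best = diag[j - 1]
            move = 0
            if up[j - 1] > best:
                best, move = up[j - 1], 1
            if left > best:
                best, move = left, 2
            D[i, j] = best
            ptr[i, j] = move
    # traceback
    i, j = la, lb
    cols = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and ptr[i, j] == 0:
            cols.append((i - 1, j - 1)); i -= 1; j -= 1
        elif i > 0 and (j == 0 or ptr[i, j] == 1):
            cols.append((i - 1, None)); i -= 1
        else:
            cols.append((None, j - 1)); j -= 1
    cols.reverse()
    out_a = ["".join(r[ia] if ia is not None else GAP for ia, _ in cols)
             for r in rows_a]
    out_b = ["".join(r[ib] if ib is not None else GAP for _, ib in cols)
             for r in rows_b]
    return out_a, out_b, float(D[la, lb])


def progressive_align(seqs: list[SequenceRecord],
                      gap_penalty: float = DEFAULT_GAP_PENALTY,
                      k: int = 3) -> Alignment:
    """Progressive multiple alignment; see module docstring."""
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        import warnings
        warnings.warn("single sequence: returning identity alignment")
        return Alignment(list(seqs))
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kmer_distance(
                seqs[i].residues.upper(), seqs[j].residues.upper(), k)
    order = _upgma_order(dist)

    def build(node) -> tuple[list[int], list[str]]:
        if isinstance(node, int):
            return [node], [seqs[node].residues.upper()]
        idx_a, rows_a = build(node[0])
        idx_b, rows_b = build(node[1])
        out_a, out_b, _ = _merge_profiles(rows_a, rows_b, gap_penalty)
        return idx_a + idx_b, out_a + out_b

    indices, rows = build(order)
    by_input = dict(zip(indices, rows))
    records = [SequenceRecord(seqs[i].id, by_input[i], PROTEIN,
                              seqs[i].description) for i in range(n)]
    return Alignment(records)


def align_to_profile(query: str, aln: Alignment,
                     gap_penalty: float = DEFAULT_GAP_PENALTY) -> tuple[str, float]:
    """Align a (fragmentary) query against a fixed reference alignment.

    Reference columns are immutable: query residues falling between
    columns (insertions) are dropped, and terminal gaps are free, so a
    fragment maps onto a contiguous window of reference columns.
    Returns the query expanded to alignment length, plus the score.
    """
    q = query.upper()
    if not q:
        raise ValueError("empty query")
    counts = _profile_counts([r.residues for r in aln.records])
    nn = np.maximum(counts.sum(axis=1), 1e-9)
    qi = np.array([_AA2I.get(c, -1) for c in q])
    prof = counts / nn[:, None]           # (ncol, 20)
    score_cols = prof @ _S                # (ncol, 20)
    m, L = len(q), aln.n_columns
    D = np.zeros((m + 1, L + 1))
    D[1:, 0] = -gap_penalty * np.arange(1, m + 1)  # insertions before window
    ptr = np.zeros((m + 1, L + 1), dtype=np.int8)
    ptr[1:, 0] = 1
    for i in range(1, m + 1):
        s = score_cols[:, qi[i - 1]] if qi[i - 1] >= 0 else np.zeros(L)
        prev, cur = D[i - 1], D[i]
        pr = ptr[i]
        for j in range(1, L + 1):
            best, move = prev[j - 1] + s[j - 1], 0
            if prev[j] - gap_penalty > best:
                best, move = prev[j] - gap_penalty, 1
            if cur[j - 1] > best:                       # free gap-in-query
                best, move = cur[j - 1], 2
            cur[j] = best
            pr[j] = move
    if np.count_nonzero(qi >= 0) == 0:
        raise ValueError("query has no alignable residues")
    i, j = m, L
    out = [GAP] * L
    while i > 0 or j > 0:
        if i > 0 and j > 0 and ptr[i, j] == 0:
            out[j - 1] = q[i - 1]; i -= 1; j -= 1
        elif i > 0 and (j == 0 or ptr[i, j] == 1):
            i -= 1
        else:
            j -= 1
    return "".join(out), float(D[m, L])


# ---------------------------------------------------------------------------
# curation and concatenation

def filter_columns(aln: Alignment, max_gap_fraction: float = 0.5) -> Alignment:
    """Drop columns whose gap fraction exceeds the threshold."""
    if not (0 <= max_gap_fraction <= 1):
        raise ValueError("max_gap_fraction must be in [0, 1]")
    nrow = len(aln.records)
    keep = [j for j in range(aln.n_columns)
            if aln.column(j).count(GAP) / nrow <= max_gap_fraction]
    if not keep:
        raise ValueError("column filter removed every column")
    new_rows = {r.id: "".join(r.residues[j] for j in keep) for r in aln.records}
    # remap partitions to surviving-column counts
    new_parts, pos = [], 0
    for name, start, end in aln.partition_map:
        width = sum(1 for j in keep if start <= j < end)
        if width:
            new_parts.append((name, pos, pos + width))
            pos += width
    records = [SequenceRecord(r.id, new_rows[r.id], PROTEIN, r.description)
               for r in aln.records]
    return Alignment(records, new_parts)


def concatenate(named_alns: list[tuple[str, Alignment]],
                require_complete: bool = False) -> Alignment:
    """Concatenate per-gene alignments into one partitioned alignment."""
    if not named_alns:
        raise ValueError("nothing to concatenate")
    for name, aln in named_alns:
        if len(set(aln.taxa)) != len(aln.taxa):
            raise ValueError(f"duplicate taxon within partition {name!r}")
    taxa: list[str] = []
    for _, aln in named_alns:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)
    if require_complete:
        taxa = [t for t in taxa
                if all(t in aln.taxa for _, aln in named_alns)]
        if not taxa:
            raise ValueError("no taxon is present in every partition")
    rows = {t: [] for t in taxa}
    parts, pos = [], 0
    for name, aln in named_alns:
        width = aln.n_columns
        for t in taxa:
            rows[t].append(aln.row(t) if t in aln.taxa else GAP * width)
        parts.append((name, pos, pos + width))
        pos += width
    records = [SequenceRecord(t, "".join(rows[t]), PROTEIN) for t in taxa]
    return Alignment(records, parts)


def write_alignment(aln: Alignment, fasta_path, partition_path=None):
    from .seqio import write_fasta
    write_fasta(aln.records, fasta_path)
    if partition_path:
        with open(partition_path, "w") as fh:
            fh.write("partition\tstart\tend\n")
            for name, start, end in aln.partition_map:
                fh.write(f"{name}\t{start}\t{end}\n")
    return fasta_path


def read_alignment(fasta_path, partition_path=None) -> Alignment:
    from .seqio import read_fasta
    records = read_fasta(fasta_path, alphabet=PROTEIN)
    parts = []
    if partition_path:
        with open(partition_path) as fh:
            next(fh)
            for line in fh:
                name, start, end = line.rstrip("\n").split("\t")
                parts.append((name, int(start), int(end)))
    return Alignment(records, parts)
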