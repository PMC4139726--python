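"""Reciprocal best-hit identification of phycobilisome subunits and
single-copy markers in metagenomic protein sets.

The search protocol mirrors the two-pass design used for metagenomic
PBS gene discovery: reference proteins from sequenced picocyanobacterial
genomes define the categories (PC = cpcBA, PEI = cpeBA, PEII = mpeBA,
RecA, six ribosomal markers); metagenomic proteins with a sufficiently
significant forward hit (E < 1e-10 by default) are then searched back
against the references plus a broad decoy database, and kept only when
the best back hit falls in the original category.

Scoring is optimal Smith-Waterman with affine gaps (BLOSUM62, open 11 /
extend 1) and fixed Karlin-Altschul statistics for the bit-score and
E-value conversion — deterministic, which is what the threshold contract
needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import AA_CHARS, SequenceRecord

#: Minimum fragment length (aa) below which hits are flagged unreliable.
RELIABILITY_FLOOR_AA = 30

PBS_CATEGORIES = ("PC", "PEI", "PEII")
MARKER_GENES = ("rplE", "rplF", "rplN", "rplP", "rpsE", "rpsM")

#: Category implied by each subunit/marker gene name.
GENE_CATEGORY = {
    "cpcB": "PC", "cpcA": "PC",
    "cpeB": "PEI", "cpeA": "PEI",
    "mpeB": "PEII", "mpeA": "PEII",
    "recA": "RecA",
    **{g: f"marker:{g}" for g in MARKER_GENES},
}


@dataclass
class ScoringScheme:
    """Protein scoring parameters, including the fixed Karlin-Altschul
    statistics used for the bit-score / E-value conversion."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self):
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        self._matrix = substitution_matrices.load(self.matrix_name)

    def aligner(self, mode: str = "local") -> PairwiseAligner:
        a = PairwiseAligner()
        a.mode = mode
        a.substitution_matrix = self._matrix
        a.open_gap_score = -self.gap_open
        a.extend_gap_score = -self.gap_extend
        return a

    def bit_score(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)


@dataclass
class SubunitHit:
    query_id: str
    reference_id: str
    category: str
    bit_score: float
    e_value: float
    reciprocal_confirmed: bool
    below_reliability_floor: bool = False


def _check_protein(seq: str, label: str):
    bad = set(seq.upper()) - AA_CHARS
    if bad:
        raise ValueError(f"{label}: non-protein characters {sorted(bad)}")


def local_align(query: str, target: str,
                scheme: ScoringScheme | None = None):
    """Optimal Smith-Waterman alignment under affine gaps.

    Returns ``(raw_score, bit_score, aligned_spans)`` where
    ``aligned_spans`` pairs 0-based half-open intervals on query and
    target.  An all-negative scoring region yields score 0 and no span.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    _check_protein(query, "query")
    _check_protein(target, "target")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner("local")
    score = aligner.score(query.upper(), target.upper())
    if score <= 0:
        return 0.0, scheme.bit_score(0.0), []
    aln = aligner.align(query.upper(), target.upper())[0]
    spans = [((int(q0), int(q1)), (int(t0), int(t1)))
             for (q0, q1), (t0, t1) in zip(*aln.aligned)]
    return float(score), scheme.bit_score(float(score)), spans


def evalue(bit_score: float, query_len: int, db_len: int) -> float:
    """Expected number of chance hits: E = m * n * 2^(-bits)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    return query_len * db_len * 2.0 ** (-bit_score)


def _best_hit(query: str, refs: list[tuple[str, str, str]], aligner):
    """Best-scoring reference for one query.

    ``refs`` rows are (ref_id, category, residues).  Ties break toward
    the lexicographically smaller reference id for reproducibility.
    """
    best = None
    for ref_id, category, residues in refs:
        s = aligner.score(query, residues)
        if best is None or s > best[0] or (s == best[0] and ref_id < best[1]):
            best = (s, ref_id, category)
    return best


def reciprocal_best_hit(metagenome_proteins: list[SequenceRecord],
                        reference_sets: dict[str, list[SequenceRecord]],
                        decoy_db: list[SequenceRecord] | None = None,
                        threshold: float = 1e-10,
                        scheme: ScoringScheme | None = None,
                        keep_unconfirmed: bool = True) -> list[SubunitHit]:
    """Two-pass reciprocal best-hit subunit assignment.

    Forward pass: each metagenomic protein is scored against every
    reference; proteins whose best forward E-value beats ``threshold``
    are provisionally assigned the best reference's category.  Back
    pass: the retained protein is searched against references plus the
    decoy database; the assignment is confirmed only if the best back
    hit is a reference of the original category.  Unconfirmed hits are
    returned flagged (``reciprocal_confirmed=False``) so downstream
    counting can exclude them.
    """
    if not reference_sets or not any(reference_sets.values()):
        raise ValueError("reference sets must be non-empty")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner("local")

    refs = [(r.id, cat, r.residues.upper())
            for cat, records in sorted(reference_sets.items())
            for r in records]
    ref_db_len = sum(len(r) for _, _, r in refs)
    decoys = [(d.id, "decoy", d.residues.upper()) for d in (decoy_db or [])]
    back_db = refs + decoys

    hits: list[SubunitHit] = []
    for prot in metagenome_proteins:
        seq = prot.residues.upper()
        best = _best_hit(seq, refs, aligner)
        if best is None:
            continue
        raw, ref_id, category = best
        bits = scheme.bit_score(raw)
        e = evalue(bits, len(seq), ref_db_len)
        if e >= threshold:
            continue
        back = _best_hit(seq, back_db, aligner)
        confirmed = back is not None and back[2] == category
        if not confirmed and not keep_unconfirmed:
            continue
        hits.append(SubunitHit(
            query_id=prot.id, reference_id=ref_id, category=category,
            bit_score=bits, e_value=e, reciprocal_confirmed=confirmed,
            below_reliability_floor=len(seq) < RELIABILITY_FLOOR_AA))
    return hits


_HIT_COLUMNS = ["query_id", "reference_id", "category", "bit_score",
                "e_value", "reciprocal_confirmed", "below_reliability_floor"]


def write_hits(hits: list[SubunitHit], path):
    with open(path, "w") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.reference_id}\t{h.category}\t"
                     f"{h.bit_score:.4f}\t{h.e_value:.6g}\t"
                     f"{int(h.reciprocal_confirmed)}\t"
                     f"{int(h.below_reliability_floor)}\n")
    return path


def read_hits(path) -> list[SubunitHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        if header.rstrip("\n").split("\t") != _HIT_COLUMNS:
            raise ValueError(f"{path}: unexpected hit table header")
        for line in fh:
            q, r, c, b, e, conf, floor = line.rstrip("\n").split("\t")
            hits.append(SubunitHit(q, r, c, float(b), float(e),
                                   bool(int(conf)), bool(int(floor))))
    return hits
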