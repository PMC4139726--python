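"""Sequence, annotation and interchange-format I/O.

Everything downstream speaks through the types defined here: plain
:class:`SequenceRecord` objects for FASTA data, :class:`GeneAnnotation`
rows for the GFF-like gene tables that accompany assembled contigs, and
:class:`AnnotatedContig` for the pair.  Coordinates are 0-based half-open
throughout the package.

Also hosts the shared sequence statistics (GC fraction, pairwise
identity) used by the gene-cluster typing and comparison steps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

# IUPAC alphabets, ambiguity codes included.
NT_CHARS = set("ACGTURYSWKMBDHVN-")
AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYBZJXUO*-")

#: Controlled vocabulary for gene annotations on phycobilisome contigs.
GENE_VOCABULARY = frozenset({
    "cpcB", "cpcA", "cpcC", "cpcD", "cpcE", "cpcF", "cpcGI", "cpcGII",
    "cpeB", "cpeA", "cpeC", "cpeE", "cpeY", "cpeZ",
    "mpeB", "mpeA", "pebA", "pebB",
    "hemH", "hmuO", "rpsA", "tRNA-Phe", "transposase",
    "recA", "rplE", "rplF", "rplN", "rplP", "rpsE", "rpsM",
    "unk", "hyp", "other",
})


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    alphabet: str = NUCLEOTIDE
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        allowed = NT_CHARS if self.alphabet == NUCLEOTIDE else AA_CHARS
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal {self.alphabet} characters {sorted(bad)}"
            )

    def __len__(self):
        return len(self.residues)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene on a contig; ``start``/``end`` are 0-based half-open."""

    contig_id: str
    gene_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.gene_name not in GENE_VOCABULARY:
            raise FormatError(f"unknown gene name {self.gene_name!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"{self.gene_name}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedContig:
    """Nucleotide sequence plus ordered, stranded gene annotations."""

    contig_id: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self):
        for g in self.genes:
            if g.end > len(self.sequence):
                raise FormatError(
                    f"{g.gene_name} on {self.contig_id}: end {g.end} beyond "
                    f"contig length {len(self.sequence)}"
                )

    def gene_sequence(self, gene: GeneAnnotation) -> str:
        s = self.sequence[gene.start:gene.end]
        if gene.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def gene_protein(self, gene: GeneAnnotation) -> str:
        """Translate a coding gene, dropping the trailing stop if present."""
        prot = str(Seq(self.gene_sequence(gene)).translate())
        return prot[:-1] if prot.endswith("*") else prot

    def reverse_complement(self) -> "AnnotatedContig":
        n = len(self.sequence)
        rc = str(Seq(self.sequence).reverse_complement())
        genes = [
            replace(g, start=n - g.end, end=n - g.start,
                    strand="-" if g.strand == "+" else "+")
            for g in reversed(self.genes)
        ]
        return AnnotatedContig(self.contig_id, rc, genes)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, alphabet: str = NUCLEOTIDE) -> list[SequenceRecord]:
    """Read a FASTA file; an empty file yields an empty list."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq), alphabet,
                                      rec.description))
    return records


def write_fasta(records, path, width: int = 80):
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id,
                         description=r.description or "")
           for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
    return path


# ---------------------------------------------------------------------------
# GFF-like gene tables

_GFF_COLUMNS = ["contig_id", "gene_name", "start", "end", "strand"]


def read_gene_table(path) -> list[GeneAnnotation]:
    """Tab-separated gene table: contig, gene, start, end, strand."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts == _GFF_COLUMNS:
                continue
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            try:
                out.append(GeneAnnotation(parts[0], parts[1],
                                          int(parts[2]), int(parts[3]), parts[4]))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_gene_table(annotations, path):
    with open(path, "w") as fh:
        fh.write("\t".join(_GFF_COLUMNS) + "\n")
        for a in annotations:
            fh.write(f"{a.contig_id}\t{a.gene_name}\t{a.start}\t{a.end}\t{a.strand}\n")
    return path


# ---------------------------------------------------------------------------
# jplace-style placement JSON

JPLACE_FIELDS = ["edge_num", "log_likelihood", "like_weight_ratio",
                 "distal_length", "pendant_length"]


def write_jplace(placements, tree_newick: str, path, metadata=None):
    """Write placements in the jplace interchange layout (version 3).

    ``placements`` is a list of ``(query_id, rows)`` where each row is a
    tuple matching :data:`JPLACE_FIELDS`.
    """
    doc = {
        "version": 3,
        "tree": tree_newick,
        "fields": JPLACE_FIELDS,
        "placements": [{"n": [qid], "p": [list(row) for row in rows]}
                       for qid, rows in placements],
        "metadata": metadata or {"invocation": "pbstyper"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    return path


def read_jplace(path):
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("fields") != JPLACE_FIELDS:
        raise FormatError(f"{path}: unexpected jplace fields {doc.get('fields')}")
    placements = [(p["n"][0], [tuple(row) for row in p["p"]])
                  for p in doc["placements"]]
    return placements, doc["tree"]


# ---------------------------------------------------------------------------
# Sequence statistics

def gc_fraction(seq, start: int | None = None, end: int | None = None) -> float:
    """GC fraction over ``[start, end)``; ambiguity codes excluded entirely."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    start = 0 if start is None else start
    end = len(residues) if end is None else end
    if not (0 <= start < end <= len(residues)):
        raise ValueError(f"invalid window [{start}, {end}) on length {len(residues)}")
    window = residues[start:end].upper()
    gc = sum(window.count(c) for c in "GC")
    at = sum(window.count(c) for c in "AT")
    if gc + at == 0:
        raise ValueError("window contains no unambiguous A/C/G/T residues")
    return gc / (gc + at)


def _identity_aligner(alphabet: str, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    if alphabet == PROTEIN:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    else:
        aligner.match_score = 5
        aligner.mismatch_score = -4
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
    if mode == "overlap":
        # free end gaps on both sequences
        aligner.open_end_insertion_score = 0
        aligner.extend_end_insertion_score = 0
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    return aligner


def pairwise_identity(a: SequenceRecord, b: SequenceRecord,
                      mode: str = "global") -> tuple[float, int, int]:
    """Percent identity between two sequences after optimal alignment.

    Returns ``(identity, n_identical, n_compared)`` where ``n_compared``
    counts aligned residue-residue columns (gap columns excluded); in
    ``overlap`` mode terminal overhangs are additionally unpenalized.
    """
    if mode not in ("global", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    if a.alphabet != b.alphabet:
        raise ValueError("sequences must share an alphabet")
    aligner = _identity_aligner(a.alphabet, mode)
    aln = aligner.align(a.residues.upper(), b.residues.upper())[0]
    n_id = n_cmp = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        n_cmp += t1 - t0
        for x, y in zip(aln.target[t0:t1], aln.query[q0:q1]):
            if x == y:
                n_id += 1
    if n_cmp == 0:
        return 0.0, 0, 0
    return n_id / n_cmp, int(n_id), int(n_cmp)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_orfs(nt_sequence: str, min_aa: int = 30) -> list[SequenceRecord]:
    """Stop-to-stop open reading frames from all six frames.

    Returns protein records ordered by decreasing length; ids encode the
    frame and peptide offset so callers can dedupe per source read.
    """
    out = []
    for strand, seq in (("+", nt_sequence), ("-", reverse_complement(nt_sequence))):
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[:len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            prot = str(Seq(sub).translate())
            pos = 0
            for chunk in prot.split("*"):
                if len(chunk) >= min_aa:
                    out.append(SequenceRecord(
                        f"orf_{strand}{frame}_{pos}", chunk, PROTEIN))
                pos += len(chunk) + 1
    out.sort(key=lambda r: -len(r.residues))
    return out


def shannon_entropy(counts) -> float:
    """Entropy (nats) of a discrete count vector; zero counts ignored."""
    total = sum(counts)
    if total == 0:
        return 0.0
    return -sum((c / total) * math.log(c / total) for c in counts if c > 0)
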