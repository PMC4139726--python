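"""Pigment-type classification of annotated PBS gene clusters and
horizontal-gene-transfer evidence scoring.

Picocyanobacterial phycobilisome gene clusters fall into gene-content
classes: type I carries phycocyanin only (cpcBA with rod linkers cpcCD);
type II adds phycoerythrin-I (cpeBA and its linkers) but loses cpcCD;
type III additionally carries phycoerythrin-II (mpeBA).  Type IIB is the
unusual class combining PC rod linkers cpcCD *and* PEI genes, with the
cpcBA/cpcCD block sitting upstream of the PEI-associated genes at the
opposite end of the cluster.

HGT evidence flags mirror the signatures seen on such clusters:
duplicated cpcGII core linkers at the cluster ends, transposases inside
the cluster, a long near-identical repeat overlapping a tRNA gene, and
local GC anomalies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import AnnotatedContig, GeneAnnotation, gc_fraction

#: Genes counted as part of the PBS cluster proper.
PBS_GENES = frozenset({
    "cpcB", "cpcA", "cpcC", "cpcD", "cpcE", "cpcF", "cpcGI", "cpcGII",
    "cpeB", "cpeA", "cpeC", "cpeE", "cpeY", "cpeZ",
    "mpeB", "mpeA", "pebA", "pebB",
})

PEI_ASSOCIATED = frozenset({"cpeB", "cpeA", "cpeC", "cpeE", "cpeY", "cpeZ"})

#: Below this contig length a call is reported with partial confidence.
MIN_CONFIDENT_LENGTH = 2000


@dataclass
class PigmentTypeCall:
    contig_id: str
    type: str                      # I, II, IIB, III or partial
    evidence: list[str] = field(default_factory=list)
    confidence: str = "full"       # full or partial


@dataclass
class HgtEvidence:
    flags: set = field(default_factory=set)
    coordinates: dict = field(default_factory=dict)  # flag -> [(start, end), ...]


def _majority_strand(genes: list[GeneAnnotation]) -> str:
    pbs = [g for g in genes if g.gene_name in PBS_GENES]
    plus = sum(1 for g in (pbs or genes) if g.strand == "+")
    return "+" if 2 * plus >= len(pbs or genes) else "-"


def classify_cluster(contig: AnnotatedContig) -> PigmentTypeCall:
    """Call the pigment type of one annotated contig.

    Decision order puts richer gene content first (III before IIB
    before II before I) so partial clusters degrade predictably.
    "Upstream" is evaluated in the cluster's transcriptional
    orientation, taken as the majority strand of its PBS genes.
    """
    genes = contig.genes
    if not genes:
        raise ValueError(f"{contig.contig_id}: no annotated genes")
    names = {g.gene_name for g in genes}
    evidence = [f"genes:{','.join(sorted(names & PBS_GENES))}"]
    confidence = "full"
    if len(contig.sequence) < MIN_CONFIDENT_LENGTH:
        confidence = "partial"
        evidence.append(f"short_contig:{len(contig.sequence)}bp")

    has_pc = {"cpcB", "cpcA"} <= names
    has_pei = {"cpeB", "cpeA"} <= names
    has_peii = {"mpeB", "mpeA"} <= names
    has_cpccd = bool(names & {"cpcC", "cpcD"})

    if has_peii:
        evidence.append("mpeBA_present")
        return PigmentTypeCall(contig.contig_id, "III", evidence, confidence)

    if has_pei and has_cpccd:
        evidence.append("cpeBA_with_cpcCD")
        # order check: cpcBA block upstream of the PEI-associated genes
        orientation = _majority_strand(genes)
        ordered = sorted(genes, key=lambda g: g.start,
                         reverse=(orientation == "-"))
        pc_pos = [i for i, g in enumerate(ordered)
                  if g.gene_name in ("cpcB", "cpcA", "cpcC", "cpcD")]
        pei_pos = [i for i, g in enumerate(ordered)
                   if g.gene_name in PEI_ASSOCIATED]
        if pc_pos and pei_pos and max(pc_pos) < min(pei_pos):
            evidence.append("cpcBA_upstream_of_PEI_block")
        else:
            evidence.append("order_conflict:cpcBA_not_upstream_of_PEI")
            confidence = "partial"
        return PigmentTypeCall(contig.contig_id, "IIB", evidence, confidence)

    if has_pei:
        evidence.append("cpeBA_without_cpcCD")
        return PigmentTypeCall(contig.contig_id, "II", evidence, confidence)

    if has_pc:
        evidence.append("cpcBA_only")
        return PigmentTypeCall(contig.contig_id, "I", evidence, confidence)

    evidence.append("diagnostic_genes_missing")
    return PigmentTypeCall(contig.contig_id, "partial", evidence, "partial")


def gc_contrast(contig: AnnotatedContig, region_a: tuple[int, int],
                region_b: tuple[int, int]) -> tuple[float, float, float]:
    """GC fraction of two disjoint regions and their signed difference
    (a minus b)."""
    (a0, a1), (b0, b1) = region_a, region_b
    if a0 < b1 and b0 < a1:
        raise ValueError("regions overlap")
    gc_a = gc_fraction(contig.sequence, a0, a1)
    gc_b = gc_fraction(contig.sequence, b0, b1)
    return gc_a, gc_b, gc_a - gc_b


# ---------------------------------------------------------------------------
# repeats

def find_repeats(sequence: str, min_len: int = 100, seed_len: int = 31,
                 min_identity: float = 0.95):
    """Direct intra-sequence repeats by exact-seed chaining.

    Exact ``seed_len``-mers occurring at two positions are grouped by
    diagonal (offset); runs of seeds on one diagonal are merged into a
    candidate repeat whose identity is then verified directly.  Returns
    ``[(start1, end1, start2, end2, length, identity), ...]``.
    """
    seq = sequence.upper()
    n = len(seq)
    index: dict[str, list[int]] = {}
    for i in range(n - seed_len + 1):
        index.setdefault(seq[i:i + seed_len], []).append(i)
    by_diag: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                by_diag.setdefault(j - i, []).append(i)
    out = []
    for diag, starts in sorted(by_diag.items()):
        if diag < min_len:   # overlapping self-match on a tiny shift
            continue
        starts.sort()
        run_start = prev = starts[0]
        runs = []
        for s in starts[1:]:
            if s - prev <= seed_len:
                prev = s
            else:
                runs.append((run_start, prev + seed_len))
                run_start = prev = s
        runs.append((run_start, prev + seed_len))
        for s0, s1 in runs:
            length = s1 - s0
            if length < min_len:
                continue
            a, b = seq[s0:s1], seq[s0 + diag:s1 + diag]
            ident = sum(x == y for x, y in zip(a, b)) / length
            if ident >= min_identity:
                out.append((s0, s1, s0 + diag, s1 + diag, length, ident))
    return out


def flag_hgt(contig: AnnotatedContig, repeat_min_len: int = 1000,
             gc_window: int = 2000, gc_z_threshold: float = 3.0,
             seed_len: int = 31) -> HgtEvidence:
    """Score horizontal-transfer evidence on one contig."""
    if repeat_min_len < 100:
        raise ValueError("repeat_min_len must be >= 100")
    ev = HgtEvidence()

    # duplicated core linker
    gii = [g for g in contig.genes if g.gene_name == "cpcGII"]
    if len(gii) >= 2:
        ev.flags.add("duplicate_cpcGII")
        ev.coordinates["duplicate_cpcGII"] = [(g.start, g.end) for g in gii]

    # transposase inside the PBS cluster span
    pbs = [g for g in contig.genes if g.gene_name in PBS_GENES]
    if pbs:
        lo = min(g.start for g in pbs)
        hi = max(g.end for g in pbs)
        inside = [g for g in contig.genes
                  if g.gene_name == "transposase" and lo <= g.start and g.end <= hi]
        if inside:
            ev.flags.add("transposase_in_cluster")
            ev.coordinates["transposase_in_cluster"] = [
                (g.start, g.end) for g in inside]

    # long near-identical repeat overlapping a tRNA gene
    trnas = [g for g in contig.genes if g.gene_name == "tRNA-Phe"]
    if trnas:
        for s0, e0, s1, e1, length, ident in find_repeats(
                contig.sequence, repeat_min_len, seed_len):
            touches = any(not (g.end <= s or g.start >= e)
                          for g in trnas for s, e in ((s0, e0), (s1, e1)))
            if touches:
                ev.flags.add("trna_adjacent_repeat")
                ev.coordinates.setdefault("trna_adjacent_repeat", []).extend(
                    [(s0, e0), (s1, e1)])
                break

    # sliding-window GC anomaly
    n = len(contig.sequence)
    if n >= 2 * gc_window:
        step = gc_window // 2
        windows = [(s, min(s + gc_window, n))
                   for s in range(0, n - gc_window + 1, step)]
        vals = np.array([gc_fraction(contig.sequence, s, e)
                         for s, e in windows])
        sd = vals.std()
        if sd > 0:
            z = (vals - vals.mean()) / sd
            hits = [w for w, zz in zip(windows, z)
                    if abs(zz) > gc_z_threshold]
            if hits:
                ev.flags.add("gc_anomaly")
                ev.coordinates["gc_anomaly"] = hits
    return ev
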