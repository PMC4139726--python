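"""Ground-truth generator: reference clusters, evolved genomes,
fragmentary read sets and community abundance profiles.

The generator emulates the statistical structure of a brackish-to-marine
picocyanobacterial metagenome study: four phycobilisome gene-cluster
architectures (types I, II, IIB, III), sequence divergence along a known
genealogy, short sequencing fragments, per-sample community abundances
along a salinity gradient, and RecA/ribosomal-marker backgrounds for
normalization.  Every read records its true source taxon and gene, so
downstream homology, placement, typing and abundance modules can be
scored against planted truth.

Nucleotide mutation uses an HKY-style model (transition/transversion
ratio 2 by default); protein divergence emerges through translation.
Genes are sense-codon strings with a single stop; codon choice steers
the overall GC content to a per-template target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .models import HKYModel, NT_ORDER, SubstitutionModel
from .msa import Alignment
from .seqio import (AnnotatedContig, GENE_VOCABULARY, GeneAnnotation,
                    PROTEIN, SequenceRecord)
from .tree import ReferenceTree

AA20 = "ARNDCQEGHILKMFPSTWYV"

#: Canonical gene lengths in amino acids (tRNA-Phe is nucleotide-only).
GENE_LENGTHS_AA = {
    "cpcB": 172, "cpcA": 162, "cpcC": 290, "cpcD": 70, "cpcE": 270,
    "cpcF": 200, "cpcGI": 250, "cpcGII": 250,
    "cpeB": 177, "cpeA": 164, "cpeC": 290, "cpeE": 244,
    "cpeY": 400, "cpeZ": 200, "mpeB": 177, "mpeA": 164,
    "pebA": 240, "pebB": 250, "hemH": 320, "hmuO": 230,
    "rpsA": 310, "transposase": 300, "recA": 350,
    "rplE": 180, "rplF": 180, "rplN": 120, "rplP": 140,
    "rpsE": 170, "rpsM": 120, "unk": 150, "hyp": 100, "other": 200,
}
TRNA_PHE_LENGTH_NT = 76

# codon table: per amino acid, the synonymous codons with min / max GC
_CODONS: dict[str, list[str]] = {}
for _c in ("".join(x) for x in __import__("itertools").product("TCAG", repeat=3)):
    _aa = str(Seq(_c).translate())
    if _aa != "*":
        _CODONS.setdefault(_aa, []).append(_c)


def _gc(c: str) -> int:
    return c.count("G") + c.count("C")


_MIN_CODON = {aa: min(cs, key=lambda c: (_gc(c), c)) for aa, cs in _CODONS.items()}
_MAX_CODON = {aa: max(cs, key=lambda c: (_gc(c), c)) for aa, cs in _CODONS.items()}


@dataclass
class ArchitectureTemplate:
    """Gene order and composition of one cluster architecture."""

    type_label: str
    gene_order: list[tuple[str, str, int]]   # (gene, strand, length_aa)
    gc_target: float = 0.56
    mobile_elements: list[str] = field(default_factory=list)

    def gene_names(self):
        return [g for g, _, _ in self.gene_order]


def default_templates(gc_targets: dict | None = None) -> dict[str, ArchitectureTemplate]:
    """The four study architectures.

    Type I: PC plus rod linkers cpcCD, no PE genes.  Type II: PC plus
    PEI (cpeBA, cpeCE linkers, lyases, bilin genes), no cpcCD.  Type
    III: type II content plus PEII (mpeBA).  Type IIB: cpcGII + cpcBA +
    cpcCD upstream of the PEI-associated block, no mpeBA.  A core block
    (recA plus six ribosomal markers) rides on every genome so
    RecA-normalized profiling has its background.
    """
    gc = gc_targets or {}

    def order(genes):
        return [(g, "+", GENE_LENGTHS_AA.get(g, 150)) for g in genes]

    # a leading non-PBS gene keeps the cluster away from the contig
    # edge (fragments sample a genome, not a cluster-initial contig);
    # a core block (recA + ribosomal markers) rides on every genome
    lead = [("other", "+", 210)]
    core = ["recA", "rplE", "rplF", "rplN", "rplP", "rpsE", "rpsM",
            "other", "hyp"]
    t1 = lead + order(["cpcGI", "cpcB", "cpcA", "cpcC", "cpcD", "cpcE",
                       "cpcF"] + core)
    t2 = lead + order(["cpcB", "cpcA", "cpcE", "cpcF", "cpeB", "cpeA",
                       "cpeC", "cpeE", "cpeY", "cpeZ", "pebA", "pebB",
                       "hemH", "hmuO"] + core)
    t2b = lead + order(["cpcGII", "cpcB", "cpcA", "cpcC", "cpcD", "unk",
                        "cpeC", "cpeB", "cpeA", "cpeE", "cpeY", "cpeZ",
                        "pebA", "pebB", "hemH", "hmuO"] + core)
    t3 = lead + order(["cpcB", "cpcA", "cpcE", "cpcF", "cpeB", "cpeA",
                       "cpeC", "cpeE", "cpeY", "cpeZ", "mpeB", "mpeA",
                       "pebA", "pebB"] + core)
    templates = {
        "I": ArchitectureTemplate("I", t1, gc.get("I", 0.60)),
        "II": ArchitectureTemplate("II", t2, gc.get("II", 0.58)),
        "IIB": ArchitectureTemplate("IIB", t2b, gc.get("IIB", 0.56)),
        "III": ArchitectureTemplate("III", t3, gc.get("III", 0.58)),
    }
    _equalize_lengths(templates)
    return templates


def _equalize_lengths(templates: dict[str, ArchitectureTemplate],
                      spacer_length: int = 60):
    """Pad templates with filler genes so all genomes have equal length.

    Real picocyanobacterial genomes are near-identical in size whatever
    their pigment type; equal contig lengths also make uniformly drawn
    read counts per gene directly proportional to taxon abundance.
    Filler genes get unique lengths so no two are identical sequences.
    """
    def total_nt(t: ArchitectureTemplate) -> int:
        genes = sum(3 * L + 3 for _, _, L in t.gene_order)
        return genes + spacer_length * (len(t.gene_order) - 1)

    target = max(total_nt(t) for t in templates.values()) + 1200
    bump = 0
    for label in sorted(templates):
        t = templates[label]
        deficit = target - total_nt(t)
        while deficit >= 3 * 60 + 3 + spacer_length:
            take = min(deficit - spacer_length - 3, 3 * 400)
            length_aa = take // 3
            t.gene_order.append(("hyp", "+", length_aa - bump % 7))
            bump += 1
            deficit = target - total_nt(t)


class GeneCatalog:
    """Ancestral amino-acid sequence per gene, shared across templates
    so homologues in different architectures descend from one ancestor."""

    def __init__(self, seed: int = 7_777):
        self.seed = seed
        self._cache: dict[str, str] = {}

    def protein(self, gene: str, length_aa: int | None = None) -> str:
        length = length_aa or GENE_LENGTHS_AA.get(gene, 150)
        key = f"{gene}:{length}"
        if key not in self._cache:
            import zlib
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed,
                                        zlib.crc32(key.encode()) % 2**31]))
            aa = rng.choice(list(AA20), size=length)
            aa[0] = "M"
            self._cache[key] = "".join(aa)
        return self._cache[key]

    def trna(self) -> str:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 424242]))
        return "".join(rng.choice(list("ACGT"), size=TRNA_PHE_LENGTH_NT))


def encode_gene(protein: str, gc_target: float, rng) -> str:
    """Back-translate steering total GC toward ``gc_target``.

    Each position independently takes its maximum-GC synonymous codon
    with the probability that makes the expected GC equal the target
    (clipped to the achievable range), then a stop codon is appended.
    """
    lo = sum(_gc(_MIN_CODON[a]) for a in protein)
    hi = sum(_gc(_MAX_CODON[a]) for a in protein)
    want = gc_target * 3 * (len(protein) + 1)
    p = 0.5 if hi == lo else float(np.clip((want - lo) / (hi - lo), 0, 1))
    picks = rng.random(len(protein)) < p
    codons = [_MAX_CODON[a] if hit else _MIN_CODON[a]
              for a, hit in zip(protein, picks)]
    codons.append("TGA" if rng.random() < gc_target else "TAA")
    return "".join(codons)


def mutate_protein(protein: str, fraction: float, rng) -> str:
    """Substitute a given fraction of residues with random others."""
    out = list(protein)
    k = int(round(fraction * len(out)))
    for p in rng.choice(len(out), size=k, replace=False):
        choices = AA20.replace(out[p], "")
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def random_spacer(length: int, gc_target: float, rng) -> str:
    if length == 0:
        return ""
    gc_half = gc_target / 2
    probs = [0.5 - gc_half, gc_half, gc_half, 0.5 - gc_half]  # A C G T
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def build_template_cluster(template: ArchitectureTemplate, rng_seed: int,
                           spacer_length: int = 60,
                           catalog: GeneCatalog | None = None,
                           contig_id: str | None = None,
                           repeat_length: int = 3977) -> AnnotatedContig:
    """Materialize one architecture template as an annotated contig.

    Genes appear in template order with contiguous, non-overlapping
    0-based half-open coordinates separated by ``spacer_length``
    intergenic runs.  Mobile elements, when enabled on the template,
    plant the HGT signatures: a second ``cpcGII`` copy at the far end of
    the cluster, a ``transposase`` between ``unk`` and ``cpeC``, and a
    duplicated segment containing the tRNA-Phe gene upstream of the
    cluster.
    """
    if not template.gene_order:
        raise ValueError("template has no genes")
    unknown = [g for g, _, _ in template.gene_order if g not in GENE_VOCABULARY]
    if unknown:
        raise ValueError(f"unknown gene name(s): {unknown}")
    for g, _, length in template.gene_order:
        if length <= 0:
            raise ValueError(f"{g}: non-positive length")
    rng = np.random.default_rng(rng_seed)
    catalog = catalog or GeneCatalog()
    cid = contig_id or f"synthetic_{template.type_label}"

    gene_order = list(template.gene_order)
    if "transposase" in template.mobile_elements:
        idx = next((i for i, (g, _, _) in enumerate(gene_order)
                    if g == "cpeC"), len(gene_order))
        tl = GENE_LENGTHS_AA["transposase"]
        gene_order[idx:idx] = [("transposase", "+", tl)] * 2
    if "duplicate_cpcGII" in template.mobile_elements:
        # second copy at the far end of the PBS cluster proper
        last_pbs = max((i for i, (g, _, _) in enumerate(gene_order)
                        if g.startswith(("cpc", "cpe", "mpe", "peb"))),
                       default=len(gene_order) - 1)
        gene_order.insert(last_pbs + 1,
                          ("cpcGII", "+", GENE_LENGTHS_AA["cpcGII"]))

    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    pos = 0

    def emit(seq: str, gene: str | None = None, strand: str = "+"):
        nonlocal pos
        if gene is not None:
            annotations.append(GeneAnnotation(cid, gene, pos, pos + len(seq),
                                              strand))
        parts.append(seq)
        pos += len(seq)

    if "trna_repeat" in template.mobile_elements:
        # duplicated upstream segment including tRNA-Phe
        seg_spacer = random_spacer(
            max(repeat_length - TRNA_PHE_LENGTH_NT, 0), template.gc_target, rng)
        trna = catalog.trna()
        segment = seg_spacer[:len(seg_spacer) // 2] + trna + seg_spacer[len(seg_spacer) // 2:]
        trna_off = len(seg_spacer) // 2
        for _ in range(2):
            start = pos
            emit(segment)
            annotations.append(GeneAnnotation(
                cid, "tRNA-Phe", start + trna_off,
                start + trna_off + TRNA_PHE_LENGTH_NT, "+"))
            emit(random_spacer(spacer_length, template.gc_target, rng))

    seen_gii = 0
    for i, (gene, strand, length_aa) in enumerate(gene_order):
        prot = catalog.protein(gene, length_aa)
        if gene == "cpcGII":
            seen_gii += 1
            if seen_gii > 1:
                # the second core-linker copy has a different origin:
                # diverged to ~53% amino-acid identity
                prot = mutate_protein(prot, 0.47, rng)
        nt = encode_gene(prot, template.gc_target, rng)
        if strand == "-":
            nt = str(Seq(nt).reverse_complement())
        emit(nt, gene, strand)
        if i < len(gene_order) - 1 and spacer_length:
            emit(random_spacer(spacer_length, template.gc_target, rng))

    annotations.sort(key=lambda a: a.start)
    return AnnotatedContig(cid, "".join(parts), annotations)


# ---------------------------------------------------------------------------
# sequence evolution

_NT2I = {c: i for i, c in enumerate(NT_ORDER)}


def _encode_nt(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.zeros(arr.shape, dtype=np.int8)
    for c, i in _NT2I.items():
        out[arr == ord(c)] = i
    return out


def _decode_nt(codes: np.ndarray) -> str:
    lut = np.frombuffer("".join(NT_ORDER).encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode()


_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA


def _repair_nonsense(child: np.ndarray, parent: np.ndarray, genes) -> None:
    """Revert codons that mutated into internal stops (in place).

    Emulates purifying selection against nonsense mutations: annotated
    coding genes keep an open reading frame, as real genes sampled from
    a living population do.  The terminal stop codon is left alone.
    """
    def stop_mask(codons: np.ndarray) -> np.ndarray:
        return ((codons[:, 0] == 3)
                & (((codons[:, 1] == 0)
                    & ((codons[:, 2] == 0) | (codons[:, 2] == 2)))
                   | ((codons[:, 1] == 2) & (codons[:, 2] == 0))))

    for g in genes:
        if g.gene_name == "tRNA-Phe" or (g.end - g.start) % 3:
            continue
        if g.strand == "+":
            view = child[g.start:g.end - 3].reshape(-1, 3)
            pview = parent[g.start:g.end - 3].reshape(-1, 3)
            stop = stop_mask(view)
            if stop.any():
                view[stop] = pview[stop]
        else:
            # read codons off the reverse complement, terminal stop at
            # the segment's 5' (= contig-coordinate start) end
            rc = np.ascontiguousarray(3 - child[g.start + 3:g.end][::-1])
            prc = np.ascontiguousarray(3 - parent[g.start + 3:g.end][::-1])
            v, pv = rc.reshape(-1, 3), prc.reshape(-1, 3)
            stop = stop_mask(v)
            if stop.any():
                v[stop] = pv[stop]
                child[g.start + 3:g.end] = (3 - rc)[::-1]


def evolve_sequences(ancestor: AnnotatedContig, tree: ReferenceTree,
                     model: HKYModel | None = None,
                     rng_seed: int = 0,
                     preserve_reading_frames: bool = True
                     ) -> list[tuple[str, AnnotatedContig]]:
    """Evolve the ancestral contig down the tree, site-independently.

    Branch lengths are expected substitutions per site; annotations are
    carried over unchanged to every leaf.  With
    ``preserve_reading_frames`` (default), substitutions that would
    introduce an internal stop codon into an annotated gene are
    reverted, mimicking purifying selection against nonsense mutations.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("tree needs at least 2 leaves")
    for node in tree.edges():
        if node.length < 0:
            raise ValueError("negative branch length")
    model = model or HKYModel()
    rng = np.random.default_rng(rng_seed)
    root_states = _encode_nt(ancestor.sequence)

    out = []

    def mutate(states: np.ndarray, t: float) -> np.ndarray:
        if t == 0:
            return states
        P = model.transition_matrix(t)
        cum = np.cumsum(P, axis=1)
        r = rng.random(states.shape[0])
        return (r[:, None] > cum[states]).sum(axis=1).astype(np.int8)

    def walk(node, states):
        if node.is_leaf:
            contig = AnnotatedContig(
                f"{ancestor.contig_id}|{node.name}", _decode_nt(states),
                [GeneAnnotation(f"{ancestor.contig_id}|{node.name}",
                                g.gene_name, g.start, g.end, g.strand)
                 for g in ancestor.genes])
            out.append((node.name, contig))
            return
        for child in node.children:
            evolved = mutate(states, child.length)
            if preserve_reading_frames and evolved is not states:
                _repair_nonsense(evolved, states, ancestor.genes)
            walk(child, evolved)

    walk(tree.root, root_states)
    order = {n.name: i for i, n in enumerate(leaves)}
    out.sort(key=lambda p: order[p[0]])
    return out


def simulate_protein_alignment(tree: ReferenceTree, model: SubstitutionModel,
                               nsites: int, rng_seed: int = 0) -> Alignment:
    """Simulate a gap-free protein alignment on a tree under the model
    (discrete-gamma site rates included)."""
    rng = np.random.default_rng(rng_seed)
    rates = model.category_rates
    cat = rng.integers(0, len(rates), size=nsites)
    pi = model.freqs
    root = rng.choice(20, size=nsites, p=pi)
    rows = {}

    def mutate(states, t):
        child = np.empty_like(states)
        for c, r in enumerate(rates):
            mask = cat == c
            if not mask.any():
                continue
            P = model.transition_matrix(t, r)
            cum = np.cumsum(P, axis=1)
            u = rng.random(mask.sum())
            child[mask] = (u[:, None] > cum[states[mask]]).sum(axis=1)
        return child

    def walk(node, states):
        if node.is_leaf:
            rows[node.name] = states
            return
        for c in node.children:
            walk(c, mutate(states, c.length))

    walk(tree.root, root)
    records = [SequenceRecord(name, "".join(AA20[i] for i in rows[name]),
                              PROTEIN)
               for name in tree.leaf_names()]
    return Alignment(records)


# ---------------------------------------------------------------------------
# communities and read sets

@dataclass
class SimulatedCommunity:
    tree: ReferenceTree
    genomes: list[tuple[str, str, AnnotatedContig]]  # (taxon, type, contig)
    abundance: pd.DataFrame                          # samples x taxa
    sample_meta: pd.DataFrame
    catalog: "GeneCatalog | None" = None

    def __post_init__(self):
        leaf = set(self.tree.leaf_names())
        missing = [t for t, _, _ in self.genomes if t not in leaf]
        if missing:
            raise ValueError(f"taxa not on tree: {missing}")
        self.abundance = self.abundance.div(self.abundance.sum(axis=1), axis=0)

    def genome(self, taxon: str) -> AnnotatedContig:
        for t, _, contig in self.genomes:
            if t == taxon:
                return contig
        raise KeyError(taxon)

    def type_of(self, taxon: str) -> str:
        for t, label, _ in self.genomes:
            if t == taxon:
                return label
        raise KeyError(taxon)

    def type_fractions(self) -> pd.DataFrame:
        """Designed per-sample pigment-type fractions."""
        types = sorted({label for _, label, _ in self.genomes})
        out = pd.DataFrame(0.0, index=self.abundance.index, columns=types)
        for taxon in self.abundance.columns:
            out[self.type_of(taxon)] += self.abundance[taxon]
        return out


@dataclass
class Read:
    read_id: str
    sample_id: str
    sequence: str
    true_taxon: str
    true_gene: str


@dataclass
class ReadSet:
    reads: list[Read]
    fragment_mean: float
    fragment_sd: float

    def __post_init__(self):
        ids = [r.read_id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("read ids not unique")


#: Fragment-length presets: long-read pyrosequencing-like and short-read.
FRAGMENT_PRESETS = {"454": (400.0, 100.0), "illumina": (100.0, 10.0)}


def fragment_and_sample(community: SimulatedCommunity,
                        n_reads_per_sample: int,
                        fragment_mean: float = 400.0,
                        fragment_sd: float = 100.0,
                        rng_seed: int = 0) -> ReadSet:
    """Draw taxon-proportional fragments per sample, recording truth."""
    if n_reads_per_sample <= 0:
        raise ValueError("n_reads_per_sample must be positive")
    shortest = min(len(c.sequence) for _, _, c in community.genomes)
    if fragment_mean > shortest:
        raise ValueError(f"fragment mean {fragment_mean} exceeds shortest "
                         f"genome length {shortest}")
    rng = np.random.default_rng(rng_seed)
    taxa = list(community.abundance.columns)
    reads: list[Read] = []
    for sample_id in community.abundance.index:
        probs = community.abundance.loc[sample_id].to_numpy()
        choice = rng.choice(len(taxa), size=n_reads_per_sample, p=probs)
        lengths = np.clip(
            rng.normal(fragment_mean, fragment_sd, size=n_reads_per_sample),
            50, None).astype(int)
        for k, (ti, L) in enumerate(zip(choice, lengths)):
            taxon = taxa[ti]
            contig = community.genome(taxon)
            glen = len(contig.sequence)
            L = int(min(L, glen))
            start = int(rng.integers(0, glen - L + 1))
            mid = start + L // 2
            gene = next((g.gene_name for g in contig.genes
                         if g.start <= mid < g.end), "intergenic")
            reads.append(Read(f"{sample_id}|read{k}", str(sample_id),
                              contig.sequence[start:start + L], taxon, gene))
    return ReadSet(reads, fragment_mean, fragment_sd)


# ---------------------------------------------------------------------------
# the bundled study design: a six-sample salinity gradient

BRACKISH_FRACTIONS = {"IIB": 0.80, "I": 0.10, "II": 0.05, "III": 0.05}
MARINE_FRACTIONS = {"III": 0.80, "II": 0.10, "I": 0.05, "IIB": 0.05}


def gradient_community(rng_seed: int = 0, n_per_clade: int = 3,
                       within_clade: float = 0.02, clade_stem: float = 0.25,
                       kappa: float = 2.0,
                       templates: dict | None = None) -> SimulatedCommunity:
    """Six-sample brackish-to-marine community with planted type mixture.

    Three brackish samples (3-7 PSU) are dominated by type IIB, three
    marine samples (25-35 PSU) by type III, mirroring the qualitative
    gradient the pipeline is meant to recover.  Genomes of each type
    evolve from their architecture template along a four-clade genealogy.
    """
    templates = templates or default_templates()
    types = ["I", "II", "IIB", "III"]
    clades = []
    for label in types:
        leaves = ",".join(
            f"{label}_{i}:{within_clade}" for i in range(1, n_per_clade + 1))
        clades.append(f"({leaves}):{clade_stem}")
    tree = ReferenceTree.from_newick("(" + ",".join(clades) + ");")
    catalog = GeneCatalog(seed=rng_seed * 1000 + 17)
    model = HKYModel(kappa=kappa)

    genomes = []
    for t_idx, label in enumerate(types):
        ancestor = build_template_cluster(
            templates[label], rng_seed * 100 + t_idx, catalog=catalog)
        for taxon, contig in evolve_sequences(
                ancestor, tree, model, rng_seed * 100 + 50 + t_idx):
            if taxon.startswith(label + "_"):
                genomes.append((taxon, label, contig))

    taxa = [t for t, _, _ in genomes]
    samples = ["brackish_1", "brackish_2", "brackish_3",
               "marine_1", "marine_2", "marine_3"]
    salinity = [3.0, 5.0, 7.0, 25.0, 30.0, 35.0]
    rows = []
    for s in samples:
        frac = BRACKISH_FRACTIONS if s.startswith("brackish") else MARINE_FRACTIONS
        rows.append([frac[lbl] / n_per_clade
                     for t in taxa for lbl in [t.rsplit("_", 1)[0]]])
    abundance = pd.DataFrame(rows, index=samples, columns=taxa)
    meta = pd.DataFrame({
        "sample_id": samples, "salinity_psu": salinity,
        "depth_m": [2.0] * 6,
        "date": ["2009-07-%02d" % (10 + i) for i in range(6)],
        "size_fraction": ["0.1-0.8"] * 6,
    }).set_index("sample_id")
    return SimulatedCommunity(tree, genomes, abundance, meta, catalog)


def subunit_reference_sets(catalog: GeneCatalog):
    """Reference proteins per homology category from the gene catalog."""
    from .homology import GENE_CATEGORY
    refs: dict[str, list[SequenceRecord]] = {}
    for gene, category in GENE_CATEGORY.items():
        refs.setdefault(category, []).append(
            SequenceRecord(f"ref_{gene}", catalog.protein(gene), PROTEIN))
    return refs


def decoy_proteins(n: int, length: int = 250, rng_seed: int = 99) -> list[SequenceRecord]:
    """Random unrelated proteins standing in for a broad sequence
    database in the reciprocal search's back pass."""
    rng = np.random.default_rng(rng_seed)
    return [SequenceRecord(f"decoy_{i}",
                           "".join(rng.choice(list(AA20), size=length)),
                           PROTEIN)
            for i in range(n)]
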