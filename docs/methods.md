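# Methods

`pbstyper` reimplements, as a tested library, the inference chain used
to genotype picocyanobacterial phycobilisome (PBS) pigment types from
metagenomic sequence data: homology-based subunit identification,
reference phylogenies, likelihood placement of short fragments,
gene-cluster architecture classification, horizontal-gene-transfer
(HGT) evidence scoring, and RecA-normalized abundance profiling.  All
of it is exercised end-to-end on a synthetic metagenome with planted
ground truth.  This note records the models, the parameters that
matter, and the design choices made where the design was genuinely
open.

## The biological model

Cluster-5 picocyanobacteria (*Synechococcus*/*Cyanobium*) carry their
PBS genes in a conserved genomic region whose organization correlates
with pigmentation:

* **Type I** — phycocyanin only: `cpcBA` subunits with rod linkers
  `cpcCD`; blue-green cells of turbid, red-light waters.
* **Type II** — adds phycoerythrin-I: `cpeBA` with `cpeCE` linkers,
  lyases and bilin-synthesis genes, and *loses* `cpcCD`.
* **Type III** — additionally carries phycoerythrin-II (`mpeBA`);
  red cells of blue-light oceanic waters.
* **Type IIB** — the unusual configuration this package exists to
  detect: `cpcGII + cpcBA + cpcCD` sitting *upstream* of the
  PEI-associated block, with no `mpeBA`.  The co-occurrence of PC rod
  linkers with PEI genes is found in no sequenced reference genome,
  and several mobile-element signatures around such clusters point to
  horizontal acquisition.

The classifier (`pigment_typing.classify_cluster`) applies these
definitions in a fixed order — III before IIB before II before I — so
richer gene content dominates and partial clusters degrade predictably.
"Upstream" is evaluated on the majority strand of the cluster's PBS
genes, which makes the call invariant to reverse-complementing the
contig.  Contigs under 2 kb are called at `partial` confidence: below
that length there is usually too little flanking context to trust an
architecture call.

HGT evidence (`flag_hgt`) looks for four signatures: (1) two `cpcGII`
core-linker annotations (the planted synthetic pair diverges to ~53%
amino-acid identity, emulating copies with conflicting phylogenetic
origins); (2) transposase genes inside the cluster span; (3) a long
(default ≥ 1 kb) near-identical (≥ 95%) intra-contig repeat overlapping
a tRNA gene, found by exact 31-mer seed chaining with direct identity
verification; (4) sliding-window GC anomalies (2 kb windows, |z| > 3).

## Homology search

Subunit categories (PC = cpcBA, PEI = cpeBA, PEII = mpeBA, RecA, six
ribosomal markers rplE/F/N/P, rpsE/M) are assigned by reciprocal best
hit: a forward search of reference proteins against the metagenomic
proteins retains queries at E < 1e-10; a back search against references
plus a decoy database must return a reference of the same category,
otherwise the hit is flagged unconfirmed and excluded from counts.
Scoring is exact Smith-Waterman (BLOSUM62, gap open 11 / extend 1)
with fixed Karlin-Altschul statistics (λ = 0.267, K = 0.041) for the
bit-score/E-value conversion.  Fixed statistics make the E-value
threshold a deterministic contract; the cutoff, not the statistics
engine, is what downstream results depend on.  Fragments shorter than
30 aa are reported but flagged below a reliability floor.  Ties break
by bit score, then lexicographic reference id.

## Alignment

The progressive aligner builds a guide tree from 3-mer distances
(UPGMA, index-ordered tie-breaks) and merges profiles by
Needleman-Wunsch with BLOSUM62 expected-score columns and a linear gap
penalty of 8.  This is a deliberate substitution for an iterative
refinement aligner: the phycobiliprotein subunits are highly conserved,
alignment quality affects the results only weakly, and determinism
makes every downstream tree reproducible.  Automated column filtering
(drop columns above a gap fraction, default 0.5) stands in for manual
curation.  Concatenation unions taxa across genes and gap-fills missing
blocks; `require_complete` reproduces the stricter keep-only-complete
behaviour used for core-genome sets.  Query fragments are
profile-aligned against the frozen reference alignment — reference
columns are immutable and query insertions are dropped — so reference
coordinates stay stable, which is what edge-indexed placement requires.

## Phylogenetics

Likelihoods use Felsenstein pruning over empirical amino-acid models
(WAG, LG, JTT, Dayhoff; published exchangeabilities embedded as
constants) with discrete-gamma rate heterogeneity (4 categories, mean
category rates; rates average to exactly 1 for any shape α).  The
engine is vectorized across sites with per-site rescaling, and is
invariant to rooting for these reversible models (checked to 1e-9).

Topology comes from neighbor-joining on maximum-likelihood pairwise
distances; branch lengths and α are then refit by coordinate-wise Brent
ascent (branch bounds [1e-8, 10]; sweep convergence 1e-6; a
non-converged fit returns with a warning rather than failing).  This
NJ + ML-refit scheme is the package's central methodological
substitution for a full ML topology search: it is deterministic and
desk-scale, and the synthetic recovery checks that define correctness
here do not require heuristic tree search.  Bootstrap support resamples
columns within partitions and reports bipartition frequencies.  Model
choice is by AIC = 2k − 2lnL over the four-candidate set, k counting
branch lengths, α, and (for +F variants) 19 frequencies.  Alternative
topologies are compared by a RELL-resampling Shimodaira-Hasegawa-style
test (default 10 000 resamples, each topology's resampled sums centered
on their own mean); the full multiscale approximately-unbiased
procedure is out of scope, and the test is used the same way — to
reject rearrangements of the PEI topology under strong signal.

## Placement

Fragments are inserted edge-by-edge into the fixed reference tree: a
new node splits the edge at an optimized position, the query hangs from
it on an optimized pendant branch, and reference branch lengths are
never re-estimated.  Two implementation facts keep this fast without
changing the result: (1) alignment columns the query does not cover
contribute the reference likelihood unchanged for any attachment, so
they fold into one precomputed constant; (2) a small grid of candidate
attachments ranks all edges first and only the top three (configurable)
are polished by Brent iteration (tolerance 1e-6).  Per-edge likelihood
weight ratios (LWR) are normalized over all edges; edges below LWR
0.001 are omitted from reports.  Output follows the jplace interchange
layout.  Defaults declared as assumptions: fragments shorter than 60 aa
are not placed, and tallies count best edges only (an LWR-weighted
tally is available).

When tallying by clade, each edge takes the pigment type of whichever
side of its bipartition is type-unanimous, which makes the labelling
independent of the tree's arbitrary rooting; edges separating type
clades from one another, where neither side is unanimous, are counted
as `mixed`.  Type shares are computed conditional on a type call —
mixed placements are ambiguous, not evidence for or against any type,
and (ambiguity striking types roughly proportionally) conditioning
keeps the share estimator unbiased, where folding ambiguous reads into
the denominator would deflate every share toward zero.

## Abundance

Per-sample subunit counts are divided by the sample's RecA count
(single-copy normalizer) and converted to within-sample proportions;
proportions are invariant to the RecA divisor, while the normalized
values make samples comparable.  Samples with zero RecA keep raw
proportions and are flagged; all-zero rows are flagged empty.  Size
fraction is carried as a grouping column, and both within-sample and
pooled groupings are supported.

## The synthetic community

The generator defines the study conditions; it is not a tuning knob.

* **Architectures**: the four templates above, with a core block
  (recA + six ribosomal markers + filler genes) on every genome, a
  leading non-PBS gene so the cluster never abuts the contig edge, and
  filler genes padding all genomes to equal length (real
  picocyanobacterial genomes are nearly equal-sized whatever the
  pigment type; equal lengths also make uniformly drawn read counts
  per gene proportional to taxon abundance).
* **Sequences**: genes are sense-codon strings with one stop; codon
  choice steers GC to a per-template target (each position takes its
  max-GC synonymous codon with the probability that matches the target
  in expectation), and intergenic spacers (default 60 bp) are drawn at
  the same GC.  Ancestral proteins are random but shared across
  templates through a seeded catalog, so homologues in different
  architectures descend from one ancestor.
* **Evolution**: nucleotide HKY (transition/transversion ratio 2.0 by
  default) along a known genealogy, site-independent, with expected
  substitutions per site equal to path length.  Substitutions that
  would introduce an internal stop codon into an annotated gene are
  reverted — the purifying-selection constraint real genes evolve
  under; without it, deep branches shred open reading frames into
  fragments no real metagenome contains.  Protein divergence emerges
  via translation.
* **Community**: four clades (one per type, three taxa each; within
  clade 0.02, clade stems 0.25 substitutions/site) across six samples:
  three brackish (3–7 PSU) at 80% type IIB / 10% I / 5% II / 5% III,
  and three marine (25–35 PSU) at 80% type III / 10% II / 5% I / 5%
  IIB — the qualitative brackish-IIB/marine-III gradient the pipeline
  must recover.
* **Reads**: taxon-proportional fragments, normal length (454-like
  default 400 ± 100 bp; an Illumina-like 100 ± 10 preset), each
  recording its true taxon and gene.  No sequencing-error model,
  chimeras, or assembly simulation — so passing tests demonstrate the
  inference chain's correctness on clean fragments, not robustness to
  sequencing artefacts.

## Numerical and evaluation choices

* Branch-length recovery is summarized as the **mean** relative error
  across branches and replicates: at a few thousand sites the sampling
  standard error of a short (~0.05) branch can exceed 15% of its value,
  so a strict per-branch bound would fail occasionally for any
  consistent estimator.  Observed means are well under 15% with the
  gamma shape recovered inside [0.35, 0.7] for a true α of 0.5.
* Gradient recovery is judged cell-by-cell (6 samples × 4 types)
  against exact binomial confidence intervals with a Bonferroni
  family-wise 95% level: two dozen simultaneous unadjusted 95%
  intervals would be expected to fail somewhere by chance alone.
* Test-suite problem sizes (e.g. 1000 reads/sample, 10–12 replicates
  for parameter and model recovery, 200-site leave-one-out reference)
  are chosen so the whole suite runs in minutes on one CPU;
  `scripts/acceptance.py` re-runs the same analyses at larger sizes
  (1500 reads/sample, more replicates) and reports every quantity with
  the problem size it used.

## Known limitations

* No heuristic ML topology search; trees are NJ + ML-refit.  Adequate
  for the clade-level questions here, not for hard topology inference.
* The decoy database standing in for a broad protein reference is
  synthetic random sequence; confirmation rates against a real
  database would be lower.
* Chromatic-acclimation subtypes (IIIa–d) are not called — they depend
  on chromophore ratios, not sequence.
* Gene annotations are inputs (from the generator or upstream tools);
  there is no ab initio gene prediction.  ORF extraction from reads is
  stop-to-stop six-frame scanning.
* The aligner has no iterative refinement; for divergent inputs the
  gap-fraction filter is the only curation.
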