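# pbstyper

Genotyping picocyanobacterial phycobilisome (PBS) pigment types from
metagenomic sequence data.

Cluster-5 picocyanobacteria (*Synechococcus*/*Cyanobium*) colour their
light-harvesting antennae according to the gene content of one
conserved genomic region: type I clusters carry phycocyanin only
(*cpcBA* with rod linkers *cpcCD*), type II adds phycoerythrin-I
(*cpeBA*), and type III adds phycoerythrin-II (*mpeBA*).  A fourth
configuration — "type IIB", with *cpcGII + cpcBA + cpcCD* upstream of
the PEI-associated genes and no *mpeBA* — combines PC rod linkers with
PEI genes in a way seen in no sequenced reference genome, and carries
mobile-element signatures (duplicated *cpcGII*, transposases, a
tRNA-adjacent repeat, GC contrasts) suggesting horizontal acquisition.
This package is for researchers who want to detect and quantify these
genotypes in environmental sequence data, and to test the whole
inference chain against planted ground truth.

The chain, end to end:

1. **Homology** — reciprocal best-hit assignment of metagenomic
   proteins to subunit categories (PC/PEI/PEII, RecA, six ribosomal
   markers), Smith–Waterman scored, retained at E < 1e-10.
2. **Alignment** — deterministic progressive alignment of subunit
   proteins; partitioned concatenation across genes.
3. **Trees** — Felsenstein-pruning likelihood under WAG/LG/JTT/Dayhoff
   + discrete gamma (Γ4); neighbor-joining on ML distances with ML
   branch-length refit; AIC model selection; column bootstrap; a
   RELL-resampling topology test.
4. **Placement** — likelihood insertion of short fragments into every
   edge of the fixed reference tree (position and pendant length
   optimized; likelihood weight ratios reported; jplace output).
5. **Typing** — pigment-type classification of annotated contigs from
   gene content and order, plus HGT evidence flags.
6. **Abundance** — RecA-normalized subunit tables and per-clade
   placement tallies along the sample gradient.
7. **Synthetic data** — a generator that plants all of the above
   (architectures, divergence along a known tree, fragmentary reads,
   a brackish-to-marine abundance gradient) so every step is testable
   without downloads.

## Worked example

Simulate the six-sample salinity-gradient community and run the full
chain:

```python
from pbstyper.pipeline import PipelineConfig, run_gradient_analysis

cfg = PipelineConfig(rng_seed=1, n_reads_per_sample=1000)
a = run_gradient_analysis(cfg)
print(a.recovered.round(3))   # placement-tally pigment-type shares
print(a.expected.round(3))    # the designed community composition
```

prints (seed 1):

```
                I     II    IIB    III
brackish_1  0.115  0.082  0.721  0.082
brackish_2  0.089  0.071  0.732  0.107
brackish_3  0.132  0.088  0.691  0.088
marine_1    0.058  0.096  0.115  0.731
marine_2    0.063  0.079  0.079  0.778
marine_3    0.089  0.107  0.071  0.732
                I    II   IIB   III
brackish_1  0.10  0.05  0.80  0.05
...
marine_3    0.05  0.10  0.05  0.80
```

The brackish samples were simulated 80% type IIB and the marine samples
80% type III; the placement tallies recover that gradient, every cell
within its binomial confidence interval.  Shares are conditional on a
type call: fragments placed on edges *between* type clades are counted
as ambiguous rather than forced into a type, and the residual spread of
a few points around the designed fractions reflects occasional
cross-clade placement of short fragments.  Typing the twelve genomes
recovers every architecture label, and the same machinery flags the
planted HGT signatures on IIB contigs:

```python
from pbstyper.pigment_typing import classify_cluster, flag_hgt
taxon, label, contig = a.community.genomes[6]      # an IIB genome
print(classify_cluster(contig).type)               # -> IIB
```

A command-line interface mirrors the modules:

```sh
pbs simulate --out sim --seed 1 --reads-per-sample 500
pbs homology proteins.fasta sim/reference_proteins.fasta --threshold 1e-10
pbs align subunits.fasta --out aligned.fasta
pbs tree aligned.fasta --bootstrap 100 --out tree.nwk
pbs place fragments.fasta aligned.fasta tree.nwk --out placements.jplace
pbs type sim/genomes.fasta sim/genes.tsv
pbs run --seed 1 --out full_run
```

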