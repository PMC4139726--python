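import numpy as np
import pytest

from pbstyper.models import HKYModel
from pbstyper.seqio import gc_fraction
from pbstyper.synthetic import (ArchitectureTemplate, GeneCatalog,
                                build_template_cluster, decoy_proteins,
                                encode_gene, evolve_sequences,
                                fragment_and_sample)
from pbstyper.tree import ReferenceTree


class TestBuildTemplateCluster:
    def test_type_one_minimal_template(self, catalog):
        t = ArchitectureTemplate(
            "I", [(g, "+", 120) for g in ("cpcB", "cpcA", "cpcC", "cpcD")],
            gc_target=0.55)
        contig = build_template_cluster(t, 1, catalog=catalog)
        assert [g.gene_name for g in contig.genes] == \
               ["cpcB", "cpcA", "cpcC", "cpcD"]

    def test_duplicate_cpcgii_sits_at_both_ends(self, catalog, templates):
        t = templates["IIB"]
        t = ArchitectureTemplate(t.type_label, list(t.gene_order),
                                 t.gc_target, ["duplicate_cpcGII"])
        contig = build_template_cluster(t, 3, catalog=catalog)
        gii = [g for g in contig.genes if g.gene_name == "cpcGII"]
        assert len(gii) == 2
        pbs = [g for g in contig.genes
               if g.gene_name.startswith(("cpc", "cpe", "peb"))]
        assert gii[0].start == min(g.start for g in pbs)
        assert gii[-1].end == max(g.end for g in pbs)

    def test_coordinate_arithmetic_zero_spacers(self, catalog):
        t = ArchitectureTemplate("I", [("cpcB", "+", 10), ("cpcA", "+", 10)],
                                 gc_target=0.5)
        contig = build_template_cluster(t, 5, spacer_length=0,
                                        catalog=catalog)
        assert len(contig.sequence) == 2 * 33
        assert [(g.start, g.end) for g in contig.genes] == [(0, 33), (33, 66)]

    def test_gc_within_two_points_of_target(self, catalog, templates):
        for label, t in templates.items():
            contig = build_template_cluster(t, 11, catalog=catalog)
            assert abs(gc_fraction(contig.sequence) - t.gc_target) < 0.02

    def test_unknown_gene_rejected(self, catalog):
        t = ArchitectureTemplate("I", [("nonsense", "+", 100)])
        with pytest.raises(ValueError, match="nonsense"):
            build_template_cluster(t, 1, catalog=catalog)

    def test_gc_converges_at_long_lengths(self, rng):
        # 100 kb of coding sequence: GC within half a point of target
        catalog = GeneCatalog(5)
        target = 0.56
        seqs = [encode_gene(catalog.protein("hyp", 4000 + i), target,
                            np.random.default_rng(i)) for i in range(8)]
        combined = "".join(seqs)
        assert len(combined) > 90_000
        assert abs(gc_fraction(combined) - target) < 0.005


class TestEvolveSequences:
    def test_zero_branch_lengths_identity(self, catalog, templates):
        contig = build_template_cluster(templates["I"], 2, catalog=catalog)
        tree = ReferenceTree.from_newick("(x:0,y:0);")
        out = evolve_sequences(contig, tree, rng_seed=4)
        assert all(c.sequence == contig.sequence for _, c in out)

    def test_jukes_cantor_expected_identity(self):
        # two leaves at total distance 0.01 under kappa=1 (JC-like):
        # expected identity = 1/4 + 3/4 exp(-4*0.01/3) ~ 0.99005
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=21000))
        from pbstyper.seqio import AnnotatedContig
        contig = AnnotatedContig("anc", seq)
        tree = ReferenceTree.from_newick("(x:0.005,y:0.005);")
        model = HKYModel(kappa=1.0)
        expected = 0.25 + 0.75 * np.exp(-4 * 0.01 / 3)
        idents = []
        for rep in range(20):
            (_, cx), (_, cy) = evolve_sequences(contig, tree, model,
                                                rng_seed=rep)
            idents.append(np.mean([a == b for a, b in
                                   zip(cx.sequence, cy.sequence)]))
        assert np.mean(idents) == pytest.approx(expected, abs=0.003)

    def test_divergence_monotonic_in_distance(self, catalog, templates):
        contig = build_template_cluster(templates["I"], 6, catalog=catalog)

        def mean_identity(d):
            leaves = ",".join(f"t{i}:{d}" for i in range(4))
            tree = ReferenceTree.from_newick(f"({leaves});")
            out = evolve_sequences(contig, tree, rng_seed=9)
            vals = []
            for i in range(4):
                for j in range(i + 1, 4):
                    a, b = out[i][1].sequence, out[j][1].sequence
                    vals.append(np.mean([x == y for x, y in zip(a, b)]))
            return np.mean(vals)

        assert mean_identity(0.3) < mean_identity(0.1)

    def test_negative_branch_rejected(self, catalog, templates):
        contig = build_template_cluster(templates["I"], 2, catalog=catalog)
        tree = ReferenceTree.from_newick("(x:0.1,y:0.1);")
        tree.leaves()[0].length = -0.1
        with pytest.raises(ValueError):
            evolve_sequences(contig, tree)


class TestFragmentAndSample:
    def test_single_taxon_community(self, community):
        single = _single_taxon(community)
        rs = fragment_and_sample(single, 100, rng_seed=1)
        assert all(r.true_taxon == single.abundance.columns[0]
                   for r in rs.reads)

    def test_two_taxon_proportions(self, community):
        import pandas as pd
        two = _subset(community, ["I_1", "III_1"], [0.9, 0.1])
        rs = fragment_and_sample(two, 10_000, rng_seed=3)
        sample = two.abundance.index[0]
        mine = [r for r in rs.reads if r.sample_id == sample]
        frac = np.mean([r.true_taxon == "I_1" for r in mine])
        assert 0.88 <= frac <= 0.92

    def test_reads_are_genome_substrings_with_truth(self, community):
        rs = fragment_and_sample(community, 30, rng_seed=8)
        for r in rs.reads[:50]:
            genome = community.genome(r.true_taxon)
            assert r.sequence in genome.sequence

    def test_determinism(self, community):
        a = fragment_and_sample(community, 50, rng_seed=12)
        b = fragment_and_sample(community, 50, rng_seed=12)
        assert [(r.read_id, r.sequence, r.true_taxon, r.true_gene)
                for r in a.reads] == \
               [(r.read_id, r.sequence, r.true_taxon, r.true_gene)
                for r in b.reads]

    def test_oversized_fragment_rejected(self, community):
        with pytest.raises(ValueError):
            fragment_and_sample(community, 10, fragment_mean=1e7)


class TestGradientCommunity:
    def test_abundance_rows_normalized(self, community):
        sums = community.abundance.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_design_fractions(self, community):
        tf = community.type_fractions()
        assert tf.loc["brackish_1", "IIB"] == pytest.approx(0.80)
        assert tf.loc["marine_3", "III"] == pytest.approx(0.80)

    def test_equalized_genome_lengths(self, community):
        lengths = [len(c.sequence) for _, _, c in community.genomes]
        assert (max(lengths) - min(lengths)) / max(lengths) < 0.01

    def test_every_taxon_on_tree(self, community):
        leaf = set(community.tree.leaf_names())
        assert all(t in leaf for t, _, _ in community.genomes)


def _single_taxon(community):
    import pandas as pd
    from pbstyper.synthetic import SimulatedCommunity
    taxon = community.abundance.columns[0]
    ab = community.abundance[[taxon]].copy()
    ab[taxon] = 1.0
    return SimulatedCommunity(community.tree,
                              [g for g in community.genomes
                               if g[0] == taxon],
                              ab, community.sample_meta, community.catalog)


def _subset(community, taxa, fracs):
    import pandas as pd
    from pbstyper.synthetic import SimulatedCommunity
    ab = community.abundance[taxa].iloc[:1].copy()
    ab.iloc[0] = fracs
    genomes = [g for g in community.genomes if g[0] in taxa]
    return SimulatedCommunity(community.tree, genomes, ab,
                              community.sample_meta.iloc[:1],
                              community.catalog)


class TestDecoys:
    def test_deterministic_given_seed(self):
        a = decoy_proteins(3, rng_seed=5)
        b = decoy_proteins(3, rng_seed=5)
        assert [r.residues for r in a] == [r.residues for r in b]
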