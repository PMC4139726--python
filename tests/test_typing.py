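import pytest

from pbstyper.pigment_typing import (classify_cluster, find_repeats,
                                     flag_hgt, gc_contrast)
from pbstyper.seqio import AnnotatedContig, GeneAnnotation
from pbstyper.synthetic import ArchitectureTemplate, build_template_cluster


def contig_with(genes, length=3000):
    """Minimal contig: evenly spaced annotations on a neutral sequence."""
    anns = []
    step = max(length // max(len(genes), 1), 60)
    for i, name in enumerate(genes):
        start = i * step
        anns.append(GeneAnnotation("c", name, start, start + 50, "+"))
    seq = ("ACGT" * (length // 4 + 1))[:length]
    return AnnotatedContig("c", seq, anns)


class TestClassifyCluster:
    @pytest.mark.parametrize("genes,expected", [
        (["cpcB", "cpcA", "cpcC", "cpcD"], "I"),
        (["cpcB", "cpcA", "cpeB", "cpeA", "cpeC", "cpeE"], "II"),
        (["cpcGII", "cpcB", "cpcA", "cpcC", "cpcD",
          "cpeB", "cpeA", "cpeC", "cpeE"], "IIB"),
        (["cpcB", "cpcA", "cpeB", "cpeA", "mpeB", "mpeA"], "III"),
        (["cpcGII", "cpcB", "cpcA", "cpcC", "cpcD",
          "cpeB", "cpeA", "mpeB", "mpeA"], "III"),   # mpeBA dominates
        (["cpcB", "hemH"], "partial"),
    ])
    def test_rule_order(self, genes, expected):
        assert classify_cluster(contig_with(genes)).type == expected

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            classify_cluster(AnnotatedContig("c", "ACGT" * 100, []))

    def test_short_contig_partial_confidence(self):
        call = classify_cluster(contig_with(["cpcB", "cpcA"], length=800))
        assert call.type == "I" and call.confidence == "partial"

    def test_order_conflict_demotes_confidence(self):
        # PEI block upstream of the cpcBA/cpcCD block: still IIB, flagged
        call = classify_cluster(contig_with(
            ["cpeB", "cpeA", "cpeC", "cpcB", "cpcA", "cpcC", "cpcD"]))
        assert call.type == "IIB" and call.confidence == "partial"
        assert any("order_conflict" in e for e in call.evidence)

    def test_closed_loop_on_generated_templates(self, catalog, templates):
        for label, t in templates.items():
            contig = build_template_cluster(t, 77, catalog=catalog)
            assert classify_cluster(contig).type == label

    def test_reverse_complement_invariance(self, catalog, templates):
        for label, t in templates.items():
            contig = build_template_cluster(t, 78, catalog=catalog)
            assert classify_cluster(contig.reverse_complement()).type == label

    def test_deleting_non_diagnostic_gene_keeps_type(self, catalog,
                                                     templates):
        contig = build_template_cluster(templates["IIB"], 79, catalog=catalog)
        kept = [g for g in contig.genes if g.gene_name != "pebA"]
        assert classify_cluster(
            AnnotatedContig("c", contig.sequence, kept)).type == "IIB"

    def test_deleting_diagnostic_gene_falls_back(self, catalog, templates):
        contig = build_template_cluster(templates["III"], 80, catalog=catalog)
        no_peii = [g for g in contig.genes
                   if g.gene_name not in ("mpeB", "mpeA")]
        assert classify_cluster(
            AnnotatedContig("c", contig.sequence, no_peii)).type == "II"


class TestGcContrast:
    def test_extreme_regions(self):
        contig = AnnotatedContig("c", "GGGG" + "AAAA", [])
        gc_a, gc_b, diff = gc_contrast(contig, (0, 4), (4, 8))
        assert (gc_a, gc_b, diff) == (1.0, 0.0, 1.0)

    def test_identical_regions_zero_difference(self):
        contig = AnnotatedContig("c", "ACGTACGT", [])
        _, _, diff = gc_contrast(contig, (0, 4), (4, 8))
        assert diff == 0.0

    def test_overlapping_regions_rejected(self):
        contig = AnnotatedContig("c", "ACGTACGT", [])
        with pytest.raises(ValueError):
            gc_contrast(contig, (0, 5), (4, 8))

    def test_generator_round_trip_upstream_contrast(self, catalog):
        # upstream region generated at 64% GC, cluster at 56%: the
        # measured contrast should recover the planted ~8-point gap
        t_up = ArchitectureTemplate("I", [("hyp", "+", 800)], gc_target=0.64)
        t_dn = ArchitectureTemplate("I", [("hyp", "+", 810)], gc_target=0.56)
        up = build_template_cluster(t_up, 21, catalog=catalog)
        down = build_template_cluster(t_dn, 22, catalog=catalog)
        contig = AnnotatedContig("c", up.sequence + down.sequence, [])
        gc_a, gc_b, diff = gc_contrast(
            contig, (0, len(up.sequence)),
            (len(up.sequence), len(contig.sequence)))
        assert diff == pytest.approx(0.08, abs=0.02)


class TestFindRepeats:
    def test_planted_duplication_with_trna(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=12000))
        segment = "".join(rng.choice(list("ACGT"), size=4000))
        seq = base[:2000] + segment + base[2000:4000] + segment + base[4000:]
        hits = find_repeats(seq, min_len=1000)
        assert hits
        s0, e0, s1, e1, length, ident = max(hits, key=lambda h: h[4])
        assert length >= 4000 and ident >= 0.99

    def test_no_repeats_in_random_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=8000))
        assert find_repeats(seq, min_len=500) == []


class TestFlagHgt:
    def test_clean_contig_no_flags(self, catalog, templates):
        contig = build_template_cluster(templates["II"], 31, catalog=catalog)
        ev = flag_hgt(contig)
        assert ev.flags == set()

    def test_generator_mobile_elements_all_flagged(self, catalog, templates):
        t = templates["IIB"]
        t = ArchitectureTemplate(t.type_label, list(t.gene_order),
                                 t.gc_target,
                                 ["duplicate_cpcGII", "transposase",
                                  "trna_repeat"])
        contig = build_template_cluster(t, 32, catalog=catalog)
        ev = flag_hgt(contig, repeat_min_len=1000)
        assert {"duplicate_cpcGII", "transposase_in_cluster",
                "trna_adjacent_repeat"} <= ev.flags
        # coordinates point at real annotations
        gii = [(g.start, g.end) for g in contig.genes
               if g.gene_name == "cpcGII"]
        assert ev.coordinates["duplicate_cpcGII"] == gii
        for start, end in ev.coordinates["transposase_in_cluster"]:
            names = [g.gene_name for g in contig.genes
                     if g.start == start and g.end == end]
            assert names == ["transposase"]

    def test_planted_exact_duplication_measured_length(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        segment = "".join(rng.choice(list("ACGT"), size=4000))
        full = seq + segment + segment + "".join(
            rng.choice(list("ACGT"), size=1000))
        trna = GeneAnnotation("c", "tRNA-Phe", 3100, 3176, "+")
        cpc = GeneAnnotation("c", "cpcB", 11200, 11500, "+")
        contig = AnnotatedContig("c", full, [trna, cpc])
        ev = flag_hgt(contig, repeat_min_len=1000)
        assert "trna_adjacent_repeat" in ev.flags
        spans = ev.coordinates["trna_adjacent_repeat"]
        assert max(e - s for s, e in spans) >= 3900

    def test_repeat_floor_enforced(self, catalog, templates):
        contig = build_template_cluster(templates["I"], 33, catalog=catalog)
        with pytest.raises(ValueError):
            flag_hgt(contig, repeat_min_len=50)
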