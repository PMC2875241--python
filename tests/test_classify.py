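"""The classification cascade on a handcrafted world with known answers."""

import pytest

from probemap import Probe, ProbeAssignment, assign_color, classify_probes, partition_counts
from probemap.annotation import extract_transcript_sequence, reverse_complement
from probemap.classify import (
    CAT_INTRONIC,
    CAT_MRNA,
    CAT_NA,
    CAT_NCRNA,
    ClassificationError,
    read_assignments_tsv,
    write_assignments_tsv,
)


def _classify_one(world, seq, **kw):
    [a] = classify_probes([Probe("p", seq)], world.annotation,
                          genome=world.genome,
                          ncrna_targets=world.ncrna, **kw)
    return a


class TestCascade:
    def test_single_exon_single_transcript_probe_is_green(self, world):
        a = _classify_one(world, world.slice(120, 145))  # inside GA exon a1
        assert a.category == CAT_MRNA
        assert a.genes == {"GA"} and a.transcripts == {"GA.T1"}
        assert a.exons == {"a1"}
        assert not a.junction
        assert a.gene_unique and a.transcript_specific and a.exon_specific
        assert a.color == "green"

    def test_probe_in_exon_shared_by_all_isoforms_is_yellow(self, world):
        # GM's exon m1 is carried by all four isoforms, so the probe is
        # gene-unique but not transcript-specific
        a = _classify_one(world, world.slice(620, 645))
        assert a.category == CAT_MRNA
        assert a.genes == {"GM"}
        assert a.transcripts == {"GM.T1", "GM.T2", "GM.T3", "GM.T4"}
        assert not a.transcript_specific
        assert a.exons == {"m1"} and a.exon_specific
        assert a.color == "yellow"

    def test_two_locus_probe_is_red(self, world):
        # [1220,1245) was duplicated into GA's exon a2 at genome build
        a = _classify_one(world, world.slice(1220, 1245))
        assert a.category == CAT_MRNA
        assert a.genes == {"GA", "GB"}
        assert not a.gene_unique
        assert a.color == "red"

    def test_junction_probe_has_blocks_not_exons(self, world):
        spliced = extract_transcript_sequence(world.annotation, world.genome,
                                              "GA.T1")
        a = _classify_one(world, spliced[90:115])  # spans a1|a2 boundary
        assert a.category == CAT_MRNA
        assert a.junction
        assert a.exons == set() and not a.exon_specific
        assert a.transcripts == {"GA.T1"}

    def test_minus_strand_gene_matched_via_spliced_sequence(self, world):
        spliced = extract_transcript_sequence(world.annotation, world.genome,
                                              "GB.T1")
        a = _classify_one(world, spliced[10:35])
        assert a.category == CAT_MRNA
        assert a.genes == {"GB"}
        assert a.color == "green"

    def test_annotation_noncoding_probe_is_ncrna(self, world):
        a = _classify_one(world, world.slice(1510, 1535))  # inside GN exon
        assert a.category == CAT_NCRNA
        assert a.ncrna_targets == {"GN.T1"}
        assert a.genes == {"GN"}
        assert a.color == "black"

    def test_external_ncrna_probe_is_ncrna(self, world):
        a = _classify_one(world, world.ncrna["NCX"][40:65])
        assert a.category == CAT_NCRNA
        assert a.ncrna_targets == {"NCX"}
        assert a.genes == set()
        assert a.color == "black"

    def test_intron_only_probe_is_putative_ncrna(self, world):
        a = _classify_one(world, world.slice(210, 235))  # GA intron
        assert a.category == CAT_INTRONIC
        assert a.genes == {"GA"}
        assert a.color == "black"

    def test_unmatched_probe_is_na_black(self, world):
        a = _classify_one(world, "A" * 25)
        assert a.category == CAT_NA
        assert a.genes == a.transcripts == a.exons == a.ncrna_targets == set()
        assert a.color == "black"

    def test_revcomp_probe_matches_when_enabled(self, world):
        seq = reverse_complement(world.slice(120, 145))
        a = _classify_one(world, seq)
        assert a.category == CAT_MRNA and a.genes == {"GA"}
        a_strict = _classify_one(world, seq, search_revcomp=False)
        # GA is plus-strand, so the reversed probe only matches when the
        # reverse complement is searched
        assert a_strict.category != CAT_MRNA

    def test_cascade_monotonicity(self, world):
        """Adding sequences at a later stage never changes probes resolved
        earlier."""
        probes = [Probe("p1", world.slice(120, 145)),
                  Probe("p2", world.slice(210, 235))]
        base = classify_probes(probes, world.annotation, genome=world.genome,
                               ncrna_targets=None)
        # stage 3 gains an entire ncRNA collection containing both probes
        loaded = dict(world.ncrna)
        loaded["decoy"] = world.slice(120, 145) + world.slice(210, 235)
        extended = classify_probes(probes, world.annotation,
                                   genome=world.genome, ncrna_targets=loaded)
        assert base[0].category == extended[0].category == CAT_MRNA
        assert base[0].genes == extended[0].genes
        # the intron-only probe now resolves at the earlier ncRNA stage
        assert base[1].category == CAT_INTRONIC
        assert extended[1].category == CAT_NCRNA

    def test_intron_pass_without_genome_rejected(self, world):
        with pytest.raises(ClassificationError, match="genome"):
            classify_probes([Probe("p", "A" * 25)], world.annotation,
                            genome=None, intron_pass=True)


class TestColorConvention:
    @pytest.mark.parametrize("category,genes,transcripts,expected", [
        (CAT_MRNA, {"g1"}, {"t1"}, "green"),
        (CAT_MRNA, {"g1"}, {"t1", "t2"}, "yellow"),
        (CAT_MRNA, {"g1", "g2"}, {"t1"}, "red"),
        (CAT_NCRNA, set(), set(), "black"),
        (CAT_INTRONIC, {"g1"}, set(), "black"),
        (CAT_NA, set(), set(), "black"),
    ])
    def test_color_mapping(self, category, genes, transcripts, expected):
        a = ProbeAssignment(probe_id="p", category=category, genes=genes,
                            transcripts=transcripts)
        a.gene_unique = len(genes) == 1
        a.transcript_specific = (category == CAT_MRNA and a.gene_unique
                                 and len(transcripts) == 1)
        assert assign_color(a) == expected


class TestPartition:
    def test_percentages_are_simple_arithmetic(self):
        assignments = ([ProbeAssignment(f"p{i}", category=CAT_MRNA)
                        for i in range(7)]
                       + [ProbeAssignment("p7", category=CAT_NCRNA)]
                       + [ProbeAssignment("p8", category=CAT_INTRONIC)]
                       + [ProbeAssignment("p9", category=CAT_NA)])
        counts = partition_counts(assignments)
        assert counts[CAT_MRNA] == {"count": 7, "pct": 70.0}
        assert counts[CAT_NCRNA] == {"count": 2, "pct": 20.0}  # intron pooled
        assert counts[CAT_NA] == {"count": 1, "pct": 10.0}

    def test_all_na_probe_set(self):
        assignments = [ProbeAssignment(f"p{i}", category=CAT_NA)
                       for i in range(4)]
        counts = partition_counts(assignments)
        assert counts[CAT_MRNA]["pct"] == 0.0
        assert counts[CAT_NA]["pct"] == 100.0

    def test_empty_input_rejected(self):
        with pytest.raises(ClassificationError):
            partition_counts([])

    def test_counts_equal_planted_composition(self, full_fixture,
                                              full_assignments):
        counts = partition_counts(full_assignments)
        truth = full_fixture.truth
        want_mrna = int((truth.category == CAT_MRNA).sum())
        want_nc = int(truth.category.isin([CAT_NCRNA, CAT_INTRONIC]).sum())
        want_na = len(truth) - want_mrna - want_nc
        assert counts[CAT_MRNA]["count"] == want_mrna
        assert counts[CAT_NCRNA]["count"] == want_nc
        assert counts[CAT_NA]["count"] == want_na

    def test_categories_partition_probes(self, full_assignments):
        cats = [a.category for a in full_assignments]
        assert all(c in (CAT_MRNA, CAT_NCRNA, CAT_INTRONIC, CAT_NA)
                   for c in cats)
        n = len(full_assignments)
        assert sum(cats.count(c) for c in
                   (CAT_MRNA, CAT_NCRNA, CAT_INTRONIC, CAT_NA)) == n


class TestAssignmentIO:
    def test_tsv_roundtrip(self, world, tmp_path):
        probes = [Probe("p1", world.slice(120, 145)),
                  Probe("p2", "A" * 25),
                  Probe("p3", world.slice(210, 235))]
        assignments = classify_probes(probes, world.annotation,
                                      genome=world.genome,
                                      ncrna_targets=world.ncrna)
        path = str(tmp_path / "a.tsv")
        write_assignments_tsv(assignments, path)
        back = read_assignments_tsv(path)
        assert back == sorted(assignments, key=lambda a: a.probe_id)
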