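"""Annotation loading, sequence extraction and coordinate projection."""

import numpy as np
import pytest

from probemap import (
    DictGenome,
    Exon,
    GenomeAnnotation,
    Transcript,
    extract_premrna_sequence,
    extract_transcript_sequence,
    load_annotation,
    project_to_genome,
    reverse_complement,
)
from probemap.annotation import (
    AnnotationError,
    CoordinateError,
    GeneLocus,
    PROTEIN_CODING,
)

GTF_TOY = """\
##toy
c1\tsrc\tgene\t101\t400\t.\t+\t.\tgene_id "g1"; gene_biotype "protein_coding";
c1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1"; exon_number "1"; exon_id "e1"; gene_biotype "protein_coding";
c1\tsrc\texon\t201\t260\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1"; exon_number "2"; exon_id "e2"; gene_biotype "protein_coding";
c1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t2"; exon_number "1"; exon_id "e1"; gene_biotype "protein_coding";
c2\tsrc\texon\t51\t110\t.\t-\t.\tgene_id "g2"; transcript_id "g2.t1"; exon_number "1"; exon_id "e3"; gene_biotype "lincRNA";
c2\tsrc\texon\t11\t40\t.\t-\t.\tgene_id "g2"; transcript_id "g2.t1"; exon_number "2"; exon_id "e4"; gene_biotype "lincRNA";
c2\tsrc\texon\t121\t160\t.\t-\t.\tgene_id "g2"; transcript_id "g2.t2"; exon_number "1"; exon_id "e5"; gene_biotype "lincRNA";
"""


@pytest.fixture()
def toy_gtf(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(GTF_TOY)
    return str(p)


class TestLoadAnnotation:
    def test_counts_match_features_written(self, toy_gtf):
        ann = load_annotation(toy_gtf)
        assert len(ann) == 2
        assert ann.n_transcripts == 4
        assert len(ann.exon_ids) == 5  # e1 shared between g1.t1 and g1.t2

    def test_one_based_inclusive_becomes_half_open(self, toy_gtf):
        ann = load_annotation(toy_gtf)
        e1 = ann.transcript("g1.t1").exons[0]
        assert (e1.start, e1.end) == (100, 150)

    def test_biotypes_and_strand(self, toy_gtf):
        ann = load_annotation(toy_gtf)
        assert ann.gene("g1").biotype == PROTEIN_CODING
        assert ann.gene("g2").biotype == "noncoding"
        assert ann.gene("g2").strand == "-"

    def test_locus_span_is_exon_hull(self, toy_gtf):
        ann = load_annotation(toy_gtf)
        assert (ann.gene("g1").start, ann.gene("g1").end) == (100, 260)
        assert (ann.gene("g2").start, ann.gene("g2").end) == (10, 160)

    def test_unknown_biotype_maps_to_noncoding(self, tmp_path, caplog):
        p = tmp_path / "odd.gtf"
        p.write_text('c1\ts\texon\t1\t50\t.\t+\t.\tgene_id "g"; '
                     'transcript_id "t"; gene_biotype "TEC";\n')
        ann = load_annotation(str(p))
        assert ann.gene("g").biotype == "noncoding"

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("c1\tsrc\texon\t101\n")
        with pytest.raises(AnnotationError, match="line 1"):
            load_annotation(str(p))

    def test_transcript_with_zero_exons_rejected(self, tmp_path):
        p = tmp_path / "noexon.gtf"
        p.write_text('c1\ts\ttranscript\t1\t50\t.\t+\t.\tgene_id "g"; '
                     'transcript_id "t"; gene_biotype "protein_coding";\n')
        with pytest.raises(AnnotationError, match="zero exons"):
            load_annotation(str(p))

    def test_four_transcript_sixteen_exon_locus(self, tmp_path):
        # a MEST-scale locus: 4 isoforms tiling 16 distinct exons
        lines = ["##x"]
        pos = 1
        exon_ivs = []
        for j in range(16):
            exon_ivs.append((pos, pos + 49))
            pos += 120
        subsets = [list(range(16)), list(range(0, 16, 2)),
                   list(range(0, 8)), list(range(8, 16))]
        for ti, subset in enumerate(subsets, start=1):
            for rank, j in enumerate(subset, start=1):
                s, e = exon_ivs[j]
                lines.append(
                    f'c1\ts\texon\t{s}\t{e}\t.\t+\t.\tgene_id "mest"; '
                    f'transcript_id "mest.t{ti}"; exon_number "{rank}"; '
                    f'exon_id "me{j}"; gene_biotype "protein_coding";')
        p = tmp_path / "mest.gtf"
        p.write_text("\n".join(lines) + "\n")
        ann = load_annotation(str(p))
        g = ann.gene("mest")
        assert len(g.transcripts) == 4
        assert len({e.exon_id for t in g.transcripts for e in t.exons}) == 16


class TestSequenceExtraction:
    @pytest.fixture()
    def mini(self):
        genome = DictGenome({"c": "ACGTNNNNTTGG"})
        exons = [Exon("x1", "c", 0, 4, 1), Exon("x2", "c", 8, 12, 2)]
        tplus = Transcript("t+", "g+", exons, PROTEIN_CODING, "+")
        eminus = [Exon("y1", "c", 8, 12, 1), Exon("y2", "c", 0, 4, 2)]
        tminus = Transcript("t-", "g-", eminus, PROTEIN_CODING, "-")
        gplus = GeneLocus("g+", "g+", "c", "+", PROTEIN_CODING, [tplus])
        gminus = GeneLocus("g-", "g-", "c", "-", PROTEIN_CODING, [tminus])
        return genome, GenomeAnnotation([gplus, gminus])

    def test_plus_strand_splice(self, mini):
        genome, ann = mini
        assert extract_transcript_sequence(ann, genome, "t+") == "ACGTTTGG"

    def test_minus_strand_equals_revcomp_of_plus_splice(self, mini):
        genome, ann = mini
        got = extract_transcript_sequence(ann, genome, "t-")
        assert got == "CCAAACGT"
        # independent per-base oracle: complement genomic bases 3'->5'
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        plus = "ACGTNNNNTTGG"
        oracle = "".join(comp[plus[i]]
                         for i in [11, 10, 9, 8, 3, 2, 1, 0])
        assert got == oracle

    def test_single_exon_transcript_is_genomic_slice(self, world):
        got = extract_transcript_sequence(world.annotation, world.genome,
                                          "GN.T1")
        assert got == world.slice(1500, 1560)

    def test_premrna_is_locus_span(self, world):
        got = extract_premrna_sequence(world.annotation, world.genome, "GA")
        assert got == world.slice(100, 400)

    def test_premrna_minus_strand_is_revcomp(self, world):
        got = extract_premrna_sequence(world.annotation, world.genome, "GB")
        assert got == reverse_complement(world.slice(1200, 1300))

    def test_intron_intervals_are_span_minus_exons(self, world):
        g = world.annotation.gene("GM")
        # set-arithmetic oracle over individual positions
        span = set(range(g.start, g.end))
        exonic = {p for t in g.transcripts for e in t.exons
                  for p in range(e.start, e.end)}
        expected = span - exonic
        got = {p for s, e in g.intron_intervals() for p in range(s, e)}
        assert got == expected

    def test_exon_beyond_chromosome_bounds(self):
        genome = DictGenome({"c": "ACGT"})
        exons = [Exon("e", "c", 2, 10, 1)]
        t = Transcript("t", "g", exons, PROTEIN_CODING, "+")
        g = GeneLocus("g", "g", "c", "+", PROTEIN_CODING, [t])
        ann = GenomeAnnotation([g])
        with pytest.raises(CoordinateError):
            extract_transcript_sequence(ann, genome, "t")


class TestProjection:
    @pytest.fixture()
    def two_exon_tx(self):
        exons = [Exon("e1", "c", 100, 150, 1), Exon("e2", "c", 200, 260, 2)]
        return Transcript("t", "g", exons, PROTEIN_CODING, "+")

    def test_junction_interval_splits_into_two_blocks(self, two_exon_tx):
        blocks = project_to_genome(two_exon_tx, 40, 25)
        assert [(b.start, b.end) for b in blocks] == [(140, 150), (200, 215)]
        # per-base naive projection oracle
        per_base = [100 + i if i < 50 else 200 + (i - 50)
                    for i in range(40, 65)]
        covered = [p for b in blocks for p in range(b.start, b.end)]
        assert covered == per_base

    def test_interval_inside_one_exon_is_single_block(self, two_exon_tx):
        blocks = project_to_genome(two_exon_tx, 5, 20)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (105, 125)

    def test_out_of_range_rejected(self, two_exon_tx):
        with pytest.raises(CoordinateError):
            project_to_genome(two_exon_tx, 100, 25)
        with pytest.raises(CoordinateError):
            project_to_genome(two_exon_tx, -1, 5)

    def test_projection_conserves_length_and_junction_rule(self,
                                                           small_fixture):
        rng = np.random.default_rng(0)
        for t in small_fixture.annotation.transcripts.values():
            bounds = np.cumsum([e.length for e in t.exons])[:-1]
            for _ in range(10):
                L = int(rng.integers(1, min(30, t.spliced_length) + 1))
                off = int(rng.integers(0, t.spliced_length - L + 1))
                blocks = project_to_genome(t, off, L)
                assert sum(b.length for b in blocks) == L
                crosses = any(off < b < off + L for b in bounds)
                assert (len(blocks) > 1) == crosses

    def test_round_trip_identity_every_base(self, small_fixture):
        """transcript -> genome -> transcript is the identity per base."""
        ann = small_fixture.annotation
        for t in ann.transcripts.values():
            strand = ann.gene(t.gene_id).strand
            # independent re-splice: genomic coordinate of each
            # transcript base, in transcript order
            coords = []
            for e in t.exons:
                rng_ = range(e.start, e.end)
                coords.extend(reversed(rng_) if strand == "-" else rng_)
            for pos in range(t.spliced_length):
                blocks = project_to_genome(t, pos, 1, strand=strand)
                assert len(blocks) == 1
                assert blocks[0].start == coords[pos]
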