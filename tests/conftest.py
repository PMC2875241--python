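"""Shared fixtures: a handcrafted mini-world with known probe placements
and seeded synthetic fixtures from the generator."""

import numpy as np
import pytest

from probemap import (
    DictGenome,
    Exon,
    FixtureSpec,
    GeneLocus,
    GenomeAnnotation,
    Transcript,
    generate,
)
from probemap.annotation import NONCODING, PROTEIN_CODING


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class World:
    """Handcrafted two-chromosome world with known gene structures.

    chrom c1 (length 2000), all coordinates 0-based half-open:
      GA (+, coding): exons a1 [100,200), a2 [300,400), one transcript
      GM (+, coding): exons m1 [600,700), m2 [750,800), m3 [850,900),
                      m4 [950,1000); four transcripts all sharing m1
      GB (-, coding): exon b1 [1200,1300), one transcript
      GN (+, noncoding): exon n1 [1500,1560), one transcript
    The 25 nt at [1220,1245) are duplicated into [320,345), so that
    window matches both GA and GB (a multi-locus probe source).
    """

    def __init__(self):
        rng = np.random.default_rng(123)
        seq = list(_rand_seq(rng, 2000))
        seq[320:345] = seq[1220:1245]  # plant the two-locus duplication
        self.c1 = "".join(seq)
        self.genome = DictGenome({"c1": self.c1})

        def tx(tid, gid, exon_defs, biotype, strand):
            exons = [Exon(exon_id=eid, chrom="c1", start=s, end=e, rank=r)
                     for r, (eid, s, e) in enumerate(exon_defs, start=1)]
            return Transcript(transcript_id=tid, gene_id=gid, exons=exons,
                              biotype=biotype, strand=strand)

        ga = GeneLocus(
            gene_id="GA", name="GA", chrom="c1", strand="+",
            biotype=PROTEIN_CODING,
            transcripts=[tx("GA.T1", "GA",
                            [("a1", 100, 200), ("a2", 300, 400)],
                            PROTEIN_CODING, "+")])
        m_exons = {"m1": (600, 700), "m2": (750, 800),
                   "m3": (850, 900), "m4": (950, 1000)}

        def m_tx(tid, names):
            return tx(tid, "GM",
                      [(n, *m_exons[n]) for n in names],
                      PROTEIN_CODING, "+")

        gm = GeneLocus(
            gene_id="GM", name="GM", chrom="c1", strand="+",
            biotype=PROTEIN_CODING,
            transcripts=[m_tx("GM.T1", ["m1", "m2", "m3", "m4"]),
                         m_tx("GM.T2", ["m1", "m2"]),
                         m_tx("GM.T3", ["m1", "m3"]),
                         m_tx("GM.T4", ["m1", "m4"])])
        gb = GeneLocus(
            gene_id="GB", name="GB", chrom="c1", strand="-",
            biotype=PROTEIN_CODING,
            transcripts=[tx("GB.T1", "GB", [("b1", 1200, 1300)],
                            PROTEIN_CODING, "-")])
        gn = GeneLocus(
            gene_id="GN", name="GN", chrom="c1", strand="+",
            biotype=NONCODING,
            transcripts=[tx("GN.T1", "GN", [("n1", 1500, 1560)],
                            NONCODING, "+")])
        self.annotation = GenomeAnnotation([ga, gm, gb, gn])

        nc_rng = np.random.default_rng(321)
        self.ncrna = {"NCX": _rand_seq(nc_rng, 120)}

    def slice(self, start, end):
        return self.c1[start:end]


@pytest.fixture(scope="session")
def world():
    return World()


@pytest.fixture(scope="session")
def small_fixture():
    """A compact generated fixture for unit-level checks."""
    plan = dict(exonic_unique=8, junction=5, multi_transcript=6,
                multi_gene=4, intronic=5, ncrna_db=4, unmapped=3)
    return generate(FixtureSpec(seed=11, n_genes=10, probe_plan=plan))


@pytest.fixture(scope="session")
def full_fixture():
    """The 20-gene, 200-probe fixture spanning all seven planted classes."""
    return generate(FixtureSpec(seed=5))


@pytest.fixture(scope="session")
def full_assignments(full_fixture):
    from probemap import classify_probes

    return classify_probes(full_fixture.probes, full_fixture.annotation,
                           genome=full_fixture.genome,
                           ncrna_targets=full_fixture.ncrna)
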