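"""Genome annotation model and transcript/genome coordinate arithmetic.

The object model mirrors the Ensembl locus hierarchy: a :class:`GeneLocus`
spans one or more :class:`Transcript` isoforms, each an ordered chain of
:class:`Exon` blocks. All coordinates are held internally as 0-based
half-open intervals; GTF/GFF3 input (1-based inclusive) is converted at the
file boundary.

Two sequence views are derived from a locus:

* the *spliced* (mature) transcript — exon sequences concatenated in rank
  order, reverse-complemented as a whole on the minus strand; and
* the *pre-mRNA* — the contiguous genomic span of the locus, introns
  included, strand-oriented.

``project_to_genome`` maps an interval on a spliced transcript back onto
the genome as one or more :class:`GenomicBlock` pieces; an interval that
crosses an exon boundary yields multiple blocks (a junction placement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

PROTEIN_CODING = "protein_coding"
NONCODING = "noncoding"

#: annotation biotype strings folded into the coding class
_CODING_BIOTYPES = {"protein_coding", "mrna", "coding"}
#: biotype strings recognised as explicitly noncoding
_NONCODING_BIOTYPES = {
    "noncoding", "non_coding", "ncrna", "lincrna", "lncrna", "mirna",
    "snorna", "snrna", "rrna", "trna", "misc_rna", "antisense",
    "pseudogene", "processed_transcript",
}


class AnnotationError(Exception):
    """Malformed or inconsistent annotation input."""


class CoordinateError(Exception):
    """An interval falls outside its coordinate frame."""


@dataclass(frozen=True)
class Exon:
    """A genomic exon block. ``rank`` is the 1-based order within the
    transcript, 1 being the 5'-most exon in transcript orientation."""

    exon_id: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"exon {self.exon_id}: start {self.start} >= end {self.end}")
        if self.rank < 1:
            raise AnnotationError(f"exon {self.exon_id}: rank must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicBlock:
    """A contiguous genomic interval carrying strand context."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CoordinateError(f"block start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """An isoform: ordered exon chain sharing one gene and strand.

    ``exons`` is kept in rank order (transcript 5'→3'); for minus-strand
    transcripts that is descending genomic coordinate.
    """

    transcript_id: str
    gene_id: str
    exons: List[Exon]
    biotype: str = PROTEIN_CODING
    strand: str = "+"
    chrom: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(
                f"transcript {self.transcript_id} has zero exons")
        ranks = [e.rank for e in self.exons]
        if ranks != list(range(1, len(self.exons) + 1)):
            raise AnnotationError(
                f"transcript {self.transcript_id}: exon ranks {ranks} are not "
                f"consecutive from 1")
        ordered = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons {a.exon_id} and "
                    f"{b.exon_id} overlap on the genome")
        if not self.chrom:
            self.chrom = self.exons[0].chrom

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    def exons_genomic_order(self) -> List[Exon]:
        return sorted(self.exons, key=lambda e: e.start)


@dataclass
class GeneLocus:
    """A gene locus: the exon hull of its member transcripts."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    biotype: str
    transcripts: List[Transcript] = field(default_factory=list)
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.transcripts:
            self.start = min(e.start for t in self.transcripts for e in t.exons)
            self.end = max(e.end for t in self.transcripts for e in t.exons)
            for t in self.transcripts:
                if t.chrom != self.chrom:
                    raise AnnotationError(
                        f"gene {self.gene_id}: transcript {t.transcript_id} on "
                        f"{t.chrom}, locus on {self.chrom}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def exon_union(self) -> List[Tuple[int, int]]:
        """Merged genomic intervals covered by any exon of any transcript."""
        ivs = sorted((e.start, e.end)
                     for t in self.transcripts for e in t.exons)
        merged: List[Tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def intron_intervals(self) -> List[Tuple[int, int]]:
        """Locus span minus the exon union: the purely intronic genome."""
        introns: List[Tuple[int, int]] = []
        prev = self.start
        for s, e in self.exon_union():
            if s > prev:
                introns.append((prev, s))
            prev = max(prev, e)
        if prev < self.end:
            introns.append((prev, self.end))
        return introns


class GenomeAnnotation:
    """Fully-linked gene → transcript → exon hierarchy with id lookups."""

    def __init__(self, genes: Iterable[GeneLocus]):
        self.genes: Dict[str, GeneLocus] = {}
        self.transcripts: Dict[str, Transcript] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            for t in g.transcripts:
                if t.transcript_id in self.transcripts:
                    raise AnnotationError(
                        f"duplicate transcript id {t.transcript_id}")
                self.transcripts[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def exon_ids(self) -> set:
        return {e.exon_id for t in self.transcripts.values() for e in t.exons}

    def gene(self, gene_id: str) -> GeneLocus:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene id {gene_id}") from None

    def transcript(self, transcript_id: str) -> Transcript:
        try:
            return self.transcripts[transcript_id]
        except KeyError:
            raise AnnotationError(
                f"unknown transcript id {transcript_id}") from None

    def gene_of_transcript(self, transcript_id: str) -> GeneLocus:
        return self.gene(self.transcript(transcript_id).gene_id)


# ---------------------------------------------------------------------------
# Sequence stores


class DictGenome:
    """In-memory genome: chromosome name → sequence string."""

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}

    def chrom_length(self, chrom: str) -> int:
        try:
            return len(self._chroms[chrom])
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.chrom_length(chrom)
        if start < 0 or end > n or start >= end:
            raise CoordinateError(
                f"interval [{start},{end}) outside {chrom} (length {n})")
        return self._chroms[chrom][start:end]

    def chrom_names(self) -> List[str]:
        return list(self._chroms)


class FastaGenome:
    """FASTA-backed genome using a pyfaidx index built on first use."""

    def __init__(self, path: str):
        from pyfaidx import Fasta

        self._fasta = Fasta(path, sequence_always_upper=True)

    def chrom_length(self, chrom: str) -> int:
        if chrom not in self._fasta:
            raise CoordinateError(f"unknown chromosome {chrom}")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        n = self.chrom_length(chrom)
        if start < 0 or end > n or start >= end:
            raise CoordinateError(
                f"interval [{start},{end}) outside {chrom} (length {n})")
        return str(self._fasta[chrom][start:end])

    def chrom_names(self) -> List[str]:
        return list(self._fasta.keys())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Annotation loading


def _norm_biotype(raw: Optional[str]) -> str:
    if raw is None:
        return ""
    low = raw.lower()
    if low in _CODING_BIOTYPES:
        return PROTEIN_CODING
    if low in _NONCODING_BIOTYPES:
        return NONCODING
    return ""


def load_annotation(path: str) -> GenomeAnnotation:
    """Parse a GTF or GFF3 file into a :class:`GenomeAnnotation`.

    Exon features must carry ``gene_id``/``transcript_id`` attributes (GTF)
    or resolvable ``Parent`` chains (GFF3). Biotypes are read from
    ``gene_biotype``/``biotype``/``transcript_biotype``; unknown biotypes
    map to noncoding with a warning. File coordinates (1-based inclusive)
    become internal 0-based half-open intervals.
    """
    import gffutils

    _prevalidate_lines(path)
    db = gffutils.create_db(
        path, dbfn=":memory:", keep_order=True, merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )

    # transcript_id -> accumulated exon records, and per-id metadata
    tx_exons: Dict[str, List[dict]] = {}
    tx_meta: Dict[str, dict] = {}
    gene_meta: Dict[str, dict] = {}

    def attr(feat, *names) -> Optional[str]:
        for n in names:
            if n in feat.attributes:
                v = feat.attributes[n]
                return v[0] if isinstance(v, list) else v
        return None

    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype in ("gene", "ncrna_gene", "pseudogene"):
            gid = attr(feat, "gene_id", "ID") or feat.id
            gene_meta.setdefault(gid, {})
            gene_meta[gid].update(
                name=attr(feat, "gene_name", "Name") or gid,
                biotype_raw=attr(feat, "gene_biotype", "biotype"),
                strand=feat.strand,
            )
        elif ftype in ("transcript", "mrna", "ncrna", "lnc_rna"):
            tid = attr(feat, "transcript_id", "ID") or feat.id
            meta = tx_meta.setdefault(tid, {})
            meta.setdefault("gene_id", attr(feat, "gene_id", "Parent"))
            bt = attr(feat, "transcript_biotype", "gene_biotype", "biotype")
            if bt:
                meta["biotype_raw"] = bt
        elif ftype == "exon":
            tid = attr(feat, "transcript_id", "Parent")
            if tid is None:
                raise AnnotationError(
                    f"{path}: exon feature without transcript_id/Parent "
                    f"near line for {feat.seqid}:{feat.start}-{feat.end}")
            rec = dict(
                chrom=feat.seqid,
                start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand,
                exon_id=attr(feat, "exon_id", "ID"),
                rank=attr(feat, "exon_number", "rank"),
                gene_id=attr(feat, "gene_id"),
                biotype_raw=attr(feat, "gene_biotype", "biotype",
                                 "transcript_biotype"),
            )
            tx_exons.setdefault(tid, []).append(rec)
            meta = tx_meta.setdefault(tid, {})
            if rec["gene_id"]:
                meta.setdefault("gene_id", rec["gene_id"])
            if rec["biotype_raw"]:
                meta.setdefault("biotype_raw", rec["biotype_raw"])

    for tid, meta in tx_meta.items():
        if tid not in tx_exons:
            raise AnnotationError(f"transcript {tid} has zero exons")

    # assemble transcripts
    genes: Dict[str, List[Transcript]] = {}
    for tid, recs in sorted(tx_exons.items()):
        meta = tx_meta.get(tid, {})
        gid = meta.get("gene_id")
        if gid is None:
            raise AnnotationError(f"transcript {tid}: no gene id resolvable")
        strand = recs[0]["strand"]
        # rank: explicit exon_number when present, else genomic order
        # oriented by strand
        if all(r["rank"] is not None for r in recs):
            recs = sorted(recs, key=lambda r: int(r["rank"]))
            ranks = list(range(1, len(recs) + 1))
        else:
            recs = sorted(recs, key=lambda r: r["start"],
                          reverse=(strand == "-"))
            ranks = list(range(1, len(recs) + 1))
        exons = []
        for r, rank in zip(recs, ranks):
            eid = r["exon_id"] or f"{tid}.E{rank}"
            exons.append(Exon(exon_id=eid, chrom=r["chrom"],
                              start=r["start"], end=r["end"], rank=rank))
        biotype_raw = meta.get("biotype_raw")
        if biotype_raw is None and gid in gene_meta:
            biotype_raw = gene_meta[gid].get("biotype_raw")
        biotype = _norm_biotype(biotype_raw)
        if not biotype:
            logger.warning(
                "transcript %s: unknown biotype %r, treating as noncoding",
                tid, biotype_raw)
            biotype = NONCODING
        genes.setdefault(gid, []).append(Transcript(
            transcript_id=tid, gene_id=gid, exons=exons,
            biotype=biotype, strand=strand))

    loci = []
    for gid, txs in sorted(genes.items()):
        strand = gene_meta.get(gid, {}).get("strand") or txs[0].strand
        name = gene_meta.get(gid, {}).get("name", gid)
        gene_bt = _norm_biotype(gene_meta.get(gid, {}).get("biotype_raw"))
        if not gene_bt:
            # a locus is coding if any isoform is
            gene_bt = (PROTEIN_CODING
                       if any(t.biotype == PROTEIN_CODING for t in txs)
                       else NONCODING)
        loci.append(GeneLocus(gene_id=gid, name=name, chrom=txs[0].chrom,
                              strand=strand, biotype=gene_bt,
                              transcripts=txs))
    return GenomeAnnotation(loci)


def _prevalidate_lines(path: str) -> None:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise AnnotationError(
                    f"{path}: malformed line {i}: expected >=8 tab-separated "
                    f"fields, got {len(fields)}")
            try:
                s, e = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}: malformed line {i}: non-numeric coordinates")
            if s < 1 or e < s:
                raise AnnotationError(
                    f"{path}: malformed line {i}: bad interval {s}..{e}")


# ---------------------------------------------------------------------------
# Sequence extraction


def extract_transcript_sequence(annotation: GenomeAnnotation, genome,
                                transcript_id: str) -> str:
    """Spliced (mature) transcript sequence, 5'→3' in transcript orientation.

    Exon genomic subsequences are concatenated in genomic order and the
    whole is reverse-complemented for minus-strand transcripts, which is
    equivalent to concatenating strand-oriented exon sequences in rank
    order.
    """
    t = annotation.transcript(transcript_id)
    strand = _transcript_strand(annotation, t)
    parts = [genome.fetch(e.chrom, e.start, e.end)
             for e in t.exons_genomic_order()]
    seq = "".join(parts).upper()
    return reverse_complement(seq) if strand == "-" else seq


def extract_premrna_sequence(annotation: GenomeAnnotation, genome,
                             gene_id: str) -> str:
    """Contiguous locus sequence (introns included), strand-oriented."""
    g = annotation.gene(gene_id)
    seq = genome.fetch(g.chrom, g.start, g.end).upper()
    return reverse_complement(seq) if g.strand == "-" else seq


def _transcript_strand(annotation: GenomeAnnotation, t: Transcript) -> str:
    if t.gene_id in annotation.genes:
        return annotation.genes[t.gene_id].strand
    return t.strand


def project_to_genome(transcript: Transcript, t_start: int, length: int,
                      strand: Optional[str] = None) -> List[GenomicBlock]:
    """Project a spliced-transcript interval onto the genome.

    Returns blocks in genomic order whose lengths sum to ``length``; more
    than one block means the interval crosses an exon–exon junction.
    ``strand`` defaults to the transcript's own strand.
    """
    if strand is None:
        strand = transcript.strand
    sl = transcript.spliced_length
    if t_start < 0 or length < 1 or t_start + length > sl:
        raise CoordinateError(
            f"interval [{t_start},{t_start + length}) outside spliced "
            f"transcript {transcript.transcript_id} (length {sl})")
    blocks: List[GenomicBlock] = []
    cum = 0
    t_end = t_start + length
    for exon in transcript.exons:  # rank order = transcript 5'->3'
        lo = max(t_start, cum)
        hi = min(t_end, cum + exon.length)
        if lo < hi:
            a, b = lo - cum, hi - cum  # offsets within this exon, 5'->3'
            if strand == "-":
                blocks.append(GenomicBlock(exon.chrom, exon.end - b,
                                           exon.end - a, strand))
            else:
                blocks.append(GenomicBlock(exon.chrom, exon.start + a,
                                           exon.start + b, strand))
        cum += exon.length
    blocks.sort(key=lambda blk: blk.start)
    assert sum(b.length for b in blocks) == length
    return blocks
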