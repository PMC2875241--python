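"""Cascading probe classification: mRNA → ncRNA → intron → unassigned.

Each probe is carried through a fixed sequence of mapping stages and is
resolved at the first stage where it has at least one perfect-match hit:

1. spliced protein-coding transcripts of the annotation  → ``mRNA``
2. spliced noncoding-biotype transcripts of the annotation → ``ncRNA``
3. an external ncRNA sequence collection (optional)        → ``ncRNA``
4. pre-mRNA locus sequences, counting only hits that fall wholly outside
   every annotated exon of the locus                       → ``intronic_putative_ncRNA``
5. otherwise                                               → ``NA``

Intron-only probes are flagged as putative ncRNAs: a perfect match inside
an intron may report signal from an unannotated exon of an alternative
transcript. Ambiguity is recorded at three levels (gene, transcript,
exon) together with a junction flag for probes whose transcript match
projects onto more than one genomic block, and summarised as a display
color: green (gene-unique and transcript-specific), yellow (gene-unique,
multiple transcripts), red (multi-locus, i.e. ambiguous), black (not
assigned to an mRNA).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .annotation import (
    PROTEIN_CODING,
    GenomeAnnotation,
    extract_premrna_sequence,
    extract_transcript_sequence,
    project_to_genome,
)
from .mapping import (
    KIND_MRNA,
    KIND_NCRNA_DB,
    KIND_PRE_MRNA,
    Probe,
    ProbeHit,
    build_index,
    map_probes,
)

logger = logging.getLogger(__name__)

CAT_MRNA = "mRNA"
CAT_NCRNA = "ncRNA"
CAT_INTRONIC = "intronic_putative_ncRNA"
CAT_NA = "NA"
CATEGORIES = (CAT_MRNA, CAT_NCRNA, CAT_INTRONIC, CAT_NA)

COLOR_GREEN = "green"
COLOR_YELLOW = "yellow"
COLOR_RED = "red"
COLOR_BLACK = "black"


class ClassificationError(Exception):
    pass


@dataclass
class ProbeAssignment:
    """Resolved mapping category and ambiguity profile of one probe."""

    probe_id: str
    category: str = CAT_NA
    genes: Set[str] = field(default_factory=set)
    transcripts: Set[str] = field(default_factory=set)
    exons: Set[str] = field(default_factory=set)
    ncrna_targets: Set[str] = field(default_factory=set)
    junction: bool = False
    gene_unique: bool = False
    transcript_specific: bool = False
    exon_specific: bool = False
    multi_hit: bool = False
    color: str = COLOR_BLACK


def assign_color(a: ProbeAssignment) -> str:
    """Display color code for ambiguity at a glance.

    green: mRNA, single locus, single transcript; yellow: mRNA, single
    locus, several transcripts; red: mRNA matching more than one locus
    (ambiguous); black: not assigned to an mRNA (ncRNA, intronic, NA).
    """
    if a.category != CAT_MRNA:
        return COLOR_BLACK
    if not a.gene_unique:
        return COLOR_RED
    return COLOR_GREEN if a.transcript_specific else COLOR_YELLOW


def _finalize_flags(a: ProbeAssignment) -> None:
    a.gene_unique = len(a.genes) == 1
    a.transcript_specific = (a.category == CAT_MRNA and a.gene_unique
                             and len(a.transcripts) == 1)
    a.exon_specific = (not a.junction) and len(a.exons) == 1
    a.color = assign_color(a)


def classify_probes(probes: Sequence[Probe], annotation: GenomeAnnotation,
                    genome=None,
                    ncrna_targets: Optional[Mapping[str, str]] = None,
                    search_revcomp: bool = True,
                    intron_pass: bool = True) -> List[ProbeAssignment]:
    """Run the full classification cascade over ``probes``.

    ``ncrna_targets`` is an optional id → sequence collection of external
    (database) ncRNAs used at stage 3. ``genome`` is required when the
    intron pass is enabled. Hits at the deciding stage populate the id
    sets; exon ids are recorded only for non-junction (single-block) mRNA
    hits, and junction-spanning probes carry no exon ids at all.
    """
    if intron_pass and genome is None:
        raise ClassificationError(
            "intron pass requested but no genome sequence provided")

    lengths = sorted({len(p) for p in probes})
    if not lengths:
        raise ClassificationError("no probes to classify")

    assignments = {p.probe_id: ProbeAssignment(probe_id=p.probe_id)
                   for p in probes}
    if len(assignments) != len(probes):
        raise ClassificationError("duplicate probe ids in input")
    remaining: List[Probe] = list(probes)

    # --- stage 1: spliced protein-coding transcripts -> mRNA
    coding = {t.transcript_id: extract_transcript_sequence(
        annotation, genome, t.transcript_id)
        for t in annotation.transcripts.values()
        if t.biotype == PROTEIN_CODING} if genome is not None else {}
    if coding:
        remaining = _stage_mrna(remaining, coding, annotation, assignments,
                                lengths, search_revcomp)

    # --- stage 2: spliced noncoding transcripts of the annotation -> ncRNA
    noncoding = {t.transcript_id: extract_transcript_sequence(
        annotation, genome, t.transcript_id)
        for t in annotation.transcripts.values()
        if t.biotype != PROTEIN_CODING} if genome is not None else {}
    if noncoding and remaining:
        remaining = _stage_ncrna(remaining, noncoding, assignments, lengths,
                                 search_revcomp, annotation=annotation)

    # --- stage 3: external ncRNA collection -> ncRNA
    if ncrna_targets and remaining:
        remaining = _stage_ncrna(remaining, dict(ncrna_targets), assignments,
                                 lengths, search_revcomp, annotation=None)

    # --- stage 4: pre-mRNA, wholly-intronic hits -> putative ncRNA
    if intron_pass and remaining:
        remaining = _stage_intron(remaining, annotation, genome, assignments,
                                  lengths, search_revcomp)

    # --- stage 5: NA (default)
    out = [assignments[p.probe_id] for p in probes]
    for a in out:
        if a.category == CAT_NA:
            a.color = COLOR_BLACK
    return out


def _group_hits(hits: Sequence[ProbeHit]) -> Dict[str, List[ProbeHit]]:
    by_probe: Dict[str, List[ProbeHit]] = {}
    for h in hits:
        by_probe.setdefault(h.probe_id, []).append(h)
    return by_probe


def _stage_mrna(probes, targets, annotation, assignments, lengths,
                search_revcomp):
    index = build_index(targets, lengths, kind=KIND_MRNA)
    by_probe = _group_hits(map_probes(probes, index, search_revcomp))
    probe_len = {p.probe_id: len(p) for p in probes}
    unresolved = []
    for p in probes:
        hits = by_probe.get(p.probe_id)
        if not hits:
            unresolved.append(p)
            continue
        a = assignments[p.probe_id]
        a.category = CAT_MRNA
        seen_targets = set()
        for h in hits:
            t = annotation.transcript(h.target_id)
            a.transcripts.add(t.transcript_id)
            a.genes.add(t.gene_id)
            if (h.target_id, h.offset) in seen_targets:
                continue
            seen_targets.add((h.target_id, h.offset))
            strand = annotation.gene(t.gene_id).strand
            blocks = project_to_genome(t, h.offset, probe_len[p.probe_id],
                                       strand=strand)
            if len(blocks) > 1:
                a.junction = True
            else:
                eid = _containing_exon(t, blocks[0].start, blocks[0].end)
                if eid is not None:
                    a.exons.add(eid)
        # multiple occurrences within one transcript collapse to one
        # membership; flag them
        a.multi_hit = len(hits) > len({(h.target_id) for h in hits})
        if a.junction:
            a.exons.clear()  # junction probes are transcript evidence only
        _finalize_flags(a)
    return unresolved


def _containing_exon(transcript, start: int, end: int) -> Optional[str]:
    for e in transcript.exons:
        if e.start <= start and end <= e.end:
            return e.exon_id
    return None


def _stage_ncrna(probes, targets, assignments, lengths, search_revcomp,
                 annotation: Optional[GenomeAnnotation]):
    kind = KIND_MRNA if annotation is not None else KIND_NCRNA_DB
    index = build_index(targets, lengths, kind=kind)
    by_probe = _group_hits(map_probes(probes, index, search_revcomp))
    unresolved = []
    for p in probes:
        hits = by_probe.get(p.probe_id)
        if not hits:
            unresolved.append(p)
            continue
        a = assignments[p.probe_id]
        a.category = CAT_NCRNA
        for h in hits:
            a.ncrna_targets.add(h.target_id)
            if annotation is not None:
                # annotation-resident noncoding transcript: its locus is
                # recorded, keeping gene-level ambiguity computable
                a.genes.add(annotation.transcript(h.target_id).gene_id)
        a.multi_hit = len(hits) > len({h.target_id for h in hits})
        _finalize_flags(a)
    return unresolved


def _stage_intron(probes, annotation, genome, assignments, lengths,
                  search_revcomp):
    premrna = {g.gene_id: extract_premrna_sequence(annotation, genome,
                                                   g.gene_id)
               for g in annotation.genes.values()}
    if not premrna:
        return list(probes)
    index = build_index(premrna, lengths, kind=KIND_PRE_MRNA)
    by_probe = _group_hits(map_probes(probes, index, search_revcomp))
    probe_len = {p.probe_id: len(p) for p in probes}
    unresolved = []
    for p in probes:
        hits = by_probe.get(p.probe_id)
        if not hits:
            unresolved.append(p)
            continue
        a = assignments[p.probe_id]
        intronic_genes = set()
        for h in hits:
            g = annotation.gene(h.target_id)
            gs, ge = _premrna_to_genomic(g, h.offset, probe_len[p.probe_id])
            if _wholly_intronic(g, gs, ge):
                intronic_genes.add(g.gene_id)
        if intronic_genes:
            a.category = CAT_INTRONIC
            a.genes = intronic_genes
            _finalize_flags(a)
        else:
            # pre-mRNA hit overlapping an exon boundary without a spliced
            # match: not intronic, remains unassigned
            unresolved.append(p)
    return unresolved


def _premrna_to_genomic(gene, offset: int, length: int) -> Tuple[int, int]:
    """Genomic interval of a hit on the strand-oriented pre-mRNA."""
    if gene.strand == "-":
        return gene.end - offset - length, gene.end - offset
    return gene.start + offset, gene.start + offset + length


def _wholly_intronic(gene, start: int, end: int) -> bool:
    """True iff [start, end) avoids every exon of every transcript."""
    for es, ee in gene.exon_union():
        if start < ee and es < end:
            return False
    return True


# ---------------------------------------------------------------------------
# Summaries and IO


def partition_counts(assignments: Sequence[ProbeAssignment]) -> Dict[str, Dict[str, float]]:
    """Probe counts and percentages in the three reporting classes:
    mRNA, ncRNA (external + annotation + intron-only pooled) and NA."""
    from .stats import pct

    if not assignments:
        raise ClassificationError("no assignments to summarise")
    n = len(assignments)
    counts = {
        CAT_MRNA: sum(a.category == CAT_MRNA for a in assignments),
        CAT_NCRNA: sum(a.category in (CAT_NCRNA, CAT_INTRONIC)
                       for a in assignments),
        CAT_NA: sum(a.category == CAT_NA for a in assignments),
    }
    return {k: {"count": c, "pct": pct(c, n)} for k, c in counts.items()}


_TSV_COLUMNS = ["probe_id", "category", "genes", "transcripts", "exons",
                "ncrna_targets", "junction", "gene_unique",
                "transcript_specific", "exon_specific", "multi_hit", "color"]


def write_assignments_tsv(assignments: Sequence[ProbeAssignment],
                          path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
        for a in sorted(assignments, key=lambda x: x.probe_id):
            fh.write("\t".join([
                a.probe_id, a.category,
                ";".join(sorted(a.genes)),
                ";".join(sorted(a.transcripts)),
                ";".join(sorted(a.exons)),
                ";".join(sorted(a.ncrna_targets)),
                str(int(a.junction)), str(int(a.gene_unique)),
                str(int(a.transcript_specific)), str(int(a.exon_specific)),
                str(int(a.multi_hit)), a.color,
            ]) + "\n")


def read_assignments_tsv(path: str) -> List[ProbeAssignment]:
    out: List[ProbeAssignment] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if len(row) != len(_TSV_COLUMNS):
                raise ClassificationError(
                    f"{path}: expected {len(_TSV_COLUMNS)} columns, "
                    f"got {len(row)}")
            split = lambda s: set(s.split(";")) if s else set()
            out.append(ProbeAssignment(
                probe_id=row[0], category=row[1],
                genes=split(row[2]), transcripts=split(row[3]),
                exons=split(row[4]), ncrna_targets=split(row[5]),
                junction=bool(int(row[6])), gene_unique=bool(int(row[7])),
                transcript_specific=bool(int(row[8])),
                exon_specific=bool(int(row[9])),
                multi_hit=bool(int(row[10])), color=row[11]))
    return out
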