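"""Remapped probe-set definitions and downloadable mapping files.

From classified probe assignments this module rebuilds summarization
units at four levels — gene, transcript, exon and ncRNA — excluding
multi-locus (ambiguous) probes from the first three, and writes the flat
mapping files a downstream expression analysis consumes:

* ``probes2genes.txt``        probe → its unique gene locus
* ``probes2transcripts.txt``  probe → each transcript of its unique gene
* ``probesets2genes.txt``     vendor probeset → gene (unanimity of its
  member probes' unique genes; split probesets are dropped and logged)
* ``ambigprobes2genes.txt``   multi-locus probes with all their loci
* ``<level>_sets.txt``        one redefined probe set per entity

The set-definition files are a documented flat TSV equivalent of a chip
definition file (CDF): entity id, probe count, comma-joined probe ids.
All outputs are deterministically ordered, so re-runs are byte-identical.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .classify import CAT_INTRONIC, CAT_MRNA, CAT_NCRNA, ProbeAssignment
from .mapping import Probe

logger = logging.getLogger(__name__)

LEVEL_GENE = "gene"
LEVEL_TRANSCRIPT = "transcript"
LEVEL_EXON = "exon"
LEVEL_NCRNA = "ncRNA"
LEVELS = (LEVEL_GENE, LEVEL_TRANSCRIPT, LEVEL_EXON, LEVEL_NCRNA)


class SetBuilderError(Exception):
    pass


@dataclass(frozen=True)
class ProbesetDefinition:
    """A redefined probe grouping for one entity at one level."""

    entity_id: str
    level: str
    probe_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise SetBuilderError(f"{self.entity_id}: empty probe set")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise SetBuilderError(f"{self.entity_id}: duplicate probe ids")

    def __len__(self) -> int:
        return len(self.probe_ids)


def build_sets(assignments: Sequence[ProbeAssignment], level: str,
               min_probes: int = 1) -> List[ProbesetDefinition]:
    """Group qualifying probes into per-entity sets at one level.

    gene: gene-unique mRNA probes, keyed by their sole locus.
    transcript: mRNA probes of a single locus, one membership per matched
    transcript (a probe may appear in several transcript sets of its gene).
    exon: single-locus, non-junction mRNA probes with exon evidence.
    ncRNA: probes classified as ncRNA (keyed by matched ncRNA ids) or as
    intron-only putative ncRNAs (keyed by their host locus).
    Entities with fewer than ``min_probes`` qualifying probes are omitted.
    """
    if level not in LEVELS:
        raise SetBuilderError(
            f"unknown level {level!r}; expected one of {LEVELS}")
    members: Dict[str, List[str]] = {}

    def add(entity: str, pid: str) -> None:
        members.setdefault(entity, []).append(pid)

    for a in sorted(assignments, key=lambda x: x.probe_id):
        if level == LEVEL_GENE:
            if a.category == CAT_MRNA and a.gene_unique:
                add(next(iter(a.genes)), a.probe_id)
        elif level == LEVEL_TRANSCRIPT:
            if a.category == CAT_MRNA and len(a.genes) == 1:
                for tid in sorted(a.transcripts):
                    add(tid, a.probe_id)
        elif level == LEVEL_EXON:
            if (a.category == CAT_MRNA and len(a.genes) == 1
                    and not a.junction):
                for eid in sorted(a.exons):
                    add(eid, a.probe_id)
        elif level == LEVEL_NCRNA:
            if a.category == CAT_NCRNA:
                for nid in sorted(a.ncrna_targets):
                    add(nid, a.probe_id)
            elif a.category == CAT_INTRONIC:
                for gid in sorted(a.genes):
                    add(gid, a.probe_id)

    out = [ProbesetDefinition(entity_id=e, level=level,
                              probe_ids=tuple(pids))
           for e, pids in sorted(members.items())
           if len(pids) >= min_probes]
    return out


def write_mapping_files(assignments: Sequence[ProbeAssignment],
                        sets: Sequence[ProbesetDefinition], out_dir: str,
                        probes: Optional[Sequence[Probe]] = None,
                        ) -> Dict[str, str]:
    """Write the mapping text files and flat set definitions.

    ``probes`` supplies vendor probeset ids for ``probesets2genes.txt``;
    without it that file is skipped. Returns a manifest of file paths
    keyed by short name.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: Dict[str, str] = {}
    ordered = sorted(assignments, key=lambda a: a.probe_id)

    unambig = [a for a in ordered if a.category == CAT_MRNA and a.gene_unique]
    ambig = [a for a in ordered
             if a.category == CAT_MRNA and len(a.genes) > 1]

    path = os.path.join(out_dir, "probes2genes.txt")
    with open(path, "w") as fh:
        fh.write("#probe_id\tgene_id\n")
        for a in unambig:
            fh.write(f"{a.probe_id}\t{next(iter(a.genes))}\n")
    manifest["probes2genes"] = path

    path = os.path.join(out_dir, "probes2transcripts.txt")
    with open(path, "w") as fh:
        fh.write("#probe_id\ttranscript_id\n")
        for a in unambig:
            for tid in sorted(a.transcripts):
                fh.write(f"{a.probe_id}\t{tid}\n")
    manifest["probes2transcripts"] = path

    path = os.path.join(out_dir, "ambigprobes2genes.txt")
    with open(path, "w") as fh:
        fh.write("#probe_id\tgene_ids\n")
        for a in ambig:
            fh.write(f"{a.probe_id}\t{';'.join(sorted(a.genes))}\n")
    manifest["ambigprobes2genes"] = path

    if probes is not None:
        path = os.path.join(out_dir, "probesets2genes.txt")
        _write_probesets2genes(ordered, probes, path)
        manifest["probesets2genes"] = path

    by_level: Dict[str, List[ProbesetDefinition]] = {}
    for s in sets:
        by_level.setdefault(s.level, []).append(s)
    for level, defs in sorted(by_level.items()):
        path = os.path.join(out_dir, f"{level}_sets.txt")
        write_sets_tsv(sorted(defs, key=lambda d: d.entity_id), path)
        manifest[f"{level}_sets"] = path
    return manifest


def _write_probesets2genes(assignments: Sequence[ProbeAssignment],
                           probes: Sequence[Probe], path: str) -> None:
    """Vendor probeset → gene by unanimity of member probes' unique genes.

    A probeset counts as mapped to a gene only when every member probe
    that maps to a gene at all maps uniquely to that same gene; split or
    purely-ambiguous probesets are dropped (and logged), keeping the file
    unambiguous in the strictest sense.
    """
    by_probe = {a.probe_id: a for a in assignments}
    grouped: Dict[str, List[Probe]] = {}
    for p in probes:
        if p.vendor_probeset:
            grouped.setdefault(p.vendor_probeset, []).append(p)
    with open(path, "w") as fh:
        fh.write("#probeset_id\tgene_id\tn_probes\n")
        for ps, members in sorted(grouped.items()):
            genes = set()
            ok = True
            for p in members:
                a = by_probe.get(p.probe_id)
                if a is None or a.category != CAT_MRNA:
                    continue
                if not a.gene_unique:
                    ok = False
                    break
                genes.add(next(iter(a.genes)))
            if not ok or len(genes) != 1:
                logger.info("probeset %s dropped: not unanimously mapped "
                            "to one gene", ps)
                continue
            fh.write(f"{ps}\t{next(iter(genes))}\t{len(members)}\n")


def write_sets_tsv(sets: Sequence[ProbesetDefinition], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#entity_id\tn_probes\tprobe_ids\n")
        for s in sets:
            fh.write(f"{s.entity_id}\t{len(s)}\t{','.join(s.probe_ids)}\n")


def read_sets_tsv(path: str, level: str = LEVEL_GENE
                  ) -> List[ProbesetDefinition]:
    out: List[ProbesetDefinition] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            entity, _n, pids = line.split("\t")
            out.append(ProbesetDefinition(entity_id=entity, level=level,
                                          probe_ids=tuple(pids.split(","))))
    return out
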