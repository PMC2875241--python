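"""Exact full-length matching of oligo probes against target sequences.

Perfect-match-only semantics make alignment heuristics unnecessary: for
each distinct probe length L every L-mer of every target is hashed to its
occurrence list, and a probe (or its reverse complement) is looked up in a
single dictionary probe. Probes containing ambiguity codes (N) never
match, and targets contribute no k-mers across an N.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .annotation import reverse_complement

logger = logging.getLogger(__name__)

VALID_ALPHABET = set("ACGTN")

KIND_MRNA = "mRNA"
KIND_NCRNA_DB = "ncRNA_db"
KIND_PRE_MRNA = "pre_mRNA"


class ProbeError(Exception):
    """Invalid probe record."""


class IndexError_(Exception):
    """Index configuration problem (empty targets, unindexed length)."""


@dataclass(frozen=True)
class Probe:
    """A microarray oligo: id, sequence (typically 25 nt), source array
    label and the vendor's probeset id (may be empty)."""

    probe_id: str
    sequence: str
    array: str = ""
    vendor_probeset: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ProbeError(f"probe {self.probe_id}: empty sequence")
        bad = set(seq) - VALID_ALPHABET
        if bad:
            raise ProbeError(
                f"probe {self.probe_id}: invalid characters {sorted(bad)}")
        if len(seq) < 8:
            raise ProbeError(
                f"probe {self.probe_id}: sequence shorter than 8 nt")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProbeHit:
    """One full-length exact occurrence of a probe on a target."""

    probe_id: str
    target_id: str
    target_kind: str
    offset: int
    orientation: str  # "forward" | "revcomp"


class ExactMatchIndex:
    """Hash index of all L-mers of a target set, for fixed lengths L."""

    def __init__(self, targets: Mapping[str, str],
                 probe_lengths: Iterable[int], kind: str = KIND_MRNA):
        if not targets:
            raise IndexError_("cannot build an index over an empty target set")
        self.kind = kind
        self.target_lengths = {tid: len(s) for tid, s in targets.items()}
        self.lengths: Set[int] = set(int(x) for x in probe_lengths)
        if not self.lengths or min(self.lengths) < 1:
            raise IndexError_(f"invalid probe lengths {sorted(self.lengths)}")
        self._maps: Dict[int, Dict[str, List[Tuple[str, int]]]] = {
            L: {} for L in self.lengths}
        for tid in sorted(targets):
            seq = targets[tid].upper()
            for L in self.lengths:
                table = self._maps[L]
                for off in range(0, len(seq) - L + 1):
                    kmer = seq[off:off + L]
                    if "N" in kmer:
                        continue  # ambiguity codes are never matchable
                    table.setdefault(kmer, []).append((tid, off))

    def lookup(self, seq: str) -> List[Tuple[str, int]]:
        """Occurrence list [(target_id, offset), ...] for a full sequence."""
        L = len(seq)
        if L not in self._maps:
            raise IndexError_(
                f"length {L} not indexed (have {sorted(self.lengths)})")
        return list(self._maps[L].get(seq.upper(), ()))

    def n_positions(self, L: int) -> int:
        return sum(len(v) for v in self._maps[L].values())


def build_index(targets: Mapping[str, str], probe_lengths: Iterable[int],
                kind: str = KIND_MRNA) -> ExactMatchIndex:
    """Build an :class:`ExactMatchIndex` over ``targets`` for the given
    probe lengths."""
    return ExactMatchIndex(targets, probe_lengths, kind=kind)


def map_probes(probes: Sequence[Probe], index: ExactMatchIndex,
               search_revcomp: bool = True) -> List[ProbeHit]:
    """All full-length perfect-match occurrences of each probe.

    With ``search_revcomp`` (default), reverse-complement occurrences are
    additionally reported with orientation ``revcomp`` — probe-sequence
    files differ in orientation convention between vendors, so matching
    both and recording the orientation is lossless. Output is sorted by
    (probe_id, target_id, offset, orientation) and therefore deterministic.
    """
    hits: List[ProbeHit] = []
    for p in probes:
        if "N" in p.sequence:
            continue  # probes with ambiguity codes never match
        for tid, off in index.lookup(p.sequence):
            hits.append(ProbeHit(p.probe_id, tid, index.kind, off, "forward"))
        if search_revcomp:
            rc = reverse_complement(p.sequence)
            for tid, off in index.lookup(rc):
                if rc == p.sequence:
                    continue  # palindrome: same occurrence already reported
                hits.append(ProbeHit(p.probe_id, tid, index.kind, off,
                                     "revcomp"))
    hits.sort(key=lambda h: (h.probe_id, h.target_id, h.offset, h.orientation))
    return hits


def naive_scan(probes: Sequence[Probe], targets: Mapping[str, str],
               kind: str = KIND_MRNA,
               search_revcomp: bool = True) -> List[ProbeHit]:
    """Brute-force O(n·m) reference scan; the oracle the index is tested
    against. Matching rules are identical (full-length, no N)."""
    hits: List[ProbeHit] = []
    for p in probes:
        if "N" in p.sequence:
            continue
        queries = [(p.sequence, "forward")]
        if search_revcomp:
            rc = reverse_complement(p.sequence)
            if rc != p.sequence:
                queries.append((rc, "revcomp"))
        for tid in sorted(targets):
            seq = targets[tid].upper()
            for q, orient in queries:
                start = seq.find(q)
                while start != -1:
                    if "N" not in q:
                        hits.append(ProbeHit(p.probe_id, tid, kind, start,
                                             orient))
                    start = seq.find(q, start + 1)
    hits.sort(key=lambda h: (h.probe_id, h.target_id, h.offset, h.orientation))
    return hits


# ---------------------------------------------------------------------------
# File IO


def read_probes_tsv(path: str, array: str = "") -> List[Probe]:
    """Read a tab-separated probe file: probe_id, probeset_id, sequence.

    A header row is auto-detected (a third column that is not a nucleotide
    sequence). Two-column files (probe_id, sequence) are accepted.
    """
    probes: List[Probe] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or row[0].startswith("#"):
                continue
            if len(row) == 2:
                pid, ps, seq = row[0], "", row[1]
            elif len(row) >= 3:
                pid, ps, seq = row[0], row[1], row[2]
            else:
                raise ProbeError(f"{path}: line {i + 1}: expected >=2 columns")
            if i == 0 and set(seq.upper()) - VALID_ALPHABET:
                continue  # header row
            probes.append(Probe(probe_id=pid, sequence=seq,
                                array=array, vendor_probeset=ps))
    if not probes:
        raise ProbeError(f"{path}: no probes read")
    return probes


def write_probes_tsv(probes: Sequence[Probe], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#probe_id\tprobeset_id\tsequence\n")
        for p in probes:
            fh.write(f"{p.probe_id}\t{p.vendor_probeset}\t{p.sequence}\n")


def write_hits_tsv(hits: Sequence[ProbeHit], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#probe_id\ttarget_id\ttarget_kind\toffset\torientation\n")
        for h in hits:
            fh.write(f"{h.probe_id}\t{h.target_id}\t{h.target_kind}\t"
                     f"{h.offset}\t{h.orientation}\n")
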