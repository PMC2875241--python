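"""Coverage and efficiency statistics of a probe mapping.

*Coverage* is the proportion of annotation entities (gene loci or
transcripts) that are hit by at least one probe of an array; an entity is
*unique mapped* when at least one of its probes maps to no other entity
at that level (strict mode requires every probe to be unambiguous).
*Efficiency* is the proportion of an array's probes that map to at least
one entity, split into probes hitting exactly one versus more than one
entity. Percentages are rounded half-up to two decimals with a decimal
point, regardless of locale.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence, Set

from .annotation import GenomeAnnotation
from .classify import CAT_MRNA, CAT_NCRNA, ProbeAssignment

LEVEL_GENE = "gene"
LEVEL_TRANSCRIPT = "transcript"


class StatsError(Exception):
    pass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.125 -> 0.13 at 2 digits), avoiding the
    round-half-even surprises of the builtin."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage ``100*count/total`` rounded half-up."""
    if total <= 0:
        raise StatsError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


@dataclass(frozen=True)
class CoverageRow:
    """One array × one level of the coverage table."""

    array: str
    level: str
    n_unique_mapped: int
    pct_unique_mapped: float
    n_all_mapped: int
    pct_all_mapped: float
    n_total_entities: int

    @classmethod
    def from_counts(cls, array: str, level: str, n_unique: int, n_all: int,
                    n_total: int) -> "CoverageRow":
        if not 0 <= n_unique <= n_all <= n_total:
            raise StatsError(
                f"inconsistent coverage counts: unique {n_unique} <= "
                f"all {n_all} <= total {n_total} violated")
        return cls(array, level, n_unique, pct(n_unique, n_total),
                   n_all, pct(n_all, n_total), n_total)


@dataclass(frozen=True)
class EfficiencyRow:
    """One array × one level of the efficiency table."""

    array: str
    level: str
    n_probes_one: int
    pct_one: float
    n_probes_multi: int
    pct_multi: float
    n_probes_mapped: int
    n_probes_total: int
    efficiency_pct: float

    @classmethod
    def from_counts(cls, array: str, level: str, n_one: int, n_multi: int,
                    n_total: int) -> "EfficiencyRow":
        n_mapped = n_one + n_multi
        if n_total < n_mapped:
            raise StatsError(
                f"total probes {n_total} < mapped probes {n_mapped}")
        if n_mapped == 0:
            return cls(array, level, 0, 0.0, 0, 0.0, 0, n_total, 0.0)
        return cls(array, level, n_one, pct(n_one, n_mapped),
                   n_multi, pct(n_multi, n_mapped), n_mapped,
                   n_total, pct(n_mapped, n_total))


def _entities_at_level(a: ProbeAssignment, level: str,
                       annotation: GenomeAnnotation) -> Set[str]:
    """Annotation entities a probe maps to at the given level.

    Spliced mapping only: mRNA hits and annotation-resident noncoding
    transcripts count; intron-only and external-database hits do not make
    a locus 'mapped'.
    """
    if level == LEVEL_GENE:
        if a.category == CAT_MRNA:
            return set(a.genes)
        if a.category == CAT_NCRNA and a.genes:
            return {g for g in a.genes if g in annotation.genes}
        return set()
    if level == LEVEL_TRANSCRIPT:
        if a.category == CAT_MRNA:
            return set(a.transcripts)
        if a.category == CAT_NCRNA:
            return {t for t in a.ncrna_targets if t in annotation.transcripts}
        return set()
    raise StatsError(f"unknown level {level!r}")


def coverage(assignments: Sequence[ProbeAssignment],
             annotation: GenomeAnnotation, level: str, array: str = "",
             strict_unique: bool = False) -> CoverageRow:
    """Coverage of the annotation by the array's probes at one level.

    ``strict_unique`` demands that *all* probes of an entity map solely to
    it; the default requires at least one such probe.
    """
    if len(annotation) == 0:
        raise StatsError("empty annotation")
    per_entity: Dict[str, List[Set[str]]] = {}
    for a in assignments:
        ents = _entities_at_level(a, level, annotation)
        for e in ents:
            per_entity.setdefault(e, []).append(ents)
    n_total = (len(annotation) if level == LEVEL_GENE
               else annotation.n_transcripts)
    n_all = len(per_entity)
    if strict_unique:
        n_unique = sum(all(len(s) == 1 for s in sets)
                       for sets in per_entity.values())
    else:
        n_unique = sum(any(len(s) == 1 for s in sets)
                       for sets in per_entity.values())
    return CoverageRow.from_counts(array, level, n_unique, n_all, n_total)


def efficiency(assignments: Sequence[ProbeAssignment], n_probes_total: int,
               level: str, annotation: GenomeAnnotation,
               array: str = "") -> EfficiencyRow:
    """Efficiency of the probe mapping at one level."""
    n_one = n_multi = 0
    for a in assignments:
        ents = _entities_at_level(a, level, annotation)
        if len(ents) == 1:
            n_one += 1
        elif len(ents) > 1:
            n_multi += 1
    if n_probes_total < n_one + n_multi:
        raise StatsError(
            f"n_probes_total {n_probes_total} < mapped {n_one + n_multi}")
    return EfficiencyRow.from_counts(array, level, n_one, n_multi,
                                     n_probes_total)


def gc_content(sequence) -> float:
    """GC content of a probe sequence in percent, 2-decimal rounding.

    Ambiguous bases count toward the length but never toward G+C.
    """
    seq = getattr(sequence, "sequence", sequence)
    if not seq:
        raise StatsError("empty sequence")
    seq = seq.upper()
    return pct(seq.count("G") + seq.count("C"), len(seq))


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def write_coverage_table(rows: Sequence[CoverageRow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#array\tlevel\tn_unique_mapped\tpct_unique_mapped\t"
                 "n_all_mapped\tpct_all_mapped\tn_total_entities\n")
        for r in rows:
            fh.write(f"{r.array}\t{r.level}\t{r.n_unique_mapped}\t"
                     f"{_fmt(r.pct_unique_mapped)}\t{r.n_all_mapped}\t"
                     f"{_fmt(r.pct_all_mapped)}\t{r.n_total_entities}\n")


def write_efficiency_table(rows: Sequence[EfficiencyRow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#array\tlevel\tn_probes_one\tpct_one\tn_probes_multi\t"
                 "pct_multi\tn_probes_mapped\tn_probes_total\t"
                 "efficiency_pct\n")
        for r in rows:
            fh.write(f"{r.array}\t{r.level}\t{r.n_probes_one}\t"
                     f"{_fmt(r.pct_one)}\t{r.n_probes_multi}\t"
                     f"{_fmt(r.pct_multi)}\t{r.n_probes_mapped}\t"
                     f"{r.n_probes_total}\t{_fmt(r.efficiency_pct)}\n")
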