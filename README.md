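# probemap

Remapping of expression-microarray oligo probes to an annotated
transcriptome, at nucleotide resolution.

Expression microarrays measure hybridization of short oligo probes
(typically 25 nt), but vendor "probesets" are frozen at array design time
and drift away from current genome annotations: probes end up matching
several gene loci, none at all, noncoding RNAs, or introns. `probemap`
re-derives what every probe actually measures against an up-to-date
annotation and rebuilds summarization units from that mapping. It is
aimed at transcriptomics analysts who want gene-, transcript-, exon- or
ncRNA-level signals from (new or archival) probe-level array data.

## What it computes

1. **Exact matching.** Every probe is matched full-length, zero-mismatch
   against spliced transcript sequences (a hash index over all L-mers of
   the targets; both orientations by default). Probes containing `N`
   never match.
2. **Genomic placement.** Transcript hits are projected back onto the
   genome; a hit crossing an exon–exon boundary yields ≥ 2 genomic
   blocks and is flagged as a junction probe.
3. **Cascading classification.** Each probe resolves at the first stage
   with a hit: protein-coding transcripts → `mRNA`; annotation noncoding
   transcripts, then an external ncRNA collection → `ncRNA`; pre-mRNA
   locus sequence with the hit wholly inside an intron →
   `intronic_putative_ncRNA`; otherwise `NA`. Ambiguity is recorded at
   gene/transcript/exon level and summarised as a color
   (green = gene-unique and transcript-specific, yellow = gene-unique,
   red = multi-locus, black = not mRNA).
4. **Probe-set redefinition.** Flat, CDF-like set definitions at gene,
   transcript, exon and ncRNA level, plus the classic mapping files
   (`probes2genes`, `probes2transcripts`, `probesets2genes`,
   `ambigprobes2genes`).
5. **Statistics.** *Coverage* = % of annotation entities hit by the
   array's probes (also "unique mapped": entities with ≥ 1 unambiguous
   probe); *efficiency* = % of the array's probes that map, split into
   one-entity vs multi-entity probes; per-probe GC content.
6. **Summarization.** Entity signal = log2 of the mean of member-probe
   intensities (mean-of-logs available as an option).

A seeded synthetic-fixture generator produces genome + GTF + ncRNA +
probe inputs with planted, construction-verified ground truth in seven
probe classes, so the whole pipeline is testable without downloads.

## Worked example

```sh
probemap simulate --seed 7 --out-dir fx
probemap run-all --genome fx/genome.fa --annotation fx/annotation.gtf \
    --probes fx/probes.tsv --ncrna fx/ncrna.fa --truth fx/truth.tsv \
    --out-dir out
```

prints

```
truth agreement: 200/200 probes (100.00%)
```

meaning every one of the 200 planted probes was classified exactly as
constructed (category, junction flag, ambiguity flags, id sets and
color). `out/` then contains `assignments.tsv`, the mapping files, the
per-level set definitions and `coverage.tsv` / `efficiency.tsv`, e.g.

```
#array  level       n_unique_mapped  pct_unique_mapped  n_all_mapped  pct_all_mapped  n_total_entities
        transcript  13               24.07              47            87.04           54
        gene        17               85.00              17            85.00           20
```

— 47 of the fixture's 54 transcripts are hit by at least one probe
(87.04%), 13 of them by a probe hitting no other transcript.

The same pipeline runs on real inputs: a genome FASTA, a GTF/GFF3 with
gene/transcript/exon features and biotypes, a tab-separated probe file
(`probe_id  probeset_id  sequence`) and optionally an ncRNA FASTA.

In Python:

```python
from probemap import FixtureSpec, generate, classify_probes

fx = generate(FixtureSpec(seed=7))
assignments = classify_probes(fx.probes, fx.annotation,
                              genome=fx.genome, ncrna_targets=fx.ncrna)
```

## Layout

- `src/probemap/annotation.py` — locus model, GTF/GFF3 loading, spliced
  and pre-mRNA sequence extraction, transcript↔genome projection
- `src/probemap/mapping.py` — exact-match index, probe IO, naive oracle
- `src/probemap/classify.py` — the classification cascade
- `src/probemap/sets.py` — probe-set redefinition and mapping files
- `src/probemap/stats.py` — coverage/efficiency tables, GC content
- `src/probemap/summarize.py` — probe→entity signal summarization
- `src/probemap/simulate.py` — synthetic fixtures with planted truth
- `src/probemap/cli.py` — `probemap` command-line front end

See `docs/methods.md` for the model, conventions and limitations.
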