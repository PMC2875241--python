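# Methods

## Problem and model

A microarray probe reports signal for whatever transcribed sequence it
hybridizes to. `probemap` models hybridization as *full-length perfect
match*: a probe is assigned to a target iff its sequence (or its reverse
complement) occurs exactly, end to end, in the target. This is the
standard assumption behind probe-remapping pipelines for short (25 nt)
oligos — a single mismatch destroys most of the duplex stability, and
restricting to perfect matches makes assignments unambiguous and
reproducible. No thermodynamic model, gapped alignment or
mismatch-tolerant matching is attempted.

Targets come in three tiers derived from one annotation plus an optional
external collection:

* **spliced transcripts** — exon sequences concatenated in rank order,
  reverse-complemented as a whole on the minus strand; split into
  protein-coding and noncoding by biotype;
* **external ncRNAs** — an id → sequence FASTA collection emulating a
  curated ncRNA database;
* **pre-mRNA** — the contiguous, strand-oriented genomic span of each
  locus (exon hull), introns included.

### Classification cascade

Probes are resolved at the first stage with at least one hit:

1. protein-coding spliced transcripts → `mRNA`
2. noncoding spliced transcripts of the annotation → `ncRNA`
3. external ncRNA collection → `ncRNA`
4. pre-mRNA, counting only hits wholly outside every annotated exon of
   the locus → `intronic_putative_ncRNA`
5. otherwise `NA`

The ordering encodes "known RNAs take precedence": a probe matching a
known transcript is never relabelled by a later stage (cascade
monotonicity, property-tested). Intron-only probes are kept as
*putative* ncRNA evidence because an intronic perfect match may report
an unannotated exon of an alternative isoform. A pre-mRNA hit that
straddles an exon boundary without a spliced-transcript match is
evidence of neither and falls through to `NA`.

Hits at the deciding stage populate the id sets. Multiple occurrences in
one target collapse to a single membership (set semantics) with a
`multi_hit` flag. Junction status is decided by projecting each mRNA hit
onto the genome: more than one genomic block ⇒ junction. Junction probes
carry no exon ids — they are transcript-level evidence — while
single-block hits record the containing exon. Exon identity follows the
annotation's `exon_id`, so an exon shared between isoforms is one
entity.

Ambiguity flags: `gene_unique` (exactly one locus), `transcript_specific`
(gene-unique and exactly one transcript), `exon_specific` (one exon, not
junction). The display color compresses these: green (gene-unique +
transcript-specific), yellow (gene-unique only), red (multi-locus),
black (any non-mRNA category). The color semantics are a documented
convention of this package.

### Coordinate conventions

Internally all intervals are 0-based half-open; GTF/GFF3 input (1-based
inclusive) converts at the file boundary. The locus span is the exon
hull. `project_to_genome` walks the exon chain in rank order and returns
blocks in genomic order whose lengths sum to the query length; the
per-base round trip transcript → genome → transcript is the identity
(tested exhaustively on fixtures). Minus-strand arithmetic maps
transcript offset *o* inside an exon to genomic `[end − o − len, end − o)`.

### Matching engine

Because only full-length exact occurrences count, matching is hashing,
not alignment: for each distinct probe length L, every L-mer of every
target is stored with its occurrence list; a probe is two dictionary
lookups (forward + reverse complement). `N` never matches — k-mers
containing `N` are not indexed and probes containing `N` are skipped.
Reverse-complement search is on by default because vendor probe files
differ in orientation convention; orientation is recorded per hit, and a
sense-only mode is available. A brute-force `str.find` scan
(`naive_scan`) with identical semantics serves as the independent oracle
in tests; index and scan are required to agree hit-for-hit.

### Statistics

Coverage (% of entities hit) and efficiency (% of probes mapping) follow
the count-and-percentage layout of the published worked examples.
"Unique mapped" defaults to *at least one* unambiguous probe per entity;
a strict mode requiring *all* probes unambiguous is provided, since the
prose definition admits either reading. Percentages are rounded half-up
to 2 decimals and printed with decimal points regardless of locale. GC
content counts ambiguous bases in the length only.

### Summarization

Entity signal = log2 of the arithmetic mean of member-probe linear
intensities (the literal reading of "log2 of the mean of all probes");
mean-of-log2 is available as the common-practice alternative. The mean
is floored at 1.0 before the log so all-zero probe vectors give 0.0
rather than −∞ (the floor is configurable; the guard case is logged).
Member probes are put in canonical (sorted) order before the reduction
so the output is exactly invariant under probe-list permutations.

## Synthetic fixtures

The generator emulates the input stack at desk scale: 20 loci on two
chromosomes (uniform ACGT composition), 1–4 isoforms per locus (isoform
1 carries every exon; extra isoforms keep proper subsets, so private and
shared exons both exist), 2–5 exons of 40–120 nt, introns of 50–200 nt
(kept short purely for fixture size), 15% noncoding loci, an 8-sequence
external ncRNA collection, and 25-mer probes planted in seven classes
(60 exonic-unique, 30 junction, 30 multi-transcript, 20 multi-gene, 25
intronic, 20 ncRNA-database, 15 unmapped — 200 probes). Multi-gene
probes are created physically, by copying a window between exons of two
loci before any sequence is extracted; unmapped probes are rejection
sampled until absent from every target in both orientations.

Every planted probe is verified by construction: an oracle independent
of the pipeline (naive scanning plus cumulative-length splice
arithmetic, no hash index, no block projection) computes the assignment
a correct pipeline must produce, the candidate is re-sampled until it
provably belongs to its class, and that assignment is frozen into the
truth table. The repo's core test then demands 100% field-by-field
agreement between pipeline and truth. One integer seed determines every
byte of output.

What the fixtures do *not* emulate: realistic base composition, repeat
families and paralogs (beyond the planted duplications), UTR structure,
alternative transcription starts, chromosome-scale sequence, or
vendor-realistic probe densities. Passing the fixture suite therefore
demonstrates correctness of the mapping/classification logic, not
recall on any particular real genome or array; genome-scale published
counts require the original annotation releases and vendor probe files
and are out of scope here.

Intensity simulation: probe intensity = baseline × entity fold-effect ×
log-normal(0, σ) noise, one shared baseline (100) so fold effects map
directly to log2 shifts. With σ = 0.2 and four probes per entity,
two-fold effects separate cleanly from nulls (≥ 95/100 seeded runs,
measured in the acceptance script).

## Numerical and degenerate-input choices

* Percent rounding: decimal half-up (not banker's), 2 decimals (1 for
  the in-text style ratios).
* Palindromic probes report their forward occurrence once (the reverse
  complement occurrence is the same interval).
* Probes shorter than 8 nt are rejected as invalid; empty target sets
  and unindexed probe lengths raise configuration errors.
* `probesets2genes` uses unanimity: a vendor probeset maps to a gene
  only if every gene-mapping member probe maps uniquely to that gene;
  split or ambiguous probesets are dropped and logged.
* `min_probes` for set building defaults to 1 (no minimum is imposed by
  the method); it is a practical knob for downstream summarization.
* All writers sort their rows, so identical inputs give byte-identical
  files.

## Problem sizes

Default fixtures use 20 genes / ~48 transcripts / 200 probes; the
exhaustive per-base round-trip covers ~10⁴ bases; oracle-equivalence
uses 100 probes × 50 targets; recovery uses 100 seeded intensity runs.
These sizes make every property checkable exhaustively while keeping
the full suite and the acceptance script in the seconds range.

## Known limitations

* Exact matching only; near-matches that hybridize in practice are
  invisible (by design, as in the perfect-match remapping approach).
* Intron detection uses the pre-mRNA locus sequence, not a whole-genome
  scan, so intergenic perfect matches are reported as `NA`, never
  located.
* Gene-level ambiguity is computed against annotation loci only; an
  external-ncRNA hit never breaks gene uniqueness (it is recorded).
* The GTF/GFF3 reader expects exon features with resolvable
  gene/transcript ids and a biotype attribute; unknown biotypes fold to
  noncoding with a warning.
* Expression summarization is deliberately minimal (no background
  correction, normalization or multi-array modelling); it consumes
  probe-level matrices produced elsewhere.
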