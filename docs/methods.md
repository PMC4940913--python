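# Methods

## The problem

Genotyping-by-sequencing (GBS), RAD-seq and ddRAD reduce a genome to the
fragments adjacent to restriction cut sites and sequence them on a
multiplexed lane. Every read has a fixed anatomy:

```
5'  [barcode 4-8 nt] [cut-site remnant] [tag ...] [filler / adapter / chimera]  3'
```

The *barcode* identifies the sample; the *remnant* is the part of the
enzyme's recognition site left at the fragment end after digestion and
adapter ligation; the *tag* is the genomic sequence that follows and is
what distinguishes alleles at a locus. Per-allele read counts are the
quantity of scientific interest: they separate confident homozygotes from
under-sampled heterozygotes, support allele-dosage estimation in
polyploids, and flag repetitive loci by excessive depth. tagtally
extracts these counts for a *user-specified* set of markers, rather than
re-mining SNPs de novo, and therefore needs only exact string matching —
no assembly, no alignment, no quality models.

## The search algorithm

Expected sequences are indexed in a trie (prefix tree) whose nodes are
keyed by nucleotide. Classifying a read is a single walk from the read's
first base: the walk aborts at the first base with no matching child, so
the number of bases examined is bounded by the length of the longest
stored sequence regardless of how many sequences are stored. With tags of
40–80 nt this makes the per-read cost essentially flat from 10² to 10⁴
tags, which is the property the whole tool is built around (and which the
acceptance suite checks both as an instrumented step bound and as a
timing-shape smoke test).

Two tries are used per FASTQ file: one over `barcode + remnant`
concatenations (one entry per remnant variant for enzymes like ApeKI,
whose recognition site G^CWGC leaves either CAGC or CTGC), and one over
the tag sequences. Folding the remnant into the barcode trie means the
"expected cut site after the barcode" check is not a separate pass.
Design choices in the matcher:

* **Longest match wins.** If one stored sequence is a proper prefix of
  another, the deepest terminal reached is returned; otherwise a read
  carrying the longer tag would be credited to the shorter one.
* **`N` never matches.** Quality scores are ignored entirely — a read
  with an error is simply unlikely to match any known tag — and `N` is
  treated as a mismatch wherever it occurs.
* **Sequence after the matched tag is ignored** during counting; only
  the demultiplexer trims it.

Adapter read-through is found by checking, from the 3' end inward, for
the smallest position whose suffix is a prefix of a known adapter, with a
minimum overlap of 6 nt by default (a random 3' hexamer matches with
probability 4⁻⁶ per position, so shorter overlaps would truncate reads
spuriously). Chimeras — re-ligation artifacts — are detected as a *full*
restriction site inside the read by plain substring search; sequence
after the site is untrustworthy and is trimmed, keeping the site itself.

## Counting and genotype coding

Counting streams FASTQ record by record (plain or gzip by `.gz` suffix);
memory holds only the tries and the counts matrix, so it is independent
of file size. Every read increments at most one (sample, tag) cell by
exactly one; everything else lands in a per-file discard tally, giving
the conservation invariant `matched + unmatched = reads processed` that
every pipeline run asserts. Counts are unbounded integers — no cap is
ever applied, so high-depth loci and pooled samples are reported exactly.
Duplicate sample names across barcodes or files are pooled.

Genotypes for biallelic markers are coded by presence/absence of the two
alleles: both present → 1 (heterozygote), only allele 0 → 0, only
allele 1 → 2, neither → missing (blank in the CSV). Allele 0 is the
alphabetically smaller tag except in input formats where the user states
the order explicitly. There is deliberately no default depth threshold —
the coding is a direct readout of the counts — but `min_depth` optionally
blanks homozygous calls supported by fewer reads, since a shallow
homozygote may be an under-sampled heterozygote. Count-matrix columns are
named `marker_variableBases_alleleName` (e.g. `TP1_A_0`); the ordering of
the two suffix fields is a fixed convention of this package.

## Tag-set input and sanitization

Seven dialects are read into one in-memory tag-set type: three CSV
layouts (merged bracket notation `ACAGACTT[A/T]GTACCCA`; two tags per
row; one tag per row with verbatim allele names, allowing non-biallelic
markers) and four pipeline outputs (reference-free tag-pair FASTA with
poly-A padding truncated to the stated length; SAM of tags aligned to a
reference, grouped into markers by coordinate and named
`reference-position`, with the original query names retained for a
correspondence table; a Stacks catalog, reconstructing allele sequences
by substituting haplotype nucleotides into the consensus at the recorded
SNP columns; and pyRAD `.alleles` files, with gap characters removed so
indel alleles become literal searchable sequences of unequal length).
Loci from de-novo assemblers with more than 8 distinct alleles are
dropped as likely paralog collapses — a deliberately blunt, editable cap.

Before counting, the tag set is sanitized: any marker sharing an allele
sequence with a different marker is removed *entirely* (all markers
involved), because a shared sequence makes read attribution ambiguous for
every one of them; the symmetric rule is the only one that leaves the
tag → marker lookup provably injective. A discard report lists what was
removed and why.

## Demultiplexing

The splitter uses the same barcode trie to assign reads, then writes each
read to its barcode's output file with the barcode removed and the
remnant retained. Retaining the remnant is what makes the two entry
points commute: splitting a lane and then counting the per-sample files
in blank-barcode mode yields exactly the same counts matrix as counting
the multiplexed lane directly (an acceptance invariant). The order of
operations is barcode strip → chimera truncation (scanning only after the
remnant) → adapter trim; the quality string is cut to match. The barcode
is appended to the read's comment field, creating an Illumina-style
`1:N:0:<barcode>` comment when none exists; a blank barcode (re-splitting
an already-split file) changes nothing, making the operation idempotent.
An optional CSV manifest of MD5 checksums, one row per output file,
supports archive submission.

## Marker consolidation

Reference-free pipelines number loci arbitrarily, so cross-project
meta-analysis needs a shared namespace. The database keys each marker by
its *complete sorted set of allele sequences*: two markers merge only on
exact set equality — a tag that is a truncation of another is treated as
a different marker, because the sequences are genuinely not identical and
the shorter one would match a superset of reads. Matching is a binary
search (`bisect`) over lexicographically sorted keys, which an acceptance
test checks against a quadratic all-pairs oracle. Markers sharing *some*
but not all alleles with an existing record are added as new records and
listed in a conflict report rather than silently merged or dropped.
Universal names are `<prefix><6-digit zero-padded number>`, with the
width chosen to keep names sortable well past any realistic marker count;
numbers keep incrementing across appends so names are stable. Exports are
a merged-notation CSV (re-importable as a tag set, with per-project alias
columns riding along) and a FASTA with IUPAC ambiguity codes at
substitution sites; markers whose alleles differ in length fall back to
the first allele's full sequence, since no same-length consensus exists.
A SAM alignment of that FASTA can be imported back to annotate records
with chromosome, position and mapping quality.

## The synthetic lane generator

Tests and acceptance checks run on generated lanes, not downloads. The
generator's defaults describe the study conditions the package is built
for: 96 barcodes of mixed length (4–8 nt), 1000 biallelic markers with
40–80 nt tags and one substitution site each, negative-binomial read
depth per (sample, tag) cell (mean 1, dispersion 0.5 — heavily
zero-inflated, like real GBS), 5 % adapter read-through, 2 % chimeras,
and substitution errors at 10⁻³ per base. At those defaults a lane is
roughly 2×10⁵ reads, which keeps the full-scale acceptance checks to a
few tens of seconds; error, adapter and chimera rates are set to zero for
the exact-recovery checks, per their contracts.

Exactness of the planted truth is engineered, not assumed:

* barcode+remnant strings and tag strings are each generated as
  prefix-free sets, so every clean read has exactly one interpretation;
* tags are screened to contain no full restriction site and no adapter
  prefix, and to not *end* with the first 1–5 bases of an adapter, so
  neither chimera truncation nor adapter trimming can ever cut inside a
  tag (occurrences spanning the tag/filler junction always end at or
  beyond the tag end, which a short argument shows trims only filler);
* erroneous reads are re-randomized until they do not spell out any
  *other* registered barcode+remnant+tag combination, so errors can lose
  a read but never re-assign it — verified with a binary-search
  interpreter independent of the matching trie.

What the generator does **not** emulate: real quality-score profiles
(irrelevant — the matcher ignores them), indel sequencing errors,
PCR-duplicate structure, variable remnant usage within one lane, or
paired-end reads. Passing the planted-truth checks therefore demonstrates
exact bookkeeping of the matching and trimming logic under realistic read
anatomy, not robustness to artifacts outside the exact-matching model —
reads distorted by such artifacts are simply discarded, which is the
tool's documented behavior.

## Numerical / degenerate-input choices

* All sequences are uppercased on ingest; non-ACGT characters are errors
  everywhere except reads, where they terminate matching.
* Reads shorter than barcode + remnant + shortest tag are no-matches,
  never errors; truncated FASTQ records are errors naming file and
  record index.
* Merged bracket notation requires ≥ 2 distinct variants; alleles of
  unequal length render with an empty side (`AC[G/]TT`), and the empty
  variant appears as `-` in tag column names.
* Two runs over the same inputs produce byte-identical CSVs (dict
  iteration is insertion-ordered and no unordered collections reach the
  output paths).

## Known limitations

* Exact matching only: no Hamming-neighborhood or quality-aware
  matching, by design; error-carrying reads are lost, so counts are
  conservative.
* Single-end, prefix-anchored reads only.
* Allele names containing underscores break the right-split parsing of
  tag column names back into (marker, variable bases, allele).
* The Stacks and pyRAD dialects target the classic tab-separated catalog
  and `.alleles` layouts; other versions of those formats may need the
  readers extended.
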