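"""Stream FASTQ against a key file and tag set; produce count and genotype tables.

This is the counting entry point of the pipeline.  For every read it
first walks a trie of ``barcode + cut-site remnant`` strings; if the read
starts with an expected barcode and remnant, it then walks the tag trie
from the first base after the remnant (or from the remnant start for
enzymes whose variable cut site is stored as part of the tag).  A read
that survives both walks increments exactly one (sample, tag) cell; all
other reads land in a per-file discard tally, so matched + unmatched
always equals the number of reads processed.

Counts are plain unbounded integers — high-depth tags (repetitive
sequence, pooled samples, polyploid dosage) are reported exactly, never
capped.
"""

from __future__ import annotations

import csv
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .enzyme_registry import Enzyme
from .fastq import iter_fastq
from .sequence_index import SequenceTrie, build_trie
from .tag_model import TagSet, tag_column_name

__all__ = [
    "KeyFile",
    "CountsMatrix",
    "GenotypeMatrix",
    "read_key_file",
    "count_tags",
    "write_counts_csv",
    "read_counts_csv",
    "call_genotypes",
    "write_genotype_csv",
    "write_tassel_name_table",
]

MISSING = -1  # genotype code for "no reads for either allele"


@dataclass
class KeyFile:
    """Rows of (FASTQ path, barcode, sample name).

    Barcodes may repeat across files, and one sample may own several
    barcodes (counts are pooled).  A blank barcode means the file holds a
    single, already-demultiplexed sample and must be the only row for
    that file.
    """

    rows: list[tuple[str, str, str]]

    def files(self) -> list[str]:
        seen: list[str] = []
        for f, _, _ in self.rows:
            if f not in seen:
                seen.append(f)
        return seen

    def rows_for_file(self, path: str) -> list[tuple[str, str]]:
        return [(b, s) for f, b, s in self.rows if f == path]

    def samples(self) -> list[str]:
        seen: list[str] = []
        for _, _, s in self.rows:
            if s not in seen:
                seen.append(s)
        return seen


def read_key_file(path) -> KeyFile:
    """Read the counting key file (headers ``File``, ``Barcode``, ``Sample``)."""
    rows: list[tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = ["File", "Barcode", "Sample"]
        missing = [h for h in required if h not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(
                f"{path}: missing required column header(s): "
                + ", ".join(repr(h) for h in missing)
            )
        for row in reader:
            fastq = (row["File"] or "").strip()
            barcode = (row["Barcode"] or "").strip().upper()
            sample = (row["Sample"] or "").strip()
            if not fastq and not sample:
                continue  # blank line
            if not fastq:
                raise ValueError(f"{path}:{reader.line_num}: missing FASTQ file name")
            if not sample:
                raise ValueError(f"{path}:{reader.line_num}: missing sample name")
            if barcode and set(barcode) - set("ACGT"):
                raise ValueError(
                    f"{path}:{reader.line_num}: barcode {barcode!r} contains "
                    "characters other than A/C/G/T"
                )
            rows.append((fastq, barcode, sample))
    if not rows:
        raise ValueError(f"{path}: key file has no rows")
    key = KeyFile(rows)
    for fastq in key.files():
        barcodes = [b for b, _ in key.rows_for_file(fastq)]
        if "" in barcodes and len(barcodes) > 1:
            raise ValueError(
                f"{path}: file {fastq!r} mixes a blank barcode with other rows; "
                "a blank barcode must be the sole row for its file"
            )
        dupes = {b for b in barcodes if barcodes.count(b) > 1}
        if dupes:
            raise ValueError(
                f"{path}: file {fastq!r} lists barcode(s) more than once: "
                + ", ".join(sorted(repr(d) for d in dupes))
            )
    return key


def build_barcode_trie(
    barcode_payloads: list[tuple[str, object]], enzyme: Enzyme
) -> SequenceTrie:
    """Trie over ``barcode + remnant`` for every remnant variant.

    Payloads become ``(user payload, tag_start)`` where ``tag_start`` is
    the offset at which tag matching should resume: right after the
    barcode when tags carry the remnant themselves, otherwise after the
    remnant.  Blank barcodes yield bare-remnant entries.  Ambiguous keys
    (one entry a prefix of another) are rejected, naming the pair.
    """
    entries: list[tuple[str, tuple[object, int]]] = []
    for barcode, payload in barcode_payloads:
        for remnant in enzyme.remnant_variants:
            tag_start = (
                len(barcode) if enzyme.tags_include_remnant
                else len(barcode) + len(remnant)
            )
            entries.append((barcode + remnant, (payload, tag_start)))
    keys = sorted(e[0] for e in entries)
    for a, b in zip(keys, keys[1:]):
        if b.startswith(a) and a != b:
            raise ValueError(
                f"ambiguous barcodes: barcode+remnant {a!r} is a prefix of {b!r}"
            )
    return build_trie(entries)


@dataclass
class CountsMatrix:
    """Samples x tags read counts plus per-file match/discard tallies."""

    samples: list[str]
    tag_names: list[str]
    counts: np.ndarray  # int64, shape (n_samples, n_tags)
    file_tallies: dict[str, tuple[int, int]] = field(default_factory=dict)
    # (matched, unmatched) per FASTQ file

    @property
    def matched(self) -> int:
        return int(self.counts.sum())

    @property
    def unmatched(self) -> int:
        return sum(u for _, u in self.file_tallies.values())

    @property
    def total_reads(self) -> int:
        return sum(m + u for m, u in self.file_tallies.values())

    def get(self, sample: str, tag: str) -> int:
        return int(
            self.counts[self.samples.index(sample), self.tag_names.index(tag)]
        )


def count_tags(
    key: KeyFile,
    tags: TagSet,
    enzyme: Enzyme,
    *,
    progress: bool = False,
    progress_every: int = 1_000_000,
) -> CountsMatrix:
    """Count tag occurrences per sample across all FASTQ files in the key.

    The tag set must be sanitized (no sequence in two markers); duplicate
    sample names across barcodes or files are pooled into one row.
    """
    lookup = tags.lookup()  # raises if not sanitized
    samples = key.samples()
    sample_idx = {s: i for i, s in enumerate(samples)}
    # column layout: markers in input order, alleles in allele order
    col_of: dict[tuple[int, int], int] = {}
    for ci, (_, where) in enumerate(tags.tag_entries()):
        col_of[where] = ci
    tag_trie = build_trie(
        (seq, col_of[where]) for seq, where in lookup.items()
    )
    tag_names = tags.tag_column_names()
    counts = np.zeros((len(samples), len(tag_names)), dtype=np.int64)
    tallies: dict[str, tuple[int, int]] = {}

    for fastq in key.files():
        bc_payloads = [
            (barcode, sample_idx[sample])
            for barcode, sample in key.rows_for_file(fastq)
        ]
        bc_trie = build_barcode_trie(bc_payloads, enzyme)
        matched = unmatched = 0
        bc_match = bc_trie.match_prefix
        tag_match = tag_trie.match_prefix
        for n_reads, (_, seq, _) in enumerate(iter_fastq(fastq), 1):
            hit = bc_match(seq)
            if hit is not None:
                (si, tag_start), _ = hit
                tag_hit = tag_match(seq, tag_start)
                if tag_hit is not None:
                    counts[si, tag_hit[0]] += 1
                    matched += 1
                    if progress and matched % progress_every == 0:
                        print(f"{fastq}: {n_reads} reads processed", file=sys.stderr)
                    continue
            unmatched += 1
        tallies[fastq] = (matched, unmatched)
        if progress:
            print(
                f"{fastq}: done; {matched} reads matched, {unmatched} discarded",
                file=sys.stderr,
            )
    return CountsMatrix(samples, tag_names, counts, tallies)


def write_counts_csv(m: CountsMatrix, path) -> None:
    """Counts CSV: first row tag names, first column sample names."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + m.tag_names)
        for i, sample in enumerate(m.samples):
            writer.writerow([sample] + [int(c) for c in m.counts[i]])


def read_counts_csv(path) -> CountsMatrix:
    """Read back a counts CSV written by :func:`write_counts_csv`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty counts file")
    tag_names = rows[0][1:]
    samples = [r[0] for r in rows[1:]]
    counts = np.array(
        [[int(c) for c in r[1:]] for r in rows[1:]], dtype=np.int64
    ).reshape(len(samples), len(tag_names))
    return CountsMatrix(samples, tag_names, counts)


@dataclass
class GenotypeMatrix:
    """Samples x markers diploid genotypes: 0/1/2, or -1 for missing."""

    samples: list[str]
    marker_names: list[str]
    codes: np.ndarray  # int8, shape (n_samples, n_markers)

    def get(self, sample: str, marker: str):
        code = int(
            self.codes[self.samples.index(sample), self.marker_names.index(marker)]
        )
        return None if code == MISSING else code


def call_genotypes(
    m: CountsMatrix, tags: TagSet, *, min_depth: int = 0
) -> GenotypeMatrix:
    """Numeric diploid genotypes from allele read counts.

    With allele-0 count ``c0`` and allele-1 count ``c1``: both positive is
    a heterozygote (1); only allele 0 present is 0; only allele 1 present
    is 2; neither is missing.  ``min_depth`` optionally blanks homozygous
    calls whose supporting depth is below the cutoff, since a low-depth
    homozygote may be an under-sampled heterozygote.
    """
    for marker in tags.markers:
        if len(marker.alleles) != 2:
            raise ValueError(
                f"marker {marker.name!r} has {len(marker.alleles)} alleles; "
                "genotype export requires all markers biallelic"
            )
    expected = tags.tag_column_names()
    if m.tag_names != expected:
        raise ValueError(
            "counts matrix columns do not correspond to the supplied tag set"
        )
    n_markers = len(tags.markers)
    c0 = m.counts[:, 0::2]
    c1 = m.counts[:, 1::2]
    codes = np.full((len(m.samples), n_markers), MISSING, dtype=np.int8)
    codes[(c0 > 0) & (c1 > 0)] = 1
    codes[(c0 > 0) & (c1 == 0)] = 0
    codes[(c0 == 0) & (c1 > 0)] = 2
    if min_depth > 0:
        codes[(codes == 0) & (c0 < min_depth)] = MISSING
        codes[(codes == 2) & (c1 < min_depth)] = MISSING
    return GenotypeMatrix(m.samples, [mk.name for mk in tags.markers], codes)


def write_genotype_csv(g: GenotypeMatrix, path) -> None:
    """Genotype CSV: 0/1/2 cells, missing left blank."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + g.marker_names)
        for i, sample in enumerate(g.samples):
            writer.writerow(
                [sample]
                + ["" if c == MISSING else int(c) for c in g.codes[i]]
            )


def write_tassel_name_table(tags: TagSet, path) -> None:
    """Correspondence table: source pipeline SNP/tag names -> marker names.

    Only meaningful for tag sets imported from aligned-tag SAM, where the
    source may have mined several SNPs from one aligned locus.
    """
    if not tags.original_names:
        raise ValueError(
            "tag set has no retained original names; import from an aligned "
            "SAM tag file to produce a name correspondence table"
        )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Original name", "Marker name"])
        for orig in sorted(tags.original_names):
            writer.writerow([orig, tags.original_names[orig]])
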