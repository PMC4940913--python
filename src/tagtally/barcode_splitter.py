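"""Demultiplex FASTQ by barcode, with adapter and chimera trimming.

Each read whose start matches a known ``barcode + cut-site remnant`` is
written to that barcode's output file with

1. the barcode removed (the cut-site remnant is retained, since
   downstream tools — including this package's own counting mode for
   pre-split files — expect reads to begin at the remnant);
2. sequence after an internal full restriction site truncated (a full
   site mid-read marks a likely chimera of two re-ligated fragments; the
   site itself is kept);
3. 3' adapter read-through trimmed off;
4. the quality string cut to the same length; and
5. the barcode appended to the read's comment field, creating an
   Illumina-style ``1:N:0:<barcode>`` comment when none exists.

Reads matching no barcode are dropped and tallied.  Outputs are
uncompressed FASTQ; an optional CSV manifest of MD5 checksums supports
deposit in public archives.
"""

from __future__ import annotations

import csv
import hashlib
import sys
from dataclasses import dataclass, field
from pathlib import Path

from .enzyme_registry import AdapterSet, Enzyme
from .fastq import iter_fastq, write_fastq_record
from .read_counter import build_barcode_trie
from .sequence_index import find_adapter_trim, find_full_cut_site

__all__ = [
    "SplitKeyFile",
    "SplitResult",
    "read_split_key_file",
    "split_fastq",
    "md5_manifest",
]

DEFAULT_MIN_ADAPTER_OVERLAP = 6  # chance suffix match at 6 nt: 4^-6 per position


@dataclass
class SplitKeyFile:
    """Rows of (input FASTQ, barcode, output FASTQ)."""

    rows: list[tuple[str, str, str]]

    def files(self) -> list[str]:
        seen: list[str] = []
        for f, _, _ in self.rows:
            if f not in seen:
                seen.append(f)
        return seen

    def rows_for_file(self, path: str) -> list[tuple[str, str]]:
        return [(b, o) for f, b, o in self.rows if f == path]


def read_split_key_file(path) -> SplitKeyFile:
    """Read the splitting key (headers ``Input File``, ``Barcode``,
    ``Output File``)."""
    rows: list[tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = ["Input File", "Barcode", "Output File"]
        missing = [h for h in required if h not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(
                f"{path}: missing required column header(s): "
                + ", ".join(repr(h) for h in missing)
            )
        for row in reader:
            infile = (row["Input File"] or "").strip()
            barcode = (row["Barcode"] or "").strip().upper()
            outfile = (row["Output File"] or "").strip()
            if not infile and not outfile:
                continue
            if not infile or not outfile:
                raise ValueError(
                    f"{path}:{reader.line_num}: both input and output file "
                    "names are required"
                )
            if barcode and set(barcode) - set("ACGT"):
                raise ValueError(
                    f"{path}:{reader.line_num}: barcode {barcode!r} contains "
                    "characters other than A/C/G/T"
                )
            rows.append((infile, barcode, outfile))
    if not rows:
        raise ValueError(f"{path}: key file has no rows")
    key = SplitKeyFile(rows)
    outputs = [o for _, _, o in rows]
    if len(set(outputs)) != len(outputs):
        dupes = sorted({o for o in outputs if outputs.count(o) > 1})
        raise ValueError(f"{path}: duplicate output file(s): {', '.join(dupes)}")
    for infile in key.files():
        barcodes = [b for b, _ in key.rows_for_file(infile)]
        if "" in barcodes and len(barcodes) > 1:
            raise ValueError(
                f"{path}: file {infile!r} mixes a blank barcode with other rows"
            )
        dupes = {b for b in barcodes if barcodes.count(b) > 1}
        if dupes:
            raise ValueError(
                f"{path}: file {infile!r} lists barcode(s) more than once: "
                + ", ".join(sorted(repr(d) for d in dupes))
            )
    return key


@dataclass
class SplitResult:
    """Per-output read tallies plus per-input unmatched tallies."""

    written: dict[str, int] = field(default_factory=dict)
    unmatched: dict[str, int] = field(default_factory=dict)

    @property
    def total_written(self) -> int:
        return sum(self.written.values())

    @property
    def total_unmatched(self) -> int:
        return sum(self.unmatched.values())


def _annotate_header(header: str, barcode: str) -> str:
    """Append the barcode to the comment, creating one if absent."""
    if not barcode:
        return header
    name, sep, comment = header.partition(" ")
    if sep and comment.strip():
        return f"{name} {comment}:{barcode}"
    return f"{name} 1:N:0:{barcode}"


def split_fastq(
    key: SplitKeyFile,
    enzyme: Enzyme,
    adapters: AdapterSet | None = None,
    *,
    min_overlap: int = DEFAULT_MIN_ADAPTER_OVERLAP,
    md5_path=None,
    progress: bool = False,
) -> SplitResult:
    """Split every input file in ``key`` by barcode.

    ``adapters=None`` disables adapter trimming.  If ``md5_path`` is
    given, an MD5 manifest of all output files is written there after
    splitting.
    """
    result = SplitResult()
    for infile in key.files():
        rows = key.rows_for_file(infile)
        handles = {}
        try:
            for barcode, outfile in rows:
                Path(outfile).parent.mkdir(parents=True, exist_ok=True)
                handles[barcode] = open(outfile, "w")
                result.written.setdefault(outfile, 0)
            # payload carries (barcode, output file); tag_start marks where
            # the remnant ends, i.e. where the chimera scan begins
            trie = build_barcode_trie(
                [(b, (b, o)) for b, o in rows], enzyme
            )
            unmatched = 0
            for header, seq, qual in iter_fastq(infile):
                hit = trie.match_prefix(seq)
                if hit is None:
                    unmatched += 1
                    continue
                ((barcode, outfile), tag_start), consumed = hit
                bc_len = len(barcode)
                out_seq = seq[bc_len:]
                # remnant length differs per matched variant; recompute from
                # the actual walk for variable-site enzymes
                remnant_len = consumed - bc_len
                pos = find_full_cut_site(out_seq, enzyme.full_sites, remnant_len)
                if pos is not None:
                    site_len = max(
                        len(s)
                        for s in enzyme.full_sites
                        if out_seq.startswith(s, pos)
                    )
                    out_seq = out_seq[: pos + site_len]
                if adapters is not None:
                    p = find_adapter_trim(out_seq, adapters, min_overlap)
                    if p is not None:
                        out_seq = out_seq[:p]
                out_qual = qual[bc_len: bc_len + len(out_seq)]
                write_fastq_record(
                    handles[barcode],
                    _annotate_header(header, barcode),
                    out_seq,
                    out_qual,
                )
                result.written[outfile] += 1
            result.unmatched[infile] = unmatched
            if progress:
                done = sum(result.written[o] for _, o in rows)
                print(
                    f"{infile}: done; {done} reads written, "
                    f"{unmatched} unmatched",
                    file=sys.stderr,
                )
        finally:
            for fh in handles.values():
                fh.close()
    if md5_path is not None:
        md5_manifest(sorted(result.written), md5_path)
    return result


def md5_manifest(paths, out) -> None:
    """CSV manifest: one row per file with its 32-hex-digit MD5 checksum."""
    digests = []
    for path in paths:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"cannot checksum missing file: {p}")
        h = hashlib.md5()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        digests.append((str(path), h.hexdigest()))
    with open(out, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in digests:
            writer.writerow(row)
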