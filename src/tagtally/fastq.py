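"""Streaming FASTQ input/output.

Reads are processed one record at a time so memory use is independent of
file size; files ending in ``.gz`` are decompressed on the fly.  Records
are the standard 4-line form (header, sequence, separator, quality).
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterator

__all__ = ["open_text_auto", "iter_fastq", "write_fastq_record"]


def open_text_auto(path, mode: str = "rt") -> io.TextIOBase:
    """Open plain or GZIP text by the ``.gz`` suffix convention."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(header, sequence, quality)`` per record.

    The header keeps its ``@`` and any comment; the separator line is
    validated and dropped.  Truncated or malformed records raise with the
    file name and 1-based record index.
    """
    with open_text_auto(path) as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            record += 1
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"{path}: truncated FASTQ record {record}")
            header = header.rstrip("\n")
            seq = seq.rstrip("\n")
            qual = qual.rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record {record}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: record {record}: sequence and quality "
                    f"lengths differ ({len(seq)} vs {len(qual)})"
                )
            yield header, seq, qual


def write_fastq_record(fh, header: str, seq: str, qual: str) -> None:
    fh.write(f"{header}\n{seq}\n+\n{qual}\n")
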