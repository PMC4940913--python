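"""Consolidate marker sets across projects under universal names.

Reference-free SNP pipelines number their loci arbitrarily, so the same
physical marker carries unrelated names in different projects.  This
module maintains a database keyed by the *complete sorted set of allele
sequences* of each marker: two markers merge only when their allele sets
are exactly identical — a tag that is a truncation of another is a
different marker.  Matching uses a binary search (``bisect``) over the
lexicographically sorted allele-set keys.

Each record gets a stable universal name ``<prefix><zero-padded number>``
(e.g. ``MyLabsTags000102``), remembers the original name per project,
and can be annotated with alignment coordinates from a SAM file of the
exported marker FASTA.
"""

from __future__ import annotations

import bisect
import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .fastq import open_text_auto
from .tag_model import MergedTag, TagSet, merge_tags

__all__ = [
    "MarkerRecord",
    "MarkerDatabase",
    "consolidate",
    "export_merged_csv",
    "export_fasta",
    "annotate_from_sam",
    "read_database",
]

NUMBER_WIDTH = 6

IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R",
    frozenset("AT"): "W", frozenset("CG"): "S",
    frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

_ALIGN_HEADERS = ("Chromosome", "Position", "Alignment quality")


@dataclass
class MarkerRecord:
    universal_name: str
    alleles: tuple[str, ...]  # sorted allele sequences — the match key
    aliases: dict[str, list[str]] = field(default_factory=dict)
    extra: dict[str, str] = field(default_factory=dict)
    alignment: tuple[str, int, int] | None = None  # (reference, 1-based pos, mapq)

    def merged(self) -> MergedTag:
        return merge_tags(list(self.alleles))


@dataclass
class MarkerDatabase:
    prefix: str
    records: list[MarkerRecord] = field(default_factory=list)
    conflicts: list[tuple[str, str, list[str]]] = field(default_factory=list)
    # (project, original marker name, allele sequences shared with existing
    # records) — markers that partially overlap an existing record

    def __len__(self) -> int:
        return len(self.records)

    def next_number(self) -> int:
        best = -1
        for rec in self.records:
            m = re.search(r"(\d+)$", rec.universal_name)
            if m:
                best = max(best, int(m.group(1)))
        return best + 1

    def find(self, universal_name: str) -> MarkerRecord | None:
        for rec in self.records:
            if rec.universal_name == universal_name:
                return rec
        return None


def _format_name(prefix: str, number: int) -> str:
    return f"{prefix}{number:0{NUMBER_WIDTH}d}"


def consolidate(
    existing: MarkerDatabase | None,
    incoming: TagSet,
    project: str,
    prefix: str,
) -> MarkerDatabase:
    """Merge ``incoming`` markers into the database under ``project``.

    A marker whose complete sorted allele-sequence set equals an existing
    record's set is merged into it (its project name becomes an alias);
    anything else — including markers sharing only some alleles, which
    are additionally listed in ``db.conflicts`` — becomes a new record
    with the next sequential universal name.  Re-consolidating a project
    already in the database is a no-op.
    """
    db = existing if existing is not None else MarkerDatabase(prefix)
    if db.prefix != prefix:
        raise ValueError(
            f"database uses prefix {db.prefix!r}; cannot consolidate with "
            f"prefix {prefix!r}"
        )
    # sorted key list for binary search, plus a per-allele index for
    # partial-overlap detection
    keyed = sorted((rec.alleles, i) for i, rec in enumerate(db.records))
    keys = [k for k, _ in keyed]
    allele_owner: dict[str, list[int]] = {}
    for i, rec in enumerate(db.records):
        for seq in rec.alleles:
            allele_owner.setdefault(seq, []).append(i)

    number = db.next_number()
    for marker in incoming.markers:
        if len(marker.alleles) < 2:
            raise ValueError(
                f"marker {marker.name!r} has fewer than two alleles and "
                "cannot be consolidated"
            )
        key = tuple(sorted(marker.tags))
        pos = bisect.bisect_left(keys, key)
        if pos < len(keys) and keys[pos] == key:
            rec = db.records[keyed[pos][1]]
            names = rec.aliases.setdefault(project, [])
            if marker.name not in names:
                names.append(marker.name)
            continue
        shared = sorted(seq for seq in key if seq in allele_owner)
        if shared:
            db.conflicts.append((project, marker.name, shared))
        rec = MarkerRecord(
            universal_name=_format_name(prefix, number),
            alleles=key,
            aliases={project: [marker.name]},
        )
        number += 1
        idx = len(db.records)
        db.records.append(rec)
        ins = bisect.bisect_left(keys, key)
        keys.insert(ins, key)
        keyed.insert(ins, (key, idx))
        for seq in key:
            allele_owner.setdefault(seq, []).append(idx)
    return db


def export_merged_csv(db: MarkerDatabase, path) -> None:
    """Write the database as a merged-notation CSV, re-importable as a
    tag set; alias, alignment and extra columns ride along."""
    projects = sorted({p for rec in db.records for p in rec.aliases})
    extra_cols = sorted({k for rec in db.records for k in rec.extra})
    any_aligned = any(rec.alignment is not None for rec in db.records)
    header = ["Marker name", "Tag sequence"] + projects
    if any_aligned:
        header += list(_ALIGN_HEADERS)
    header += extra_cols
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in db.records:
            row = [rec.universal_name, rec.merged().render()]
            row += [";".join(rec.aliases.get(p, [])) for p in projects]
            if any_aligned:
                if rec.alignment is not None:
                    ref, pos, mapq = rec.alignment
                    row += [ref, str(pos), str(mapq)]
                else:
                    row += ["", "", ""]
            row += [rec.extra.get(k, "") for k in extra_cols]
            writer.writerow(row)


def export_fasta(db: MarkerDatabase, path) -> None:
    """One FASTA record per marker, IUPAC codes at substitution sites.

    Markers whose alleles differ in length (indels) cannot be expressed
    as a single same-length consensus; for those the alphabetically
    first allele's full sequence is written.
    """
    with open(path, "w") as fh:
        for rec in db.records:
            seqs = list(rec.alleles)
            if len({len(s) for s in seqs}) == 1:
                consensus = "".join(
                    IUPAC[frozenset(col)] for col in zip(*seqs)
                )
            else:
                consensus = seqs[0]
            fh.write(f">{rec.universal_name}\n{consensus}\n")


def annotate_from_sam(db: MarkerDatabase, sam_path) -> MarkerDatabase:
    """Attach (reference, position, mapping quality) from a SAM alignment
    of the exported marker FASTA; query names must be universal names."""
    import pysam

    by_name = {rec.universal_name: rec for rec in db.records}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            target = by_name.get(rec.query_name)
            if target is None:
                warnings.warn(
                    f"{sam_path}: query name {rec.query_name!r} is not in "
                    "the marker database; skipped"
                )
                continue
            if rec.is_unmapped:
                continue  # annotation stays blank
            target.alignment = (
                rec.reference_name,
                rec.reference_start + 1,
                rec.mapping_quality,
            )
    return db


def read_database(path, prefix: str | None = None) -> MarkerDatabase:
    """Load a database previously written by :func:`export_merged_csv`.

    Columns other than the marker name, merged tag and alignment triplet
    are treated as project alias columns (empty cells meaning no alias).
    The prefix is inferred from the universal names unless given.
    """
    with open_text_auto(path) as fh:
        reader = csv.DictReader(fh)
        required = ["Marker name", "Tag sequence"]
        missing = [h for h in required if h not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(
                f"{path}: missing required column header(s): "
                + ", ".join(repr(h) for h in missing)
            )
        alias_cols = [
            c for c in reader.fieldnames
            if c not in required and c not in _ALIGN_HEADERS
        ]
        records = []
        inferred_prefix = None
        for row in reader:
            name = (row["Marker name"] or "").strip()
            if not name:
                continue
            m = re.match(r"^(.*?)(\d+)$", name)
            if m is None:
                raise ValueError(
                    f"{path}:{reader.line_num}: marker name {name!r} does not "
                    "end in a number; not a managed database"
                )
            if inferred_prefix is None:
                inferred_prefix = m.group(1)
            merged = MergedTag.parse(
                row["Tag sequence"], where=f"{path}:{reader.line_num}"
            )
            aliases = {}
            for col in alias_cols:
                cell = (row.get(col) or "").strip()
                if cell:
                    aliases[col] = cell.split(";")
            alignment = None
            if row.get("Chromosome"):
                alignment = (
                    row["Chromosome"],
                    int(row["Position"]),
                    int(row["Alignment quality"]),
                )
            records.append(
                MarkerRecord(
                    universal_name=name,
                    alleles=tuple(sorted(merged.expand())),
                    aliases=aliases,
                    alignment=alignment,
                )
            )
    if not records:
        raise ValueError(f"{path}: database file has no records")
    db_prefix = prefix if prefix is not None else (inferred_prefix or "")
    return MarkerDatabase(db_prefix, records)
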