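"""Readers for the seven tag-set dialects, subsetting, and sanitization.

Tag sets can come from CSV files maintained by hand (three layouts) or be
lifted directly from the output of other SNP-calling pipelines: a
reference-free tag-pair FASTA, a SAM file of tags aligned to a reference,
a Stacks ``cstacks`` catalog, or a pyRAD ``.alleles`` file.  Whatever the
source, the result is the same in-memory :class:`~tagtally.tag_model.TagSet`.

CSV header strings are matched case-sensitively and exactly; extra
columns are ignored so annotated files round-trip.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .fastq import open_text_auto
from .tag_model import (
    Marker,
    MergedTag,
    TagSet,
    normalize_sequence,
    order_alleles,
)

__all__ = [
    "TAG_FORMATS",
    "MarkerSubset",
    "DiscardReport",
    "read_tag_file",
    "read_marker_subset",
    "filter_markers",
    "sanitize_tag_set",
    "write_merged_csv",
]

TAG_FORMATS = (
    "uneak_fasta",
    "tassel_sam",
    "stacks_catalog",
    "pyrad_alleles",
    "csv_two_tags",
    "csv_one_per_row",
    "csv_merged",
)

# Maximum distinct alleles kept per locus when importing de-novo assembly
# output; loci above this are more likely collapsed paralogs than real
# multi-allelic markers.
MAX_ALLELES_PER_LOCUS = 8


@dataclass(frozen=True)
class MarkerSubset:
    """Names of markers to retain; everything else is ignored."""

    names: frozenset[str]

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class DiscardReport:
    """Markers removed by :func:`sanitize_tag_set` and why."""

    removed: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.removed)


def _require_headers(fieldnames, required, path) -> None:
    missing = [h for h in required if h not in (fieldnames or [])]
    if missing:
        raise ValueError(
            f"{path}: missing required column header(s): "
            + ", ".join(repr(h) for h in missing)
        )


def _check_marker_names_unique(markers: list[Marker], path) -> None:
    seen = set()
    for m in markers:
        if m.name in seen:
            raise ValueError(f"{path}: duplicate marker name {m.name!r}")
        seen.add(m.name)


# --- CSV dialects ---------------------------------------------------------

def _read_csv_merged(path) -> TagSet:
    markers = []
    with open_text_auto(path) as fh:
        reader = csv.DictReader(fh)
        _require_headers(reader.fieldnames, ["Marker name", "Tag sequence"], path)
        for row in reader:
            name = (row["Marker name"] or "").strip()
            if not name:
                continue
            where = f"{path}:{reader.line_num}"
            merged = MergedTag.parse(row["Tag sequence"], where=where)
            markers.append(order_alleles(merged.expand(), name))
    if not markers:
        raise ValueError(f"{path}: no markers found")
    _check_marker_names_unique(markers, path)
    return TagSet(markers)


def _read_csv_two_tags(path) -> TagSet:
    markers = []
    with open_text_auto(path) as fh:
        reader = csv.DictReader(fh)
        _require_headers(
            reader.fieldnames,
            ["Marker name", "Tag sequence 0", "Tag sequence 1"],
            path,
        )
        for row in reader:
            name = (row["Marker name"] or "").strip()
            if not name:
                continue
            where = f"{path}:{reader.line_num}"
            tag0 = normalize_sequence(row["Tag sequence 0"], where=where)
            tag1 = normalize_sequence(row["Tag sequence 1"], where=where)
            if tag0 == tag1:
                raise ValueError(f"{where}: marker {name!r} has identical tags")
            # this format fixes which tag is allele 0: order as given
            markers.append(Marker(name, (("0", tag0), ("1", tag1))))
    if not markers:
        raise ValueError(f"{path}: no markers found")
    _check_marker_names_unique(markers, path)
    return TagSet(markers)


def _read_csv_one_per_row(path) -> TagSet:
    # allele names are explicit here, so they are kept verbatim and
    # never re-sorted; non-biallelic markers are allowed
    order: list[str] = []
    alleles: dict[str, list[tuple[str, str]]] = {}
    with open_text_auto(path) as fh:
        reader = csv.DictReader(fh)
        _require_headers(
            reader.fieldnames,
            ["Marker name", "Allele name", "Tag sequence"],
            path,
        )
        for row in reader:
            name = (row["Marker name"] or "").strip()
            if not name:
                continue
            where = f"{path}:{reader.line_num}"
            allele = (row["Allele name"] or "").strip()
            if not allele:
                raise ValueError(f"{where}: empty allele name for marker {name!r}")
            seq = normalize_sequence(row["Tag sequence"], where=where)
            if name not in alleles:
                order.append(name)
                alleles[name] = []
            if allele in [a for a, _ in alleles[name]]:
                raise ValueError(
                    f"{where}: duplicate allele name {allele!r} for marker {name!r}"
                )
            alleles[name].append((allele, seq))
    if not order:
        raise ValueError(f"{path}: no markers found")
    markers = [Marker(name, tuple(alleles[name])) for name in order]
    return TagSet(markers)


# --- pipeline output dialects ---------------------------------------------

_UNEAK_HEADER_RE = re.compile(r"^(?P<marker>.+)_(?P<role>query|hit)_(?P<length>\d+)$")


def _read_uneak_fasta(path) -> TagSet:
    """Reference-free tag-pair FASTA: headers ``>{marker}_{query|hit}_{len}``.

    Sequences are padded to a fixed length with poly-A by the source
    pipeline, so each is truncated back to the stated true length.
    """
    pairs: dict[str, list[str]] = {}
    order: list[str] = []
    with open_text_auto(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            m = _UNEAK_HEADER_RE.match(rec.id)
            if m is None:
                raise ValueError(
                    f"{path}: cannot parse tag-pair FASTA header {rec.id!r}; "
                    "expected marker_query_NN or marker_hit_NN"
                )
            name = m.group("marker")
            length = int(m.group("length"))
            seq = normalize_sequence(str(rec.seq)[:length], where=f"{path}:{rec.id}")
            if name not in pairs:
                pairs[name] = []
                order.append(name)
            pairs[name].append(seq)
    markers = []
    for name in order:
        seqs = sorted(set(pairs[name]))
        if len(seqs) < 2:
            warnings.warn(
                f"{path}: marker {name!r} has fewer than two distinct tags; skipped"
            )
            continue
        markers.append(order_alleles(seqs, name))
    if not markers:
        raise ValueError(f"{path}: no tag pairs found")
    _check_marker_names_unique(markers, path)
    return TagSet(markers)


def _read_tassel_sam(path) -> TagSet:
    """SAM of tags aligned to a reference, as used by reference-based GBS.

    Tags are grouped into markers by alignment coordinate (reference,
    1-based leftmost position, strand) and markers are named
    ``{reference}-{position}``; reverse-strand records are
    reverse-complemented back to read orientation first.  The original
    query names are retained so a correspondence table can be written.
    """
    import pysam

    groups: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    names_by_group: dict[tuple, list[str]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            seq = rec.get_forward_sequence()
            key = (rec.reference_name, rec.reference_start + 1, rec.is_reverse)
            if key not in groups:
                groups[key] = []
                names_by_group[key] = []
                order.append(key)
            groups[key].append(normalize_sequence(seq, where=f"{path}:{rec.query_name}"))
            names_by_group[key].append(rec.query_name)

    markers = []
    original: dict[str, str] = {}
    used_names: set[str] = set()
    for key in order:
        ref, pos, is_reverse = key
        seqs = sorted(set(groups[key]))
        if len(seqs) < 2:
            warnings.warn(
                f"{path}: locus {ref}-{pos} has fewer than two distinct tags; skipped"
            )
            continue
        name = f"{ref}-{pos}"
        if name in used_names:  # both strands at one coordinate
            name = f"{ref}-{pos}-rev" if is_reverse else f"{ref}-{pos}-fwd"
        used_names.add(name)
        markers.append(order_alleles(seqs, name))
        for qname in names_by_group[key]:
            if qname in original and original[qname] != name:
                warnings.warn(
                    f"{path}: query name {qname!r} maps to multiple loci; "
                    f"keeping {original[qname]!r}"
                )
                continue
            original[qname] = name
    if not markers:
        raise ValueError(f"{path}: no aligned tag loci found")
    return TagSet(markers, original_names=original)


def _companion_path(tags_path: Path, what: str) -> Path:
    """catalog.tags.tsv[.gz] -> catalog.{snps,alleles}.tsv[.gz]."""
    name = tags_path.name
    if "tags" not in name:
        raise ValueError(
            f"{tags_path}: expected a catalog *tags* file so the matching "
            f"{what} file can be located"
        )
    candidate = tags_path.with_name(name.replace("tags", what, 1))
    if candidate.exists():
        return candidate
    # allow mixed compression between the three files
    alt = (
        candidate.with_suffix("")
        if candidate.suffix == ".gz"
        else candidate.with_name(candidate.name + ".gz")
    )
    if alt.exists():
        return alt
    raise FileNotFoundError(f"{candidate}: companion catalog file not found")


def _read_stacks_catalog(path) -> TagSet:
    """Stacks ``cstacks`` catalog: consensus tags + SNP columns + haplotypes.

    Full-length allele sequences are reconstructed by substituting each
    haplotype's nucleotides into the consensus at the recorded SNP
    columns (0-based).  Loci without at least two clean haplotypes are
    skipped.
    """
    tags_path = Path(path)
    snps_path = _companion_path(tags_path, "snps")
    alleles_path = _companion_path(tags_path, "alleles")

    consensus: dict[str, str] = {}
    order: list[str] = []
    with open_text_auto(tags_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 10:
                raise ValueError(f"{tags_path}:{lineno}: expected >=10 columns")
            locus, seq_type, seq = cols[2], cols[6], cols[9]
            if seq_type != "consensus":
                continue
            consensus[locus] = normalize_sequence(seq, where=f"{tags_path}:{lineno}")
            order.append(locus)

    snp_cols: dict[str, list[int]] = {}
    with open_text_auto(snps_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise ValueError(f"{snps_path}:{lineno}: expected >=4 columns")
            locus, column = cols[2], int(cols[3])
            snp_cols.setdefault(locus, []).append(column)

    haplotypes: dict[str, list[str]] = {}
    with open_text_auto(alleles_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise ValueError(f"{alleles_path}:{lineno}: expected >=4 columns")
            locus, hap = cols[2], cols[3].strip().upper()
            haplotypes.setdefault(locus, []).append(hap)

    markers = []
    for locus in order:
        cols = sorted(snp_cols.get(locus, []))
        haps = haplotypes.get(locus, [])
        if not cols or not haps:
            continue  # monomorphic locus
        base = consensus[locus]
        seqs = set()
        for hap in haps:
            if len(hap) != len(cols) or set(hap) - set("ACGT"):
                warnings.warn(
                    f"{alleles_path}: locus {locus}: haplotype {hap!r} skipped"
                )
                continue
            chars = list(base)
            ok = True
            for nt, col in zip(hap, cols):
                if col >= len(chars):
                    warnings.warn(
                        f"{snps_path}: locus {locus}: SNP column {col} beyond "
                        "consensus length; haplotype skipped"
                    )
                    ok = False
                    break
                chars[col] = nt
            if ok:
                seqs.add("".join(chars))
        if len(seqs) < 2:
            continue
        markers.append(order_alleles(sorted(seqs), locus))
    if not markers:
        raise ValueError(f"{tags_path}: no polymorphic catalog loci found")
    _check_marker_names_unique(markers, tags_path)
    return TagSet(markers)


_PYRAD_LOCUS_NUM_RE = re.compile(r"\|(\d+)\|?\s*$")


def _read_pyrad_alleles(path) -> TagSet:
    """pyRAD ``.alleles``: blocks of ``>name  seq`` lines closed by ``//``.

    Gap characters (``-``) are deleted so the stored alleles are literal
    searchable sequences; indel alleles therefore differ in length.  Loci
    with more than :data:`MAX_ALLELES_PER_LOCUS` distinct alleles are
    dropped as likely paralog collapses.
    """
    markers = []
    current: list[str] = []
    counter = 0
    with open_text_auto(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("//"):
                counter += 1
                m = _PYRAD_LOCUS_NUM_RE.search(line)
                locus_id = m.group(1) if m else str(counter)
                name = f"L{locus_id}"
                seqs = set()
                for raw in current:
                    seq = raw.replace("-", "").upper()
                    if not seq or set(seq) - set("ACGT"):
                        warnings.warn(
                            f"{path}: locus {name}: allele with non-ACGT "
                            "characters skipped"
                        )
                        continue
                    seqs.add(seq)
                current = []
                if len(seqs) > MAX_ALLELES_PER_LOCUS:
                    warnings.warn(
                        f"{path}: locus {name} has {len(seqs)} distinct alleles "
                        f"(> {MAX_ALLELES_PER_LOCUS}); dropped as likely paralog"
                    )
                    continue
                if len(seqs) < 2:
                    continue
                markers.append(order_alleles(sorted(seqs), name))
            elif line.startswith(">"):
                parts = line[1:].split()
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected '>name sequence', got {line!r}"
                    )
                current.append(parts[1])
            else:
                raise ValueError(f"{path}:{lineno}: unexpected line {line!r}")
    if current:
        raise ValueError(f"{path}: final locus not terminated by '//'")
    if not markers:
        raise ValueError(f"{path}: no polymorphic loci found")
    _check_marker_names_unique(markers, path)
    return TagSet(markers)


_READERS = {
    "uneak_fasta": _read_uneak_fasta,
    "tassel_sam": _read_tassel_sam,
    "stacks_catalog": _read_stacks_catalog,
    "pyrad_alleles": _read_pyrad_alleles,
    "csv_two_tags": _read_csv_two_tags,
    "csv_one_per_row": _read_csv_one_per_row,
    "csv_merged": _read_csv_merged,
}


def read_tag_file(path, format: str, subset: MarkerSubset | None = None) -> TagSet:
    """Read a tag set in one of the seven supported dialects.

    ``subset``, if given, restricts the result to the named markers (see
    :func:`filter_markers`).
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(
            f"unknown tag format {format!r}; supported: {', '.join(TAG_FORMATS)}"
        ) from None
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tag file not found: {path}")
    tagset = reader(path)
    if subset is not None:
        tagset = filter_markers(tagset, subset)
    return tagset


def read_marker_subset(path) -> MarkerSubset:
    """Read a one-column CSV of marker names (header ``Marker name``
    optional)."""
    names: list[str] = []
    with open_text_auto(path) as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            names.append(row[0].strip())
    if names and names[0] == "Marker name":
        names = names[1:]
    return MarkerSubset(frozenset(names))


def filter_markers(tagset: TagSet, subset: MarkerSubset) -> TagSet:
    """Keep only markers named in ``subset``; warn for names not found."""
    present = {m.name for m in tagset.markers}
    for missing in sorted(subset.names - present):
        warnings.warn(f"marker {missing!r} in subset list not found in tag set")
    markers = [m for m in tagset.markers if m.name in subset.names]
    if not markers:
        warnings.warn("marker subset removed every marker from the tag set")
    original = None
    if tagset.original_names is not None:
        kept = {m.name for m in markers}
        original = {
            orig: name for orig, name in tagset.original_names.items() if name in kept
        }
    return TagSet(markers, original_names=original)


def sanitize_tag_set(tagset: TagSet) -> tuple[TagSet, DiscardReport]:
    """Drop every marker that shares an allele sequence with another marker.

    A shared sequence makes read attribution ambiguous for *all* markers
    involved, so all of them are removed and listed in the report.
    """
    owners: dict[str, list[int]] = {}
    for seq, (mi, _) in tagset.tag_entries():
        owners.setdefault(seq, []).append(mi)
    report = DiscardReport()
    doomed: set[int] = set()
    for seq, idxs in owners.items():
        if len(set(idxs)) > 1:
            for mi in set(idxs):
                doomed.add(mi)
                report.removed.setdefault(tagset.markers[mi].name, []).append(seq)
    for name in report.removed:
        report.removed[name].sort()
    markers = [m for i, m in enumerate(tagset.markers) if i not in doomed]
    original = None
    if tagset.original_names is not None:
        kept = {m.name for m in markers}
        original = {
            orig: name for orig, name in tagset.original_names.items() if name in kept
        }
    return TagSet(markers, original_names=original), report


def write_merged_csv(tagset: TagSet, path) -> None:
    """Write a tag set in the merged-CSV dialect (re-importable)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Marker name", "Tag sequence"])
        for marker in tagset.markers:
            if len(marker.alleles) < 2:
                raise ValueError(
                    f"marker {marker.name!r} has a single allele and cannot "
                    "be written in merged notation"
                )
            writer.writerow([marker.name, marker.merged().render()])
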