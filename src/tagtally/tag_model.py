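"""Core domain types for GBS/RAD-seq markers and allele tags.

A *tag* is the unique genomic sequence at the start of a sequencing read,
immediately following the sample barcode and the restriction cut-site
remnant.  A *marker* is a locus with one tag per allele.  Both (or all)
alleles of a marker can be written compactly in the bracketed merged
notation ``sharedPrefix[var0/var1]sharedSuffix``, which keeps the shared
sequence once and makes the polymorphic site easy to see by eye.

Sequences are plain Python strings over the uppercase alphabet A/C/G/T;
:func:`normalize_sequence` is the single choke point for validation, so
lowercase input is accepted everywhere and normalized on ingest.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "normalize_sequence",
    "MergedTag",
    "Marker",
    "TagSet",
    "merge_alleles",
    "merge_tags",
    "expand_merged",
    "order_alleles",
    "tag_column_name",
    "parse_tag_column_name",
]

VALID_BASES = frozenset("ACGT")

_MERGED_RE = re.compile(r"^([ACGT]*)\[([ACGT]*(?:/[ACGT]*)+)\]([ACGT]*)$")


def normalize_sequence(seq: str, *, where: str = "") -> str:
    """Uppercase ``seq`` and verify it is a non-empty A/C/G/T string.

    ``where`` is prepended to error messages so callers can report a file
    name and line number.
    """
    s = seq.strip().upper()
    loc = f"{where}: " if where else ""
    if not s:
        raise ValueError(f"{loc}empty sequence")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(
            f"{loc}sequence {s!r} contains illegal characters "
            f"{''.join(sorted(bad))!r} (allowed: A, C, G, T)"
        )
    return s


@dataclass(frozen=True)
class MergedTag:
    """All alleles of one marker in bracketed notation.

    ``prefix`` and ``suffix`` are shared by every allele; ``variants``
    holds the allele-specific middles, which may be empty strings when
    alleles differ in length (an indel renders as e.g. ``AC[G/]TT``).
    """

    prefix: str
    variants: tuple[str, ...]
    suffix: str

    def __post_init__(self) -> None:
        if len(self.variants) < 2:
            raise ValueError("a merged tag needs at least two variants")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError(f"duplicate variants in merged tag {self.render()!r}")

    def render(self) -> str:
        return f"{self.prefix}[{'/'.join(self.variants)}]{self.suffix}"

    def expand(self) -> list[str]:
        """Full allele sequences, one per variant, order preserved."""
        return [self.prefix + v + self.suffix for v in self.variants]

    @classmethod
    def parse(cls, text: str, *, where: str = "") -> "MergedTag":
        """Parse bracketed notation like ``ACAGACTT[A/T]GTACCCA``."""
        s = text.strip().upper()
        loc = f"{where}: " if where else ""
        m = _MERGED_RE.match(s)
        if m is None:
            raise ValueError(
                f"{loc}cannot parse merged tag {text!r}: expected "
                "prefix[var0/var1/...]suffix over A/C/G/T"
            )
        prefix, middle, suffix = m.groups()
        variants = tuple(middle.split("/"))
        merged = cls(prefix, variants, suffix)
        for seq in merged.expand():
            normalize_sequence(seq, where=where)
        return merged


def merge_alleles(tag0: str, tag1: str) -> MergedTag:
    """Merge two allele tags into bracketed notation.

    The shared prefix is maximal; the shared suffix is then maximal over
    what remains, so the variable middles are as short as possible.  For
    alleles of unequal length one middle may be empty.
    """
    return merge_tags([tag0, tag1])


def merge_tags(tags: list[str]) -> MergedTag:
    """Merge two or more allele tags; order of variants follows ``tags``."""
    seqs = [normalize_sequence(t) for t in tags]
    if len(seqs) < 2:
        raise ValueError("need at least two tags to merge")
    if len(set(seqs)) != len(seqs):
        raise ValueError("cannot merge identical tags: no variable site")
    # maximal shared prefix across all tags
    lcp = 0
    limit = min(len(s) for s in seqs)
    while lcp < limit and all(s[lcp] == seqs[0][lcp] for s in seqs):
        lcp += 1
    rests = [s[lcp:] for s in seqs]
    # maximal shared suffix of the remainders
    lcs = 0
    limit = min(len(r) for r in rests)
    while lcs < limit and all(r[-1 - lcs] == rests[0][-1 - lcs] for r in rests):
        lcs += 1
    suffix = rests[0][len(rests[0]) - lcs:] if lcs else ""
    variants = tuple(r[: len(r) - lcs] for r in rests)
    return MergedTag(seqs[0][:lcp], variants, suffix)


def expand_merged(merged: "MergedTag | str") -> list[str]:
    """Expand a merged tag (or its string rendering) to full sequences."""
    if isinstance(merged, str):
        merged = MergedTag.parse(merged)
    return merged.expand()


@dataclass(frozen=True)
class Marker:
    """One locus: a name and an ordered list of ``(allele_name, tag)``."""

    name: str
    alleles: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"marker {self.name!r} has no alleles")
        seqs = [seq for _, seq in self.alleles]
        if len(set(seqs)) != len(seqs):
            raise ValueError(f"marker {self.name!r} has duplicate allele sequences")

    @property
    def allele_names(self) -> list[str]:
        return [n for n, _ in self.alleles]

    @property
    def tags(self) -> list[str]:
        return [seq for _, seq in self.alleles]

    def merged(self) -> MergedTag:
        return merge_tags(self.tags)


def order_alleles(tags: list[str], name: str = "") -> Marker:
    """Build a marker with alleles sorted lexicographically.

    The alphabetically first tag becomes allele ``"0"``, the next ``"1"``,
    and so on.  Formats that name alleles explicitly bypass this and keep
    their own order.
    """
    seqs = sorted(normalize_sequence(t) for t in tags)
    if len(seqs) < 2:
        raise ValueError("order_alleles needs at least two distinct tags")
    if len(set(seqs)) != len(seqs):
        raise ValueError(f"duplicate tags for marker {name!r}")
    return Marker(name, tuple((str(i), s) for i, s in enumerate(seqs)))


def tag_column_name(marker: Marker, allele_index: int) -> str:
    """Column header for one allele: ``marker_variableBases_alleleName``.

    The variable-site nucleotides come from merging all of the marker's
    alleles; an empty variant (deletion allele) or a single-allele marker
    renders the middle field as ``"-"``.
    """
    allele_name = marker.alleles[allele_index][0]
    if len(marker.alleles) >= 2:
        var = marker.merged().variants[allele_index] or "-"
    else:
        var = "-"
    return f"{marker.name}_{var}_{allele_name}"


def parse_tag_column_name(column: str) -> tuple[str, str, str]:
    """Split a column header back into (marker, variable bases, allele name).

    Splits from the right, so marker names containing underscores are safe
    as long as allele names do not (true for all numerically named alleles).
    """
    parts = column.rsplit("_", 2)
    if len(parts) != 3 or not parts[0]:
        raise ValueError(f"cannot parse tag column name {column!r}")
    return parts[0], parts[1], parts[2]


@dataclass
class TagSet:
    """A searchable collection of markers.

    ``original_names`` is populated by the aligned-tag (SAM) reader: it maps
    the source pipeline's SNP/tag names to the position-based marker names
    used here, so a correspondence table can be exported.
    """

    markers: list[Marker] = field(default_factory=list)
    original_names: dict[str, str] | None = None

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def tag_entries(self) -> list[tuple[str, tuple[int, int]]]:
        """All ``(tag sequence, (marker index, allele index))`` pairs."""
        out = []
        for mi, marker in enumerate(self.markers):
            for ai, (_, seq) in enumerate(marker.alleles):
                out.append((seq, (mi, ai)))
        return out

    def lookup(self) -> dict[str, tuple[int, int]]:
        """Tag sequence -> (marker index, allele index); errors on collisions.

        A collision means the tag set was not sanitized: the same sequence
        would be attributable to more than one marker.
        """
        table: dict[str, tuple[int, int]] = {}
        for seq, where in self.tag_entries():
            if seq in table:
                other = self.markers[table[seq][0]].name
                mine = self.markers[where[0]].name
                raise ValueError(
                    f"tag sequence {seq!r} occurs in markers {other!r} and "
                    f"{mine!r}; sanitize the tag set first"
                )
            table[seq] = where
        return table

    def tag_column_names(self) -> list[str]:
        """Count-matrix column headers: markers in input order, alleles in order."""
        return [
            tag_column_name(m, ai)
            for m in self.markers
            for ai in range(len(m.alleles))
        ]
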