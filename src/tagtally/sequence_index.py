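"""Prefix-trie matching of reads to barcodes and tags.

The matching engine is a trie (prefix tree) over the expected sequences.
To classify a read we walk the trie from the read's first base, one
nucleotide per step; the walk stops at the first base with no child, so a
read that matches nothing is rejected after a handful of steps and the
number of steps for any read is bounded by the length of the longest
stored sequence — independent of how many sequences are stored.  That
bound is what makes exact matching against tens of thousands of 40–80 nt
tags cheap.

Only exact matches count: quality scores are ignored and any ``N`` (or
other non-ACGT symbol) in the read terminates the walk.  Sequence after
the end of the matched tag is ignored.

Adapter search runs in the opposite orientation — from the 3' end of the
read, where a read-through adapter may be truncated — and chimera
detection is a plain substring scan for full restriction sites.
"""

from __future__ import annotations

from typing import Any, Iterable

from .enzyme_registry import AdapterSet

__all__ = [
    "SequenceTrie",
    "build_trie",
    "match_read_start",
    "find_adapter_trim",
    "find_full_cut_site",
]

# Trie nodes are plain dicts: children under single-character keys
# 'A'/'C'/'G'/'T', terminal payload under the empty-string key (which can
# never collide with a base).
_TERM = ""


class SequenceTrie:
    """Trie over A/C/G/T strings with an opaque payload at each terminal.

    A node may be both a terminal and an internal node (one stored
    sequence may be a prefix of another); :meth:`match_prefix` resolves
    that by returning the deepest terminal reached.
    """

    __slots__ = ("_root", "depth", "_n")

    def __init__(self) -> None:
        self._root: dict = {}
        self.depth = 0  # length of the longest stored sequence
        self._n = 0

    def __len__(self) -> int:
        return self._n

    def insert(self, seq: str, payload: Any) -> None:
        if not seq:
            raise ValueError("cannot index an empty sequence")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"cannot index {seq!r}: illegal characters {bad}")
        node = self._root
        for ch in seq:
            node = node.setdefault(ch, {})
        if _TERM in node:
            if node[_TERM] != payload:
                raise ValueError(
                    f"sequence {seq!r} already indexed with a different payload"
                )
            return
        node[_TERM] = payload
        self._n += 1
        if len(seq) > self.depth:
            self.depth = len(seq)

    def get(self, seq: str, default: Any = None) -> Any:
        node = self._root
        for ch in seq:
            node = node.get(ch)
            if node is None:
                return default
        return node.get(_TERM, default)

    def __contains__(self, seq: str) -> bool:
        sentinel = object()
        return self.get(seq, sentinel) is not sentinel

    def match_prefix(self, read: str, start: int = 0):
        """Longest stored sequence that prefixes ``read[start:]``.

        Returns ``(payload, consumed)`` where ``consumed`` counts bases
        from ``start``, or ``None`` if no stored sequence matches.
        """
        node = self._root
        best = None
        i = start
        n = len(read)
        while i < n:
            node = node.get(read[i])
            if node is None:
                break
            i += 1
            if _TERM in node:
                best = (node[_TERM], i - start)
        return best

    def walk_steps(self, read: str, start: int = 0) -> tuple[Any, int]:
        """Match result plus the number of bases examined during the walk.

        One step is one base looked at; the walk aborts on the first base
        with no matching child, so the count is bounded by :attr:`depth`
        for every possible read.  Returns ``(match, steps)`` where
        ``match`` is as in :meth:`match_prefix`.
        """
        node = self._root
        best = None
        steps = 0
        i = start
        n = len(read)
        while i < n:
            n_children = len(node) - (1 if _TERM in node else 0)
            if n_children == 0:
                break  # leaf: no base comparison needed
            child = node.get(read[i])
            steps += 1
            if child is None:
                break
            node = child
            i += 1
            if _TERM in node:
                best = (node[_TERM], i - start)
        return best, steps


def build_trie(entries: Iterable[tuple[str, Any]]) -> SequenceTrie:
    """Index ``(sequence, payload)`` pairs; sequences must be unique
    (re-inserting the same sequence with an equal payload is a no-op,
    a conflicting payload is an error)."""
    trie = SequenceTrie()
    for seq, payload in entries:
        trie.insert(seq, payload)
    return trie


def match_read_start(trie: SequenceTrie, read: str):
    """Module-level alias for :meth:`SequenceTrie.match_prefix` at 0."""
    return trie.match_prefix(read, 0)


def find_adapter_trim(read: str, adapters: AdapterSet, min_overlap: int = 6):
    """Position at which 3' adapter sequence begins, or ``None``.

    Returns the smallest ``p`` such that ``read[p:]`` is a prefix of one
    of the adapter sequences with at least ``min_overlap`` bases of
    overlap, or such that a complete adapter occurs at ``p``.  Everything
    from ``p`` on should be trimmed.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n = len(read)
    for p in range(0, n - min_overlap + 1):
        tail = n - p
        for adapter in adapters.sequences:
            k = min(tail, len(adapter))
            if read[p:p + k] == adapter[:k]:
                return p
    return None


def find_full_cut_site(read: str, sites: Iterable[str], search_from: int = 0):
    """Leftmost occurrence of any full restriction site at index >=
    ``search_from``, or ``None``."""
    if search_from < 0:
        raise ValueError("search_from must be >= 0")
    best = None
    for site in sites:
        pos = read.find(site, search_from)
        if pos != -1 and (best is None or pos < best):
            best = pos
    return best
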