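"""Restriction enzymes and sequencing adapters known to the pipeline.

The tables at the top of this file are the registry: adding support for a
new enzyme or adapter chemistry means adding one entry here and nothing
else.  For each enzyme the record stores

* ``remnant_variants`` — the cut-site remnant expected immediately after
  the sample barcode at the start of every read.  Enzymes with a variable
  base in the recognition site (ApeKI: G^CWGC) have one entry per
  expansion, and their tags are conventionally stored *including* the
  remnant, flagged by ``tags_include_remnant``.
* ``full_sites`` — complete recognition sites scanned for *inside* reads.
  A full site mid-read suggests a chimera of two re-ligated fragments, so
  sequence after it is untrustworthy.  For double digests both
  reconstituted sites are listed; PstI/NsiI 3' overhangs are incompatible
  with the MspI 5' overhang, so no hybrid junction site exists for the
  shipped pairs.

Remnants derive from the published recognition sites: PstI CTGCA^G leaves
TGCAG after the barcode, NsiI ATGCA^T leaves TGCAT, ApeKI G^CWGC leaves
CAGC or CTGC.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Enzyme", "AdapterSet", "get_enzyme", "get_adapter_set",
           "register_enzyme", "register_adapter_set", "ENZYMES", "ADAPTERS"]


@dataclass(frozen=True)
class Enzyme:
    name: str
    remnant_variants: tuple[str, ...]
    full_sites: tuple[str, ...]
    tags_include_remnant: bool

    def __post_init__(self) -> None:
        if not self.remnant_variants:
            raise ValueError(f"enzyme {self.name!r} has no remnant variants")
        for seq in self.remnant_variants + self.full_sites:
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"enzyme {self.name!r}: bad sequence {seq!r}")
        if self.tags_include_remnant != (len(self.remnant_variants) > 1):
            raise ValueError(
                f"enzyme {self.name!r}: tags_include_remnant must be set "
                "exactly when the cut site is variable (>1 remnant)"
            )


@dataclass(frozen=True)
class AdapterSet:
    """Adapter sequences searched from the 3' end of reads."""

    name: str
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"adapter set {self.name!r} is empty")


# --- the registry ---------------------------------------------------------

ENZYMES: dict[str, Enzyme] = {}
ADAPTERS: dict[str, AdapterSet] = {}


def register_enzyme(enzyme: Enzyme) -> Enzyme:
    ENZYMES[enzyme.name] = enzyme
    return enzyme


def register_adapter_set(adapters: AdapterSet) -> AdapterSet:
    ADAPTERS[adapters.name] = adapters
    return adapters


register_enzyme(Enzyme(
    name="PstI-MspI",
    remnant_variants=("TGCAG",),
    full_sites=("CTGCAG", "CCGG"),
    tags_include_remnant=False,
))
register_enzyme(Enzyme(
    name="NsiI-MspI",
    remnant_variants=("TGCAT",),
    full_sites=("ATGCAT", "CCGG"),
    tags_include_remnant=False,
))
register_enzyme(Enzyme(
    name="ApeKI",
    remnant_variants=("CAGC", "CTGC"),
    full_sites=("GCAGC", "GCTGC"),
    tags_include_remnant=True,
))

# Illumina universal adapter start, as read through from the 3' end of
# short inserts; one chemistry ships by default.
register_adapter_set(AdapterSet(
    name="TruSeq",
    sequences=("AGATCGGAAGAGC",),
))

DEFAULT_ADAPTER_SET = "TruSeq"


def get_enzyme(name: str) -> Enzyme:
    """Look up an enzyme; unknown names list what is registered."""
    try:
        return ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; registered enzymes: "
            + ", ".join(sorted(ENZYMES))
        ) from None


def get_adapter_set(name: str) -> AdapterSet:
    try:
        return ADAPTERS[name]
    except KeyError:
        raise KeyError(
            f"unknown adapter set {name!r}; registered adapter sets: "
            + ", ".join(sorted(ADAPTERS))
        ) from None
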