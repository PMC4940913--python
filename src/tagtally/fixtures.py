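"""Seeded synthetic multiplexed FASTQ with exact planted ground truth.

The generator emulates a single-end GBS/RAD-seq lane: every read is
``barcode + cut-site remnant + allele tag + 3' context``, where the 3'
context is random filler, a truncated adapter read-through, or a full
restriction site followed by decoy sequence (a chimera).  Barcodes have
mixed lengths, read depth per (sample, tag) cell is drawn from a
negative-binomial-shaped distribution to mimic the strong depth
heterogeneity of real GBS lanes, and substitution errors are injected at
a per-base rate.

The construction guarantees make the truth tables *exact* rather than
approximate:

* barcode+remnant strings and tag strings are each prefix-free sets, so
  every clean read has exactly one valid interpretation;
* tags never contain a full restriction site or adapter prefix, and never
  end with the first bases of an adapter, so trimming can never cut into
  the tag region of a read;
* a read with injected errors is re-randomized until it does not spell
  out any *other* registered barcode+remnant+tag combination — errors can
  lose a read, never re-assign it.

Every read's intended (sample, tag) cell, its planted 3' context and
whether it should survive matching are recorded, so the expected counts
matrix and demultiplexing tallies are known cell-for-cell.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .enzyme_registry import (
    AdapterSet,
    Enzyme,
    get_adapter_set,
    get_enzyme,
)
from .read_counter import CountsMatrix
from .tag_io import write_merged_csv
from .tag_model import TagSet, order_alleles

__all__ = ["FixtureSpec", "ReadLabel", "FixtureResult", "generate_fixture"]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic lane.

    Defaults describe a full-size lane slice: 96 mixed-length barcodes,
    1000 biallelic markers with 40-80 nt tags, about two hundred thousand
    reads in total, mild adapter read-through and chimera contamination,
    and a typical Illumina substitution error rate.
    """

    n_samples: int = 96
    n_markers: int = 1000
    barcode_lengths: tuple[int, int] = (4, 8)
    tag_length: tuple[int, int] = (40, 80)
    enzyme_name: str = "PstI-MspI"
    adapter_set_name: str = "TruSeq"
    reads_per_cell_mean: float = 1.0
    reads_per_cell_dispersion: float = 0.5
    error_rate: float = 0.001
    adapter_readthrough_fraction: float = 0.05
    chimera_fraction: float = 0.02
    read_length: int = 100
    min_adapter_overlap: int = 6
    gzip_fastq: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.error_rate,
            self.adapter_readthrough_fraction,
            self.chimera_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.adapter_readthrough_fraction + self.chimera_fraction > 1.0:
            raise ValueError("adapter and chimera fractions sum above 1")
        if self.n_samples < 1 or self.n_markers < 1:
            raise ValueError("need at least one sample and one marker")
        lo, hi = self.tag_length
        if lo < 10 or hi < lo:
            raise ValueError("tag_length range must be sane and >= 10")
        # distinct-sequence capacity is astronomical for >=10 nt tags, but
        # reject specs that could not possibly be satisfied
        if 2 * self.n_markers > 4 ** lo:
            raise ValueError("more tags requested than distinct sequences exist")


@dataclass(frozen=True)
class ReadLabel:
    """Ground truth for one read, in FASTQ output order."""

    sample_index: int
    column_index: int  # counts-matrix column (marker x allele)
    kind: str  # "normal" | "adapter" | "chimera"
    has_errors: bool
    survives: bool  # should be counted for its intended cell
    barcode_index: int | None  # barcode whose output file receives the read


@dataclass
class FixtureResult:
    fastq_path: Path
    key_path: Path
    split_key_path: Path
    tag_path: Path
    split_dir: Path
    samples: list[str]
    barcodes: list[str]
    tagset: TagSet
    truth_counts: CountsMatrix
    truth_split_written: dict[str, int]  # output path -> expected reads
    truth_split_unmatched: int
    labels: list[ReadLabel]

    @property
    def n_reads(self) -> int:
        return len(self.labels)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _region_clean(
    region: str, enzyme: Enzyme, adapters: AdapterSet, min_overlap: int
) -> bool:
    """True if trimming could never cut inside ``region`` (remnant+tag)."""
    for site in enzyme.full_sites:
        if site in region:
            return False
    for adapter in adapters.sequences:
        if adapter[:min_overlap] in region:
            return False
        for q in range(1, min_overlap):
            if region.endswith(adapter[:q]):
                return False
    return True


def _prefix_free_insert(sorted_list: list[str], candidate: str) -> bool:
    """Insert ``candidate`` keeping the list sorted iff no element is a
    prefix of another afterwards; returns whether it was inserted."""
    i = bisect.bisect_left(sorted_list, candidate)
    if i > 0 and candidate.startswith(sorted_list[i - 1]):
        return False
    if i < len(sorted_list) and sorted_list[i].startswith(candidate):
        return False
    sorted_list.insert(i, candidate)
    return True


def _make_barcodes(
    rng: np.random.Generator, spec: FixtureSpec, enzyme: Enzyme
) -> list[str]:
    lo, hi = spec.barcode_lengths
    barcodes: list[str] = []
    combo_keys: list[str] = []  # barcode+remnant strings, kept prefix-free
    attempts = 0
    while len(barcodes) < spec.n_samples:
        attempts += 1
        if attempts > 1000 * spec.n_samples:
            raise RuntimeError("could not generate a prefix-free barcode set")
        length = int(rng.integers(lo, hi + 1))
        bc = _random_bases(rng, length)
        keys = [bc + r for r in enzyme.remnant_variants]
        snapshot = list(combo_keys)
        if all(_prefix_free_insert(snapshot, k) for k in keys):
            combo_keys = snapshot
            barcodes.append(bc)
    return barcodes


def _make_markers(
    rng: np.random.Generator,
    spec: FixtureSpec,
    enzyme: Enzyme,
    adapters: AdapterSet,
) -> TagSet:
    """Biallelic markers with one substitution site per tag pair."""
    lo, hi = spec.tag_length
    remnants = enzyme.remnant_variants
    markers = []
    stored: list[str] = []  # tags as stored/searched, kept prefix-free
    width = len(str(spec.n_markers))
    attempts = 0
    while len(markers) < spec.n_markers:
        attempts += 1
        if attempts > 1000 * spec.n_markers:
            raise RuntimeError("could not generate a clean prefix-free tag set")
        length = int(rng.integers(lo, hi + 1))
        core = _random_bases(rng, length)
        if enzyme.tags_include_remnant:
            remnant = remnants[rng.integers(0, len(remnants))]
            ref = remnant + core
            snp_lo = len(remnant)
        else:
            ref = core
            snp_lo = 0
        pos = int(rng.integers(snp_lo, len(ref)))
        alt_base = _BASES[
            ( _BASES.index(ref[pos]) + int(rng.integers(1, 4)) ) % 4
        ]
        alt = ref[:pos] + alt_base + ref[pos + 1:]
        ok = True
        for tag in (ref, alt):
            regions = (
                [tag] if enzyme.tags_include_remnant
                else [r + tag for r in remnants]
            )
            if not all(
                _region_clean(rg, enzyme, adapters, spec.min_adapter_overlap)
                for rg in regions
            ):
                ok = False
                break
        if not ok:
            continue
        snapshot = list(stored)
        if not (_prefix_free_insert(snapshot, ref)
                and _prefix_free_insert(snapshot, alt)):
            continue
        stored = snapshot
        name = f"M{len(markers) + 1:0{width}d}"
        markers.append(order_alleles([ref, alt], name))
    return TagSet(markers)


class _NaiveAssigner:
    """Trie-free interpretation of a read against the registered dictionary.

    Both the barcode+remnant strings and the tag strings are prefix-free
    sets, so for any read the only candidate match is the sorted
    predecessor of the read (respectively of its tag region), found by
    binary search and confirmed with a direct string comparison.  Used to
    validate erroneous reads and assign truth labels independently of the
    matching trie.
    """

    def __init__(self, combos, tag_of_col):
        # combos: (barcode+remnant, tag_start, barcode_index)
        self._combos = sorted(combos)
        self._combo_keys = [c[0] for c in self._combos]
        self._tags = sorted(
            (tag, ci) for ci, tag in enumerate(tag_of_col)
        )
        self._tag_keys = [t for t, _ in self._tags]

    def __call__(self, read):
        """(barcode index or None, column index or None) for ``read``."""
        i = bisect.bisect_right(self._combo_keys, read)
        if i == 0 or not read.startswith(self._combo_keys[i - 1]):
            return None, None
        _, tag_start, bi = self._combos[i - 1]
        rest = read[tag_start:]
        j = bisect.bisect_right(self._tag_keys, rest)
        if j == 0 or not rest.startswith(self._tag_keys[j - 1]):
            return bi, None
        return bi, self._tags[j - 1][1]


def generate_fixture(spec: FixtureSpec, outdir) -> FixtureResult:
    """Write FASTQ, key files and tag file under ``outdir``; return truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    enzyme = get_enzyme(spec.enzyme_name)
    adapters = get_adapter_set(spec.adapter_set_name)

    barcodes = _make_barcodes(rng, spec, enzyme)
    tagset = _make_markers(rng, spec, enzyme, adapters)
    sw = len(str(spec.n_samples))
    samples = [f"S{i + 1:0{sw}d}" for i in range(spec.n_samples)]

    # tags laid out in counts-matrix column order
    tag_of_col = [seq for seq, _ in tagset.tag_entries()]
    n_cols = len(tag_of_col)

    # one barcode per sample; combos for the naive validity check
    combos = []
    for bi, bc in enumerate(barcodes):
        for remnant in enzyme.remnant_variants:
            tag_start = (
                len(bc) if enzyme.tags_include_remnant else len(bc) + len(remnant)
            )
            combos.append((bc + remnant, tag_start, bi))

    m = spec.reads_per_cell_mean
    r = spec.reads_per_cell_dispersion
    depth = rng.negative_binomial(
        r, r / (r + m), size=(spec.n_samples, n_cols)
    )

    naive = _NaiveAssigner(combos, tag_of_col)
    adapter_seq = adapters.sequences[0]
    sites = enzyme.full_sites
    p_chim = spec.chimera_fraction
    p_adap = spec.adapter_readthrough_fraction

    reads: list[tuple[str, ReadLabel]] = []
    truth = np.zeros((spec.n_samples, n_cols), dtype=np.int64)
    split_counts = np.zeros(spec.n_samples, dtype=np.int64)
    n_unmatched_split = 0

    for si in range(spec.n_samples):
        bc = barcodes[si]
        for ci in range(n_cols):
            tag = tag_of_col[ci]
            if enzyme.tags_include_remnant:
                core = bc + tag
            else:
                remnant = enzyme.remnant_variants[0]
                core = bc + remnant + tag
            fill_len = max(spec.read_length - len(core), 10)
            for _ in range(int(depth[si, ci])):
                u = rng.random()
                if u < p_chim:
                    kind = "chimera"
                    site = sites[int(rng.integers(0, len(sites)))]
                    decoy = _random_bases(rng, max(fill_len - len(site), 6))
                    read = core + site + decoy
                elif u < p_chim + p_adap:
                    kind = "adapter"
                    k = int(rng.integers(
                        spec.min_adapter_overlap, len(adapter_seq) + 1
                    ))
                    read = core + adapter_seq[:k]
                else:
                    kind = "normal"
                    read = core + _random_bases(rng, fill_len)

                has_errors = False
                nb, nc = si, ci
                if spec.error_rate > 0:
                    n_err = int(rng.binomial(len(read), spec.error_rate))
                    if n_err > 0:
                        has_errors = True
                        for _attempt in range(100):
                            chars = list(read)
                            for p in rng.choice(
                                len(read), size=n_err, replace=False
                            ):
                                chars[p] = _BASES[
                                    (_BASES.index(chars[p])
                                     + int(rng.integers(1, 4))) % 4
                                ]
                            mutated = "".join(chars)
                            nb, nc = naive(mutated)
                            if (nb, nc) == (si, ci) or nc is None:
                                break
                        else:
                            raise RuntimeError(
                                "could not inject errors without creating a "
                                "different valid read"
                            )
                        read = mutated
                survives = (nb, nc) == (si, ci)
                if survives:
                    truth[si, ci] += 1
                if nb is not None:
                    split_counts[nb] += 1
                else:
                    n_unmatched_split += 1
                reads.append(
                    (read, ReadLabel(si, ci, kind, has_errors, survives, nb))
                )

    order = rng.permutation(len(reads))
    fastq_name = "lane.fastq.gz" if spec.gzip_fastq else "lane.fastq"
    fastq_path = outdir / fastq_name
    from .fastq import open_text_auto

    with open_text_auto(fastq_path, "wt") as fh:
        for out_i, idx in enumerate(order):
            read, _ = reads[idx]
            fh.write(f"@F{out_i:07d}\n{read}\n+\n{'I' * len(read)}\n")
    labels = [reads[idx][1] for idx in order]

    key_path = outdir / "key.csv"
    with open(key_path, "w", newline="") as fh:
        fh.write("File,Barcode,Sample\n")
        for bc, sample in zip(barcodes, samples):
            fh.write(f"{fastq_path},{bc},{sample}\n")

    split_dir = outdir / "split"
    split_key_path = outdir / "split_key.csv"
    out_paths = [str(split_dir / f"{s}.fastq") for s in samples]
    with open(split_key_path, "w", newline="") as fh:
        fh.write("Input File,Barcode,Output File\n")
        for bc, out in zip(barcodes, out_paths):
            fh.write(f"{fastq_path},{bc},{out}\n")

    tag_path = outdir / "tags.csv"
    write_merged_csv(tagset, tag_path)

    n_matched = int(truth.sum())
    truth_counts = CountsMatrix(
        samples=samples,
        tag_names=tagset.tag_column_names(),
        counts=truth,
        file_tallies={str(fastq_path): (n_matched, len(reads) - n_matched)},
    )
    truth_split_written = {
        out: int(split_counts[i]) for i, out in enumerate(out_paths)
    }
    return FixtureResult(
        fastq_path=fastq_path,
        key_path=key_path,
        split_key_path=split_key_path,
        tag_path=tag_path,
        split_dir=split_dir,
        samples=samples,
        barcodes=barcodes,
        tagset=tagset,
        truth_counts=truth_counts,
        truth_split_written=truth_split_written,
        truth_split_unmatched=n_unmatched_split,
        labels=labels,
    )
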