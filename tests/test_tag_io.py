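"""The seven tag-set dialects, marker subsetting and sanitization."""

import random
import warnings

import pytest

from tagtally.tag_io import (
    MarkerSubset,
    filter_markers,
    read_marker_subset,
    read_tag_file,
    sanitize_tag_set,
    write_merged_csv,
)
from tagtally.tag_model import Marker, TagSet, order_alleles


def marker_content(tagset):
    """Name -> set of allele sequences, ignoring allele order."""
    return {m.name: frozenset(m.tags) for m in tagset.markers}


# --- builders for tiny dialect files --------------------------------------

def write_csv_merged(path):
    path.write_text(
        "Marker name,Tag sequence\n"
        "M1,CCGATTAG[C/T]AGGGGTT\n"
        "M2,ACAGACTT[A/T]GTACCCA\n"
        "M3,AC[G/]TTCCAA\n"
    )


def write_csv_two_tags(path):
    # tag 0 comes alphabetically AFTER tag 1: this format keeps user order
    path.write_text(
        "Marker name,Tag sequence 0,Tag sequence 1\n"
        "M1,TTGATTAGCAGG,ATGATTAGCAGG\n"
    )


def write_csv_one_per_row(path):
    path.write_text(
        "Marker name,Allele name,Tag sequence\n"
        "M1,ref,ACGTACGTAC\n"
        "M1,alt,ACGTACCTAC\n"
        "M1,rare,ACGTACTTAC\n"
        "M2,x,GGGGCCCCAA\n"
        "M2,y,GGGGCCCCAT\n"
    )


def write_uneak_fasta(path):
    pad = "A" * 64
    path.write_text(
        f">TP1_query_10\n{('ACGTACGTAC' + pad)[:64]}\n"
        f">TP1_hit_10\n{('ACGTACGTAT' + pad)[:64]}\n"
        f">TP2_query_12\n{('GGCCGGCCAAGG' + pad)[:64]}\n"
        f">TP2_hit_12\n{('GGCCGGCCTAGG' + pad)[:64]}\n"
    )


def write_tassel_sam(path):
    # two alleles aligned forward at chr1:101; two aligned reverse at
    # chr1:500 (stored reference-orientation, so the reader must
    # reverse-complement them back); one unmapped record to skip
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        "@SQ\tSN:chr1\tLN:10000",
        "S1_101a\t0\tchr1\t101\t60\t10M\t*\t0\t0\tACGTACGTAA\t*",
        "S1_101b\t0\tchr1\t101\t60\t10M\t*\t0\t0\tACGTACGTAG\t*",
        "S1_500a\t16\tchr1\t500\t60\t10M\t*\t0\t0\tTTTTACGCGT\t*",
        "S1_500b\t16\tchr1\t500\t60\t10M\t*\t0\t0\tTTTAACGCGT\t*",
        "S1_901\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*",
    ]
    path.write_text("\n".join(lines) + "\n")


def write_stacks_catalog(dirpath):
    tags = dirpath / "batch_1.catalog.tags.tsv"
    snps = dirpath / "batch_1.catalog.snps.tsv"
    alleles = dirpath / "batch_1.catalog.alleles.tsv"
    tags.write_text(
        "0\t0\t1\tchr1\t100\t+\tconsensus\t0\t1_1\tACGTACGTAC\t0\t0\t0\n"
        "1\t0\t2\tchr1\t200\t+\tconsensus\t0\t2_1\tGGTTGGTTGG\t0\t0\t0\n"
    )
    snps.write_text(
        "0\t0\t1\t4\tE\t0.0\tA\tC\n"
        "0\t0\t1\t8\tE\t0.0\tA\tT\n"
        "1\t0\t2\t2\tE\t0.0\tT\tA\n"
    )
    alleles.write_text(
        "0\t0\t1\tAA\t50.0\t10\n"
        "0\t0\t1\tCT\t50.0\t12\n"
        "1\t0\t2\tT\t60.0\t9\n"
        "1\t0\t2\tA\t40.0\t6\n"
    )
    return tags


def write_pyrad_alleles(path):
    pairs = ["AA", "AC", "AG", "AT", "CA", "CC", "CG", "CT", "GA"]
    big = "\n".join(f">big_{i}\tACGTACG{p}" for i, p in enumerate(pairs))
    path.write_text(
        ">1A_0\tACGTAC-GTT\n"
        ">1A_1\tACGTACCGTT\n"
        ">1B_0\tACGTAC-GTT\n"
        "//          -     |1|\n"
        ">2A_0\tAAAATTTTGG\n"
        ">2A_1\tAAAATTTTGG\n"
        "//                |2|\n"
        f"{big}\n"
        "//                |3|\n"
    )


class TestCsvDialects:
    def test_merged_rows_expand_to_markers(self, tmp_path):
        f = tmp_path / "tags.csv"
        write_csv_merged(f)
        ts = read_tag_file(f, "csv_merged")
        assert marker_content(ts) == {
            "M1": frozenset({"CCGATTAGCAGGGGTT", "CCGATTAGTAGGGGTT"}),
            "M2": frozenset({"ACAGACTTAGTACCCA", "ACAGACTTTGTACCCA"}),
            "M3": frozenset({"ACGTTCCAA", "ACTTCCAA"}),
        }
        # alphabetical allele order
        assert ts.markers[0].alleles[0] == ("0", "CCGATTAGCAGGGGTT")

    def test_two_tags_keeps_user_allele_order(self, tmp_path):
        f = tmp_path / "tags.csv"
        write_csv_two_tags(f)
        ts = read_tag_file(f, "csv_two_tags")
        assert ts.markers[0].alleles == (
            ("0", "TTGATTAGCAGG"), ("1", "ATGATTAGCAGG"),
        )

    def test_one_per_row_allows_non_biallelic_verbatim_names(self, tmp_path):
        f = tmp_path / "tags.csv"
        write_csv_one_per_row(f)
        ts = read_tag_file(f, "csv_one_per_row")
        assert ts.markers[0].allele_names == ["ref", "alt", "rare"]
        assert len(ts.markers[0].alleles) == 3

    def test_missing_header_named_in_error(self, tmp_path):
        f = tmp_path / "tags.csv"
        f.write_text("Name,Sequence\nM1,ACGT\n")
        with pytest.raises(ValueError, match="'Marker name'"):
            read_tag_file(f, "csv_merged")

    def test_illegal_sequence_reports_line_number(self, tmp_path):
        f = tmp_path / "tags.csv"
        f.write_text(
            "Marker name,Tag sequence 0,Tag sequence 1\n"
            "M1,ACGTACGT,ACGXACGT\n"
        )
        with pytest.raises(ValueError, match=":2"):
            read_tag_file(f, "csv_two_tags")

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "tags.csv"
        f.write_text("Marker name,Tag sequence\n")
        with pytest.raises(ValueError, match="no markers"):
            read_tag_file(f, "csv_merged")

    def test_unknown_format_rejected(self, tmp_path):
        f = tmp_path / "tags.csv"
        write_csv_merged(f)
        with pytest.raises(ValueError, match="unknown tag format"):
            read_tag_file(f, "nope")


class TestPipelineDialects:
    def test_uneak_fasta_truncates_padding_and_pairs_tags(self, tmp_path):
        f = tmp_path / "pairs.fasta"
        write_uneak_fasta(f)
        ts = read_tag_file(f, "uneak_fasta")
        assert marker_content(ts) == {
            "TP1": frozenset({"ACGTACGTAC", "ACGTACGTAT"}),
            "TP2": frozenset({"GGCCGGCCAAGG", "GGCCGGCCTAGG"}),
        }

    def test_tassel_sam_groups_by_coordinate(self, tmp_path):
        f = tmp_path / "tags.sam"
        write_tassel_sam(f)
        ts = read_tag_file(f, "tassel_sam")
        content = marker_content(ts)
        assert content["chr1-101"] == frozenset({"ACGTACGTAA", "ACGTACGTAG"})
        # reverse-strand records come back in read orientation
        assert content["chr1-500"] == frozenset({"ACGCGTAAAA", "ACGCGTTAAA"})
        assert ts.original_names["S1_101a"] == "chr1-101"
        assert ts.original_names["S1_500b"] == "chr1-500"
        assert "S1_901" not in ts.original_names  # unmapped skipped

    def test_stacks_catalog_reconstructs_haplotypes(self, tmp_path):
        tags = write_stacks_catalog(tmp_path)
        ts = read_tag_file(tags, "stacks_catalog")
        assert marker_content(ts) == {
            "1": frozenset({"ACGTACGTAC", "ACGTCCGTTC"}),
            "2": frozenset({"GGTTGGTTGG", "GGATGGTTGG"}),
        }

    def test_pyrad_alleles_strips_gaps_and_caps_paralogs(self, tmp_path):
        f = tmp_path / "loci.alleles"
        write_pyrad_alleles(f)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ts = read_tag_file(f, "pyrad_alleles")
        assert marker_content(ts) == {
            "L1": frozenset({"ACGTACGTT", "ACGTACCGTT"}),
        }
        assert any("paralog" in str(w.message) for w in caught)


class TestSubsetAndSanitize:
    def make_tagset(self):
        return TagSet([
            order_alleles(["ACGTAA", "ACGTAT"], "M1"),
            order_alleles(["CCGTAA", "CCGTAT"], "M2"),
            order_alleles(["GGGTAA", "GGGTAT"], "M3"),
        ])

    def test_filter_keeps_named_markers_in_order(self):
        ts = filter_markers(self.make_tagset(), MarkerSubset(frozenset({"M3", "M1"})))
        assert ts.marker_names() == ["M1", "M3"]

    def test_filter_warns_for_unknown_names(self):
        subset = MarkerSubset(frozenset({"M1", "X1", "X2", "X3"}))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ts = filter_markers(self.make_tagset(), subset)
        assert ts.marker_names() == ["M1"]
        assert sum("not found" in str(w.message) for w in caught) == 3

    def test_empty_subset_warns_and_empties(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ts = filter_markers(self.make_tagset(), MarkerSubset(frozenset()))
        assert len(ts) == 0
        assert any("every marker" in str(w.message) for w in caught)

    def test_subset_file_roundtrip(self, tmp_path):
        f = tmp_path / "subset.csv"
        f.write_text("Marker name\nM1\nM3\n")
        assert read_marker_subset(f).names == frozenset({"M1", "M3"})

    def test_shared_allele_removes_both_markers(self):
        ts = TagSet([
            Marker("M1", (("0", "ACGT"), ("1", "ACGG"))),
            Marker("M2", (("0", "ACGT"), ("1", "TTTT"))),
            Marker("M3", (("0", "CCCC"), ("1", "GGGG"))),
        ])
        clean, report = sanitize_tag_set(ts)
        assert clean.marker_names() == ["M3"]
        assert set(report.removed) == {"M1", "M2"}
        assert report.removed["M1"] == ["ACGT"]
        clean.lookup()  # injective after sanitization

    def test_disjoint_sets_untouched(self):
        ts = self.make_tagset()
        clean, report = sanitize_tag_set(ts)
        assert clean.marker_names() == ts.marker_names()
        assert len(report) == 0

    def test_planted_collisions_match_brute_force(self):
        """Removed markers equal the all-against-all pairwise overlap set."""
        rng = random.Random(11)
        for _ in range(10):
            markers = []
            seqs = set()
            for i in range(40):
                while True:
                    a = "".join(rng.choice("ACGT") for _ in range(12))
                    b = a[:6] + ("A" if a[6] != "A" else "C") + a[7:]
                    if a not in seqs and b not in seqs and a != b:
                        break
                seqs |= {a, b}
                markers.append(order_alleles([a, b], f"M{i}"))
            # plant collisions: some markers reuse an earlier allele
            k = rng.randint(1, 5)
            for j in range(k):
                victim = markers[rng.randrange(len(markers))]
                shared = victim.tags[0]
                other = "".join(rng.choice("ACGT") for _ in range(12))
                if other in seqs or other == shared:
                    continue
                markers.append(order_alleles([shared, other], f"C{j}"))
            ts = TagSet(markers)
            clean, report = sanitize_tag_set(ts)
            # brute-force oracle
            expected = set()
            for i, mi in enumerate(markers):
                for j, mj in enumerate(markers):
                    if i != j and set(mi.tags) & set(mj.tags):
                        expected.add(mi.name)
            assert set(report.removed) == expected
            assert {m.name for m in clean.markers} == {
                m.name for m in markers
            } - expected


class TestRoundTrips:
    @pytest.mark.parametrize(
        "builder, fmt",
        [
            (write_csv_merged, "csv_merged"),
            (write_csv_two_tags, "csv_two_tags"),
            (write_csv_one_per_row, "csv_one_per_row"),
            (write_uneak_fasta, "uneak_fasta"),
            (write_tassel_sam, "tassel_sam"),
            (write_pyrad_alleles, "pyrad_alleles"),
        ],
    )
    def test_every_reader_roundtrips_through_merged_csv(
        self, tmp_path, builder, fmt
    ):
        src = tmp_path / "src.dat"
        builder(src)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = read_tag_file(src, fmt)
        out = tmp_path / "merged.csv"
        write_merged_csv(ts, out)
        ts2 = read_tag_file(out, "csv_merged")
        assert marker_content(ts2) == marker_content(ts)

    def test_stacks_roundtrip(self, tmp_path):
        tags = write_stacks_catalog(tmp_path)
        ts = read_tag_file(tags, "stacks_catalog")
        out = tmp_path / "merged.csv"
        write_merged_csv(ts, out)
        assert marker_content(read_tag_file(out, "csv_merged")) == marker_content(ts)
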