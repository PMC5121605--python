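"""SAM ingestion, toy mapper, MapQ/duplicate filters and rate tables."""
import pytest

from charauth.mapping_filter import (
    Alignment,
    filter_mapq,
    group_average,
    load_library_metadata,
    mapping_rate_table,
    parse_sam,
    remove_duplicates,
    toy_map,
)
from charauth.preprocess import ReadRecord
from charauth.seqs import revcomp
from charauth.synthetic_data import GenomeSet, generate_genomes

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"


def aln(read_id="r", lib="l", gid="g", start=0, strand="+", mapq=30,
        length=50, mism=(), bqs=0):
    return Alignment(read_id, lib, gid, start, strand, mapq, length,
                     tuple(mism), bqs)


class TestParseSam:
    def test_crafted_records(self, tmp_path):
        sam = SAM_HEADER + "\n".join(
            [
                # unmapped -> dropped
                "u1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tFFFF",
                # forward, 1-based pos 100 -> start 99, MD mismatch at qpos 2
                "m1\t0\tchr1\t100\t37\t6M\t*\t0\t0\tACGTAC\tFFFFFF\tMD:Z:2A3",
                # reverse strand
                "m2\t16\tchr1\t200\t25\t6M\t*\t0\t0\tACGTAC\tFFFFFF\tMD:Z:6",
            ]
        ) + "\n"
        path = tmp_path / "x.sam"
        path.write_text(sam)
        out = parse_sam(path, library="libA")
        assert [a.read_id for a in out] == ["m1", "m2"]
        a1, a2 = out
        assert a1.start == 99 and a1.strand == "+"
        assert a1.mismatch_list == ((2, "A", "G"),)
        assert a2.strand == "-" and a2.start == 199 and a2.mapq == 25
        assert a1.base_qual_sum == 6 * 37

    def test_reverse_strand_mismatch_in_read_coordinates(self, tmp_path):
        # SAM stores reverse reads reference-forward; qpos 1 of the stored
        # sequence is read position len-1-1 as sequenced, bases complemented.
        sam = SAM_HEADER + "m\t16\tchr1\t50\t30\t4M\t*\t0\t0\tAGGT\tFFFF\tMD:Z:1C2\n"
        path = tmp_path / "y.sam"
        path.write_text(sam)
        (a,) = parse_sam(path, library="l")
        assert a.mismatch_list == ((2, "G", "C"),)

    def test_malformed_record_raises(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(SAM_HEADER + "m1\t0\tchr1\tnotanumber\t37\t4M\n")
        with pytest.raises(ValueError, match="malformed SAM"):
            parse_sam(path)


@pytest.fixture(scope="module")
def toy_genome():
    g = generate_genomes(1, [5000], 0.5, 99)["genome_1"]
    # plant an exact duplicated 60-mer so multi-mapping is guaranteed
    dup = g[500:560]
    g = g[:3000] + dup + g[3060:]
    return GenomeSet([("g1", g)])


class TestToyMap:
    def test_verbatim_extract_maps_uniquely(self, toy_genome):
        g = toy_genome["g1"]
        read = ReadRecord("r", g[1000:1050], (37,) * 50, "l")
        (a,) = toy_map([read], toy_genome)
        assert (a.start, a.strand, a.mapq) == (1000, "+", 37)
        assert a.mismatch_list == ()

    def test_duplicated_sequence_gets_mapq_zero(self, toy_genome):
        g = toy_genome["g1"]
        read = ReadRecord("r", g[500:560], (37,) * 60, "l")
        (a,) = toy_map([read], toy_genome)
        assert a.mapq == 0

    def test_reverse_complement_extract(self, toy_genome):
        g = toy_genome["g1"]
        frag = g[2000:2055]
        read = ReadRecord("r", revcomp(frag), (37,) * 55, "l")
        (a,) = toy_map([read], toy_genome)
        # brute-force oracle: the forward occurrence of the fragment
        assert g.find(frag) == 2000
        assert (a.start, a.strand) == (2000, "-")

    def test_mismatches_reported_in_read_orientation(self, toy_genome):
        g = toy_genome["g1"]
        frag = g[1200:1250]
        # mutate the base that becomes read position 1 after revcomp
        mutated = list(revcomp(frag))
        wanted = "A" if mutated[1] != "A" else "C"
        mutated[1] = wanted
        read = ReadRecord("r", "".join(mutated), (37,) * 50, "l")
        (a,) = toy_map([read], toy_genome)
        assert a.strand == "-"
        assert any(pos == 1 and qb == wanted for pos, _, qb in a.mismatch_list)

    def test_short_read_unaligned(self, toy_genome):
        read = ReadRecord("r", "ACGTACGT", (37,) * 8, "l")
        assert toy_map([read], toy_genome, k=16) == []


class TestFilters:
    def test_mapq_boundary(self):
        alns = [aln(read_id="a", mapq=24), aln(read_id="b", mapq=25)]
        out = filter_mapq(alns, 25)
        assert [a.read_id for a in out] == ["b"]
        assert filter_mapq([], 25) == []
        assert filter_mapq(alns, 0) == alns

    def test_duplicates_highest_quality_survives(self):
        trio = [
            aln(read_id="x", start=10, bqs=90),
            aln(read_id="y", start=10, bqs=100),
            aln(read_id="z", start=10, bqs=95),
        ]
        out, frac = remove_duplicates(trio)
        assert [a.read_id for a in out] == ["y"]
        assert frac == pytest.approx(2 / 3)

    def test_duplicate_tie_breaks_lexicographically(self):
        pair = [aln(read_id="b", bqs=50), aln(read_id="a", bqs=50)]
        out, _ = remove_duplicates(pair)
        assert [a.read_id for a in out] == ["a"]

    def test_distinct_keys_untouched_and_idempotent(self):
        alns = [
            aln(read_id="a", start=1),
            aln(read_id="b", start=2),
            aln(read_id="c", start=1, strand="-"),
            aln(read_id="d", start=1, length=40),
        ]
        out, frac = remove_duplicates(alns)
        assert out == alns and frac == 0.0
        again, frac2 = remove_duplicates(out)
        assert again == out and frac2 == 0.0

    def test_five_prime_key_uses_alignment_end_on_minus_strand(self):
        a = aln(read_id="a", start=100, strand="-", length=50)
        b = aln(read_id="b", start=100, strand="-", length=50, bqs=10)
        c = aln(read_id="c", start=110, strand="-", length=40, bqs=5)
        out, _ = remove_duplicates([a, b, c])
        # a/b share 5' coordinate 150 and length; c has length 40
        assert [x.read_id for x in out] == ["b", "c"]

    def test_filters_are_monotone(self, toy_genome):
        g = toy_genome["g1"]
        reads = [
            ReadRecord(f"r{i}", g[i * 37 : i * 37 + 50], (30,) * 50, "l")
            for i in range(40)
        ]
        alns = toy_map(reads, toy_genome)
        kept = filter_mapq(alns, 25)
        assert set(a.read_id for a in kept) <= set(a.read_id for a in alns)
        deduped, _ = remove_duplicates(kept)
        assert set(a.read_id for a in deduped) <= set(a.read_id for a in kept)


class TestMappingRateTable:
    def test_percent_arithmetic(self):
        alns = [aln(read_id=f"r{i}", lib="L", gid="g", start=i * 100, mapq=30)
                for i in range(10)]
        df = mapping_rate_table(alns, {"L": 10000})
        row = df.iloc[0]
        assert row.percent_mapped == pytest.approx(0.1)
        assert row.mapped_after_filters == 10

    def test_zero_alignment_library_reports_zero(self):
        df = mapping_rate_table([], {"L": 100}, genome_ids=["g"])
        assert df.iloc[0].percent_mapped == 0.0

    def test_zero_raw_total_rejected(self):
        with pytest.raises(ValueError, match="raw total"):
            mapping_rate_table([], {"L": 0})


class TestGroupAverage:
    def test_single_element_group(self):
        meta = load_library_metadata()
        val = group_average(meta, lambda r: r["library"] == "Barley5", 3)
        assert val == 0.123

    def test_empty_group_rejected(self):
        meta = load_library_metadata()
        with pytest.raises(ValueError, match="empty"):
            group_average(meta, lambda r: False, 2)

    def test_half_away_from_zero_rounding(self):
        import pandas as pd

        meta = pd.DataFrame({"percent_mapped": [0.001, 0.001, 0.001, 0.000]})
        assert group_average(meta, [True] * 4, 4) == 0.0008


def test_metadata_fixture_shape():
    meta = load_library_metadata()
    assert len(meta) == 51
    assert meta.loc[~meta.is_blank].shape[0] == 44
    assert set(meta.method_class) == {"shotgun", "target", "WG", "SS"}
    assert meta.percent_mapped.isna().sum() == 7  # blanks carry no rate
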