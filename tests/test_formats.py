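"""Parsers/writers: sync round trips, pileup grammar, tables, merging."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import naive_pileup_decode, random_pileup_sample
from pooldiv.formats import (ParseError, TableSchema, format_sync_line,
                             merge_streams, parse_mpileup_line,
                             parse_sync_line, read_frequency_table, read_sync,
                             write_sync)
from pooldiv.model import FilterReason, SampleCounts, Variant
from pooldiv.regions import read_regions


# ---------------------------------------------------------------- sync

def test_parse_sync_basic():
    v = parse_sync_line("Chr1\t123\tA\t6:0:2:0:0:0")
    assert (v.chromosome, v.position, v.ref_base) == ("Chr1", 123, "A")
    s = v.samples[0]
    assert (s.a_count, s.c_count) == (6, 2)
    assert s.read_depth == 8


def test_parse_sync_zero_counts():
    v = parse_sync_line("Chr1\t5\tN\t0:0:0:0:0:0")
    assert v.samples[0].read_depth == 0


def test_parse_sync_field_order_is_atcg():
    s = parse_sync_line("Chr1\t7\tA\t1:2:3:4:5:6").samples[0]
    assert (s.a_count, s.t_count, s.c_count, s.g_count, s.n_count, s.del_count) \
        == (1, 2, 3, 4, 5, 6)


def test_parse_sync_missing_sample_and_four_field_dialect():
    v = parse_sync_line("Chr1\t9\tA\t.:.:.:.:.:.\t-\t1:2:3:4")
    assert not v.samples[0].passed and v.samples[0].filter_reason is FilterReason.MISSING
    assert not v.samples[1].passed
    s = v.samples[2]
    assert (s.a_count, s.t_count, s.c_count, s.g_count) == (1, 2, 3, 4)
    assert s.n_count == 0 and s.del_count == 0


@pytest.mark.parametrize("line", [
    "Chr1\t1\tA",                      # too few columns
    "Chr1\tx\tA\t0:0:0:0:0:0",         # non-integer position
    "Chr1\t0\tA\t0:0:0:0:0:0",         # position < 1
    "Chr1\t1\tA\t0:0:q:0:0:0",         # non-integer count
    "Chr1\t1\tA\t0:0:0:0:0",           # wrong token count
])
def test_parse_sync_errors(line):
    with pytest.raises(ParseError):
        parse_sync_line(line, lineno=7)


def test_sync_round_trip_bytes():
    lines = ["Chr1\t123\tA\t6:0:2:0:0:0",
             "Chr1\t124\tN\t0:0:0:0:0:0",
             "Chr2\t7\tA\t1:2:3:4:5:6\t.:.:.:.:.:."]
    for line in lines:
        assert format_sync_line(parse_sync_line(line)) == line


def test_write_sync_rejects_unsorted():
    vs = [parse_sync_line("c\t5\tA\t1:0:0:0:0:0"),
          parse_sync_line("c\t3\tA\t1:0:0:0:0:0")]
    with pytest.raises(ValueError):
        write_sync(vs, io.StringIO())


def test_write_sync_empty_stream():
    out = io.StringIO()
    assert write_sync([], out) == 0
    assert out.getvalue() == ""


def test_read_sync_skips_header(tmp_path):
    p = tmp_path / "x.sync"
    p.write_text("#chrom\tpos\tref\ts1\nChr1\t1\tA\t2:0:0:0:0:0\n")
    vs = list(read_sync(p))
    assert len(vs) == 1 and vs[0].samples[0].a_count == 2


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.tuples(st.integers(0, 99), st.integers(0, 99), st.integers(0, 99),
                          st.integers(0, 99), st.integers(0, 9), st.integers(0, 9)),
                min_size=1, max_size=4))
def test_sync_round_trip_property(sample_tuples):
    cols = "\t".join(":".join(map(str, t)) for t in sample_tuples)
    line = f"chrX\t42\tG\t{cols}"
    assert format_sync_line(parse_sync_line(line)) == line


# ---------------------------------------------------------------- mpileup

def test_mpileup_basic_counts():
    v = parse_mpileup_line("Chr1\t10\tA\t5\t..,TT\tIII!!")
    s = v.samples[0]
    assert (s.a_count, s.t_count) == (3, 2)


def test_mpileup_quality_threshold_drops_low_columns():
    # qualities: I=40, !=0 — the two T's carry the '!' columns
    v = parse_mpileup_line("Chr1\t10\tA\t5\t..,TT\tII,!!", min_base_quality=20)
    s = v.samples[0]
    assert (s.a_count, s.t_count) == (2, 0)


def test_mpileup_indel_skipped():
    v = parse_mpileup_line("Chr1\t11\tG\t3\t.+2AT,.\tJJJ")
    s = v.samples[0]
    assert s.g_count == 3 and s.read_depth == 3


def test_mpileup_read_start_end_and_deletion():
    v = parse_mpileup_line("c\t1\tT\t4\t^I..$,*\tJJJJ")
    s = v.samples[0]
    assert s.t_count == 3 and s.del_count == 1


@pytest.mark.parametrize("line", [
    "c\t1\tA\t2\t..\tJ",        # quality string too short
    "c\t1\tA\t2\t.+A.\tJJ",     # malformed indel length
    "c\t1\tA\t2\t.\tJJ",        # quality string too long
])
def test_mpileup_errors(line):
    with pytest.raises(ParseError):
        parse_mpileup_line(line, lineno=3)


def test_mpileup_matches_naive_decoder_on_random_lines(rng):
    """The optimized parser agrees with a regex-based reference decoder."""
    for _ in range(1000):
        ref = str(rng.choice(list("ACGTN")))
        bases, quals = random_pileup_sample(rng, ref)
        minq = int(rng.integers(0, 30))
        expected = naive_pileup_decode(ref, bases, quals, minq)
        line = f"chr1\t5\t{ref}\t{len(quals)}\t{bases}\t{quals}"
        s = parse_mpileup_line(line, min_base_quality=minq).samples[0]
        got = dict(zip(("A", "C", "G", "T"), s.base_counts()))
        got["N"] = s.n_count
        got["DEL"] = s.del_count
        assert got == expected, (bases, quals, minq)


# ---------------------------------------------------------------- tables

def _table(tmp_path, body):
    p = tmp_path / "t.tsv"
    p.write_text(body)
    return p


def test_frequency_table_scaling(tmp_path):
    p = _table(tmp_path, "chrom\tpos\tref\talt\ts1\nc\t1\tA\tC\t0.25\n")
    schema = TableSchema(samples=["s1"], scaling_depth=100)
    v = next(read_frequency_table(p, schema))
    assert (v.samples[0].a_count, v.samples[0].c_count) == (75, 25)


def test_frequency_table_boundary_and_rounding(tmp_path):
    p = _table(tmp_path, "chrom\tpos\tref\talt\ts1\nc\t1\tA\tC\t0\nc\t2\tA\tC\t0.333\n")
    schema = TableSchema(samples=["s1"], scaling_depth=10)
    vs = list(read_frequency_table(p, schema))
    assert (vs[0].samples[0].a_count, vs[0].samples[0].c_count) == (10, 0)
    schema3 = TableSchema(samples=["s1"], scaling_depth=3)
    vs = list(read_frequency_table(p, schema3))
    assert (vs[1].samples[0].a_count, vs[1].samples[0].c_count) == (2, 1)


def test_frequency_table_errors(tmp_path):
    p = _table(tmp_path, "chrom\tpos\tref\talt\ts1\nc\t1\tA\tC\t1.5\n")
    with pytest.raises(ParseError):
        list(read_frequency_table(p, TableSchema(samples=["s1"])))
    p2 = _table(tmp_path, "chrom\tpos\ts1\nc\t1\t0.5\n")
    with pytest.raises(ParseError):
        list(read_frequency_table(p2, TableSchema(samples=["s1"])))


def test_count_table(tmp_path):
    p = _table(tmp_path, "chrom\tpos\tref\talt\ts1_ref\ts1_alt\nc\t1\tG\tT\t7\t3\n")
    v = next(read_frequency_table(p, TableSchema(samples=["s1"], kind="counts")))
    assert (v.samples[0].g_count, v.samples[0].t_count) == (7, 3)


# ---------------------------------------------------------------- regions

def test_read_regions_coordinate_conventions(tmp_path):
    bed = tmp_path / "r.bed"
    bed.write_text("chr1\t99\t200\n")
    rl = read_regions(bed)
    assert list(rl.intervals()) == [("chr1", 100, 200)]

    gff = tmp_path / "r.gff"
    gff.write_text("chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1\n")
    assert list(read_regions(gff).intervals()) == [("chr1", 100, 200)]

    txt = tmp_path / "r.txt"
    txt.write_text("chr2:5\nchr3:10-20\n")
    rl = read_regions(txt)
    assert ("chr2", 5) in rl and ("chr3", 15) in rl and ("chr3", 21) not in rl


def test_read_regions_rejects_inverted_interval(tmp_path):
    p = tmp_path / "r.txt"
    p.write_text("chr1:20-10\n")
    with pytest.raises(ValueError):
        read_regions(p)


# ---------------------------------------------------------------- merging

def _stream(positions, chrom="c", base="A", depth=4):
    return [Variant(chrom, p, ref_base=base,
                    samples=[SampleCounts.from_bases(**{base: depth})])
            for p in positions]


def test_merge_streams_union_and_intersection():
    a = _stream([1, 2])
    b = _stream([2, 3])
    union = list(merge_streams([a, b], mode="union"))
    assert [v.position for v in union] == [1, 2, 3]
    assert all(len(v.samples) == 2 for v in union)
    # absent samples are filled as missing
    assert not union[0].samples[1].passed
    inter = list(merge_streams([_stream([1, 2]), _stream([2, 3])], mode="intersection"))
    assert [v.position for v in inter] == [2]


def test_merge_streams_single_stream_identity():
    for mode in ("union", "intersection"):
        out = list(merge_streams([_stream([1, 5, 9])], mode=mode))
        assert [v.position for v in out] == [1, 5, 9]


def test_merge_streams_ref_conflict():
    a = _stream([1], base="A")
    b = _stream([1], base="C")
    with pytest.raises(ValueError, match="c:1"):
        list(merge_streams([a, b], mode="union"))
    # a reference genome resolves the conflict
    out = list(merge_streams([_stream([1], base="A"), _stream([1], base="C")],
                             mode="union", reference={"c": "C"}))
    assert out[0].ref_base == "C"


def test_merge_streams_union_superset_of_intersection(rng):
    for _ in range(20):
        pa = sorted(rng.choice(50, size=rng.integers(1, 20), replace=False) + 1)
        pb = sorted(rng.choice(50, size=rng.integers(1, 20), replace=False) + 1)
        union = list(merge_streams([_stream(pa), _stream(pb)], mode="union"))
        inter = list(merge_streams([_stream(pa), _stream(pb)], mode="intersection"))
        assert len(union) >= len(inter)
        assert (len(union) == len(inter)) == (list(pa) == list(pb))
        positions = [v.position for v in union]
        assert positions == sorted(positions)


def test_merge_streams_rejects_unsorted():
    bad = _stream([5, 2])
    with pytest.raises(ValueError):
        list(merge_streams([bad, _stream([1])], mode="union"))
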