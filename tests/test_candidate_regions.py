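"""Region-file parsers and interval expansion/merging."""

import numpy as np
import pytest

from eveorf.candidate_regions import (
    CandidateRegion,
    RegionParseError,
    expand_and_merge,
    parse_bed,
    parse_blast_tab,
    parse_psl,
    parse_repeatmasker_out,
    write_bed,
)

RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def rm_line(chrom="chr1", begin=1001, end=2000, name="MLT1A", klass="LTR/ERVL-MaLR"):
    return (f"  463  12.5  4.6  1.1  {chrom}   {begin}   {end} (100) +  "
            f"{name}  {klass}   1  500  (10)  1\n")


class TestRepeatMasker:
    def test_coordinates_converted_and_class_kept(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER + rm_line() + rm_line(begin=5001, end=5500, klass="LINE/L1"))
        regions = parse_repeatmasker_out(p)
        assert [(r.chrom, r.start, r.end) for r in regions] == [
            ("chr1", 1000, 2000), ("chr1", 5000, 5500)]
        assert regions[0].source == "repeatmasker" and regions[0].round == 1
        assert regions[1].meta["repeat_class"] == "LINE/L1"

    def test_empty_body(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER)
        assert parse_repeatmasker_out(p) == []

    def test_missing_header_requires_flag(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(rm_line())
        with pytest.raises(RegionParseError):
            parse_repeatmasker_out(p)
        assert len(parse_repeatmasker_out(p, require_header=False)) == 1

    def test_unparseable_line_reports_line_number(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER + "garbage\n")
        with pytest.raises(RegionParseError, match=":4"):
            parse_repeatmasker_out(p)


class TestBed:
    def test_basic_and_source_tag(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nchr1\t0\t300\nchr2\t10\t20\tname1\t0\t-\n")
        regions = parse_bed(p, source="retrotector")
        assert [(r.chrom, r.start, r.end) for r in regions] == [
            ("chr1", 0, 300), ("chr2", 10, 20)]
        assert all(r.source == "retrotector" for r in regions)
        assert regions[1].meta["strand"] == "-"

    def test_empty_interval_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t5\t5\n")
        with pytest.raises(RegionParseError):
            parse_bed(p)


PSL_HEADER = (
    "psLayout version 3\n\nmatch\tmis- \trep. \tN's\n"
    "     \tmatch\tmatch\t    \n---------------------------------\n"
)


def psl_line(t_name="chr2", t_start=100, t_end=400):
    f = ["100", "0", "0", "0", "0", "0", "0", "0", "+", "q1", "500", "0", "100",
         t_name, "10000", str(t_start), str(t_end), "1", "300,", "0,", str(t_start) + ","]
    return "\t".join(f) + "\n"


class TestPsl:
    def test_header_and_headerless_parse_identically(self, tmp_path):
        a, b = tmp_path / "a.psl", tmp_path / "b.psl"
        a.write_text(PSL_HEADER + psl_line())
        b.write_text(psl_line())
        ra, rb = parse_psl(a), parse_psl(b)
        assert [(r.chrom, r.start, r.end) for r in ra] == \
               [(r.chrom, r.start, r.end) for r in rb] == [("chr2", 100, 400)]
        assert ra[0].source == "homology" and ra[0].round == 2

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "a.psl"
        p.write_text("1\t2\t3\n")
        with pytest.raises(RegionParseError, match="21"):
            parse_psl(p)


def blast_line(q="q1", s="chr1", sstart=101, send=500):
    return (f"{q}\t{s}\t98.0\t100\t1\t0\t1\t100\t{sstart}\t{send}\t1e-50\t200\n")


class TestBlastTab:
    @pytest.mark.parametrize("sstart,send", [(101, 500), (500, 101)])
    def test_orientation_normalized(self, tmp_path, sstart, send):
        p = tmp_path / "hits.tsv"
        p.write_text(blast_line(sstart=sstart, send=send))
        (r,) = parse_blast_tab(p)
        assert (r.chrom, r.start, r.end, r.source, r.round) == ("chr1", 100, 500, "homology", 2)

    def test_non_numeric_coordinates_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(blast_line(sstart="x", send=500))
        with pytest.raises(RegionParseError):
            parse_blast_tab(p)


def region(chrom, start, end, source="bed"):
    return CandidateRegion(chrom=chrom, start=start, end=end, source=source)


class TestExpandAndMerge:
    LENS = {"chr1": 10_000, "chr2": 120}

    def test_union_of_overlap(self):
        merged = expand_and_merge([region("chr1", 10, 100), region("chr1", 50, 200)],
                                  0, self.LENS)
        assert [(r.start, r.end) for r in merged] == [(10, 200)]

    def test_clipping_to_chromosome(self):
        merged = expand_and_merge([region("chr2", 0, 50)], 100, self.LENS)
        assert [(r.start, r.end) for r in merged] == [(0, 120)]

    def test_disjoint_untouched_and_sorted(self):
        merged = expand_and_merge([region("chr1", 20, 30), region("chr1", 0, 10)],
                                  0, self.LENS)
        assert [(r.start, r.end) for r in merged] == [(0, 10), (20, 30)]

    def test_touching_merges_at_gap_zero_but_gap_one_does_not(self):
        touching = [region("chr1", 0, 10), region("chr1", 10, 20)]
        assert len(expand_and_merge(touching, 0, self.LENS)) == 1
        close = [region("chr1", 0, 10), region("chr1", 11, 20)]
        assert len(expand_and_merge(close, 0, self.LENS)) == 2
        assert len(expand_and_merge(close, 0, self.LENS, merge_gap=1)) == 1

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(RegionParseError):
            expand_and_merge([region("chrX", 0, 10)], 0, self.LENS)

    def test_provenance_union(self):
        merged = expand_and_merge(
            [region("chr1", 0, 100, "repeatmasker"),
             CandidateRegion("chr1", 50, 200, "homology", round=2)],
            0, self.LENS)
        assert merged[0].meta["sources"] == "homology;repeatmasker"
        assert merged[0].round == 1

    @pytest.mark.parametrize("trial", range(20))
    def test_agrees_with_per_base_bitmap_oracle(self, trial):
        """Merged output covers exactly the union of flank-expanded inputs."""
        rng = np.random.default_rng(1000 + trial)
        chrom_len = 5000
        flank = int(rng.integers(0, 200))
        regions = [
            region("chr1", s, s + int(rng.integers(1, 400)))
            for s in rng.integers(0, chrom_len - 400, size=int(rng.integers(1, 40)))
        ]
        merged = expand_and_merge(regions, flank, {"chr1": chrom_len})
        bitmap = np.zeros(chrom_len, dtype=bool)
        for r in regions:
            bitmap[max(0, r.start - flank): min(chrom_len, r.end + flank)] = True
        out = np.zeros(chrom_len, dtype=bool)
        prev_end = -1
        for r in merged:
            assert r.start > prev_end, "output must be disjoint and sorted"
            prev_end = r.end
            out[r.start:r.end] = True
        assert np.array_equal(bitmap, out)

    def test_round_trip_through_bed(self, tmp_path):
        regions = [region("chr1", 5, 50), region("chr2", 0, 100)]
        p = tmp_path / "r.bed"
        write_bed(regions, p)
        back = parse_bed(p)
        assert [(r.chrom, r.start, r.end) for r in back] == \
               [(r.chrom, r.start, r.end) for r in regions]
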