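"""Best-hit selection, gene categories, LINE-pol flag, gene overlaps, tallies."""

import numpy as np
import pytest
from intervaltree import IntervalTree

from eveorf.annotator import (
    BestHit,
    OrfAnnotation,
    annotate_orfs,
    assign_category,
    flag_line_pol,
    gene_overlap,
    load_exon_index,
    parse_hit_table,
    select_best_hit,
    summarize_counts,
)
from eveorf.motif_filter import MotifHit

from conftest import make_orf


def hit(subject="ACC_1", evalue=1e-10, bitscore=100.0, db="viral"):
    return BestHit(subject_id=subject, description=subject, evalue=evalue,
                   bitscore=bitscore, db=db)


class TestSelectBestHit:
    def test_minimal_evalue_wins(self):
        best = select_best_hit([hit("A", 1e-10), hit("B", 1e-50)])
        assert best.subject_id == "B"

    def test_empty_absent(self):
        assert select_best_hit([]) is None

    def test_evalue_tie_broken_by_bitscore_then_first(self):
        best = select_best_hit([hit("A", 1e-5, 150), hit("B", 1e-5, 200)])
        assert best.subject_id == "B"
        best = select_best_hit([hit("A", 1e-5, 200), hit("B", 1e-5, 200)])
        assert best.subject_id == "A"

    def test_order_invariant(self):
        hits = [hit(s, e, b) for s, e, b in
                [("A", 1e-3, 50), ("B", 1e-9, 80), ("C", 1e-9, 90)]]
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = list(hits)
            rng.shuffle(perm)
            assert select_best_hit(perm).subject_id == "C"


def motif_hit(name, score=20.0):
    return MotifHit(profile_name=name, profile_source="pfam",
                    score=score, evalue=0.0, ali_from=1, ali_to=10)


class TestAssignCategory:
    def test_category_from_profile_file(self, profiles):
        orf = make_orf()
        orf.motif_hits.append(motif_hit("Gag_p24"))
        assert assign_category(orf, profiles) == "gag"

    def test_keyword_fallback_for_unlisted_profile(self):
        orf = make_orf()
        orf.motif_hits.append(motif_hit("RVT_3"))
        assert assign_category(orf, None) == "pol"

    def test_unmapped_profile_is_other(self):
        orf = make_orf()
        orf.motif_hits.append(motif_hit("DUF1234"))
        assert assign_category(orf, None) == "other"

    def test_best_scoring_hit_decides(self, profiles):
        orf = make_orf()
        orf.motif_hits += [motif_hit("Gag_p24", 10.0), motif_hit("RVT_1", 25.0)]
        assert assign_category(orf, profiles) == "pol"

    def test_no_hits_is_other(self):
        assert assign_category(make_orf(), None) == "other"


class TestFlagLinePol:
    def test_line_accession_flags(self):
        orf = make_orf()
        assert flag_line_pol(orf, "pol", viral_best=hit("YP_073558.1"))
        assert flag_line_pol(orf, "pol", viral_best=hit("NP_048132.1"))
        assert not flag_line_pol(orf, "pol", viral_best=hit("YP_000001.1"))

    def test_line_repeat_class_flags(self):
        orf = make_orf()
        assert flag_line_pol(orf, "pol", repeat_class="LINE/L1")
        assert not flag_line_pol(orf, "pol", repeat_class="LTR/ERVK")

    def test_non_pol_never_flagged(self):
        orf = make_orf()
        assert not flag_line_pol(orf, "env", repeat_class="LINE/L1",
                                 viral_best=hit("YP_073558.1"))


GTF = """\
chr1\tsrc\tgene\t300\t600\t.\t+\t.\tgene_id "G1";
chr1\tsrc\texon\t350\t500\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
chr1\tsrc\texon\t520\t600\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
chr2\tsrc\texon\t10\t50\t.\t+\t.\tgene_id "G3"; transcript_id "G3.t1";
"""


class TestGeneOverlap:
    @pytest.fixture()
    def exon_index(self, tmp_path_factory):
        p = tmp_path_factory.mktemp("gtf") / "genes.gtf"
        p.write_text(GTF)
        return load_exon_index(p)

    def test_overlapping_gene_found_strand_blind(self, exon_index):
        orf = make_orf(start=100, aa_len=100)  # span 100..399
        assert gene_overlap(orf, exon_index) == ["G1"]

    def test_two_genes_sorted(self, exon_index):
        orf = make_orf(start=400, aa_len=100)  # span 400..699 hits G1 and G2
        assert gene_overlap(orf, exon_index) == ["G1", "G2"]

    def test_no_overlap_empty(self, exon_index):
        orf = make_orf(start=700, aa_len=80)
        assert gene_overlap(orf, exon_index) == []

    def test_unknown_chromosome_warns_and_empty(self, exon_index, capsys):
        orf = make_orf(chrom="chrZ", start=1, aa_len=80)
        assert gene_overlap(orf, exon_index) == []
        assert "chrZ" in capsys.readouterr().err

    def test_agrees_with_per_base_scan(self, exon_index):
        """Every 1 bp of exon overlap counts; brute-force cross-check."""
        exons = [(350, 500, "G1"), (520, 600, "G2")]
        for start in range(250, 650, 7):
            orf = make_orf(start=start, aa_len=80)
            expected = sorted({g for a, b, g in exons
                               if any(a <= pos <= b
                                      for pos in range(orf.start, orf.end + 1))})
            assert gene_overlap(orf, exon_index) == expected


class TestHitTables:
    def test_parse_and_best_hit_per_db(self, tmp_path):
        orf = make_orf(start=1, aa_len=100)
        qid = f"{orf.chrom}.{orf.start}.{orf.end}.{orf.strand}"
        lines = [
            f"{qid}\tACC_A\t90\t100\t0\t0\t1\t100\t1\t100\t1e-30\t120",
            f"{qid}\tACC_B\t95\t100\t0\t0\t1\t100\t1\t100\t1e-60\t220",
        ]
        p = tmp_path / "viral.tsv"
        p.write_text("\n".join(lines) + "\n")
        table = parse_hit_table(p, "viral")
        assert select_best_hit(table[qid]).subject_id == "ACC_B"

    def test_annotate_orfs_assembles_bundle(self, tmp_path, profiles):
        orf = make_orf(start=1, aa_len=100)
        orf.motif_hits.append(motif_hit("RVT_1"))
        qid = f"{orf.chrom}.{orf.start}.{orf.end}.{orf.strand}"
        p = tmp_path / "viral.tsv"
        p.write_text(f"{qid}\tYP_073558.1\t90\t100\t0\t0\t1\t100\t1\t100\t1e-30\t120\n")
        ann = annotate_orfs([orf], profiles,
                            hit_tables={"viral": parse_hit_table(p, "viral")})
        a = ann[orf.key()]
        assert a.category == "pol"
        assert a.line_pol  # flagged via the LINE reverse-transcriptase accession
        assert a.best_hits["viral"].subject_id == "YP_073558.1"


class TestSummarizeCounts:
    def _annotated(self, specs):
        orfs, anns = [], {}
        for i, (category, line_pol, has_met) in enumerate(specs):
            orf = make_orf(start=1 + 1000 * i, aa_len=80)
            if not has_met:
                orf.aa_seq = "A" * 80
            else:
                orf.aa_seq = "MA" + "A" * 78
            orfs.append(orf)
            anns[orf.key()] = OrfAnnotation(category=category, line_pol=line_pol)
        return orfs, anns

    def test_hand_count(self):
        orfs, anns = self._annotated(
            [("gag", False, True), ("pol", True, True), ("env", False, False)])
        counts = summarize_counts(orfs, anns)
        assert counts == {"total": 3, "met": 2, "gag": 1, "pro": 0, "pol": 1,
                          "env": 1, "other": 0, "pol_line": 1}

    def test_empty(self):
        assert summarize_counts([], {}) == {
            "total": 0, "met": 0, "gag": 0, "pro": 0, "pol": 0,
            "env": 0, "other": 0, "pol_line": 0}

    def test_conservation(self):
        rng = np.random.default_rng(11)
        cats = ["gag", "pro", "pol", "env", "other"]
        specs = [(cats[int(rng.integers(5))], bool(rng.integers(2)),
                  bool(rng.integers(2))) for _ in range(40)]
        specs = [(c, lp and c == "pol", m) for c, lp, m in specs]
        orfs, anns = self._annotated(specs)
        counts = summarize_counts(orfs, anns)
        assert sum(counts[c] for c in cats) == counts["total"] == 40
        assert counts["pol_line"] <= counts["pol"]
        assert counts["met"] <= counts["total"]
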