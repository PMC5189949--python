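"""Panel BED parsing, pileup TSV round trips, alignment extraction, VCF output."""

import numpy as np
import pysam
import pytest

from bper.exceptions import ConsistencyError, PanelParseError, PileupValidationError
from bper.panel import Alteration, PanelPosition, PileupMatrix
from bper.panel_io import (
    pileup_from_alignments,
    read_panel,
    read_pileup_tsv,
    write_pileup_tsv,
    write_vcf,
)
from bper.simulate import write_planted_sam


class TestReadPanel:
    def test_bed_to_one_based_positions(self, tmp_path):
        bed = tmp_path / "panel.bed"
        bed.write_text("chr7\t55242464\t55242466\tEGFR\t0\tGA\n")
        panel = read_panel(bed)
        assert [(p.contig, p.pos, p.ref_base, p.gene) for p in panel] == [
            ("chr7", 55242465, "G", "EGFR"),
            ("chr7", 55242466, "A", "EGFR"),
        ]

    def test_hotspot_flag_and_sorting(self, tmp_path):
        bed = tmp_path / "panel.bed"
        bed.write_text("chr2\t10\t11\tX\t1\tC\nchr1\t5\t6\tY\t0\tG\n")
        panel = read_panel(bed)
        assert [(p.contig, p.pos) for p in panel] == [("chr1", 6), ("chr2", 11)]
        assert panel[1].hotspot and not panel[0].hotspot

    def test_ref_bases_from_fasta(self, tmp_path):
        fasta = tmp_path / "ref.fa"
        fasta.write_text(">chr1\nACGTACGT\n")
        bed = tmp_path / "panel.bed"
        bed.write_text("chr1\t2\t5\n")
        panel = read_panel(bed, reference=str(fasta))
        assert [p.ref_base for p in panel] == ["G", "T", "A"]

    def test_empty_file_gives_empty_panel(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("")
        assert read_panel(bed) == []

    @pytest.mark.parametrize("line", ["chr1\t10\t10\tG\t0\tA", "chr1\t12\t10\tG\t0\tA", "chr1\t10"])
    def test_malformed_interval_raises(self, tmp_path, line):
        bed = tmp_path / "bad.bed"
        bed.write_text(line + "\n")
        with pytest.raises(PanelParseError):
            read_panel(bed)

    def test_missing_ref_base_raises(self, tmp_path):
        bed = tmp_path / "noref.bed"
        bed.write_text("chr1\t10\t12\tGENE\n")
        with pytest.raises(PanelParseError, match="reference"):
            read_panel(bed)


class TestPileupTsv:
    def _matrix(self):
        panel = [PanelPosition("chr12", 25398283 + i, b) for i, b in enumerate("GCCA")]
        counts = [{}, {"sub:A": 30, "del:3": 4}, {"ins:TT": 2}, {}]
        return PileupMatrix("S1", panel, [9000, 10000, 10000, 0], counts)

    def test_round_trip_identity(self, tmp_path):
        mat = self._matrix()
        path = tmp_path / "pileup.tsv"
        write_pileup_tsv(mat, path)
        back = read_pileup_tsv(path)
        assert back.sample_id == mat.sample_id
        assert back.positions == mat.positions
        assert list(back.depth) == list(mat.depth)
        assert back.counts == mat.counts

    def test_direct_row_parse(self, tmp_path):
        path = tmp_path / "row.tsv"
        path.write_text(
            "sample_id\tcontig\tpos\tref\tdepth\talteration\tcount\n"
            "S1\tchr12\t25398284\tC\t10000\tsub:A\t30\n"
        )
        mat = read_pileup_tsv(path)
        i = mat.index_of("chr12", 25398284)
        assert mat.depth[i] == 10000 and mat.count(i, "sub:A") == 30

    def test_duplicate_alteration_row_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "sample_id\tcontig\tpos\tref\tdepth\talteration\tcount\n"
            "S1\tchr1\t10\tC\t100\tsub:A\t3\n"
            "S1\tchr1\t10\tC\t100\tsub:A\t4\n"
        )
        with pytest.raises(PileupValidationError, match="duplicate"):
            read_pileup_tsv(path)

    def test_counts_exceeding_depth_rejected(self, tmp_path):
        path = tmp_path / "over.tsv"
        path.write_text(
            "sample_id\tcontig\tpos\tref\tdepth\talteration\tcount\n"
            "S1\tchr1\t10\tC\t100\tsub:A\t60\nS1\tchr1\t10\tC\t100\tsub:T\t60\n"
        )
        with pytest.raises(PileupValidationError, match="exceed"):
            read_pileup_tsv(path)

    def test_unknown_alteration_kind_rejected(self, tmp_path):
        path = tmp_path / "kind.tsv"
        path.write_text(
            "sample_id\tcontig\tpos\tref\tdepth\talteration\tcount\n"
            "S1\tchr1\t10\tC\t100\tdup:A\t3\n"
        )
        with pytest.raises(PanelParseError):
            read_pileup_tsv(path)

    def test_zero_depth_position_flagged_uncallable(self, tmp_path):
        mat = self._matrix()
        path = tmp_path / "p.tsv"
        write_pileup_tsv(mat, path)
        back = read_pileup_tsv(path)
        assert [p.pos for p in back.uncallable_positions()] == [25398286]


class TestAlignmentExtraction:
    def test_planted_deletion_counts_at_every_deleted_base(self, tmp_path):
        sam = tmp_path / "planted.sam"
        ref = write_planted_sam(
            sam, n_reads=1000, read_start=51, read_length=100, deletion=(80, 3, 10), seed=7,
        )
        panel = [PanelPosition("panel1", pos, ref[pos - 1]) for pos in range(51, 151)]
        mat = pileup_from_alignments(sam, panel, sample_id="S")
        for pos in (80, 81, 82):
            i = mat.index_of("panel1", pos)
            assert mat.count(i, "del:3") == 10
            assert mat.depth[i] == 1000
        # a matched-only position: full depth, no counts
        j = mat.index_of("panel1", 60)
        assert mat.depth[j] == 1000 and mat.counts[j] == {}

    def test_planted_substitution_counted_once(self, tmp_path):
        sam = tmp_path / "sub.sam"
        ref = write_planted_sam(sam, n_reads=100, seed=3)
        alt = "A" if ref[89] != "A" else "C"
        write_planted_sam(sam, n_reads=100, substitution=(90, alt, 1), seed=3)
        panel = [PanelPosition("panel1", 90, ref[89])]
        mat = pileup_from_alignments(sam, panel)
        i = mat.index_of("panel1", 90)
        assert mat.depth[i] == 100 and mat.count(i, f"sub:{alt}") == 1

    def test_low_mapq_reads_excluded(self, tmp_path):
        sam = tmp_path / "mapq.sam"
        ref = write_planted_sam(sam, n_reads=50, seed=1)
        panel = [PanelPosition("panel1", 60, ref[59])]
        assert pileup_from_alignments(sam, panel, min_mapq=20).depth[0] == 50
        assert pileup_from_alignments(sam, panel, min_mapq=99).depth[0] == 0


class TestWriteVcf:
    def _call(self, position, alteration, af=0.02, depth=10_000, passed=True, reason=""):
        from bper.caller import VariantCall

        return VariantCall(
            position=position, alteration=alteration, depth=depth,
            alt_reads=int(af * depth), af=af, mu=5e-5, sigma=1e-5, tau=0.003,
            z=10.0, p_binom=1e-30, passed=passed, filter_reason=reason,
        )

    def test_empty_call_list_is_valid_header_only_vcf(self, tmp_path):
        panel = [PanelPosition("chr1", 10, "A")]
        out = tmp_path / "empty.vcf"
        write_vcf([], "S1", panel, out)
        with pysam.VariantFile(str(out)) as vf:
            assert list(vf) == []

    def test_snv_and_long_deletion_records(self, tmp_path):
        panel = [PanelPosition("chr7", 55242460 + i, b) for i, b in enumerate("GATTACAGG")]
        snv = self._call(panel[0], Alteration("sub", "T"))
        dele = self._call(panel[3], Alteration("del", "", 3))  # deletes TAC at 55242463..65
        out = tmp_path / "calls.vcf"
        write_vcf([snv, dele], "S1", panel, out)
        with pysam.VariantFile(str(out)) as vf:
            recs = list(vf)
        assert recs[0].pos == 55242460 and recs[0].ref == "G" and recs[0].alts == ("T",)
        assert recs[0].info["DP"] == 10_000 and recs[0].info["AF"] == pytest.approx(0.02)
        # left-anchored deletion: REF length span+1, ALT length 1
        assert recs[1].pos == 55242462
        assert len(recs[1].ref) == 4 and recs[1].ref == "TTAC" and recs[1].alts == ("T",)
        assert recs[1].filter.keys() == ["PASS"]

    def test_call_off_panel_raises(self, tmp_path):
        panel = [PanelPosition("chr1", 10, "A")]
        rogue = self._call(PanelPosition("chr1", 99, "C"), Alteration("sub", "T"))
        with pytest.raises(ConsistencyError):
            write_vcf([rogue], "S1", panel, tmp_path / "x.vcf")
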