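"""Conversion counting from alignments, the 3C read filter and QC metrics."""

import numpy as np
import pandas as pd
import pytest

from m5cpipe.counting import (
    CytosineCount,
    ReadRecord,
    apply_3c,
    count_cytosines,
    global_conversion_rate,
    pbc1,
    read_3c_filter,
    signal_to_noise,
)
from m5cpipe.transcripts import revcomp

#          0         1         2
#          0123456789012345678901234567890123456789
GENOME = {"chr1": "AACGTACGTACCGGTACGTACGTACCGGTAGCATCGATCG"}


def _read(name, chrom, pos, seq, qual_char="I", flag=0, mapq=60, qual=None):
    return {
        "name": name, "flag": flag, "chrom": chrom, "pos": pos, "mapq": mapq,
        "cigar": f"{len(seq)}M", "seq": seq,
        "qual": qual if qual is not None else qual_char * len(seq),
    }


class TestCountCytosines:
    def test_converted_and_nonconverted_tallies(self, tmp_path, sam_writer):
        # 20 nt read over chr1:0-20; reference Cs inside the untrimmed core
        # [6, 14) sit at 6, 10, 11.  The read converts the C at 6 (reads T),
        # keeps 10 and 11 as C (non-converted).
        ref = GENOME["chr1"][:20]
        seq = ref[:6] + "T" + ref[7:]
        sam = sam_writer(tmp_path / "a.sam", [_read("r1", "chr1", 0, seq)],
                         {"chr1": 40})
        counts, reads = count_cytosines(sam, GENOME)
        by_pos = counts.set_index("pos0")
        assert set(by_pos.index) == {6, 10, 11}
        assert by_pos.loc[6, "conv_raw"] == 1 and by_pos.loc[6, "nonconv_raw"] == 0
        assert by_pos.loc[11, "nonconv_raw"] == 1 and by_pos.loc[11, "conv_raw"] == 0
        assert len(reads) == 1 and reads[0].n_nonconverted == 2

    def test_low_quality_base_not_counted(self, tmp_path, sam_writer):
        ref = GENOME["chr1"][:20]
        qual = list("I" * 20)
        qual[11] = "5"  # Phred 20 < 30 at the non-converted C
        sam = sam_writer(tmp_path / "a.sam",
                         [_read("r1", "chr1", 0, ref, qual="".join(qual))],
                         {"chr1": 40})
        counts, _ = count_cytosines(sam, GENOME)
        assert 11 not in set(counts.pos0)

    def test_end_trim_masks_terminal_bases(self, tmp_path, sam_writer):
        # C at reference position 2 sits 2 nt from the read 5' end: masked
        # by the 6-nt end trim.
        ref = GENOME["chr1"][:20]
        sam = sam_writer(tmp_path / "a.sam", [_read("r1", "chr1", 0, ref)],
                         {"chr1": 40})
        counts, _ = count_cytosines(sam, GENOME)
        assert 2 not in set(counts.pos0)
        counts2, _ = count_cytosines(sam, GENOME, end_trim=0)
        assert 2 in set(counts2.pos0)

    def test_reverse_reads_score_g_to_a(self, tmp_path, sam_writer):
        # reverse-strand read: reference G positions carry the evidence;
        # a G->A mismatch is a conversion, G retained is non-conversion.
        ref = GENOME["chr1"][:20]
        seq = ref[:13] + "A" + ref[14:]  # ref G at 13 -> A
        sam = sam_writer(tmp_path / "a.sam",
                         [_read("r1", "chr1", 0, seq, flag=16)], {"chr1": 40})
        counts, _ = count_cytosines(sam, GENOME)
        assert (counts.strand == "-").all()
        by_pos = counts.set_index("pos0")
        assert by_pos.loc[13, "conv_raw"] == 1
        assert by_pos.loc[12, "nonconv_raw"] == 1  # ref G at 12 retained

    def test_secondary_and_low_mapq_reads_skipped(self, tmp_path, sam_writer):
        ref = GENOME["chr1"][:20]
        sam = sam_writer(
            tmp_path / "a.sam",
            [_read("r1", "chr1", 0, ref, flag=256),
             _read("r2", "chr1", 0, ref, mapq=0)],
            {"chr1": 40},
        )
        counts, _ = count_cytosines(sam, GENOME)
        assert len(counts) == 0

    def test_missing_contig_named_in_error(self, tmp_path, sam_writer):
        sam = sam_writer(tmp_path / "a.sam",
                         [_read("r1", "chrX", 0, "ACGTACGTACGTACGTACGT")],
                         {"chrX": 40})
        with pytest.raises(KeyError, match="chrX"):
            count_cytosines(sam, GENOME)

    def test_counts_match_brute_force_rewalk(self, tmp_path, sam_writer):
        """Oracle: an independent per-base walk over the same toy reads."""
        rng = np.random.default_rng(0)
        reads = []
        for i in range(30):
            pos = int(rng.integers(0, 20))
            seq = list(GENOME["chr1"][pos: pos + 20])
            for j in range(len(seq)):  # sprinkle C->T / G->A conversions
                if seq[j] == "C" and rng.random() < 0.5:
                    seq[j] = "T"
                if seq[j] == "G" and rng.random() < 0.5:
                    seq[j] = "A"
            reads.append(_read(f"r{i}", "chr1", pos, "".join(seq),
                               flag=0 if i % 2 == 0 else 16))
        sam = sam_writer(tmp_path / "a.sam", reads, {"chr1": 40})
        counts, _ = count_cytosines(sam, GENOME, min_base_quality=0, end_trim=0)

        expected: dict[tuple, list] = {}
        for r in reads:
            strand = "-" if r["flag"] & 16 else "+"
            ref_non, ref_conv = ("C", "T") if strand == "+" else ("G", "A")
            for j, base in enumerate(r["seq"]):
                rpos = r["pos"] + j
                ref = GENOME["chr1"][rpos]
                if ref != ref_non:
                    continue
                row = expected.setdefault(("chr1", rpos, strand), [0, 0, 0])
                if base == ref_non:
                    row[0] += 1
                elif base == ref_conv:
                    row[1] += 1
                else:
                    row[2] += 1
        for _, rec in counts.iterrows():
            key = (rec.chrom, rec.pos0, rec.strand)
            assert expected[key] == [rec.nonconv_raw, rec.conv_raw, rec.other_raw]
        assert len(expected) == len(counts)

    def test_strand_symmetry_under_reverse_complement(self, tmp_path, sam_writer):
        """Reverse-complementing genome and reads leaves tallies invariant
        up to coordinate remapping."""
        L = 40
        fwd_reads = [_read("r1", "chr1", 5, GENOME["chr1"][5:25])]
        sam = sam_writer(tmp_path / "fwd.sam", fwd_reads, {"chr1": L})
        counts_fwd, _ = count_cytosines(sam, GENOME, end_trim=0)

        rc_genome = {"chr1": revcomp(GENOME["chr1"])}
        rc_reads = [_read("r1", "chr1", L - 25, revcomp(GENOME["chr1"][5:25]),
                          flag=16)]
        sam2 = sam_writer(tmp_path / "rc.sam", rc_reads, {"chr1": L})
        counts_rc, _ = count_cytosines(sam2, rc_genome, end_trim=0)

        remapped = {
            (L - 1 - p, "-" if s == "+" else "+"): (nc, cv, ot)
            for p, s, nc, cv, ot in zip(
                counts_rc.pos0, counts_rc.strand, counts_rc.nonconv_raw,
                counts_rc.conv_raw, counts_rc.other_raw)
        }
        for rec in counts_fwd.itertuples():
            assert remapped[(rec.pos0, rec.strand)] == (
                rec.nonconv_raw, rec.conv_raw, rec.other_raw)


class TestThreeCFilter:
    @pytest.mark.parametrize("n_nonconv,kept", [(0, True), (3, True), (4, False)])
    def test_boundary(self, n_nonconv, kept):
        obs = [(i, i < n_nonconv) for i in range(6)]
        assert read_3c_filter(ReadRecord("r", "chr1", "+", obs)) is kept

    def test_apply_is_identity_without_failing_reads(self):
        counts = pd.DataFrame(
            [{"chrom": "chr1", "pos0": 5, "strand": "+",
              "nonconv_raw": 2, "conv_raw": 18, "other_raw": 0,
              "nonconv_3c": 2, "conv_3c": 18, "other_3c": 0}]
        )
        reads = [ReadRecord("r", "chr1", "+", [(5, True)])]
        out = apply_3c(counts, reads)
        assert out.nonconv_3c.iloc[0] == 2 and out.conv_3c.iloc[0] == 18

    def test_artifact_reads_removed_from_coverage(self):
        # 20 reads at one site, 2 artifact reads with >3 non-converted Cs:
        # post-3C coverage drops to 18.
        counts = pd.DataFrame(
            [{"chrom": "chr1", "pos0": p, "strand": "+",
              "nonconv_raw": 2, "conv_raw": 18, "other_raw": 0,
              "nonconv_3c": 2, "conv_3c": 18, "other_3c": 0}
             for p in (5, 10, 15, 20, 25)]
        )
        arts = [
            ReadRecord(f"a{k}", "chr1", "+", [(p, True) for p in (5, 10, 15, 20)])
            for k in range(2)
        ]
        out = apply_3c(counts, arts)
        assert (out.nonconv_3c[:4] == 0).all()
        cov = out.nonconv_3c + out.conv_3c + out.other_3c
        assert (cov[:4] == 18).all() and cov.iloc[4] == 20

    def test_idempotent(self):
        counts = pd.DataFrame(
            [{"chrom": "chr1", "pos0": p, "strand": "+",
              "nonconv_raw": 4, "conv_raw": 16, "other_raw": 0,
              "nonconv_3c": 4, "conv_3c": 16, "other_3c": 0}
             for p in (1, 2, 3, 4)]
        )
        arts = [ReadRecord("a", "chr1", "+", [(p, True) for p in (1, 2, 3, 4)])]
        once = apply_3c(counts, arts)
        twice = apply_3c(once, arts)
        pd.testing.assert_frame_equal(once, twice)


class TestDerivedMetrics:
    def test_signal_to_noise_values(self):
        counts = pd.DataFrame(
            [
                {"chrom": "c", "pos0": 1, "strand": "+", "nonconv_raw": 2,
                 "conv_raw": 18, "other_raw": 0, "nonconv_3c": 2,
                 "conv_3c": 16, "other_3c": 0},
                {"chrom": "c", "pos0": 2, "strand": "+", "nonconv_raw": 2,
                 "conv_raw": 18, "other_raw": 0, "nonconv_3c": 2,
                 "conv_3c": 15, "other_3c": 0},
                {"chrom": "c", "pos0": 3, "strand": "+", "nonconv_raw": 0,
                 "conv_raw": 10, "other_raw": 0, "nonconv_3c": 0,
                 "conv_3c": 10, "other_3c": 0},
                {"chrom": "c", "pos0": 4, "strand": "+", "nonconv_raw": 0,
                 "conv_raw": 0, "other_raw": 0, "nonconv_3c": 0,
                 "conv_3c": 0, "other_3c": 0},
            ]
        )
        s2n = signal_to_noise(counts)
        assert s2n.iloc[0] == pytest.approx(0.90)
        assert s2n.iloc[1] == pytest.approx(0.85)
        assert s2n.iloc[2] == pytest.approx(1.0)
        assert np.isnan(s2n.iloc[3])

    def test_conversion_rate(self):
        counts = pd.DataFrame(
            [{"chrom": "c", "pos0": 1, "strand": "+", "nonconv_raw": 4,
              "conv_raw": 996, "other_raw": 0, "nonconv_3c": 4,
              "conv_3c": 996, "other_3c": 0}]
        )
        assert global_conversion_rate(counts) == pytest.approx(0.996)
        counts.loc[0, "nonconv_raw"] = 0
        assert global_conversion_rate(counts) == 1.0
        with pytest.raises(ValueError):
            global_conversion_rate(counts.iloc[0:0])

    @pytest.mark.parametrize(
        "loc_counts,expected",
        [([1, 1, 3], 2 / 3), ([1, 1, 1], 1.0), ([2, 2], 0.0)],
    )
    def test_pbc1(self, loc_counts, expected):
        assert pbc1(loc_counts) == pytest.approx(expected)

    def test_cytosine_count_rejects_negative(self):
        with pytest.raises(ValueError):
            CytosineCount("c", 1, "+", nonconv_raw=-1)
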