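"""Structural-variant reading, IMD clustering, and 32-channel classification."""

import itertools

import numpy as np
import pytest

from cnsv.channels import SV32_CHANNELS, SV_SIZE_BINS
from cnsv.sv import (
    SVRecord,
    annotate_clustered,
    build_sv_matrix,
    classify_sv,
    compute_imd,
    infer_svclass,
    read_bedpe,
    write_bedpe,
)

from conftest import tight_cluster_sv_set


class TestInferSVClass:
    @pytest.mark.parametrize("c1,c2,s1,s2,expected", [
        ("2", "2", "+", "+", "del"),
        ("2", "2", "-", "-", "tds"),
        ("3", "3", "+", "-", "inv"),
        ("3", "3", "-", "+", "inv"),
        ("1", "X", "-", "-", "trans"),
    ])
    def test_strand_convention(self, c1, c2, s1, s2, expected):
        assert infer_svclass(c1, c2, s1, s2) == expected

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValueError):
            infer_svclass("1", "1", "+", ".")


class TestReadBedpe:
    HEADER = "chrom1\tstart1\tend1\tchrom2\tstart2\tend2"

    def _write(self, tmp_path, rows, header=None):
        p = tmp_path / "sv.bedpe"
        p.write_text((header or self.HEADER) + "\n" + "\n".join(rows) + "\n")
        return p

    def test_interchromosomal_without_svclass_is_trans(self, tmp_path):
        p = self._write(tmp_path, ["chr1\t999\t1000\tchr5\t1999\t2000\t+\t-"],
                        header=self.HEADER + "\tstrand1\tstrand2")
        recs = read_bedpe(p)
        assert recs[0].svclass == "trans"
        assert (recs[0].chrom1, recs[0].chrom2) == ("1", "5")

    def test_svclass_synonyms_normalized(self, tmp_path):
        p = self._write(
            tmp_path,
            ["1\t999\t1000\t1\t49999\t50000\tdeletion",
             "1\t999\t1000\t1\t49999\t50000\tDUP",
             "1\t999\t1000\t1\t49999\t50000\tINV",
             "1\t999\t1000\t2\t49999\t50000\tBND"],
            header=self.HEADER + "\tsvclass")
        assert [r.svclass for r in read_bedpe(p)] == ["del", "tds", "inv", "trans"]

    def test_row_missing_strand_and_svclass_skipped(self, tmp_path, caplog):
        p = self._write(tmp_path,
                        ["1\t999\t1000\t1\t49999\t50000\t+\t-",
                         "1\t999\t1000\t1\t99999\t100000\t+\t"],
                        header=self.HEADER + "\tstrand1\tstrand2")
        with caplog.at_level("WARNING", logger="cnsv.sv"):
            recs = read_bedpe(p)
        assert len(recs) == 1

    def test_no_svclass_and_no_strands_is_fatal(self, tmp_path):
        p = self._write(tmp_path, ["1\t999\t1000\t1\t49999\t50000"])
        with pytest.raises(ValueError, match="svclass"):
            read_bedpe(p)

    def test_missing_mandatory_column_is_fatal(self, tmp_path):
        p = tmp_path / "sv.bedpe"
        p.write_text("chrom1\tstart1\tend1\tchrom2\tstart2\tsvclass\n")
        with pytest.raises(ValueError, match="end2"):
            read_bedpe(p)

    def test_midpoint_position_with_floor(self, tmp_path):
        # interval [101, 104] 1-based -> midpoint floor(205/2) = 102
        p = self._write(tmp_path, ["1\t100\t104\t1\t50000\t50001\tdel"],
                        header=self.HEADER + "\tsvclass")
        assert read_bedpe(p)[0].pos1 == 102

    def test_round_trip_preserves_positions(self, tmp_path):
        recs = [SVRecord("S", "1", 12345, "2", 67890, "+", "-", "trans"),
                SVRecord("S", "4", 1000, "4", 51000, "+", "+", "del")]
        p = write_bedpe(recs, tmp_path / "rt.bedpe")
        back = read_bedpe(p)
        assert [(r.chrom1, r.pos1, r.chrom2, r.pos2, r.svclass) for r in back] \
            == [(r.chrom1, r.pos1, r.chrom2, r.pos2, r.svclass) for r in recs]


class TestComputeImd:
    def test_first_breakpoint_takes_successor_distance(self):
        assert compute_imd([100, 300, 1300]).tolist() == [200.0, 200.0, 1000.0]

    def test_single_breakpoint_has_no_imd(self):
        imd = compute_imd([42])
        assert np.isnan(imd).all()

    def test_coincident_breakpoints(self):
        assert compute_imd([5, 5]).tolist() == [0.0, 0.0]

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            compute_imd([10, 5])


class TestAnnotateClustered:
    def test_tight_run_clustered_background_not(self):
        """12 breakpoints 1 kb apart on one chromosome are clustered;
        sparse 10 Mb-spaced breakpoints elsewhere are not."""
        recs = tight_cluster_sv_set(12)
        annotate_clustered(recs)
        assert all(r.clustered for r in recs if r.svclass == "trans")
        assert not any(r.clustered for r in recs if r.svclass == "del")

    def test_nine_breakpoints_never_clustered(self):
        recs = tight_cluster_sv_set(9)
        annotate_clustered(recs)
        assert not any(r.clustered for r in recs)

    def test_tenth_breakpoint_enables_clustering(self):
        recs = tight_cluster_sv_set(10)
        annotate_clustered(recs)
        assert any(r.clustered for r in recs)

    def test_uniform_spacing_gives_no_clusters(self):
        recs = [SVRecord("S", "1", 10_000_000 * (i + 1), "2",
                         10_000_000 * (i + 1), "+", "-", "trans")
                for i in range(12)]
        annotate_clustered(recs)
        assert not any(r.clustered for r in recs)

    def test_single_breakpoint_sample_all_non_clustered(self):
        recs = [SVRecord("S", "1", 1000, "2", 2000, "+", "-", "trans")]
        annotate_clustered(recs)
        assert not recs[0].clustered

    def test_segment_mean_threshold_against_oracle(self):
        """Verify the threshold arithmetic directly: with the tight
        cluster, the cluster segment's mean raw IMD must be <= sample
        mean / 10, and the background segments' means must not."""
        recs = tight_cluster_sv_set(12)
        bps = annotate_clustered(recs)
        by_chrom = {}
        for bp in bps:
            by_chrom.setdefault(bp.chromosome, []).append(bp)
        imds = np.array([bp.imd for bp in bps if not np.isnan(bp.imd)])
        sample_mean = imds.mean()
        cluster_imds = np.array([bp.imd for bp in by_chrom["1"]])
        assert cluster_imds.mean() <= sample_mean / 10
        for chrom in ("2", "3"):
            other = np.array([bp.imd for bp in by_chrom[chrom]])
            assert other.mean() > sample_mean / 10

    def test_scale_invariance(self):
        """Multiplying all coordinates by a positive constant leaves
        clustered flags unchanged (the threshold is relative)."""
        recs = tight_cluster_sv_set(12)
        annotate_clustered(recs)
        flags = [r.clustered for r in recs]
        scaled = [SVRecord(r.sample, r.chrom1, r.pos1 * 3, r.chrom2,
                           r.pos2 * 3, r.strand1, r.strand2, r.svclass)
                  for r in recs]
        annotate_clustered(scaled)
        assert [r.clustered for r in scaled] == flags

    def test_samples_annotated_independently(self):
        recs = tight_cluster_sv_set(12)
        lone = SVRecord("other", "1", 1_000_000, "1", 1_051_000, "+", "+", "del")
        annotate_clustered(recs + [lone])
        assert not lone.clustered
        assert any(r.clustered for r in recs)


class TestClassifySV:
    @pytest.mark.parametrize("svtype,size,clustered,label", [
        ("del", 5_000, False, "non-clustered_del_0-10kb"),
        ("inv", 15_000_000, True, "clustered_inv_>10Mb"),
        ("tds", 10_000, False, "non-clustered_tds_0-10kb"),  # right-closed edge
        ("tds", 10_001, False, "non-clustered_tds_10-100kb"),
    ])
    def test_intra_examples(self, svtype, size, clustered, label):
        rec = SVRecord("S", "1", 1000, "1", 1000 + size, svclass=svtype,
                       clustered=clustered)
        assert classify_sv(rec) == label

    def test_translocations_unbinned(self):
        rec = SVRecord("S", "1", 1000, "2", 99_000_000, svclass="trans",
                       clustered=True)
        assert classify_sv(rec) == "clustered_trans"

    def test_partition_all_32_reachable(self):
        seen = set()
        sizes = {"0-10kb": 5_000, "10-100kb": 50_000, "100kb-1Mb": 500_000,
                 "1Mb-10Mb": 5_000_000, ">10Mb": 50_000_000}
        for clustered, svtype in itertools.product((True, False),
                                                   ("del", "tds", "inv")):
            for b in SV_SIZE_BINS:
                rec = SVRecord("S", "1", 1000, "1", 1000 + sizes[b],
                               svclass=svtype, clustered=clustered)
                seen.add(classify_sv(rec))
        for clustered in (True, False):
            rec = SVRecord("S", "1", 1000, "2", 2000, svclass="trans",
                           clustered=clustered)
            seen.add(classify_sv(rec))
        assert seen == set(SV32_CHANNELS)


class TestBuildSVMatrix:
    def test_conservation_one_of_each_type(self):
        recs = [
            SVRecord("S", "1", 1000, "1", 6000, svclass="del"),
            SVRecord("S", "2", 1000, "2", 6000, svclass="tds"),
            SVRecord("S", "3", 1000, "3", 6000, svclass="inv"),
            SVRecord("S", "4", 1000, "5", 6000, svclass="trans"),
        ]
        m = build_sv_matrix(recs)
        assert m.df.shape == (32, 1)
        assert m.column("S").sum() == 4
        assert (m.column("S") > 0).sum() == 4

    def test_empty_channels_present_as_zeros(self):
        m = build_sv_matrix([SVRecord("S", "1", 1000, "1", 6000, svclass="del")])
        assert len(m.channel_labels) == 32
        assert m.total() == 1
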