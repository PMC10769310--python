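"""Depth profiles, copy-number normalization, presence calls, downsampling."""

import numpy as np
import pysam
import pytest

from retrotrace.coverage import (
    MissingReferenceError,
    DepthProfile,
    call_presence,
    compute_depth_profile,
    downsample_reads,
    estimate_copy_number,
    genome_depth_from_fastq,
    is_low_depth,
)
from retrotrace.models import CopyNumberEstimate


def make_bam(path, reads, ref="Q", ref_len=500):
    """Write a tiny sorted+indexed BAM from (pos, seq, mapq, qual, cigar) tuples."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref, "LN": ref_len}]}
    )
    tmp = str(path) + ".unsorted"
    with pysam.AlignmentFile(tmp, "wb", header=header) as fh:
        for i, (pos, seq, mapq, qual, cigar) in enumerate(reads):
            a = pysam.AlignedSegment(header=header)
            a.query_name = f"r{i}"
            a.reference_name = ref
            a.reference_start = pos
            a.mapping_quality = mapq
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual)
            a.cigartuples = cigar
            fh.write(a)
    pysam.sort("-o", str(path), tmp)
    pysam.index(str(path))
    return path


class TestDepthProfile:
    def test_no_alignments_all_zero(self, tmp_path):
        bam = make_bam(tmp_path / "e.bam", [])
        profile = compute_depth_profile(bam, "Q")
        assert profile.depth.sum() == 0 and len(profile.depth) == 500

    def test_single_read_covers_its_span(self, tmp_path):
        bam = make_bam(tmp_path / "one.bam", [(0, "A" * 100, 60, "I" * 100, [(0, 100)])])
        profile = compute_depth_profile(bam, "Q")
        assert np.all(profile.depth[:100] == 1)
        assert np.all(profile.depth[100:] == 0)

    def test_mapq_filter_and_clips_and_deletions(self, tmp_path):
        reads = [
            (0, "A" * 100, 10, "I" * 100, [(0, 100)]),  # below min_mapq
            # 20S60M: clipped bases contribute nothing
            (200, "A" * 80, 60, "I" * 80, [(4, 20), (0, 60)]),
            # 30M10D30M: the deletion gap gains no depth
            (300, "A" * 60, 60, "I" * 60, [(0, 30), (2, 10), (0, 30)]),
        ]
        bam = make_bam(tmp_path / "f.bam", reads)
        profile = compute_depth_profile(bam, "Q", min_mapq=20)
        assert np.all(profile.depth[:100] == 0)
        assert np.all(profile.depth[200:260] == 1)
        assert np.all(profile.depth[300:330] == 1)
        assert np.all(profile.depth[330:340] == 0)
        assert np.all(profile.depth[340:370] == 1)

    def test_missing_reference_rejected(self, tmp_path):
        bam = make_bam(tmp_path / "g.bam", [])
        with pytest.raises(MissingReferenceError):
            compute_depth_profile(bam, "nope")


class TestCopyNumber:
    def test_uniform_depth_normalization(self):
        profile = DepthProfile(query="Q", depth=np.full(200, 150))
        est = estimate_copy_number(profile, genome_depth=50.0)
        assert est.cn == pytest.approx(3.0)
        assert est.breadth == 1.0

    def test_zero_profile(self):
        est = estimate_copy_number(DepthProfile(query="Q", depth=np.zeros(100)), 50.0)
        assert est.cn == 0.0 and est.breadth == 0.0

    def test_invalid_genome_depth(self):
        with pytest.raises(ValueError):
            estimate_copy_number(DepthProfile(query="Q", depth=np.ones(10)), 0.0)

    def test_estimate_invariant_to_downsampling(self, tmp_path, small_world):
        # cn has depth in numerator and denominator, so thinning 200x->100x
        # (here: retaining half the reads) leaves it unchanged within noise
        from retrotrace.coverage import compute_depth_profile

        truth, strain = small_world["truth"], small_world["strain"]
        te = truth.te_models["Ty4"]
        g = small_world["genomes"][strain]
        full_fq = small_world["fastq"]
        half_fq = downsample_reads(full_fq, 200.0, 100.0, tmp_path / "half.fastq", seed=1)
        from retrotrace.sequencing import emit_alignments

        half_bam = emit_alignments(half_fq, g, truth.te_models, tmp_path / "half.bam")
        cn_full = estimate_copy_number(
            compute_depth_profile(small_world["bam"], te.internal_query),
            genome_depth_from_fastq(full_fq, g.length),
        ).cn
        cn_half = estimate_copy_number(
            compute_depth_profile(half_bam, te.internal_query),
            genome_depth_from_fastq(half_fq, g.length),
        ).cn
        assert cn_half == pytest.approx(cn_full, rel=0.10)


class TestPresenceCalls:
    def test_thresholds_from_figure(self):
        ltr = CopyNumberEstimate(cn=1.2, breadth=1.0, genome_depth=50)
        internal = CopyNumberEstimate(cn=0.3, breadth=0.6, genome_depth=50)
        call = call_presence(ltr, internal)
        assert call.ltr_present and not call.internal_present
        assert call.interpretation == "past activity"

    def test_absent_subfamily(self):
        zero = CopyNumberEstimate(cn=0.0, breadth=0.0, genome_depth=50)
        call = call_presence(zero, zero)
        assert not call.ltr_present and not call.internal_present
        assert call.interpretation == "absent"

    def test_recent_activity_interpretation(self):
        ltr = CopyNumberEstimate(cn=4.0, breadth=1.0, genome_depth=50)
        internal = CopyNumberEstimate(cn=2.0, breadth=1.0, genome_depth=50)
        assert call_presence(ltr, internal).interpretation == "recent activity"

    def test_threshold_is_strict(self):
        at = CopyNumberEstimate(cn=1.0, breadth=1.0, genome_depth=50)
        internal = CopyNumberEstimate(cn=0.5, breadth=1.0, genome_depth=50)
        call = call_presence(at, internal)
        assert not call.ltr_present and not call.internal_present


class TestDownsampling:
    def test_below_target_returned_unchanged(self, tmp_path, small_world):
        out = downsample_reads(small_world["fastq"], 80.0, 100.0, tmp_path / "o.fastq", seed=1)
        assert out.read_bytes() == small_world["fastq"].read_bytes()

    def test_at_target_identical(self, tmp_path, small_world):
        out = downsample_reads(small_world["fastq"], 100.0, 100.0, tmp_path / "o.fastq", seed=1)
        assert out.read_bytes() == small_world["fastq"].read_bytes()

    def test_thinning_retains_binomial_fraction(self, tmp_path, small_world):
        n_in = sum(1 for _ in open(small_world["fastq"])) // 4
        out = downsample_reads(small_world["fastq"], 200.0, 100.0, tmp_path / "o.fastq", seed=2)
        n_out = sum(1 for _ in open(out)) // 4
        p = 0.5
        assert abs(n_out - n_in * p) <= 4 * np.sqrt(n_in * p * (1 - p))

    def test_deterministic_given_seed(self, tmp_path, small_world):
        a = downsample_reads(small_world["fastq"], 200.0, 100.0, tmp_path / "a.fastq", seed=3)
        b = downsample_reads(small_world["fastq"], 200.0, 100.0, tmp_path / "b.fastq", seed=3)
        assert a.read_bytes() == b.read_bytes()

    def test_invalid_target_rejected(self, tmp_path, small_world):
        with pytest.raises(ValueError):
            downsample_reads(small_world["fastq"], 200.0, 0.0, tmp_path / "o.fastq", seed=1)


def test_low_depth_flagging():
    assert is_low_depth(9.99)
    assert not is_low_depth(10.0)
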