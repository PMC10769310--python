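"""Copy-number estimation from read depth over LTR and internal TE queries.

Copy number is normalized depth: mean per-base read depth over a query
divided by the single-copy genome depth.  Because LTR-LTR recombination
turns full-length elements into solo LTRs, LTR and internal queries are
profiled separately; a strain with N full-length elements and S solo LTRs
is expected to show cn_internal = N and cn_ltr = 2N + S.  Subfamily
presence is called at fixed thresholds (LTR copy number > 1, internal
copy number > 0.5), and samples sequenced above 100x are down-sampled to
100x first so depth noise is comparable across strains.  Edge positions of
the query are not trimmed from the profile.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .models import CopyNumberEstimate, PresenceCall

#: paper-level defaults
TAU_LTR = 1.0
TAU_INT = 0.5
DOWNSAMPLE_TARGET = 100.0
MIN_GENOME_DEPTH = 10.0  # strains sequenced below this are flagged/excluded


class MissingReferenceError(KeyError):
    """The requested query is absent from the alignment header."""


@dataclass
class DepthProfile:
    """Per-position read depth over one TE query."""

    query: str
    depth: np.ndarray  # nonnegative ints, length == query length
    min_mapq: int = 0
    downsampled_from: float | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if (self.depth < 0).any():
            raise ValueError("depth must be nonnegative")

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    @property
    def breadth(self) -> float:
        return float((self.depth > 0).mean()) if len(self.depth) else 0.0


def downsample_reads(
    fastq_in,
    current_depth: float,
    target_depth: float,
    fastq_out,
    seed: int,
) -> Path:
    """Thin a FASTQ to a target depth; no-op when already at or below it.

    Reads are retained independently with probability target/current, so the
    retained count is Binomial(n, target/current).  Deterministic given
    ``seed``; when no thinning is needed the file is copied byte-identically.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be > 0")
    if current_depth <= 0:
        raise ValueError("current_depth must be > 0")
    fastq_in, fastq_out = Path(fastq_in), Path(fastq_out)
    if current_depth <= target_depth:
        if fastq_in != fastq_out:
            shutil.copyfile(fastq_in, fastq_out)
        return fastq_out
    keep_p = target_depth / current_depth
    rng = np.random.default_rng([606, seed])
    with open(fastq_in) as src, open(fastq_out, "w") as dst:
        while True:
            block = [src.readline() for _ in range(4)]
            if not block[0]:
                break
            if rng.random() < keep_p:
                dst.writelines(block)
    return fastq_out


def compute_depth_profile(alignments, query: str, min_mapq: int = 0) -> DepthProfile:
    """Per-position count of aligned read bases over ``query``.

    Only reads with MAPQ >= ``min_mapq`` contribute.  Soft-clipped bases and
    read deletions contribute no depth; positions outside any alignment are
    zero.  The full query length is profiled (no edge trimming).
    """
    with pysam.AlignmentFile(str(alignments)) as bam:
        if query not in bam.references:
            raise MissingReferenceError(f"query {query!r} not in alignment header")
        length = bam.get_reference_length(query)
        depth = np.zeros(length, dtype=np.int64)
        for read in bam.fetch(query):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            for start, end in read.get_blocks():
                depth[start:end] += 1
    return DepthProfile(query=query, depth=depth, min_mapq=min_mapq)


def estimate_copy_number(profile: DepthProfile, genome_depth: float) -> CopyNumberEstimate:
    """Normalize a depth profile by the single-copy genome depth."""
    if genome_depth <= 0:
        raise ValueError("genome_depth must be > 0")
    return CopyNumberEstimate(
        cn=profile.mean_depth / genome_depth,
        breadth=profile.breadth,
        genome_depth=genome_depth,
    )


def call_presence(
    cn_ltr: CopyNumberEstimate,
    cn_int: CopyNumberEstimate,
    tau_ltr: float = TAU_LTR,
    tau_int: float = TAU_INT,
) -> PresenceCall:
    """Threshold copy numbers into a presence/absence call.

    LTR presence requires cn > tau_ltr (default 1); internal presence
    requires cn > tau_int (default 0.5).  Internal presence is evidence of
    recent activity; an LTR-only signal records past activity.
    """
    return PresenceCall(
        ltr_present=cn_ltr.cn > tau_ltr,
        internal_present=cn_int.cn > tau_int,
        tau_ltr=tau_ltr,
        tau_int=tau_int,
    )


def genome_depth_from_fastq(fastq_path, genome_length: int) -> float:
    """Single-copy genome depth implied by a uniform WGS read set.

    Computed as total sequenced bases / genome length.  With uniformly
    simulated reads this equals the median background depth up to sampling
    noise; repeats occupy a negligible fraction of the genome at the scales
    simulated here.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    total = 0
    with open(fastq_path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                total += len(line.strip())
    return total / genome_length


def is_low_depth(genome_depth: float, min_depth: float = MIN_GENOME_DEPTH) -> bool:
    """Flag strains sequenced below the minimum usable genome depth."""
    return genome_depth < min_depth
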