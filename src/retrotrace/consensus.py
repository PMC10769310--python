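"""Strain-specific TE consensus sequences from filtered read pileups.

A strain's copies of a subfamily are summarized by a single consensus
called from the pooled pileup of all reads mapped to the TE query.
Alignments below MAPQ 20 and bases below quality 20 are excluded, and only
aligned match/mismatch columns are counted (indels are skipped).  The
consensus substitutes the majority base wherever read support exists;
uncovered positions are filled from the reference query.  To avoid
consensus sequences biased toward the reference, strains with normalized
depth < 0.75 or breadth < 0.9 over the query are dropped from downstream
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .coverage import MissingReferenceError
from .models import BASES

MIN_MAPQ = 20
MIN_BASEQ = 20
DELTA_MIN = 0.75  # minimum normalized depth for retention
BETA_MIN = 0.9  # minimum breadth for retention

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class Pileup:
    """Filtered per-position base counts over one TE query."""

    query: str
    counts: np.ndarray  # shape (query_length, 4), A/C/G/T
    min_mapq: int = MIN_MAPQ
    min_baseq: int = MIN_BASEQ

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (length, 4)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def build_pileup(
    alignments,
    query: str,
    min_mapq: int = MIN_MAPQ,
    min_baseq: int = MIN_BASEQ,
) -> Pileup:
    """Base counts per query position over quality-filtered reads.

    Reads below ``min_mapq`` contribute nothing; bases below ``min_baseq``
    are dropped column-wise.  Only aligned match/mismatch columns count:
    inserted read bases have no reference column and deleted reference
    columns gain no depth.
    """
    with pysam.AlignmentFile(str(alignments)) as bam:
        if query not in bam.references:
            raise MissingReferenceError(f"query {query!r} not in alignment header")
        length = bam.get_reference_length(query)
        counts = np.zeros((length, 4), dtype=np.int64)
        for read in bam.fetch(query):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                base = seq[qpos]
                idx = _BASE_INDEX.get(base)
                if idx is not None:
                    counts[rpos, idx] += 1
    return Pileup(query=query, counts=counts, min_mapq=min_mapq, min_baseq=min_baseq)


@dataclass
class ConsensusSequence:
    """A called consensus over a TE query, with its retention metrics."""

    sequence: str  # over {A,C,G,T,N}, same length as the query
    breadth: float  # fraction of positions with depth >= min_depth
    n_ref_filled: int  # positions filled from the reference for lack of depth
    normalized_depth: float | None = None  # set from the coverage stage
    retained: bool | None = None

    def identity_to(self, other: str) -> float:
        """Fraction identity to another equal-length sequence (Ns excluded)."""
        if len(other) != len(self.sequence):
            raise ValueError("length mismatch")
        pairs = [
            (a, b)
            for a, b in zip(self.sequence, other)
            if a in _BASE_INDEX and b in _BASE_INDEX
        ]
        if not pairs:
            return 0.0
        return sum(a == b for a, b in pairs) / len(pairs)


def call_consensus(
    pileup: Pileup,
    reference: str,
    min_frac: float = 0.5,
    min_depth: int = 1,
) -> ConsensusSequence:
    """Majority-rule consensus of a pileup against its reference query.

    Per position: with depth >= ``min_depth`` and a unique majority base at
    fraction > ``min_frac``, the majority base is emitted; with depth but no
    majority (ties included), N; with depth below ``min_depth``, the
    reference base is emitted (reference fill, counted).  Breadth is the
    fraction of positions with depth >= ``min_depth``; reference-filled
    positions can never exceed 1 - breadth of sites.
    """
    if len(reference) != pileup.counts.shape[0]:
        raise ValueError(
            f"reference length {len(reference)} != pileup length {pileup.counts.shape[0]}"
        )
    counts = pileup.counts
    depth = counts.sum(axis=1)
    out = []
    n_fill = 0
    for i, d in enumerate(depth):
        if d < min_depth:
            out.append(reference[i])
            n_fill += 1
            continue
        row = counts[i]
        top = row.max()
        if (row == top).sum() > 1 or top / d <= min_frac:
            out.append("N")
        else:
            out.append(BASES[int(row.argmax())])
    breadth = float((depth >= min_depth).mean()) if len(depth) else 0.0
    return ConsensusSequence(sequence="".join(out), breadth=breadth, n_ref_filled=n_fill)


def filter_consensus(
    cons: ConsensusSequence,
    delta_min: float = DELTA_MIN,
    beta_min: float = BETA_MIN,
) -> bool:
    """Retention rule: keep only strains with depth >= 0.75 and breadth >= 0.9.

    ``cons.normalized_depth`` must have been set from the coverage stage.
    Sets and returns ``cons.retained``.
    """
    if cons.normalized_depth is None:
        raise ValueError("normalized_depth must be set before filtering")
    cons.retained = cons.normalized_depth >= delta_min and cons.breadth >= beta_min
    return cons.retained
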