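"""Pairwise divergence, sliding-window scans, and recombination breakpoints.

Divergence is measured with Kimura's two-parameter (K2P) model, which
corrects observed differences for multiple hits while distinguishing
transitions (P, purine<->purine or pyrimidine<->pyrimidine) from
transversions (Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Recombinant elements are detected by sliding a 50-bp window in 10-bp steps
along an alignment of a query element against two candidate parental
references; runs where the query is consistently closer to one parent than
the other define parental segments, and sign changes of the distance
difference flanked by long consistent runs define breakpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

# status markers for windows / pairs
OK = "ok"
SATURATED = "saturated"  # a log argument of the K2P formula was <= 0
UNDEFINED = "undefined"  # too few comparable sites

MIN_COMPARABLE_SITES = 10

_PURINES = frozenset("AG")
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}  # 0/1 purines, 2/3 pyrimidines


class SaturationError(ValueError):
    """Raised when a distance matrix entry is saturated or undefined."""


@dataclass(frozen=True)
class K2PResult:
    """K2P distance with its transition/transversion decomposition."""

    d: float  # nan unless status == OK
    P: float  # transition proportion over compared sites
    Q: float  # transversion proportion over compared sites
    n_sites: int  # number of compared (both-ACGT) columns
    status: str

    def __float__(self) -> float:
        return self.d


def _encode(seq: str) -> np.ndarray:
    """Encode a sequence to int8 codes; non-ACGT (gaps, N) become -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def k2p_from_counts(n_sites: int, n_transitions: int, n_transversions: int) -> K2PResult:
    """Evaluate the K2P formula from site counts."""
    if n_sites < MIN_COMPARABLE_SITES:
        return K2PResult(math.nan, math.nan, math.nan, n_sites, UNDEFINED)
    P = n_transitions / n_sites
    Q = n_transversions / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(math.nan, P, Q, n_sites, SATURATED)
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(d, P, Q, n_sites, OK)


def k2p_distance(a: str, b: str) -> K2PResult:
    """K2P distance between two equal-length aligned sequences.

    Columns where either sequence is not a plain A/C/G/T base (gaps, N) are
    excluded pairwise.  Pairs with fewer than 10 comparable columns are
    reported ``undefined``; pairs whose observed divergence puts a log
    argument at or below zero are reported ``saturated``.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    ca, cb = _encode(a), _encode(b)
    return _k2p_encoded(ca, cb)


def _k2p_encoded(ca: np.ndarray, cb: np.ndarray) -> K2PResult:
    mask = (ca >= 0) & (cb >= 0)
    n = int(mask.sum())
    if n < MIN_COMPARABLE_SITES:
        return K2PResult(math.nan, math.nan, math.nan, n, UNDEFINED)
    xa, xb = ca[mask], cb[mask]
    diff = xa != xb
    # same purine/pyrimidine class but different base -> transition
    transitions = int((diff & ((xa >> 1) == (xb >> 1))).sum())
    transversions = int(diff.sum()) - transitions
    return k2p_from_counts(n, transitions, transversions)


@dataclass
class SeqAlignment:
    """A gap-aware multiple sequence alignment over {A,C,G,T,-,N}.

    Sequences produced by the substitution-only simulator are homologous and
    equal-length, so collections of simulated elements are valid alignments
    without an external aligner.
    """

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one record")
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, ids: Iterable[str]) -> "SeqAlignment":
        ids = list(ids)
        missing = [i for i in ids if i not in self.records]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return SeqAlignment({i: self.records[i] for i in ids})

    def slice_columns(self, start: int, end: int) -> "SeqAlignment":
        if not (0 <= start < end <= self.length):
            raise ValueError(f"invalid column slice [{start}, {end})")
        return SeqAlignment({i: s[start:end] for i, s in self.records.items()})

    @classmethod
    def from_fasta(cls, path) -> "SeqAlignment":
        from Bio import SeqIO

        return cls({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.records.items():
                fh.write(f">{rid}\n{seq}\n")


@dataclass
class DivergenceTrack:
    """Windowed K2P divergence of one query against one or more references."""

    query_id: str
    centers: np.ndarray  # window-center alignment columns, strictly increasing
    window: int
    step: int
    d: dict[str, np.ndarray]  # per reference: K2P distance per window (nan if not OK)
    status: dict[str, list[str]]  # per reference: OK/SATURATED/UNDEFINED per window

    @property
    def n_windows(self) -> int:
        return len(self.centers)

    def to_frame(self):
        import pandas as pd

        cols = {"window_center": self.centers}
        for ref, vals in self.d.items():
            cols[f"d_{ref}"] = vals
            cols[f"status_{ref}"] = self.status[ref]
        return pd.DataFrame(cols)


def sliding_divergence(
    aln: SeqAlignment,
    query_id: str,
    ref_ids: list[str],
    window: int = 50,
    step: int = 10,
) -> DivergenceTrack:
    """Sliding-window K2P divergence of ``query_id`` against each reference.

    Windows start at columns 0, step, 2*step, ... and span ``window`` columns;
    the last window is the one whose end still fits in the alignment.
    Windows where more than half of the query bases are non-ACGT are marked
    undefined regardless of the reference.
    """
    if window > aln.length:
        raise ValueError(f"window ({window}) exceeds alignment length ({aln.length})")
    if step < 1 or window < 1:
        raise ValueError("window and step must be >= 1")
    query = _encode(aln.records[query_id])
    refs = {r: _encode(aln.records[r]) for r in ref_ids}
    starts = np.arange(0, aln.length - window + 1, step)
    centers = starts + window / 2.0
    d = {r: np.full(len(starts), np.nan) for r in ref_ids}
    status = {r: [UNDEFINED] * len(starts) for r in ref_ids}
    for wi, s in enumerate(starts):
        qwin = query[s : s + window]
        query_bad = (qwin < 0).sum() > window / 2
        for r in ref_ids:
            if query_bad:
                continue
            res = _k2p_encoded(qwin, refs[r][s : s + window])
            status[r][wi] = res.status
            if res.status == OK:
                d[r][wi] = res.d
    return DivergenceTrack(query_id=query_id, centers=centers, window=window, step=step, d=d, status=status)


@dataclass
class Segment:
    """A parental segment between breakpoints, in alignment columns."""

    start: float
    end: float
    parent: str


@dataclass
class BreakpointSet:
    """Inferred recombination breakpoints and parental segment labels."""

    breakpoints: list[float] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")


class NoSignalError(ValueError):
    """Raised when a divergence track has no usable windows."""


def detect_breakpoints(
    track: DivergenceTrack,
    ref_a: str,
    ref_b: str,
    min_run: int = 5,
) -> BreakpointSet:
    """Locate parent switches in a two-reference divergence track.

    For each window let s = d(query, ref_a) - d(query, ref_b).  A breakpoint
    is placed at the midpoint between the bounding window centers of every
    sign change of s that is preceded and followed by at least ``min_run``
    windows of consistent sign; shorter runs are treated as jitter and yield
    no breakpoint.  Each segment is labeled with the nearer parent (the
    majority sign of its windows).
    """
    sa, sb = track.d[ref_a], track.d[ref_b]
    usable = ~(np.isnan(sa) | np.isnan(sb))
    if not usable.any():
        raise NoSignalError("no window has defined divergence to both references")
    centers = track.centers[usable]
    s = sa[usable] - sb[usable]
    # sign per window; exact ties adopt the previous sign (continuation)
    signs = np.sign(s)
    for i in range(len(signs)):
        if signs[i] == 0:
            signs[i] = signs[i - 1] if i > 0 else 0.0
    if signs[0] == 0:
        nz = np.nonzero(signs)[0]
        if len(nz) == 0:
            raise NoSignalError("query equidistant from both references everywhere")
        signs[: nz[0]] = signs[nz[0]]

    # run-length encoding of signs
    runs: list[tuple[float, int, int]] = []  # (sign, first_idx, last_idx)
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            runs.append((signs[start], start, i - 1))
            start = i

    breakpoints: list[float] = []
    for (_, first1, last1), (_, first2, last2) in zip(runs, runs[1:]):
        len1 = last1 - first1 + 1
        len2 = last2 - first2 + 1
        if len1 >= min_run and len2 >= min_run:
            breakpoints.append((centers[last1] + centers[first2]) / 2.0)

    label = {1.0: ref_b, -1.0: ref_a}  # s < 0 -> closer to ref_a
    bounds = [float(centers[0])] + breakpoints + [float(centers[-1])]
    segments: list[Segment] = []
    for lo, hi in zip(bounds, bounds[1:]):
        in_seg = (centers >= lo) & (centers <= hi)
        seg_sign = 1.0 if signs[in_seg].sum() > 0 else -1.0
        segments.append(Segment(start=lo, end=hi, parent=label[seg_sign]))
    # merge any adjacent segments that ended up with the same label
    merged: list[Segment] = []
    kept_bps: list[float] = []
    for seg in segments:
        if merged and merged[-1].parent == seg.parent:
            merged[-1] = Segment(merged[-1].start, seg.end, seg.parent)
        else:
            if merged:
                kept_bps.append(seg.start)
            merged.append(seg)
    return BreakpointSet(breakpoints=kept_bps, segments=merged)


def partition_alignment(aln: SeqAlignment, breakpoints: list[float]) -> list[SeqAlignment]:
    """Split an alignment into column ranges at the given breakpoints.

    Breakpoint positions are alignment columns (fractional positions are
    floored); the resulting slices tile the alignment exactly, so
    concatenating the partitions reproduces the input column-for-column.
    """
    if any(b2 <= b1 for b1, b2 in zip(breakpoints, breakpoints[1:])):
        raise ValueError("breakpoints must be strictly increasing")
    cuts = [int(b) for b in breakpoints]
    if any(c < 1 or c > aln.length - 1 for c in cuts):
        raise ValueError(f"breakpoints must lie within [1, {aln.length - 1}]")
    bounds = [0] + cuts + [aln.length]
    return [aln.slice_columns(lo, hi) for lo, hi in zip(bounds, bounds[1:])]
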