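"""Annotation of TE copies in genome assemblies.

Two complementary detectors are provided:

* a homology pipeline (seed -> chain -> trimmed extension against a query
  library) that finds LTR and internal-region hits, defragments co-linear
  hits into element chains, and classifies each chain as a full-length
  element (FLE), a truncated element, or a solo LTR;
* a structural detector that finds LTR pairs de novo from the genome alone:
  exact repeat seeds at an inter-LTR spacing within bounds, x-drop
  extension, similarity >= 80%, 5-bp target-site duplication identity, and
  TG...CA termini, with overlapping candidates resolved to the best-scoring
  one.  Its parameter set (seed 100, LTR length 100-1000, start-to-start
  distance 1500-15000, similarity 80.0, TSD 5, motif tg..ca, x-drop 5,
  match/mismatch +2/-2, boundary vicinity 60) mirrors standard structural
  LTR prediction defaults for yeast Ty elements.

Because the simulator evolves sequences by substitution only, homologous
copies stay on a single alignment diagonal; the extension step is therefore
an ungapped maximal-scoring-segment trim rather than a banded gapped
alignment, which is exact under that regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import FLE, INTERNAL, LTR, SOLO_LTR, TRUNCATED, TEModel, revcomp

DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_SEED_K = 12
DEFAULT_MIN_HIT_LENGTH = 50
DEFAULT_MAX_GAP = 500
DEFAULT_THETA_FLE = 0.9
DEFAULT_D_JOIN = 500
SOLO_MIN_LTR_FRACTION = 0.8


@dataclass
class RepeatHit:
    """A local homology hit of one TE query region on a genome contig."""

    subfamily: str
    region: str  # LTR or INTERNAL
    contig: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    percent_identity: float
    qstart: int  # interval on the (forward) query
    qend: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit interval must have start < end")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity must be in [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


def _seed_clusters(query: str, genome: str, k: int, max_qgap: int = 600):
    """Exact k-mer matches grouped by alignment diagonal.

    Substitution-only homology keeps a true hit on one diagonal; each
    (diagonal, query-position run) cluster becomes one extension candidate.
    """
    index: dict[str, list[int]] = {}
    for qpos in range(len(query) - k + 1):
        index.setdefault(query[qpos : qpos + k], []).append(qpos)
    by_diag: dict[int, list[int]] = {}
    for gpos in range(len(genome) - k + 1):
        hits = index.get(genome[gpos : gpos + k])
        if not hits:
            continue
        for qpos in hits:
            by_diag.setdefault(gpos - qpos, []).append(qpos)
    for diag, qlist in by_diag.items():
        qlist.sort()
        run = [qlist[0]]
        for q in qlist[1:]:
            if q - run[-1] <= max_qgap:
                run.append(q)
            else:
                yield diag, run[0], run[-1] + k
                run = [q]
        yield diag, run[0], run[-1] + k


def _best_segment(matches: np.ndarray, mismatch_penalty: float) -> tuple[int, int, int] | None:
    """Maximal-scoring contiguous segment of a 0/1 match array.

    Match scores +1, mismatch scores -``mismatch_penalty``; the returned
    segment is the ungapped local alignment (start, end, n_matches).
    """
    scores = np.where(matches, 1.0, -mismatch_penalty)
    best = best_start = best_end = -1.0
    cur = 0.0
    cur_start = 0
    best_range = None
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = s
            cur_start = i
        else:
            cur += s
        if cur > best:
            best = cur
            best_range = (cur_start, i + 1)
    if best_range is None or best <= 0:
        return None
    a, b = best_range
    return a, b, int(matches[a:b].sum())


def find_repeat_hits(
    genome: dict[str, str],
    library: list[TEModel],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_k: int = DEFAULT_SEED_K,
    min_length: int = DEFAULT_MIN_HIT_LENGTH,
) -> list[RepeatHit]:
    """Find local homology hits of every library query on both strands.

    Seeds are shared ``seed_k``-mers; seeds on a common diagonal are chained
    and the implied full-query window is trimmed to its maximal-scoring
    ungapped segment.  Hits shorter than ``min_length`` or below
    ``min_identity`` percent identity are discarded.
    """
    if not genome or not any(genome.values()):
        raise ValueError("genome is empty")
    if not library:
        raise ValueError("query library is empty")
    penalty = min_identity / (100.0 - min_identity) if min_identity < 100 else 99.0
    hits: list[RepeatHit] = []
    for contig, gseq in genome.items():
        gseq = gseq.upper()
        garr = np.frombuffer(gseq.encode(), dtype=np.uint8)
        for te in library:
            for region, qfwd in ((LTR, te.ltr_seq), (INTERNAL, te.internal_seq)):
                qlen = len(qfwd)
                for strand in "+-":
                    q = qfwd if strand == "+" else revcomp(qfwd)
                    qarr = np.frombuffer(q.encode(), dtype=np.uint8)
                    for diag, q0, q1 in _seed_clusters(q, gseq, seed_k):
                        # expand candidate to the full query span, clipped
                        g0 = max(diag, 0)
                        g1 = min(diag + qlen, len(gseq))
                        if g1 - g0 < min_length:
                            continue
                        qs0 = g0 - diag
                        matches = garr[g0:g1] == qarr[qs0 : qs0 + (g1 - g0)]
                        seg = _best_segment(matches, penalty)
                        if seg is None:
                            continue
                        a, b, n_match = seg
                        if b - a < min_length:
                            continue
                        identity = 100.0 * n_match / (b - a)
                        if identity < min_identity:
                            continue
                        hs, he = g0 + a, g0 + b
                        qs, qe = qs0 + a, qs0 + b
                        if strand == "-":
                            qs, qe = qlen - qe, qlen - qs
                        hits.append(
                            RepeatHit(
                                subfamily=te.name,
                                region=region,
                                contig=contig,
                                start=hs,
                                end=he,
                                strand=strand,
                                percent_identity=identity,
                                qstart=qs,
                                qend=qe,
                            )
                        )
    return _dedupe_hits(hits)


def _dedupe_hits(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Drop hits mostly contained in a better hit of the same query/strand."""
    out: list[RepeatHit] = []
    key = lambda h: (h.contig, h.subfamily, h.region, h.strand)
    hits = sorted(hits, key=lambda h: (key(h), -h.length * h.percent_identity))
    kept: dict[tuple, list[RepeatHit]] = {}
    for h in hits:
        group = kept.setdefault(key(h), [])
        redundant = False
        for other in group:
            ov = min(h.end, other.end) - max(h.start, other.start)
            if ov > 0.5 * h.length:
                redundant = True
                break
        if not redundant:
            group.append(h)
    for group in kept.values():
        out.extend(group)
    return sorted(out, key=lambda h: (h.contig, h.start, h.end))


# ---------------------------------------------------------------------------
# defragmentation and classification


@dataclass
class Chain:
    """Co-linear hits of one subfamily merged into a candidate element."""

    subfamily: str
    contig: str
    strand: str
    hits: list[RepeatHit]
    canonical: list[tuple[int, int]]  # per hit: interval in canonical coords

    @property
    def start(self) -> int:
        return min(h.start for h in self.hits)

    @property
    def end(self) -> int:
        return max(h.end for h in self.hits)


def _canonical_options(hit: RepeatHit, te: TEModel) -> list[tuple[int, int]]:
    """Possible intervals of a hit on canonical (LTR+internal+LTR) coordinates."""
    if hit.region == INTERNAL:
        return [(te.ltr_length + hit.qstart, te.ltr_length + hit.qend)]
    five = (hit.qstart, hit.qend)
    three = (te.ltr_length + te.internal_length + hit.qstart,
             te.ltr_length + te.internal_length + hit.qend)
    return [five, three]


def defragment_hits(
    hits: list[RepeatHit],
    te_models: dict[str, TEModel],
    max_gap: int = DEFAULT_MAX_GAP,
    slack: int = 50,
) -> list[Chain]:
    """Merge co-linear same-subfamily, same-strand hits into element chains.

    Hits are chained when the genomic gap is at most ``max_gap`` and their
    canonical element coordinates advance monotonically along the genome
    (reversed for minus-strand chains); hits with incompatible (non-monotone)
    query order start a new chain.  Chains never span contigs.
    """
    chains: list[Chain] = []
    groups: dict[tuple, list[RepeatHit]] = {}
    for h in hits:
        groups.setdefault((h.contig, h.subfamily, h.strand), []).append(h)
    for (contig, sub, strand), group in sorted(groups.items()):
        te = te_models[sub]
        group = sorted(group, key=lambda h: h.start)
        cur: Chain | None = None
        cursor = None  # canonical end (+) / canonical start (-) of last hit
        for h in group:
            options = _canonical_options(h, te)
            chosen = None
            if cur is not None and h.start - cur.end <= max_gap:
                if strand == "+":
                    ok = [o for o in options if o[0] >= cursor - slack]
                    chosen = min(ok, key=lambda o: o[0]) if ok else None
                else:
                    ok = [o for o in options if o[1] <= cursor + slack]
                    chosen = max(ok, key=lambda o: o[1]) if ok else None
            if chosen is None:
                if cur is not None:
                    chains.append(cur)
                chosen = (
                    min(options, key=lambda o: o[0])
                    if strand == "+"
                    else max(options, key=lambda o: o[1])
                )
                cur = Chain(subfamily=sub, contig=contig, strand=strand, hits=[h], canonical=[chosen])
            else:
                cur.hits.append(h)
                cur.canonical.append(chosen)
            cursor = chosen[1] if strand == "+" else chosen[0]
        if cur is not None:
            chains.append(cur)
    return sorted(chains, key=lambda c: (c.contig, c.start))


@dataclass
class ElementCall:
    """A classified genomic TE copy."""

    clazz: str  # FLE / truncated / soloLTR
    subfamily: str
    contig: str
    start: int
    end: int
    strand: str
    hits: list[RepeatHit]
    fraction_of_canonical: float
    nested_flag: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for s, e in sorted(intervals):
        if last_end is None or s >= last_end:
            total += e - s
            last_end = e
        elif e > last_end:
            total += e - last_end
            last_end = e
    return total


def classify_elements(
    chains: list[Chain],
    te_models: dict[str, TEModel],
    theta_fle: float = DEFAULT_THETA_FLE,
    d_join: int = DEFAULT_D_JOIN,
) -> list[ElementCall]:
    """Classify chains into FLE / truncated / solo LTR.

    FLE: the chain covers at least ``theta_fle`` of the canonical length and
    includes hits to both terminal LTRs and the internal region.  Solo LTR:
    the chain consists only of LTR hits covering at least 80% of the LTR,
    with no internal-region hit within ``d_join`` bp.  Everything else is
    truncated.  Chains overlapped by a hit from a different subfamily get
    the nested flag (flagged, not resolved).
    """
    calls: list[ElementCall] = []
    for chain in chains:
        te = te_models[chain.subfamily]
        covered = _union_length(chain.canonical)
        fraction = covered / te.canonical_length
        regions = {h.region for h in chain.hits}
        has_ltr5 = any(
            h.region == LTR and c[0] < te.ltr_length
            for h, c in zip(chain.hits, chain.canonical)
        )
        has_ltr3 = any(
            h.region == LTR and c[0] >= te.ltr_length + te.internal_length
            for h, c in zip(chain.hits, chain.canonical)
        )
        if fraction >= theta_fle and has_ltr5 and has_ltr3 and INTERNAL in regions:
            clazz = FLE
        elif regions == {LTR}:
            ltr_cov = _union_length(
                [(h.qstart, h.qend) for h in chain.hits]
            )
            near_internal = any(
                h.region == INTERNAL
                and h.contig == chain.contig
                and h.start < chain.end + d_join
                and h.end > chain.start - d_join
                for other in chains
                for h in other.hits
                if other is not chain and other.subfamily == chain.subfamily
            )
            if ltr_cov >= SOLO_MIN_LTR_FRACTION * te.ltr_length and not near_internal:
                clazz = SOLO_LTR
            else:
                clazz = TRUNCATED
        else:
            clazz = TRUNCATED
        calls.append(
            ElementCall(
                clazz=clazz,
                subfamily=chain.subfamily,
                contig=chain.contig,
                start=chain.start,
                end=chain.end,
                strand=chain.strand,
                hits=chain.hits,
                fraction_of_canonical=fraction,
            )
        )
    # nested flag: interleaved hits from a different subfamily
    for call in calls:
        for other in calls:
            if other is call or other.contig != call.contig:
                continue
            if other.subfamily == call.subfamily:
                continue
            if other.start > call.start and other.end < call.end:
                call.nested_flag = True
    return sorted(calls, key=lambda c: (c.contig, c.start))


def select_best_calls(calls: list[ElementCall]) -> list[ElementCall]:
    """Resolve overlapping calls from competing (sister) subfamilies.

    With a library of related subfamilies, one genomic copy is typically hit
    by every query above the identity floor; the locus is assigned to the
    subfamily whose hits match it best (length-weighted identity), and the
    competing overlapping calls are dropped.
    """
    scored = sorted(
        calls,
        key=lambda c: -sum(h.length * h.percent_identity for h in c.hits) / max(
            sum(h.length for h in c.hits), 1
        ),
    )
    kept: list[ElementCall] = []
    for c in scored:
        clash = any(
            k.contig == c.contig
            and min(k.end, c.end) - max(k.start, c.start)
            > 0.5 * min(c.end - c.start, k.end - k.start)
            for k in kept
        )
        if not clash:
            kept.append(c)
    return sorted(kept, key=lambda c: (c.contig, c.start))


def extract_fle_internal(
    calls: list[ElementCall],
    genome: dict[str, str],
    te_models: dict[str, TEModel],
    id_prefix: str = "",
) -> dict[str, str]:
    """Extract the internal region of every FLE, strand-normalized.

    The genomic span is projected through the element's longest
    internal-region hit onto the full internal query, so every extracted
    sequence has exactly the query's internal length and sequences from
    colinear subfamilies are directly alignable.  Minus-strand elements are
    reverse complemented so all outputs read 5'->3' on the element.  Record
    ids are ``[prefix]contig:start-end``.  Non-FLE calls produce no output;
    FLEs whose internal span cannot be resolved are skipped with a warning.
    """
    import warnings

    out: dict[str, str] = {}
    for call in calls:
        if call.clazz != FLE:
            continue
        int_hits = [h for h in call.hits if h.region == INTERNAL]
        if not int_hits:
            warnings.warn(
                f"FLE at {call.contig}:{call.start}-{call.end} lacks an internal hit; skipped"
            )
            continue
        hit = max(int_hits, key=lambda h: h.length)
        length = te_models[call.subfamily].internal_length
        if call.strand == "+":
            lo = hit.start - hit.qstart
            hi = lo + length
        else:
            hi = hit.start + hit.qend
            lo = hi - length
        gseq = genome[call.contig]
        if lo < 0 or hi > len(gseq):
            warnings.warn(
                f"FLE at {call.contig}:{call.start}-{call.end} projects outside the contig; skipped"
            )
            continue
        seq = gseq[lo:hi]
        if call.strand == "-":
            seq = revcomp(seq)
        out[f"{id_prefix}{call.contig}:{lo}-{hi}"] = seq
    return out


# ---------------------------------------------------------------------------
# structural detection of LTR pairs


@dataclass
class LTRParams:
    """Parameter block of the structural LTR detector."""

    seed: int = 100  # minimum chained exact-match length
    minlenltr: int = 100
    maxlenltr: int = 1000
    mindistltr: int = 1500  # LTR start-to-start distance bounds
    maxdistltr: int = 15000
    similar: float = 80.0  # minimum inter-LTR percent identity
    xdrop: int = 5
    mat: int = 2
    mis: int = -2
    tsd_len: int = 5
    motif: str = "tgca"  # each LTR starts TG and ends CA
    motifmis: int = 0
    vic: int = 60  # boundary search vicinity
    overlaps: str = "best"
    seed_k: int = 20  # exact-match word size used for seeding


@dataclass
class LTRCandidate:
    """A structurally predicted LTR pair."""

    contig: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    distance: int  # start-to-start
    similarity: float
    tsd: tuple[str, str]
    motif_ok: bool

    @property
    def span(self) -> tuple[int, int]:
        return (self.ltr5[0], self.ltr3[1])


def _xdrop_extend(garr: np.ndarray, sep: int, left: int, right: int, p: LTRParams) -> tuple[int, int]:
    """Extend [left, right) on arm1 (paired with arm1+sep) by x-drop."""
    n = len(garr)
    # rightward
    best = cur = 0
    best_pos = right
    i = right
    while i < n - sep and i + sep < n:
        cur += p.mat if garr[i] == garr[i + sep] else p.mis
        if cur > best:
            best, best_pos = cur, i + 1
        if best - cur > p.xdrop:
            break
        i += 1
    right = best_pos
    # leftward
    best = cur = 0
    best_pos = left
    i = left - 1
    while i >= 0 and i + sep >= 0:
        cur += p.mat if garr[i] == garr[i + sep] else p.mis
        if cur > best:
            best, best_pos = cur, i
        if best - cur > p.xdrop:
            break
        i -= 1
    return best_pos, right


def detect_ltr_candidates(
    genome: dict[str, str],
    params: LTRParams | None = None,
) -> list[LTRCandidate]:
    """De novo structural prediction of LTR pairs from the genome alone.

    Candidate arms are seeded by exact ``seed_k``-mer matches at a common
    separation within the inter-LTR distance bounds; seeds at one separation
    are chained and must cover at least ``seed`` exact bases.  Arms are
    extended by ungapped x-drop, boundaries are refined within ``vic`` bp to
    satisfy TG...CA termini on both arms and a flanking ``tsd_len``-bp
    target-site duplication, and the arm pair must reach ``similar`` percent
    identity with both arm lengths and the start distance in bounds.
    Overlapping candidates keep the higher-similarity one.
    """
    p = params or LTRParams()
    out: list[LTRCandidate] = []
    for contig, seq in genome.items():
        seq = seq.upper()
        garr = np.frombuffer(seq.encode(), dtype=np.uint8)
        index: dict[str, list[int]] = {}
        k = p.seed_k
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append(pos)
        pairs_by_sep: dict[int, list[int]] = {}
        for positions in index.values():
            if len(positions) < 2 or len(positions) > 100:
                continue
            for i, a in enumerate(positions):
                for b in positions[i + 1 :]:
                    sep = b - a
                    if sep > p.maxdistltr:
                        break
                    if sep >= p.mindistltr:
                        pairs_by_sep.setdefault(sep, []).append(a)
        candidates: list[LTRCandidate] = []
        for sep, starts in pairs_by_sep.items():
            starts = sorted(set(starts))
            # cluster seed positions within one arm span
            run: list[int] = []
            for pos in starts + [None]:
                if pos is not None and (not run or pos - run[-1] <= p.maxlenltr):
                    run.append(pos)
                    continue
                if run:
                    cand = _candidate_from_run(garr, seq, contig, sep, run, p)
                    if cand is not None:
                        candidates.append(cand)
                run = [pos] if pos is not None else []
        out.extend(_resolve_overlaps(candidates))
    return sorted(out, key=lambda c: (c.contig, c.span))


def _candidate_from_run(
    garr: np.ndarray,
    seq: str,
    contig: str,
    sep: int,
    run: list[int],
    p: LTRParams,
) -> LTRCandidate | None:
    k = p.seed_k
    left, right = _xdrop_extend(garr, sep, run[0], run[-1] + k, p)
    # the seed threshold is enforced as the number of identical bases in the
    # seeded, extended repeat pair (an exact-k-mer-anchored arm must contain
    # at least `seed` matching positions to survive)
    n_match = int((garr[left:right] == garr[left + sep : right + sep]).sum())
    if n_match < p.seed:
        return None
    # refine boundaries to TG starts / CA ends on both arms with a flanking
    # TSD.  The x-drop bounds (+- vic) are searched first; if divergence
    # stalled the extension short of a motif-consistent boundary, widen to
    # any placement that keeps the seed run inside an arm of legal length.
    run_lo, run_hi = run[0], run[-1] + k
    s_min = max(min(left - p.vic, run_hi - p.maxlenltr), p.tsd_len)
    s_max = min(left + p.vic, run_lo + k)
    e_min = max(right - p.vic, run_hi - k)
    e_max = min(max(right + p.vic, s_min + p.maxlenltr), len(seq) - sep - p.tsd_len)
    start_opts = [
        s
        for s in range(s_min, s_max + 1)
        if seq[s : s + 2] == "TG" and seq[s + sep : s + sep + 2] == "TG"
    ]
    end_opts = [
        e
        for e in range(e_min, e_max + 1)
        if seq[e - 2 : e] == "CA" and seq[e + sep - 2 : e + sep] == "CA"
    ]
    best: LTRCandidate | None = None
    for s in start_opts:
        for e in end_opts:
            length = e - s
            if not (p.minlenltr <= length <= p.maxlenltr):
                continue
            tsd5 = seq[s - p.tsd_len : s]
            tsd3 = seq[e + sep : e + sep + p.tsd_len]
            if p.motifmis == 0 and tsd5 != tsd3:
                continue
            arm1 = garr[s:e]
            arm2 = garr[s + sep : e + sep]
            similarity = 100.0 * float((arm1 == arm2).mean())
            if similarity < p.similar:
                continue
            cand = LTRCandidate(
                contig=contig,
                ltr5=(s, e),
                ltr3=(s + sep, e + sep),
                distance=sep,
                similarity=similarity,
                tsd=(tsd5, tsd3),
                motif_ok=True,
            )
            if best is None or cand.similarity > best.similarity or (
                cand.similarity == best.similarity
                and (cand.ltr5[1] - cand.ltr5[0]) > (best.ltr5[1] - best.ltr5[0])
            ):
                best = cand
    return best


def _resolve_overlaps(candidates: list[LTRCandidate]) -> list[LTRCandidate]:
    """Keep the higher-similarity candidate wherever spans overlap."""
    kept: list[LTRCandidate] = []
    for cand in sorted(candidates, key=lambda c: (-c.similarity, c.span)):
        s, e = cand.span
        if all(min(e, k.span[1]) - max(s, k.span[0]) <= 0 for k in kept):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# output writers


def write_gff3(calls: list[ElementCall], path) -> None:
    """Element calls as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("# coordinates are 1-based inclusive (converted from internal 0-based half-open)\n")
        for i, c in enumerate(calls, 1):
            attrs = (
                f"ID=te{i:04d};class={c.clazz};subfamily={c.subfamily};"
                f"fraction_of_canonical={c.fraction_of_canonical:.3f};nested={str(c.nested_flag).lower()}"
            )
            fh.write(
                f"{c.contig}\tretrotrace\tmobile_genetic_element\t{c.start + 1}\t{c.end}\t.\t{c.strand}\t.\t{attrs}\n"
            )


def write_bed(calls: list[ElementCall], path) -> None:
    """Element calls as BED6+2 (0-based half-open; class, subfamily extra cols)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\t{c.subfamily}\t0\t{c.strand}\t{c.clazz}\t{c.subfamily}\n"
            )


def summarize_calls(calls: list[ElementCall]):
    """Per contig x subfamily counts of FLE / truncated / solo LTR."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append({"contig": c.contig, "subfamily": c.subfamily, "class": c.clazz})
    if not rows:
        return pd.DataFrame(columns=["contig", "subfamily", FLE, TRUNCATED, SOLO_LTR])
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["contig", "subfamily", "class"]).size().unstack(fill_value=0).reset_index()
    )
    for col in (FLE, TRUNCATED, SOLO_LTR):
        if col not in table:
            table[col] = 0
    return table[["contig", "subfamily", FLE, TRUNCATED, SOLO_LTR]]
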