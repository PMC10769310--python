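"""Genome assembly, short-read, and read-alignment emission for simulations.

``emit_genomes`` plants the simulated TE copies into random background
sequence with 5-bp target-site duplications (TSDs) flanking every
insertion, mirroring the footprint left by Ty integration.  ``simulate_reads``
draws uniform single-end reads with per-base substitution errors.
``emit_alignments`` converts reads into sorted, indexed BAM alignments
against the LTR/internal TE queries using the reads' recorded provenance:
it is an idealized mapper with perfect sensitivity for reads overlapping a
planted element, standing upstream of the copy-number profiler.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .models import BASES, TEModel, random_dna, revcomp
from .simulate import SimElement, TruthSet

TSD_LENGTH = 5  # matches the structural detector's fixed 5-bp TSD bounds
DEFAULT_MIN_OVERLAP = 20
UNIQUE_MAPQ = 60


class PlacementError(ValueError):
    """The background sequence is too short to host all elements."""


@dataclass
class Placement:
    """A planted element's location in a strain genome (final coordinates)."""

    element: SimElement
    start: int  # element interval, TSDs excluded
    end: int
    strand: str  # '+' or '-'
    tsd: str

    def part_layout(self) -> list[tuple[int, int, object]]:
        """Genome-forward intervals of each part: (gstart, gend, part)."""
        out = []
        if self.strand == "+":
            off = self.start
            for p in self.element.parts:
                out.append((off, off + len(p), p))
                off += len(p)
        else:
            off = self.end
            for p in self.element.parts:
                out.append((off - len(p), off, p))
                off -= len(p)
        return sorted(out)


@dataclass
class StrainGenome:
    strain: str
    sequence: str
    placements: list[Placement]

    @property
    def length(self) -> int:
        return len(self.sequence)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.strain}\n")
            for i in range(0, len(self.sequence), 80):
                fh.write(self.sequence[i : i + 80] + "\n")

    def write_bed(self, path) -> None:
        """Truth BED6+2 (0-based half-open): class and subfamily in extra cols."""
        with open(path, "w") as fh:
            for pl in self.placements:
                e = pl.element
                fh.write(
                    f"{self.strain}\t{pl.start}\t{pl.end}\t{e.eid}\t0\t{pl.strand}"
                    f"\t{e.clazz}\t{e.subfamily}\n"
                )


@dataclass
class GenomeSet:
    strains: dict[str, StrainGenome]

    def __getitem__(self, strain: str) -> StrainGenome:
        return self.strains[strain]

    def write(self, outdir) -> dict[str, dict[str, Path]]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for strain, g in self.strains.items():
            fa = outdir / f"{strain}.fasta"
            bed = outdir / f"{strain}.truth.bed"
            g.write_fasta(fa)
            g.write_bed(bed)
            paths[strain] = {"fasta": fa, "bed": bed}
        return paths


def emit_genomes(
    truth: TruthSet,
    bg_length: int,
    seed: int,
    min_spacing: int = 1000,
    margin: int = 500,
) -> GenomeSet:
    """Plant every strain's elements into fresh random background sequence.

    Insertion sites are drawn uniformly with at least ``min_spacing`` bp
    between sites (so separate elements are never chained by annotation) and
    ``margin`` bp clear of the contig ends.  Each insertion duplicates the
    5 bp at its target site, flanking the element with identical 5-mers.
    Element orientation is random.
    """
    # spawn-keyed stream: immune to collisions with any other integer-seeded
    # generator used elsewhere in a scenario
    rng = np.random.default_rng([202, seed])
    strains = {}
    for strain in truth.strains:
        strains[strain] = build_strain_genome(
            strain, truth.elements[strain], bg_length, rng, min_spacing=min_spacing, margin=margin
        )
    return GenomeSet(strains=strains)


def build_strain_genome(
    strain: str,
    elements: list[SimElement],
    bg_length: int,
    rng: np.random.Generator,
    min_spacing: int = 1000,
    margin: int = 500,
) -> StrainGenome:
    """Plant a list of elements into one fresh random background contig."""
    m = len(elements)
    slack = (bg_length - 2 * margin) - (m - 1) * min_spacing if m else bg_length
    if m and slack <= 0:
        raise PlacementError(
            f"bg_length={bg_length} too short for {m} elements at spacing {min_spacing}"
        )
    background = random_dna(bg_length, rng)
    if m:
        offsets = np.sort(rng.uniform(0.0, slack, size=m))
        sites = (margin + offsets + np.arange(m) * min_spacing).astype(int)
    else:
        sites = np.array([], dtype=int)
    pieces = []
    placements = []
    prev = 0
    out_len = 0
    for site, e in zip(sites, elements):
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        tsd = background[site : site + TSD_LENGTH]
        seq = e.sequence if strand == "+" else revcomp(e.sequence)
        pieces.append(background[prev:site])
        out_len += site - prev
        pieces.append(tsd)
        out_len += TSD_LENGTH
        start = out_len
        pieces.append(seq)
        out_len += len(seq)
        placements.append(Placement(element=e, start=start, end=out_len, strand=strand, tsd=tsd))
        prev = site  # suffix starts with the duplicated 5-mer
    pieces.append(background[prev:])
    return StrainGenome(strain=strain, sequence="".join(pieces), placements=placements)


# ---------------------------------------------------------------------------
# reads


def _quality_char(error_rate: float) -> str:
    if error_rate <= 0:
        q = 40
    else:
        q = min(40, int(round(-10.0 * math.log10(error_rate))))
    return chr(33 + q)


def simulate_reads(
    genome: StrainGenome | tuple[str, str],
    coverage: float,
    read_length: int,
    error_rate: float,
    seed: int,
    out_path,
) -> tuple[Path, int]:
    """Simulate uniform single-end WGS reads to FASTQ.

    The read count is Poisson with mean coverage * genome_length /
    read_length; start positions are uniform and both strands are sampled
    equally.  Per-base substitution errors occur at ``error_rate`` and the
    quality string encodes that error rate as a constant Phred score.  Read
    names record provenance as ``strain|index|start|strand`` for the
    idealized aligner.  Byte-identical output for identical seeds.
    """
    if isinstance(genome, tuple):
        strain, seq = genome
    else:
        strain, seq = genome.strain, genome.sequence
    if read_length > len(seq):
        raise ValueError("read_length exceeds genome length")
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng([303, seed])
    n = int(rng.poisson(coverage * len(seq) / read_length))
    starts = rng.integers(0, len(seq) - read_length + 1, size=n)
    strands = rng.integers(0, 2, size=n)  # 0: '+', 1: '-'
    n_errors = rng.binomial(read_length, error_rate, size=n) if error_rate > 0 else np.zeros(n, int)
    qual = _quality_char(error_rate) * read_length
    alt = {b: [c for c in BASES if c != b] for b in BASES}
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for i in range(n):
            p = int(starts[i])
            rs = seq[p : p + read_length]
            if strands[i]:
                rs = revcomp(rs)
            k = int(n_errors[i])
            if k:
                sites = rng.integers(0, read_length, size=k)
                picks = rng.integers(0, 3, size=k)
                chars = list(rs)
                for s, c in zip(sites, picks):
                    chars[s] = alt[chars[s]][c]
                rs = "".join(chars)
            name = f"{strain}|{i}|{p}|{'-' if strands[i] else '+'}"
            fh.write(f"@{name}\n{rs}\n+\n{qual}\n")
    return out_path, n


def read_fastq(path):
    """Yield (name, seq, qual) records from an uncompressed FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            yield header[1:].strip(), seq, qual


# ---------------------------------------------------------------------------
# idealized alignment emission


def te_query_header(te_models: dict[str, TEModel]) -> pysam.AlignmentHeader:
    refs = []
    for name in sorted(te_models):
        te = te_models[name]
        refs.append({"SN": te.ltr_query, "LN": te.ltr_length})
        refs.append({"SN": te.internal_query, "LN": te.internal_length})
    return pysam.AlignmentHeader.from_dict({"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": refs})


def emit_alignments(
    fastq_path,
    genome: StrainGenome,
    te_models: dict[str, TEModel],
    out_path,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> Path:
    """Emit provenance-based alignments of reads to the TE queries (BAM).

    Every read whose source interval overlaps a planted element by at least
    ``min_overlap`` bp is aligned (MAPQ 60) to the query regions its bases
    derive from, one record per overlapped element part, with the
    non-element remainder soft-clipped.  Reads overlapping an element by
    fewer bases (TSD/junction stragglers) are emitted at MAPQ 0; reads fully
    inside background are not emitted.  Output is coordinate-sorted and
    indexed.
    """
    header = te_query_header(te_models)
    out_path = Path(out_path)
    tmp = out_path.with_suffix(".unsorted.bam")
    placements = sorted(genome.placements, key=lambda p: p.start)
    p_starts = [p.start for p in placements]
    import bisect

    with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
        for name, rs, qual in read_fastq(fastq_path):
            try:
                strain, _, start, rstrand = name.rsplit("|", 3)
            except ValueError as exc:
                raise ValueError(f"read {name!r} lacks provenance fields") from exc
            rp = int(start)
            rl = len(rs)
            r_end = rp + rl
            gf = rs if rstrand == "+" else revcomp(rs)  # genome-forward read
            lo = bisect.bisect_right(p_starts, r_end) - 1
            for pl in placements[max(lo - 1, 0) : lo + 1]:
                ov = min(r_end, pl.end) - max(rp, pl.start)
                if ov <= 0:
                    continue
                mapq = UNIQUE_MAPQ if ov >= min_overlap else 0
                for gstart, gend, part in pl.part_layout():
                    os_, oe = max(rp, gstart), min(r_end, gend)
                    if oe <= os_:
                        continue
                    if pl.strand == "+":
                        qs = part.qstart + (os_ - gstart)
                        stored = gf
                        left = os_ - rp
                    else:
                        qs = part.qstart + (gend - oe)
                        stored = revcomp(gf)
                        left = r_end - oe
                    mlen = oe - os_
                    right = rl - left - mlen
                    a = pysam.AlignedSegment(header=header)
                    a.query_name = name
                    a.reference_name = (
                        te_models[part.source].ltr_query
                        if part.region == "LTR"
                        else te_models[part.source].internal_query
                    )
                    a.reference_start = qs
                    a.mapping_quality = mapq
                    a.flag = 16 if pl.strand != rstrand else 0
                    cigar = []
                    if left:
                        cigar.append((4, left))
                    cigar.append((0, mlen))
                    if right:
                        cigar.append((4, right))
                    a.cigartuples = cigar
                    a.query_sequence = stored
                    a.query_qualities = pysam.qualitystring_to_array(qual)
                    bam.write(a)
    pysam.sort("-o", str(out_path), str(tmp))
    os.remove(tmp)
    pysam.index(str(out_path))
    return out_path
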