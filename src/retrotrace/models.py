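"""Core domain types shared across the pipeline.

The central object is :class:`TEModel`, which captures the canonical
architecture of a Ty1/Copia-superfamily LTR retrotransposon: a long terminal
repeat (LTR) repeated at both ends of an internal region that carries the
*gag* and *pol* coding sequences.  Copy-number profiling, annotation, and
consensus calling all treat the LTR and the internal region as separate
queries, because LTR-LTR recombination within a full-length element (FLE)
excises the internal sequence and leaves a solo LTR behind.  Internal-region
presence is therefore evidence of recent activity, while LTR-only presence
records past activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: element classes used throughout annotation and simulation
FLE = "FLE"
TRUNCATED = "truncated"
SOLO_LTR = "soloLTR"

#: query regions
LTR = "LTR"
INTERNAL = "internal"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of ``length`` bases."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


@dataclass(frozen=True)
class TEModel:
    """A subfamily's LTR and internal consensus with canonical architecture.

    Parameters
    ----------
    name
        Subfamily identifier (e.g. ``"Ty4"`` or ``"Tsu4"``), unique within a
        library.
    ltr_seq
        LTR consensus sequence (uppercase A/C/G/T).
    internal_seq
        Internal-region consensus sequence (uppercase A/C/G/T).
    """

    name: str
    ltr_seq: str
    internal_seq: str

    def __post_init__(self) -> None:
        for label, seq in (("ltr_seq", self.ltr_seq), ("internal_seq", self.internal_seq)):
            if not seq:
                raise ValueError(f"{label} must be nonempty")
            if set(seq) - set(BASES):
                raise ValueError(f"{label} contains characters outside {{A,C,G,T}}")
        if not self.name:
            raise ValueError("name must be nonempty")

    @property
    def ltr_length(self) -> int:
        return len(self.ltr_seq)

    @property
    def internal_length(self) -> int:
        return len(self.internal_seq)

    @property
    def canonical_length(self) -> int:
        """Length of a canonical full-length element: LTR + internal + LTR."""
        return 2 * len(self.ltr_seq) + len(self.internal_seq)

    @property
    def ltr_query(self) -> str:
        """Reference name used for the LTR query in alignment files."""
        return f"{self.name}_LTR"

    @property
    def internal_query(self) -> str:
        """Reference name used for the internal-region query."""
        return f"{self.name}_I"

    @property
    def full_sequence(self) -> str:
        """Canonical FLE sequence (5' LTR + internal + 3' LTR)."""
        return self.ltr_seq + self.internal_seq + self.ltr_seq

    def query_length(self, region: str) -> int:
        if region == LTR:
            return self.ltr_length
        if region == INTERNAL:
            return self.internal_length
        raise ValueError(f"unknown region {region!r}")

    def query_name(self, region: str) -> str:
        return self.ltr_query if region == LTR else self.internal_query


def validate_library(library: list[TEModel]) -> None:
    """Check that subfamily names are unique within a query library."""
    names = [te.name for te in library]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate subfamily names in library: {names}")


def mutate_sequence(
    seq: str,
    distance: float,
    rng: np.random.Generator,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Evolve ``seq`` by ``distance`` expected substitutions per site.

    Substitutions follow the Jukes-Cantor model: the number of substitution
    events is Poisson with mean ``distance * len(seq)``; each event picks a
    uniform site and replaces its base with one of the three alternatives
    uniformly.  Multiple hits at one site are allowed (so observed divergence
    saturates naturally).  Indels are never introduced, which keeps homologous
    copies pre-aligned.  Sites listed in ``protected`` (e.g. the functionally
    constrained TG/CA termini of an LTR) are never touched.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if distance == 0:
        return seq
    n_events = rng.poisson(distance * len(seq))
    if n_events == 0:
        return seq
    out = list(seq)
    sites = rng.integers(0, len(seq), size=n_events)
    choices = rng.integers(0, 3, size=n_events)
    for site, choice in zip(sites, choices):
        if site in protected:
            continue
        alternatives = [b for b in BASES if b != out[site]]
        out[site] = alternatives[choice]
    return "".join(out)


def ltr_protected_sites(ltr_length: int) -> frozenset[int]:
    """Sites of an LTR held invariant under mutation.

    LTR retrotransposon integration requires the terminal TG...CA
    dinucleotides of each LTR, so these four bases are treated as under
    absolute functional constraint when simulating sequence evolution.
    """
    return frozenset({0, 1, ltr_length - 2, ltr_length - 1})


def random_te_model(
    name: str,
    rng: np.random.Generator,
    ltr_length: int = 370,
    internal_length: int = 5160,
) -> TEModel:
    """Draw a random TE consensus with canonical LTR termini.

    Defaults give a 5,900-bp canonical element, matching the size class of
    the yeast Ty4 family (~370-bp LTRs flanking a ~5.2-kb internal region).
    The LTR starts with TG and ends with CA, the conserved termini required
    for integration and checked by structural LTR detection.
    """
    if ltr_length < 10 or internal_length < 10:
        raise ValueError("ltr_length and internal_length must be >= 10")
    ltr = "TG" + random_dna(ltr_length - 4, rng) + "CA"
    internal = random_dna(internal_length, rng)
    return TEModel(name=name, ltr_seq=ltr, internal_seq=internal)


def diverged_te_model(
    base: TEModel,
    name: str,
    distance: float,
    rng: np.random.Generator,
) -> TEModel:
    """Derive a sister subfamily by evolving ``base`` by ``distance`` subs/site.

    Used to plant a pair of related subfamilies (e.g. a Ty4-like and a
    Tsu4-like lineage) whose homologous regions stay colinear, so that
    inter-subfamily recombinants remain well-defined splices.
    """
    protected = ltr_protected_sites(base.ltr_length)
    return TEModel(
        name=name,
        ltr_seq=mutate_sequence(base.ltr_seq, distance, rng, protected),
        internal_seq=mutate_sequence(base.internal_seq, distance, rng),
    )


@dataclass
class CopyNumberEstimate:
    """Normalized copy number and breadth for one TE query in one strain.

    ``cn`` is mean per-base depth over the query divided by the single-copy
    genome depth; ``breadth`` is the fraction of query positions covered by at
    least one read.
    """

    cn: float
    breadth: float
    genome_depth: float

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError("cn must be >= 0")
        if not (0.0 <= self.breadth <= 1.0):
            raise ValueError("breadth must be in [0, 1]")
        if self.cn == 0 and self.breadth != 0:
            raise ValueError("cn == 0 implies breadth == 0")


@dataclass
class PresenceCall:
    """Subfamily presence/absence call for one strain.

    ``internal_present`` is read as evidence of recent transpositional
    activity; an LTR-only signal records past activity.
    """

    ltr_present: bool
    internal_present: bool
    tau_ltr: float
    tau_int: float

    @property
    def interpretation(self) -> str:
        if self.internal_present:
            return "recent activity"
        if self.ltr_present:
            return "past activity"
        return "absent"
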