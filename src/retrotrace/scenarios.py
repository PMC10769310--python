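"""Canonical simulation scenarios used across analyses and tests.

Each builder fixes the study conditions for one question — copy-number
recovery, annotation accuracy, consensus fidelity, breakpoint mapping, and
end-to-end HTT inference — so that every driver (analysis scripts, the
test suite, the acceptance script) exercises the same ground-truth worlds.

Default conditions: short-read WGS at 50x (30x for consensus work) with
100-bp reads and 1% base-call error; within-species host trees of height
0.05 substitutions/site; a Ty4-sized TE model (370-bp LTRs, 5.16-kb
internal region); sister subfamilies diverged by ~12%; two-species host
divergence 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .divergence import SeqAlignment
from .models import TEModel, diverged_te_model, mutate_sequence, random_dna, random_te_model
from .models import FLE
from .simulate import (
    ConfigError,
    ExtinctionEvent,
    HTTEvent,
    RecombEvent,
    SimConfig,
    TruthSet,
    branch_nodes,
    evolve_te_repertoire,
    join_species_trees,
    simulate_host_tree,
)

#: study-condition defaults
COVERAGE = 50.0
CONSENSUS_COVERAGE = 30.0
READ_LENGTH = 100
ERROR_RATE = 0.01
TREE_HEIGHT = 0.05
SUBFAMILY_DIVERGENCE = 0.12
SPECIES_DIVERGENCE = 0.25
BG_LENGTH = 40_000


def copy_number_truth(n_strains: int = 20, seed: int = 0) -> TruthSet:
    """Single-species world for copy-number recovery.

    Two ancestral FLEs seed the root; transposition and solo-LTR formation
    proliferate and erode copies along the tree, so strains end with varied
    planted (N_FLE, N_solo).  No loss or truncation: every strain keeps at
    least two LTR units, which keeps expected copy numbers clear of the
    presence thresholds.
    """
    tree = simulate_host_tree(n_strains, seed=seed, height=TREE_HEIGHT)
    te = random_te_model("Ty4", np.random.default_rng([101, seed]))
    cfg = SimConfig(
        rate_transposition=30.0,
        rate_solo=15.0,
        coverage=COVERAGE,
        read_length=READ_LENGTH,
        error_rate=ERROR_RATE,
        seed=seed + 2,
        ancestral_copies={"Ty4": 2},
    )
    return evolve_te_repertoire(tree, te, cfg)


def annotation_truth(n_strains: int = 8, seed: int = 0) -> TruthSet:
    """World with all element classes for annotation accuracy checks.

    Transposition, solo formation, truncation, and loss all act, producing
    FLEs, internal-region fragments, and solo LTRs in the same genomes.
    """
    tree = simulate_host_tree(n_strains, seed=seed, height=TREE_HEIGHT)
    te = random_te_model("Ty4", np.random.default_rng([101, seed]))
    cfg = SimConfig(
        rate_transposition=40.0,
        rate_solo=15.0,
        rate_truncation=10.0,
        rate_loss=5.0,
        coverage=COVERAGE,
        read_length=READ_LENGTH,
        error_rate=ERROR_RATE,
        seed=seed + 2,
        ancestral_copies={"Ty4": 2},
    )
    return evolve_te_repertoire(tree, te, cfg)


@dataclass
class HTTScenario:
    """A two-species world with one planted HTT and one recombinant clade."""

    truth: TruthSet
    te_models: dict[str, TEModel]
    host_tree: dendropy.Tree
    species_of: dict[str, str]  # strain -> species label
    donor_species: str
    recipient_species: str
    recipient_clade: frozenset[str]  # strains that received the transfer
    recomb_strains: frozenset[str]  # strains carrying the recombinant
    breakpoints: list[int]
    species_divergence: float


def _clade_of_size(tree: dendropy.Tree, leaves_wanted: set[str], target: int) -> tuple[str, frozenset[str]]:
    """Pick the internal branch whose clade (within ``leaves_wanted``) is
    closest to ``target`` leaves; returns (branch label, clade leaf set)."""
    best = None
    for label, node in branch_nodes(tree).items():
        if node.is_leaf():
            continue
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        if not clade <= leaves_wanted:
            continue
        score = (abs(len(clade) - target), label)
        if best is None or score < best[0]:
            best = (score, label, clade)
    if best is None:
        raise ValueError("no suitable subclade found")
    return best[1], best[2]


def _htt_world_valid(
    truth: TruthSet,
    leaves_a: set[str],
    leaves_b: set[str],
    recomb_strains: frozenset[str],
) -> bool:
    """A realized HTT world must keep its diagnostic lineages alive.

    Stochastic decay can occasionally sterilize a planted history (e.g. the
    donor species' last FLE turning solo before any transposition); such
    degenerate draws are rejected and the repertoire is re-simulated.
    """
    def has_fle(strain: str, subfamily: str) -> bool:
        return any(
            e.clazz == FLE and e.subfamily == subfamily for e in truth.elements[strain]
        )

    if not any(has_fle(s, "Tsu4") for s in leaves_a):
        return False
    if not any(has_fle(s, "Ty4") for s in leaves_b):
        return False
    if not all(has_fle(s, "Ty4xTsu4") for s in recomb_strains):
        return False
    return True


def htt_recombination_truth(
    n_per_species: int = 12,
    seed: int = 0,
    breakpoints: tuple[int, int] = (1700, 3700),
) -> HTTScenario:
    """Two species, one HTT into a recipient subclade, one recombinant clade.

    Species A carries the Tsu4-like subfamily ancestrally; species B carries
    the Ty4-like subfamily.  One horizontal transfer moves a Tsu4 FLE from a
    basal species-A branch onto the stem of a subclade of species B; inside
    that subclade, recombination between the co-resident subfamilies then
    creates a Ty4(5')-Tsu4(middle)-Ty4(3') mosaic whose internal region
    switches parents at the planted breakpoints.
    """
    rng = np.random.default_rng([102, seed])
    tree_a = simulate_host_tree(n_per_species, seed=seed + 10, height=0.02, label_prefix="A")
    tree_b = simulate_host_tree(n_per_species, seed=seed + 11, height=0.02, label_prefix="B")
    tree = join_species_trees({"A": tree_a, "B": tree_b}, species_divergence=SPECIES_DIVERGENCE)

    base = random_te_model("Ty4", rng)
    tsu = diverged_te_model(base, "Tsu4", SUBFAMILY_DIVERGENCE, rng)
    te_models = {"Ty4": base, "Tsu4": tsu}

    nodes = branch_nodes(tree)
    leaves_a = {l.taxon.label for l in tree.leaf_node_iter() if l.taxon.label.startswith("A")}
    leaves_b = {l.taxon.label for l in tree.leaf_node_iter() if l.taxon.label.startswith("B")}
    stem_a = next(lb for lb, nd in nodes.items() if not nd.is_leaf()
                  and {l.taxon.label for l in nd.leaf_iter()} == leaves_a)
    stem_b = next(lb for lb, nd in nodes.items() if not nd.is_leaf()
                  and {l.taxon.label for l in nd.leaf_iter()} == leaves_b)
    recipient_branch, recipient_clade = _clade_of_size(tree, leaves_b, max(3, n_per_species // 3))
    # recombination happens one step inside the recipient clade
    recomb_branch, recomb_strains = recipient_branch, recipient_clade
    rec_node = nodes[recipient_branch]
    kids = [k for k in rec_node.child_nodes() if not k.is_leaf()]
    if kids:
        recomb_branch = kids[0].label
        recomb_strains = frozenset(l.taxon.label for l in kids[0].leaf_iter())

    truth = None
    for attempt in range(20):
        cfg = SimConfig(
            rate_transposition=20.0,
            rate_solo=3.0,
            # extant TE copies descend from recent transposition bursts, so
            # TE sequence divergence trails host divergence
            te_substitution_scale=0.3,
            coverage=COVERAGE,
            read_length=READ_LENGTH,
            error_rate=ERROR_RATE,
            seed=seed + 2 + 1000 * attempt,
            ancestral_copies={"Ty4": 2, "Tsu4": 2},
            extinction_events=[
                ExtinctionEvent(branch=stem_a, subfamily="Ty4", time=0.0),
                ExtinctionEvent(branch=stem_b, subfamily="Tsu4", time=0.0),
            ],
            htt_events=[HTTEvent(donor_branch=stem_a, recipient_branch=recipient_branch, time=0.4)],
            recomb_events=[
                RecombEvent(
                    subfamily_a="Ty4",
                    subfamily_b="Tsu4",
                    breakpoints=list(breakpoints),
                    branch=recomb_branch,
                    time=0.6,
                )
            ],
        )
        try:
            candidate = evolve_te_repertoire(tree, te_models, cfg)
        except ConfigError:
            continue
        if _htt_world_valid(candidate, leaves_a, leaves_b, recomb_strains):
            truth = candidate
            break
    if truth is None:
        raise RuntimeError("could not realize a valid HTT world in 20 attempts")
    species_of = {l: ("A" if l.startswith("A") else "B") for l in truth.strains}
    return HTTScenario(
        truth=truth,
        te_models=te_models,
        host_tree=tree,
        species_of=species_of,
        donor_species="A",
        recipient_species="B",
        recipient_clade=recipient_clade,
        recomb_strains=recomb_strains,
        breakpoints=list(breakpoints),
        species_divergence=SPECIES_DIVERGENCE,
    )


# ---------------------------------------------------------------------------
# sequence-level generators (no read simulation involved)


def evolve_alignment(
    tree: dendropy.Tree,
    length: int,
    seed: int,
    scale: float = 1.0,
) -> SeqAlignment:
    """Evolve a random root sequence down a tree (Jukes-Cantor, no indels)."""
    rng = np.random.default_rng(seed)
    root_seq = random_dna(length, rng)
    seqs: dict = {}
    state = {tree.seed_node: root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = state[node.parent_node]
        d = (node.edge.length or 0.0) * scale
        seq = mutate_sequence(parent_seq, d, rng)
        state[node] = seq
        if node.is_leaf():
            seqs[node.taxon.label] = seq
    return SeqAlignment(seqs)


@dataclass
class RecombinantPair:
    """A synthetic recombinant with its parents and true breakpoints."""

    alignment: SeqAlignment  # records: parentA, parentB, recombinant
    breakpoints: list[int]
    segment_parents: list[str]  # parent label per segment, alternating


def simulate_recombinant(
    length: int = 5000,
    n_breakpoints: int = 1,
    parent_divergence: float = 0.10,
    seed: int = 0,
    min_segment: int = 600,
) -> RecombinantPair:
    """Construct a mosaic sequence switching between two diverged parents.

    The parents differ by ``parent_divergence`` substitutions/site (the 5-15%
    regime where window-based assignment is informative); breakpoints are
    uniform subject to a minimum segment length so every segment carries
    signal.
    """
    rng = np.random.default_rng(seed)
    ancestor = random_dna(length, rng)
    half = parent_divergence / 2.0
    parent_a = mutate_sequence(ancestor, half, rng)
    parent_b = mutate_sequence(ancestor, half, rng)
    lo, hi = min_segment, length - min_segment
    while True:
        bps = sorted(int(b) for b in rng.integers(lo, hi, size=n_breakpoints))
        if len(set(bps)) == n_breakpoints and all(
            b2 - b1 >= min_segment for b1, b2 in zip(bps, bps[1:])
        ):
            break
    bounds = [0] + bps + [length]
    segs = []
    parents = []
    for k, (a, b) in enumerate(zip(bounds, bounds[1:])):
        src = parent_a if k % 2 == 0 else parent_b
        segs.append(src[a:b])
        parents.append("parentA" if k % 2 == 0 else "parentB")
    aln = SeqAlignment(
        {"parentA": parent_a, "parentB": parent_b, "recombinant": "".join(segs)}
    )
    return RecombinantPair(alignment=aln, breakpoints=bps, segment_parents=parents)


def random_resolvable_tree(
    n_taxa: int,
    seed: int,
    blen_range: tuple[float, float] = (0.005, 0.03),
) -> dendropy.Tree:
    """Random topology with branch lengths bounded away from zero.

    Topologies come from the Yule process; every branch length is redrawn
    uniformly from ``blen_range`` so each internal edge carries enough
    expected substitutions to be recoverable — the standard design for
    benchmarking tree estimators (an ultrametric Yule tree can contain
    arbitrarily short, statistically unresolvable internal edges, which
    would measure the tree prior rather than the estimator).
    """
    tree = simulate_host_tree(n_taxa, seed=seed)
    rng = np.random.default_rng(seed + 77_000)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(*blen_range))
    return tree


def deep_split_tree(
    clade_depth: float = 0.01,
    stem: float = 0.08,
) -> dendropy.Tree:
    """Two four-taxon clades separated by a long central branch."""
    def clade(labels):
        a, b, c, d = labels
        return (
            f"(({a}:{clade_depth},{b}:{clade_depth}):{clade_depth},"
            f"({c}:{clade_depth},{d}:{clade_depth}):{clade_depth})"
        )

    nwk = f"({clade('ABCD')}:{stem / 2},{clade('EFGH')}:{stem / 2});"
    return dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted",
                             suppress_internal_node_taxa=True)
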