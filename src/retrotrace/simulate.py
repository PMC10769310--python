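"""Forward simulation of TE repertoires along a host phylogeny.

Strains diverge along a Yule host tree; each lineage carries a repertoire of
TE copies that evolve by substitution only (Jukes-Cantor), so homologous
copies remain colinear and alignable without an external aligner.  Along
each branch, Poisson-distributed events modify the repertoire:

* transposition — a full-length element (FLE) begets a new copy;
* solo-LTR formation — intra-element LTR-LTR recombination excises the
  internal region and one LTR, leaving a solo LTR;
* truncation — a copy is clipped to a random sub-interval of its canonical
  span;
* loss — a copy is deleted outright.

Scheduled events plant known evolutionary histories: horizontal transfers
copy an FLE lineage from a donor branch into a recipient branch, and
inter-subfamily recombination splices internal-region segments between two
co-resident subfamilies at stated breakpoints.  Everything is recorded in a
:class:`TruthSet` so downstream stages can be scored against ground truth.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .models import (
    FLE,
    INTERNAL,
    LTR,
    SOLO_LTR,
    TRUNCATED,
    TEModel,
    ltr_protected_sites,
    mutate_sequence,
)


class ConfigError(ValueError):
    """An event in the configuration cannot be applied to the tree/state."""


# ---------------------------------------------------------------------------
# host trees


def simulate_host_tree(
    n_strains: int,
    seed: int,
    height: float = 0.05,
    label_prefix: str = "s",
) -> dendropy.Tree:
    """Rooted ultrametric binary tree over strains under a Yule process.

    Branch lengths are rescaled so the root-to-tip distance equals
    ``height`` substitutions/site (default 0.05, a within-species scale).
    Leaves are labeled ``s01``, ``s02``, ... left to right; internal nodes
    are labeled ``n01``, ... in preorder so branches can be addressed by
    their child node's label.
    """
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    rng = np.random.default_rng([404, seed])

    # node: [child_a, child_b, birth_depth]; leaves keep children None
    root = {"children": None, "depth": 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_strains:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(0, len(active)))
        node = active[idx]
        node["depth"] = t
        kids = [{"children": None, "depth": t}, {"children": None, "depth": t}]
        node["children"] = kids
        active[idx : idx + 1] = kids
    t += rng.exponential(1.0 / n_strains)
    for leaf in active:
        leaf["depth"] = t

    # the root node sits at the depth of the first split; rescale the
    # root-to-tip span below it to `height`
    root_depth = root["depth"]
    scale = height / (t - root_depth) if t > root_depth else 1.0

    counter = {"leaf": 0}
    width = max(2, len(str(n_strains)))

    def newick(node, parent_depth) -> str:
        blen = (node["depth"] - parent_depth) * scale
        if node["children"] is None:
            counter["leaf"] += 1
            return f"{label_prefix}{counter['leaf']:0{width}d}:{blen:.10g}"
        left = newick(node["children"][0], node["depth"])
        right = newick(node["children"][1], node["depth"])
        return f"({left},{right}):{blen:.10g}"

    if root["children"] is None:  # n_strains >= 2 guarantees a split
        raise AssertionError("unreachable")
    left = newick(root["children"][0], root["depth"])
    right = newick(root["children"][1], root["depth"])
    tree = dendropy.Tree.get(
        data=f"({left},{right});",
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    label_internal_nodes(tree)
    return tree


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "n") -> None:
    """Assign deterministic preorder labels to unlabeled internal nodes."""
    i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        i += 1
        if not node.label:
            node.label = f"{prefix}{i:02d}"


def join_species_trees(
    subtrees: dict[str, dendropy.Tree],
    species_divergence: float = 0.25,
) -> dendropy.Tree:
    """Join per-species strain trees under a common root.

    Each subtree keeps its internal structure; stems are set so that the
    leaf-to-leaf distance between any two species is ``species_divergence``
    plus the within-species depths.  Used to build two-species host trees
    for HTT scenarios.
    """
    if len(subtrees) < 2:
        raise ValueError("need >= 2 species subtrees")
    parts = []
    for name, sub in subtrees.items():
        nwk = sub.as_string(schema="newick", suppress_rooting=True).strip().rstrip(";")
        parts.append(f"{nwk}:{species_divergence / 2.0:.10g}")
    tree = dendropy.Tree.get(
        data="(" + ",".join(parts) + ");",
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    # subtree-internal labels collide across species; relabel fresh
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            node.label = None
    label_internal_nodes(tree)
    return tree


def branch_nodes(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    """Map branch ids (child node labels / leaf taxon labels) to nodes."""
    label_internal_nodes(tree)
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        label = node.taxon.label if node.is_leaf() else node.label
        out[label] = node
    return out


# ---------------------------------------------------------------------------
# elements


@dataclass
class Part:
    """A contiguous segment of a TE copy, mapped to one query region.

    ``source`` names the subfamily whose query this segment derives from
    (segments of an inter-subfamily recombinant point at different sources);
    ``qstart:qend`` is the half-open interval on that query.
    """

    region: str  # LTR or INTERNAL
    source: str
    qstart: int
    qend: int
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != self.qend - self.qstart:
            raise ValueError("part sequence length does not match query span")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SimElement:
    """One TE copy in one lineage."""

    eid: str
    subfamily: str
    clazz: str  # FLE / truncated / soloLTR
    parts: list[Part]
    founder: str  # id of the ancestral insertion this copy descends from
    origin: str  # free-text provenance (ancestral / transposition / HTT / ...)

    @property
    def sequence(self) -> str:
        return "".join(p.seq for p in self.parts)

    @property
    def length(self) -> int:
        return sum(len(p) for p in self.parts)

    def clone(self, eid: str | None = None, origin: str | None = None) -> "SimElement":
        return SimElement(
            eid=eid or self.eid,
            subfamily=self.subfamily,
            clazz=self.clazz,
            parts=[_copy.copy(p) for p in self.parts],
            founder=self.founder,
            origin=origin or self.origin,
        )

    def slice(self, start: int, end: int) -> list[Part]:
        """Clip the element to local interval [start, end) and return parts."""
        if not (0 <= start < end <= self.length):
            raise ValueError("invalid slice interval")
        out: list[Part] = []
        off = 0
        for p in self.parts:
            lo, hi = max(start, off), min(end, off + len(p))
            if lo < hi:
                out.append(
                    Part(
                        region=p.region,
                        source=p.source,
                        qstart=p.qstart + (lo - off),
                        qend=p.qstart + (hi - off),
                        seq=p.seq[lo - off : hi - off],
                    )
                )
            off += len(p)
        return out

    def sources(self) -> set[str]:
        return {p.source for p in self.parts}


def element_from_model(te: TEModel, eid: str, origin: str = "ancestral") -> SimElement:
    parts = [
        Part(LTR, te.name, 0, te.ltr_length, te.ltr_seq),
        Part(INTERNAL, te.name, 0, te.internal_length, te.internal_seq),
        Part(LTR, te.name, 0, te.ltr_length, te.ltr_seq),
    ]
    return SimElement(eid=eid, subfamily=te.name, clazz=FLE, parts=parts, founder=eid, origin=origin)


# ---------------------------------------------------------------------------
# configuration and truth


@dataclass
class HTTEvent:
    """A horizontal transfer of one FLE lineage between branches.

    ``time`` is the fraction along each branch at which the transfer is
    sampled (donor) and injected (recipient).
    """

    donor_branch: str
    recipient_branch: str
    time: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.time <= 1.0):
            raise ValueError("HTT time must be a branch fraction in [0, 1]")


@dataclass
class RecombEvent:
    """An inter-subfamily recombination splicing internal-region segments.

    Breakpoints are strictly increasing internal-region coordinates.  If
    ``branch`` is None the event fires on the first processed branch where
    FLEs of both subfamilies co-reside.
    """

    subfamily_a: str
    subfamily_b: str
    breakpoints: list[int]
    branch: str | None = None
    time: float = 0.5

    def __post_init__(self) -> None:
        if not self.breakpoints:
            raise ValueError("recombination requires >= 1 breakpoint")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if self.breakpoints[0] <= 0:
            raise ValueError("breakpoints must be positive internal coordinates")


@dataclass
class ExtinctionEvent:
    """Lineage-specific extinction: every copy of a subfamily is purged.

    Removes, at ``time`` (branch fraction) on ``branch``, all elements
    carrying any sequence from ``subfamily``.  Used to model the
    lineage-specific extinctions that leave patchy presence/absence maps.
    """

    branch: str
    subfamily: str
    time: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.time <= 1.0):
            raise ValueError("extinction time must be a branch fraction in [0, 1]")


@dataclass
class SimConfig:
    """Simulation parameters: per-branch event rates and sequencing settings.

    Rates are events per branch-length unit (substitutions/site), so a rate
    of 20 on a 0.05-long branch yields one expected event.
    """

    rate_transposition: float = 0.0
    rate_solo: float = 0.0
    rate_truncation: float = 0.0
    rate_loss: float = 0.0
    te_substitution_scale: float = 1.0
    htt_events: list[HTTEvent] = field(default_factory=list)
    recomb_events: list[RecombEvent] = field(default_factory=list)
    extinction_events: list[ExtinctionEvent] = field(default_factory=list)
    coverage: float = 50.0
    read_length: int = 100
    error_rate: float = 0.01
    seed: int = 0
    ancestral_copies: dict[str, int] | None = None  # subfamily -> copies at root

    def __post_init__(self) -> None:
        for name in ("rate_transposition", "rate_solo", "rate_truncation", "rate_loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.te_substitution_scale < 0:
            raise ValueError("te_substitution_scale must be >= 0")


@dataclass
class EventRecord:
    branch: str
    time: float  # position along the branch, in branch-length units
    kind: str
    eid: str | None
    detail: dict = field(default_factory=dict)


@dataclass
class TruthSet:
    """Ground truth of a simulated TE history.

    Holds the leaf-state repertoires, the full event log, and the generating
    configuration; downstream accuracy tests compare pipeline output against
    the accessors here.
    """

    tree: dendropy.Tree
    te_models: dict[str, TEModel]
    elements: dict[str, list[SimElement]]  # strain -> planted copies
    events: list[EventRecord]
    config: SimConfig

    @property
    def strains(self) -> list[str]:
        return list(self.elements)

    def presence(self, subfamily: str) -> dict[str, bool]:
        """True presence/absence of any sequence from ``subfamily`` per strain."""
        return {
            strain: any(subfamily in e.sources() for e in elems)
            for strain, elems in self.elements.items()
        }

    def internal_presence(self, subfamily: str) -> dict[str, bool]:
        """Presence of internal-region sequence from ``subfamily`` per strain."""
        return {
            strain: any(
                p.region == INTERNAL and p.source == subfamily
                for e in elems
                for p in e.parts
            )
            for strain, elems in self.elements.items()
        }

    def expected_cn(self, strain: str, subfamily: str, region: str) -> float:
        """Expected normalized depth over a query: planted bases / query length."""
        te = self.te_models[subfamily]
        total = sum(
            len(p)
            for e in self.elements[strain]
            for p in e.parts
            if p.region == region and p.source == subfamily
        )
        return total / te.query_length(region)

    def ltr_unit_count(self, strain: str, subfamily: str | None = None) -> int:
        """Number of LTR segments planted in a strain (2/FLE, 1/solo)."""
        return sum(
            1
            for e in self.elements[strain]
            for p in e.parts
            if p.region == LTR and (subfamily is None or p.source == subfamily)
        )

    def class_counts(self, strain: str) -> dict[str, int]:
        out = {FLE: 0, TRUNCATED: 0, SOLO_LTR: 0}
        for e in self.elements[strain]:
            out[e.clazz] += 1
        return out


# ---------------------------------------------------------------------------
# the simulation proper


def evolve_te_repertoire(
    tree: dendropy.Tree,
    te_models: TEModel | list[TEModel] | dict[str, TEModel],
    cfg: SimConfig,
) -> TruthSet:
    """Simulate element gain and decay along every branch of the host tree.

    Branches are processed parent-before-child; a branch receiving a
    horizontal transfer is additionally deferred until its donor branch has
    been processed (a circular dependency raises :class:`ConfigError`).
    Deterministic given ``cfg.seed``.
    """
    if isinstance(te_models, TEModel):
        te_models = {te_models.name: te_models}
    elif isinstance(te_models, list):
        te_models = {te.name: te for te in te_models}
    rng = np.random.default_rng([505, cfg.seed])
    nodes = branch_nodes(tree)

    for ev in cfg.htt_events:
        for b in (ev.donor_branch, ev.recipient_branch):
            if b not in nodes:
                raise ConfigError(f"HTT event references unknown branch {b!r}")
    for ev in cfg.extinction_events:
        if ev.branch not in nodes:
            raise ConfigError(f"extinction event references unknown branch {ev.branch!r}")
    for ev in cfg.recomb_events:
        if ev.branch is not None and ev.branch not in nodes:
            raise ConfigError(f"recombination event references unknown branch {ev.branch!r}")
        for sub in (ev.subfamily_a, ev.subfamily_b):
            if sub not in te_models:
                raise ConfigError(f"recombination event references unknown subfamily {sub!r}")
        internal_len = te_models[ev.subfamily_a].internal_length
        if ev.breakpoints[-1] >= internal_len:
            raise ConfigError("recombination breakpoints exceed internal-region length")

    counter = {"n": 0}

    def new_eid() -> str:
        counter["n"] += 1
        return f"e{counter['n']:04d}"

    # root repertoire
    copies = cfg.ancestral_copies or {next(iter(te_models)): 1}
    root_state: list[SimElement] = []
    for sub, k in copies.items():
        if sub not in te_models:
            raise ConfigError(f"ancestral_copies references unknown subfamily {sub!r}")
        for _ in range(k):
            root_state.append(element_from_model(te_models[sub], new_eid()))

    # branch scheduling
    preorder = [
        (node.taxon.label if node.is_leaf() else node.label)
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node
    ]
    incoming = {}
    for i, ev in enumerate(cfg.htt_events):
        incoming.setdefault(ev.recipient_branch, []).append((i, ev))
    parent_branch = {}
    for label, node in nodes.items():
        p = node.parent_node
        if p is tree.seed_node:
            parent_branch[label] = None
        else:
            parent_branch[label] = p.taxon.label if p.is_leaf() else p.label

    end_states: dict[str, list[SimElement]] = {}
    snapshots: dict[int, SimElement] = {}
    events: list[EventRecord] = []
    pending_recomb = [ev for ev in cfg.recomb_events if ev.branch is None]
    rates = (
        ("transposition", cfg.rate_transposition),
        ("solo", cfg.rate_solo),
        ("truncation", cfg.rate_truncation),
        ("loss", cfg.rate_loss),
    )

    def evolve_state(state: list[SimElement], dt: float) -> None:
        d = dt * cfg.te_substitution_scale
        if d <= 0:
            return
        for e in state:
            for p in e.parts:
                if p.region == LTR:
                    te = te_models[p.source]
                    prot = frozenset(
                        q - p.qstart
                        for q in ltr_protected_sites(te.ltr_length)
                        if p.qstart <= q < p.qend
                    )
                else:
                    prot = frozenset()
                p.seq = mutate_sequence(p.seq, d, rng, prot)

    def pick(seq: list[SimElement]) -> SimElement:
        return seq[int(rng.integers(0, len(seq)))]

    def process_branch(label: str) -> None:
        node = nodes[label]
        length = node.edge.length or 0.0
        parent = parent_branch[label]
        base = root_state if parent is None else end_states[parent]
        state = [e.clone() for e in base]

        schedule: list[tuple[float, int, str, object]] = []
        for order, (kind, rate) in enumerate(rates):
            n = rng.poisson(rate * length)
            for t in sorted(rng.uniform(0.0, length, size=n)):
                schedule.append((t, order, kind, None))
        for i, ev in enumerate(cfg.htt_events):
            if ev.donor_branch == label:
                schedule.append((ev.time * length, 4, "htt_out", i))
            if ev.recipient_branch == label:
                schedule.append((ev.time * length, 5, "htt_in", i))
        for ev in cfg.recomb_events:
            if ev.branch == label:
                schedule.append((ev.time * length, 6, "recombination", ev))
        for ev in cfg.extinction_events:
            if ev.branch == label:
                schedule.append((ev.time * length, 3, "extinction", ev))
        for ev in list(pending_recomb):
            subs = {s for e in state if e.clazz == FLE for s in (e.subfamily,)}
            if ev.subfamily_a in subs and ev.subfamily_b in subs:
                schedule.append((0.5 * length, 6, "recombination", ev))
                pending_recomb.remove(ev)
        schedule.sort(key=lambda x: (x[0], x[1]))

        t_prev = 0.0
        for t, _, kind, payload in schedule:
            evolve_state(state, t - t_prev)
            t_prev = t
            if kind == "transposition":
                fles = [e for e in state if e.clazz == FLE]
                if not fles:
                    events.append(EventRecord(label, t, "transposition_skipped", None))
                    continue
                src = pick(fles)
                new = src.clone(eid=new_eid(), origin=f"transposition of {src.eid}")
                state.append(new)
                events.append(EventRecord(label, t, "transposition", new.eid, {"source": src.eid}))
            elif kind == "solo":
                fles = [e for e in state if e.clazz == FLE]
                if not fles:
                    events.append(EventRecord(label, t, "solo_skipped", None))
                    continue
                e = pick(fles)
                e.parts = [e.parts[0]]  # the 5' LTR survives the excision
                e.clazz = SOLO_LTR
                events.append(EventRecord(label, t, "solo", e.eid))
            elif kind == "truncation":
                fles = [e for e in state if e.clazz == FLE]
                if not fles:
                    events.append(EventRecord(label, t, "truncation_skipped", None))
                    continue
                e = pick(fles)
                # clip to a sub-interval of the internal region, so truncated
                # architectures are unambiguous against solo LTRs
                ltr5_len = len(e.parts[0])
                int_len = e.length - ltr5_len - len(e.parts[-1])
                keep = max(150, int(rng.uniform(0.2, 0.9) * int_len))
                keep = min(keep, int_len)
                start = ltr5_len + int(rng.integers(0, int_len - keep + 1))
                e.parts = e.slice(start, start + keep)
                e.clazz = TRUNCATED
                events.append(
                    EventRecord(label, t, "truncation", e.eid, {"kept": [start, start + keep]})
                )
            elif kind == "loss":
                if not state:
                    events.append(EventRecord(label, t, "loss_skipped", None))
                    continue
                e = pick(state)
                state.remove(e)
                events.append(EventRecord(label, t, "loss", e.eid))
            elif kind == "htt_out":
                fles = [e for e in state if e.clazz == FLE]
                if not fles:
                    raise ConfigError(f"HTT donor branch {label!r} carries no FLE")
                snapshots[payload] = pick(fles).clone()
                events.append(EventRecord(label, t, "htt_out", snapshots[payload].eid))
            elif kind == "htt_in":
                donor = snapshots[payload]
                ev = cfg.htt_events[payload]
                new = donor.clone(eid=new_eid(), origin=f"HTT from {ev.donor_branch}")
                state.append(new)
                events.append(
                    EventRecord(label, t, "htt_in", new.eid, {"donor_branch": ev.donor_branch})
                )
            elif kind == "extinction":
                ev = payload
                victims = [e for e in state if ev.subfamily in e.sources()]
                for e in victims:
                    state.remove(e)
                events.append(
                    EventRecord(
                        label, t, "extinction", None,
                        {"subfamily": ev.subfamily, "removed": [e.eid for e in victims]},
                    )
                )
            elif kind == "recombination":
                ev = payload
                fles_a = [e for e in state if e.clazz == FLE and e.subfamily == ev.subfamily_a]
                fles_b = [e for e in state if e.clazz == FLE and e.subfamily == ev.subfamily_b]
                if not fles_a or not fles_b:
                    raise ConfigError(
                        f"recombination on branch {label!r}: subfamily "
                        f"{ev.subfamily_a if not fles_a else ev.subfamily_b!r} absent"
                    )
                ea, eb = pick(fles_a), pick(fles_b)
                state.append(_recombine(ea, eb, ev, new_eid()))
                events.append(
                    EventRecord(
                        label,
                        t,
                        "recombination",
                        state[-1].eid,
                        {"parents": [ea.eid, eb.eid], "breakpoints": list(ev.breakpoints)},
                    )
                )
        evolve_state(state, length - t_prev)
        end_states[label] = state

    done: set[str] = set()
    remaining = list(preorder)
    while remaining:
        progressed = False
        for label in list(remaining):
            parent = parent_branch[label]
            if parent is not None and parent not in done:
                continue
            donors = [ev.donor_branch for _, ev in incoming.get(label, [])]
            if any(d not in done and d != label for d in donors):
                continue
            process_branch(label)
            done.add(label)
            remaining.remove(label)
            progressed = True
        if not progressed:
            raise ConfigError("circular HTT dependencies between branches")

    if pending_recomb:
        raise ConfigError(
            "recombination event never applicable: subfamilies "
            f"{[(e.subfamily_a, e.subfamily_b) for e in pending_recomb]} never co-resident"
        )

    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    elements = {label: end_states[label] for label in sorted(leaves)}
    return TruthSet(tree=tree, te_models=dict(te_models), elements=elements, events=events, config=cfg)


def _recombine(ea: SimElement, eb: SimElement, ev: RecombEvent, eid: str) -> SimElement:
    """Splice internal segments of ``eb`` into ``ea`` at the event breakpoints."""
    int_a = next(p for p in ea.parts if p.region == INTERNAL)
    int_b = next(p for p in eb.parts if p.region == INTERNAL)
    bounds = [0] + list(ev.breakpoints) + [len(int_a.seq)]
    segs: list[Part] = []
    for k, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        donor = int_a if k % 2 == 0 else int_b
        segs.append(
            Part(INTERNAL, donor.source, donor.qstart + lo, donor.qstart + hi, donor.seq[lo:hi])
        )
    ltr5 = _copy.copy(ea.parts[0])
    ltr3 = _copy.copy(ea.parts[-1])
    return SimElement(
        eid=eid,
        subfamily=f"{ev.subfamily_a}x{ev.subfamily_b}",
        clazz=FLE,
        parts=[ltr5, *segs, ltr3],
        founder=eid,
        origin=f"recombination({ea.eid},{eb.eid})",
    )
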