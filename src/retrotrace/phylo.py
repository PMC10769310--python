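"""Distance trees, bootstrap, tree comparison, and presence/absence parsimony.

This is the machinery that turns element alignments and presence maps into
horizontal-transfer (HTT) inferences:

* neighbor-joining trees from K2P distance matrices, with nonparametric
  bootstrap over alignment columns and midpoint rooting;
* Robinson-Foulds distances and monophyly tests, used to quantify
  incongruence between TE trees (or between per-segment trees of a
  recombinant alignment) and the host phylogeny;
* Dollo (single gain, arbitrary losses) and Fitch (unrestricted) parsimony
  over subfamily presence/absence on the host tree;
* an HTT ratio test: a species pair whose minimum inter-species TE distance
  is far smaller than the host divergence is inconsistent with purely
  vertical transmission.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .divergence import OK, SaturationError, SeqAlignment, _encode, _k2p_encoded

#: distance assigned to saturated pairs when saturation handling is "cap"
SATURATION_CAP = 5.0


@dataclass
class DistanceMatrix:
    """Symmetric matrix of substitutions/site with row labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix entries must be finite")
        if np.any(m < 0):
            raise ValueError("distance matrix entries must be >= 0")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(path, sep="\t")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.matrix):
                fh.write(label + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")


def distance_matrix(
    aln: SeqAlignment,
    model: str = "k2p",
    saturation: str = "error",
) -> DistanceMatrix:
    """All-pairs K2P distance matrix for an alignment.

    ``saturation`` controls what happens when a pair is saturated or has too
    few comparable sites: ``"error"`` raises :class:`SaturationError` naming
    the pair (the default, appropriate for point estimates), while ``"cap"``
    substitutes a large fixed distance (used inside bootstrap resampling,
    where an occasional resampled pair can saturate by chance).
    """
    if model != "k2p":
        raise ValueError(f"unsupported model {model!r}")
    if len(aln) < 3:
        raise ValueError("distance matrix requires >= 3 sequences")
    labels = aln.ids
    enc = {i: _encode(aln.records[i]) for i in labels}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = _k2p_encoded(enc[labels[i]], enc[labels[j]])
            if res.status != OK:
                if saturation == "cap":
                    d = SATURATION_CAP
                else:
                    raise SaturationError(
                        f"pair ({labels[i]}, {labels[j]}) is {res.status}"
                    )
            else:
                d = res.d
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, matrix=m)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted) from a distance matrix.

    Ties in the Q criterion are broken toward the lexicographically smallest
    pair of cluster representative labels (the representative of a cluster is
    its smallest leaf label), making the agglomeration order deterministic.
    Negative branch lengths arising from the NJ formulas are clamped to zero
    with the deficit moved onto the sister branch, preserving the joined pair
    distance.  On an exactly additive matrix the generating tree and its
    branch lengths are recovered exactly.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    d = dm.matrix.astype(float).copy()
    if n == 2:
        half = d[0, 1] / 2.0
        newick = f"({_quote(labels[0])}:{half:.10g},{_quote(labels[1])}:{half:.10g});"
        return _parse_tree(newick, rooted=False)

    newicks = [_quote(l) for l in labels]
    reps = list(labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        tie_ij = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((ai, aj) for ai, aj in tie_ij if ai < aj),
            key=lambda p: tuple(sorted((reps[active[p[0]]], reps[active[p[1]]]))),
        )
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        # distances from the new node u to every other active cluster
        new_row = {}
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        u = len(newicks)
        newicks.append(f"({newicks[i]}:{li:.10g},{newicks[j]}:{lj:.10g})")
        reps.append(min(reps[i], reps[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for ak, val in new_row.items():
            d[u, ak] = d[ak, u] = max(val, 0.0)
        active = [a for a in active if a not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = f"({newicks[a]}:{la:.10g},{newicks[b]}:{lb:.10g},{newicks[c]}:{lc:.10g});"
    return _parse_tree(newick, rooted=False)


_NEWICK_UNSAFE = set(":,()[]; \t'")


def _quote(label: str) -> str:
    """Quote a taxon label for safe embedding in a newick string."""
    if set(label) & _NEWICK_UNSAFE:
        return "'" + label.replace("'", "''") + "'"
    return label


def _parse_tree(newick: str, rooted: bool) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        rooting="force-rooted" if rooted else "force-unrooted",
        suppress_internal_node_taxa=True,
    )
    return tree


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _node_leafsets(tree: dendropy.Tree) -> dict:
    """Map every node to the frozenset of leaf labels below it."""
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset({node.taxon.label})
        else:
            acc = frozenset()
            for ch in node.child_nodes():
                acc |= below[ch]
            below[node] = acc
    return below


def splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (un)rooted tree as normalized leaf sets.

    Each bipartition is represented by the side that does not contain the
    lexicographically smallest leaf, so that trees with different rootings
    are directly comparable.
    """
    all_leaves = frozenset(leaf_labels(tree))
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()
    below = _node_leafsets(tree)
    for node, side in below.items():
        if node is tree.seed_node:
            continue
        side = all_leaves - side if ref in side else side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    return len(splits(t1) ^ splits(t2))


def test_monophyly(tree: dendropy.Tree, taxa: set[str]) -> bool:
    """True iff some edge of the (unrooted) tree isolates exactly ``taxa``."""
    if not taxa:
        raise ValueError("taxa set must be nonempty")
    leaves = frozenset(leaf_labels(tree))
    taxa = frozenset(taxa)
    if not taxa <= leaves:
        raise ValueError(f"taxa not in tree: {sorted(taxa - leaves)}")
    if len(taxa) in (1, len(leaves)):
        return True
    below = set(_node_leafsets(tree).values())
    return taxa in below or (leaves - taxa) in below


def bootstrap_support(
    aln: SeqAlignment,
    n_reps: int = 100,
    seed: int | None = None,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ point-estimate tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the point-estimate tree is the
    percentage of replicate trees containing that bipartition.  Supports are
    attached to the tree as internal-node labels and also returned as a
    mapping from normalized bipartition to percentage.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    point = nj_tree(distance_matrix(aln, saturation="cap"))
    target = splits(point)
    counts = {s: 0 for s in target}
    ids = aln.ids
    enc = np.vstack([_encode(aln.records[i]) for i in ids])
    length = aln.length
    chars = np.array(list("ACGT?"))
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        res = enc[:, cols]
        rep_aln = SeqAlignment(
            {i: "".join(chars[np.where(row >= 0, row, 4)]) for i, row in zip(ids, res)}
        )
        rep_tree = nj_tree(distance_matrix(rep_aln, saturation="cap"))
        for s in splits(rep_tree):
            if s in counts:
                counts[s] += 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    all_leaves = frozenset(ids)
    ref = min(all_leaves)
    below = _node_leafsets(point)
    for node in point.preorder_node_iter():
        if node.is_leaf() or node is point.seed_node:
            continue
        side = below[node]
        side = all_leaves - side if ref in side else side
        if side in supports:
            node.label = f"{supports[side]:.0f}"
    return point, supports


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Operates on a clone; the input tree is untouched.  Ties between equally
    long paths are broken toward the lexicographically smallest leaf-label
    pair.  A tree whose path lengths are all zero cannot define a midpoint;
    it is returned rooted as-is with a warning.
    """
    rooted = tree.clone(depth=1)
    rooted.is_rooted = True
    dist: dict = {}
    for node in rooted.preorder_node_iter():
        p = node.parent_node
        dist[node] = 0.0 if p is None else dist[p] + (node.edge.length or 0.0)
    leaves = sorted(rooted.leaf_node_iter(), key=lambda l: l.taxon.label)

    def path_to_root(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent_node
        return out

    paths = {l: path_to_root(l) for l in leaves}
    best = None
    for i, u in enumerate(leaves):
        on_u_path = set(map(id, paths[u]))
        for v in leaves[i + 1 :]:
            lca = next(n for n in paths[v] if id(n) in on_u_path)
            d = dist[u] + dist[v] - 2.0 * dist[lca]
            key = (-d, u.taxon.label, v.taxon.label)
            if best is None or key < best[0]:
                best = (key, u, v, lca, d)
    _, u, v, lca, diameter = best
    if diameter <= 0.0:
        warnings.warn("all path lengths zero; tree has no midpoint")
        return rooted
    half = diameter / 2.0

    def edge_at(leaf):
        """Edge containing the point `half` along the path from `leaf`."""
        node, acc = leaf, 0.0
        while node is not lca:
            el = node.edge.length or 0.0
            if acc + el >= half - 1e-12:
                return node, half - acc
            acc += el
            node = node.parent_node
        return None, None

    node, above = edge_at(u)
    if node is None:
        node, above = edge_at(v)
    el = node.edge.length or 0.0
    above = min(max(above, 0.0), el)
    rooted.reroot_at_edge(node.edge, length1=el - above, length2=above,
                          update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


# ---------------------------------------------------------------------------
# presence/absence parsimony and the HTT ratio test


@dataclass
class EventInference:
    """Gain/loss reconstruction for one subfamily on a rooted host tree."""

    n_gains: int
    n_losses: int
    gain_clade: frozenset[str] | None  # leaves below the Dollo gain node
    loss_clades: list[frozenset[str]]  # leaves below each lost branch
    fitch_changes: int

    def replay(self, tree: dendropy.Tree) -> dict[str, bool]:
        """Leaf states implied by the gain/loss assignment (consistency check)."""
        states = {label: False for label in leaf_labels(tree)}
        if self.gain_clade is None:
            return states
        lost = set().union(*self.loss_clades) if self.loss_clades else set()
        for label in self.gain_clade:
            states[label] = label not in lost
        return states


def dollo_events(tree: dendropy.Tree, presence: dict[str, bool]) -> EventInference:
    """Dollo and Fitch parsimony for a binary presence/absence character.

    Dollo parsimony allows a single gain and any number of losses: the gain
    is placed at the latest node covering all present leaves (their MRCA) and
    a loss is charged to the stem of every maximal all-absent subtree below
    it.  Fitch parsimony returns the unrestricted minimum number of state
    changes for comparison; for a presence pattern explicable by m events the
    Fitch count never exceeds the Dollo gain+loss total.
    """
    leaves = leaf_labels(tree)
    missing = leaves - presence.keys()
    if missing:
        raise ValueError(f"presence map lacks states for leaves: {sorted(missing)}")
    present = {label for label in leaves if presence[label]}
    if not present:
        return EventInference(0, 0, None, [], 0)

    below = _node_leafsets(tree)
    # Dollo gain node: smallest clade containing every present leaf
    gain_node = tree.seed_node
    changed = True
    while changed:
        changed = False
        for ch in gain_node.child_nodes():
            if present <= below[ch]:
                gain_node = ch
                changed = True
                break
    loss_clades: list[frozenset[str]] = []

    def collect_losses(node) -> None:
        for ch in node.child_nodes():
            if not (below[ch] & present):
                loss_clades.append(below[ch])
            else:
                collect_losses(ch)

    collect_losses(gain_node)

    # Fitch minimum changes (unrestricted parsimony)
    changes = 0
    state: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            state[node] = {presence[node.taxon.label]}
        else:
            acc = None
            for ch in node.child_nodes():
                if acc is None:
                    acc = state[ch]
                elif acc & state[ch]:
                    acc = acc & state[ch]
                else:
                    acc = acc | state[ch]
                    changes += 1
            state[node] = acc

    return EventInference(
        n_gains=1,
        n_losses=len(loss_clades),
        gain_clade=below[gain_node],
        loss_clades=loss_clades,
        fitch_changes=changes,
    )


@dataclass
class HTTFlag:
    """A species pair whose TE divergence is anomalously low."""

    species_pair: tuple[str, str]
    ratio: float
    te_pair: tuple[str, str]
    te_distance: float
    host_distance: float


def htt_signal(
    te_dm: DistanceMatrix,
    host_dm: DistanceMatrix,
    species_map: dict[str, str],
    ratio_threshold: float = 0.5,
) -> list[HTTFlag]:
    """Flag species pairs whose TE similarity exceeds vertical expectation.

    For every species pair with TE sequences on both sides, the statistic is
    r = (minimum inter-species TE distance) / (host distance); under vertical
    transmission TE divergence tracks host divergence (r near or above 1),
    while a recent horizontal transfer drives r toward 0.  Pairs with
    r < ``ratio_threshold`` are returned, sorted by ratio.
    """
    unmapped = [s for s in te_dm.labels if s not in species_map]
    if unmapped:
        raise ValueError(f"TE sequences without a species: {unmapped}")
    by_species: dict[str, list[str]] = {}
    for seq_id in te_dm.labels:
        by_species.setdefault(species_map[seq_id], []).append(seq_id)
    for sp in host_dm.labels:
        if sp not in by_species:
            warnings.warn(f"species {sp!r} has no TE sequences; omitted from ratio test")
    species = [sp for sp in host_dm.labels if sp in by_species]
    flags: list[HTTFlag] = []
    for i, s1 in enumerate(species):
        for s2 in species[i + 1 :]:
            host_d = host_dm.get(s1, s2)
            if host_d <= 0:
                continue
            best = None
            for a in by_species[s1]:
                for b in by_species[s2]:
                    d = te_dm.get(a, b)
                    if best is None or d < best[0]:
                        best = (d, a, b)
            r = best[0] / host_d
            if r < ratio_threshold:
                flags.append(
                    HTTFlag(
                        species_pair=tuple(sorted((s1, s2))),
                        ratio=r,
                        te_pair=(best[1], best[2]),
                        te_distance=best[0],
                        host_distance=host_d,
                    )
                )
    return sorted(flags, key=lambda f: f.ratio)
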