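"""Independent brute-force oracles used to validate the library.

Everything here is deliberately written the slow, obvious way (explicit
counting, exhaustive enumeration) and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
ACGT = {"A", "C", "G", "T"}


def k2p_brute(a: str, b: str):
    """K2P distance by explicit per-column classification.

    Returns (d, status) where status is 'ok', 'saturated', or 'undefined'.
    """
    assert len(a) == len(b)
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in ACGT or y not in ACGT:
            continue
        n += 1
        if x == y:
            continue
        same_class = (x in PURINES) == (y in PURINES)
        if same_class:
            ts += 1
        else:
            tv += 1
    if n < 10:
        return None, "undefined"
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return None, "saturated"
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), "ok"


# ---------------------------------------------------------------------------
# rooted binary tree enumeration (nested-tuple topologies over leaf names)


def all_rooted_topologies(leaves: list[str]):
    """Every rooted binary topology over the given labeled leaves.

    Built by inserting leaves one at a time onto every edge (including above
    the current root), giving 1, 1, 3, 15, 105, 945 ... topologies.
    """
    if len(leaves) == 1:
        return [leaves[0]]
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        nxt = []
        for t in trees:
            nxt.extend(_insert_everywhere(t, leaf))
        trees = nxt
    return trees


def _insert_everywhere(tree, leaf):
    out = [(tree, leaf)]  # above the current root
    if isinstance(tree, tuple):
        left, right = tree
        out.extend((l2, right) for l2 in _insert_everywhere(left, leaf))
        out.extend((left, r2) for r2 in _insert_everywhere(right, leaf))
    return out


def tree_nodes(tree):
    """Postorder list of subtrees (leaves are strings, internals tuples)."""
    if isinstance(tree, str):
        return [tree]
    left, right = tree
    return tree_nodes(left) + tree_nodes(right) + [tree]


def min_changes_brute(tree, states: dict[str, bool]) -> int:
    """Unrestricted parsimony by enumerating all internal state assignments."""
    nodes = tree_nodes(tree)
    internals = [n for n in nodes if isinstance(n, tuple)]
    best = None
    for assign in itertools.product([False, True], repeat=len(internals)):
        state = dict(zip(map(id, internals), assign))

        def s(node):
            return states[node] if isinstance(node, str) else state[id(node)]

        changes = 0
        for node in internals:
            for child in node:
                if s(child) != s(node):
                    changes += 1
        if best is None or changes < best:
            best = changes
    return best


def dollo_losses_brute(tree, states: dict[str, bool]):
    """Minimum losses under a single gain, by the same enumeration.

    Feasible assignments have at most one 0->1 transition (counting a
    present root as the gain).  Returns (n_gains, min_losses) or (0, 0) for
    an all-absent pattern.
    """
    if not any(states.values()):
        return 0, 0
    nodes = tree_nodes(tree)
    internals = [n for n in nodes if isinstance(n, tuple)]
    best = None
    for assign in itertools.product([False, True], repeat=len(internals)):
        state = dict(zip(map(id, internals), assign))

        def s(node):
            return states[node] if isinstance(node, str) else state[id(node)]

        gains = 1 if s(tree) else 0
        losses = 0
        for node in internals:
            for child in node:
                if s(child) and not s(node):
                    gains += 1
                elif s(node) and not s(child):
                    losses += 1
        if gains == 1 and (best is None or losses < best):
            best = losses
    return 1, best


def parsimony_tables_brute(tree, leaves: list[str]):
    """Exhaustive parsimony tables for every presence pattern on one tree.

    Enumerates all (leaf pattern x internal assignment) state vectors at
    once (numpy-batched, but still plain enumeration) and returns two dicts
    keyed by leaf pattern tuple: minimum unrestricted changes, and minimum
    losses subject to exactly one gain (None where the pattern is all-absent).
    """
    import numpy as np

    nodes = tree_nodes(tree)
    idx = {id(n): i for i, n in enumerate(nodes)}
    name_idx = {n: i for i, n in enumerate(nodes) if isinstance(n, str)}
    edges = [
        (idx[id(n)], idx[id(c)]) for n in nodes if isinstance(n, tuple) for c in n
    ]
    leaf_idx = [name_idx[l] for l in leaves]
    internal_idx = [i for i, n in enumerate(nodes) if isinstance(n, tuple)]
    root_i = idx[id(tree)]
    nl, ni = len(leaf_idx), len(internal_idx)
    combos = np.arange(2 ** (nl + ni))
    states = np.zeros((len(combos), len(nodes)), dtype=bool)
    for bit, i in enumerate(leaf_idx + internal_idx):
        states[:, i] = (combos >> bit) & 1
    changes = np.zeros(len(combos), dtype=int)
    gains = states[:, root_i].astype(int).copy()
    losses = np.zeros(len(combos), dtype=int)
    for p, c in edges:
        diff = states[:, p] != states[:, c]
        changes += diff
        gains += (~states[:, p]) & states[:, c]
        losses += states[:, p] & (~states[:, c])
    pattern_bits = combos & (2**nl - 1)
    fitch: dict = {}
    dollo: dict = {}
    for pat in range(2**nl):
        sel = pattern_bits == pat
        key = tuple(bool((pat >> b) & 1) for b in range(nl))
        fitch[key] = int(changes[sel].min())
        feasible = sel & (gains == 1)
        dollo[key] = int(losses[feasible].min()) if feasible.any() else None
    return fitch, dollo


def topology_to_newick(tree, blen: float = 1.0) -> str:
    def rec(t):
        if isinstance(t, str):
            return f"{t}:{blen}"
        return f"({rec(t[0])},{rec(t[1])}):{blen}"

    return rec(tree) + ";"
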