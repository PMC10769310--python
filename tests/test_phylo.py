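"""Neighbor joining, bootstrap, tree comparison, parsimony, and HTT flags."""

import dendropy
import numpy as np
import pytest

from oracles import k2p_brute
from retrotrace.divergence import SeqAlignment
from retrotrace.models import mutate_sequence, random_dna
from retrotrace.phylo import (
    DistanceMatrix,
    SaturationError,
    bootstrap_support,
    distance_matrix,
    dollo_events,
    htt_signal,
    midpoint_root,
    nj_tree,
    rf_distance,
    splits,
)
from retrotrace.phylo import test_monophyly as is_monophyletic
from retrotrace.scenarios import deep_split_tree, evolve_alignment, random_resolvable_tree
from retrotrace.simulate import simulate_host_tree


def tree_from(newick, rooted=False):
    return dendropy.Tree.get(
        data=newick, schema="newick",
        rooting="force-rooted" if rooted else "force-unrooted",
        suppress_internal_node_taxa=True,
    )


def patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.patristic_distance(taxa[a], taxa[b])


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        aln = SeqAlignment({k: "ACGT" * 30 for k in "abc"})
        dm = distance_matrix(aln)
        assert np.allclose(dm.matrix, 0)

    def test_equals_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        anc = random_dna(400, rng)
        aln = SeqAlignment({f"s{i}": mutate_sequence(anc, 0.1, rng) for i in range(5)})
        dm = distance_matrix(aln)
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    exp, status = k2p_brute(aln.records[a], aln.records[b])
                    assert status == "ok"
                    assert dm.matrix[i, j] == pytest.approx(exp, abs=1e-12)

    def test_saturated_pair_raises_naming_pair(self):
        aln = SeqAlignment({"a": "A" * 60, "b": "G" * 60, "c": "A" * 60})
        with pytest.raises(SaturationError, match="a.*b|b.*a"):
            distance_matrix(aln)

    def test_validation_rejects_asymmetry(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(list("ABC"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        t = nj_tree(dm)
        d = patristic(t)
        assert d("A", "B") == pytest.approx(2.0, abs=1e-12)
        assert d("A", "C") == pytest.approx(4.0, abs=1e-12)
        assert d("B", "C") == pytest.approx(4.0, abs=1e-12)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        m = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        t = nj_tree(DistanceMatrix(list("ABCD"), m))
        assert frozenset("AB") in splits(t) or frozenset("CD") in splits(t)
        d = patristic(t)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert d(a, b) == pytest.approx(m[i, j], abs=1e-10)

    def test_simulated_eight_taxon_recovery(self):
        hits = 0
        for rep in range(30):
            tree = random_resolvable_tree(8, seed=500 + rep)
            aln = evolve_alignment(tree, length=2000, seed=900 + rep)
            inferred = nj_tree(distance_matrix(aln))
            if rf_distance(tree, inferred) == 0:
                hits += 1
        assert hits >= 28  # full 100-replicate rate checked at acceptance

    def test_nonfinite_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, np.inf], [np.inf, 0]]))


class TestRFAndMonophyly:
    def test_identical_trees_distance_zero(self):
        t1 = tree_from("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = tree_from("((A:2,B:2):2,(C:2,D:2):2,E:2);")
        assert rf_distance(t1, t2) == 0

    def test_one_nni_gives_two(self):
        t1 = tree_from("(((A:1,B:1):1,C:1):1,D:1,E:1);")
        t2 = tree_from("(((A:1,C:1):1,B:1):1,D:1,E:1);")
        assert rf_distance(t1, t2) == 2

    def test_star_vs_resolved_four_taxon(self):
        star = tree_from("(A:1,B:1,C:1,D:1);")
        resolved = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(star, resolved) == 1

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rf_distance(tree_from("(A:1,B:1,C:1);"), tree_from("(A:1,B:1,D:1);"))

    def test_monophyly_cases(self):
        t = tree_from("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert is_monophyletic(t, {"A"})
        assert is_monophyletic(t, {"A", "B", "C", "D", "E"})
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})
        with pytest.raises(ValueError):
            is_monophyletic(t, set())


class TestMidpointRoot:
    def test_cherry_rooted_at_two(self):
        t = tree_from("(A:1,B:3);")
        rooted = midpoint_root(t)
        depths = {leaf.taxon.label: leaf.distance_from_root() for leaf in rooted.leaf_node_iter()}
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_root_balances_deepest_paths(self):
        for seed in range(5):
            t = simulate_host_tree(7, seed=seed, height=0.1)
            t2 = tree_from(t.as_string(schema="newick").replace("[&R] ", ""))
            rooted = midpoint_root(t2)
            depths = sorted(
                (leaf.distance_from_root() for leaf in rooted.leaf_node_iter()), reverse=True
            )
            kids = rooted.seed_node.child_nodes()
            sub_depths = []
            for k in kids:
                dk = max(
                    leaf.distance_from_root() for leaf in (k.leaf_iter() if not k.is_leaf() else [k])
                )
                sub_depths.append(dk)
            assert max(sub_depths) == pytest.approx(depths[0])
            assert abs(sub_depths[0] - sub_depths[1]) < 1e-9


class TestBootstrap:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        anc = random_dna(300, rng)
        aln = SeqAlignment({f"t{i}": mutate_sequence(anc, 0.05, rng) for i in range(5)})
        _, s1 = bootstrap_support(aln, n_reps=30, seed=99)
        _, s2 = bootstrap_support(aln, n_reps=30, seed=99)
        assert s1 == s2

    def test_deep_split_strongly_supported(self):
        tree = deep_split_tree()
        aln = evolve_alignment(tree, length=2000, seed=21)
        _, supports = bootstrap_support(aln, n_reps=100, seed=7)
        central = frozenset("EFGH")
        assert supports[central] >= 95.0

    def test_supports_invariant_to_record_order(self):
        tree = deep_split_tree()
        aln = evolve_alignment(tree, length=800, seed=33)
        rev = SeqAlignment(dict(reversed(list(aln.records.items()))))
        _, s1 = bootstrap_support(aln, n_reps=25, seed=5)
        _, s2 = bootstrap_support(rev, n_reps=25, seed=5)
        assert set(s1) == set(s2)

    def test_invalid_rep_count(self):
        aln = SeqAlignment({"a": "ACGT" * 10, "b": "ACGT" * 10, "c": "ACGT" * 10})
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_reps=0)


class TestParsimony:
    def test_textbook_four_taxon_case(self):
        t = tree_from("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        inf = dollo_events(t, {"A": True, "B": False, "C": True, "D": False})
        assert inf.n_gains == 1 and inf.n_losses == 2
        assert inf.fitch_changes == 2
        assert inf.gain_clade == frozenset("ABCD")

    def test_all_present_single_gain_no_loss(self):
        t = tree_from("((A:1,B:1):1,(C:1,D:1):1);", rooted=True)
        inf = dollo_events(t, {l: True for l in "ABCD"})
        assert (inf.n_gains, inf.n_losses, inf.fitch_changes) == (1, 0, 0)

    def test_single_subclade_gain_on_stem(self):
        t = tree_from("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);", rooted=True)
        inf = dollo_events(t, {"A": True, "B": True, "C": False, "D": False, "E": False})
        assert inf.gain_clade == frozenset("AB")
        assert inf.n_losses == 0 and inf.fitch_changes == 1

    def test_all_absent_zero_events(self):
        t = tree_from("((A:1,B:1):1,C:1);", rooted=True)
        inf = dollo_events(t, {l: False for l in "ABC"})
        assert (inf.n_gains, inf.n_losses) == (0, 0)

    def test_oracle_variants_agree(self):
        # the batched enumeration oracle equals the plain one on a 5-leaf tree
        import oracles

        leaves = list("ABCDE")
        topo = oracles.all_rooted_topologies(leaves)[7]
        fitch_tab, dollo_tab = oracles.parsimony_tables_brute(topo, leaves)
        for bits in range(1, 32):
            states = {l: bool((bits >> i) & 1) for i, l in enumerate(leaves)}
            key = tuple(states[l] for l in leaves)
            assert oracles.min_changes_brute(topo, states) == fitch_tab[key]
            assert oracles.dollo_losses_brute(topo, states) == (1, dollo_tab[key])

    def test_replay_reproduces_leaf_states(self):
        t = tree_from("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);", rooted=True)
        presence = {"A": True, "B": False, "C": True, "D": False, "E": True}
        inf = dollo_events(t, presence)
        assert inf.replay(t) == presence


class TestHTTSignal:
    @staticmethod
    def _host_dm():
        return DistanceMatrix(["X", "Y"], np.array([[0.0, 0.10], [0.10, 0.0]]))

    def test_proportional_distances_not_flagged(self):
        te = DistanceMatrix(["x1", "y1"], np.array([[0.0, 0.10], [0.10, 0.0]]))
        flags = htt_signal(te, self._host_dm(), {"x1": "X", "y1": "Y"})
        assert flags == []

    def test_recent_transfer_flagged(self):
        te = DistanceMatrix(["x1", "y1"], np.array([[0.0, 0.01], [0.01, 0.0]]))
        flags = htt_signal(te, self._host_dm(), {"x1": "X", "y1": "Y"})
        assert len(flags) == 1
        assert flags[0].species_pair == ("X", "Y")
        assert flags[0].ratio == pytest.approx(0.1)

    def test_vertical_cospeciation_false_flag_rate(self):
        # TE evolves along the 2-species host tree at the host rate; the
        # min-distance ratio should essentially never drop below 0.5
        false_flags = 0
        host = DistanceMatrix(["X", "Y"], np.array([[0.0, 0.2], [0.2, 0.0]]))
        nwk = "((x1:0.01,x2:0.01):0.09,(y1:0.01,y2:0.01):0.09);"
        tree = tree_from(nwk, rooted=True)
        for rep in range(100):
            aln = evolve_alignment(tree, length=2000, seed=3000 + rep)
            te_dm = distance_matrix(aln)
            flags = htt_signal(
                te_dm, host, {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
            )
            false_flags += bool(flags)
        assert false_flags <= 5

    def test_species_without_sequences_warns_and_omitted(self):
        te = DistanceMatrix(["x1", "x2"], np.array([[0.0, 0.01], [0.01, 0.0]]))
        with pytest.warns(UserWarning, match="no TE sequences"):
            flags = htt_signal(te, self._host_dm(), {"x1": "X", "x2": "X"})
        assert flags == []
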