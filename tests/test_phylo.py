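"""Newick handling, monophyly, Fitch parsimony (vs exhaustive enumeration),
and MAD rooting (vs a grid-search + numeric-refinement oracle)."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from bifphos import (
    TreeSimSpec,
    ValidationError,
    fitch_min_changes,
    gen_labeled_tree,
    is_monophyletic,
    mad_root,
    parse_newick,
    write_newick,
)
from bifphos.phylo import STATES, mad_score_edges


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_min_changes(lt, root_constraint="free"):
    """Minimum changes by exhaustive enumeration of internal-node labelings.

    A root-state constraint is scored as an ancestral-state observation
    attached at the root: labelings whose root state disagrees with it pay
    one extra change (the zero-length stem to the pseudo-ancestor).
    """
    tree = lt.tree.clone(depth=1)
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = math.inf
    for combo in itertools.product(STATES, repeat=len(internal)):
        assign = dict(zip([id(n) for n in internal], combo))
        changes = 0
        if root_constraint != "free" and assign[id(tree.seed_node)] != root_constraint:
            changes += 1
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            for ch in nd.child_nodes():
                s_child = (
                    lt.tip_states[ch.taxon.label] if ch.is_leaf() else assign[id(ch)]
                )
                changes += assign[id(nd)] != s_child
        best = min(best, changes)
    return best


def rooted_rms_deviation(tree):
    """RMS relative ancestor deviation of a rooted tree, from node depths."""
    depth, anc = {}, {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
            anc[id(nd)] = [id(nd)]
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
            anc[id(nd)] = anc[id(nd.parent_node)] + [id(nd)]
    tips = list(tree.leaf_node_iter())
    sq, n = 0.0, 0
    for b, c in itertools.combinations(tips, 2):
        common = set(anc[id(b)]) & set(anc[id(c)])
        mrca_depth = max(depth[i] for i in common)
        d_bc = depth[id(b)] + depth[id(c)] - 2 * mrca_depth
        if d_bc == 0:
            continue
        sq += (2 * (depth[id(b)] - mrca_depth) / d_bc - 1.0) ** 2
        n += 1
    return math.sqrt(sq / n)


def oracle_objective(lt, bipartition, rho):
    """Deviation when rooting at relative position rho on the given branch."""
    tree = lt.tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        tips = frozenset(x.taxon.label for x in edge.head_node.leaf_iter())
        if tips == bipartition:
            L = edge.length or 0.0
            tree.reroot_at_edge(edge, length1=(1 - rho) * L, length2=rho * L)
            tree.is_rooted = True
            return rooted_rms_deviation(tree)
    raise AssertionError("bipartition not found")


def oracle_grid_search(lt, n_rho=101):
    """Dense grid over every branch and root position."""
    bips = []
    for edge in lt.tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        head_tips = frozenset(x.taxon.label for x in edge.head_node.leaf_iter())
        all_tips = frozenset(x.taxon.label for x in lt.tree.leaf_node_iter())
        if head_tips and head_tips != all_tips:
            bips.append(head_tips)
    best = (math.inf, None, None)
    for bip in bips:
        for rho in np.linspace(0.0, 1.0, n_rho):
            val = oracle_objective(lt, bip, float(rho))
            if val < best[0]:
                best = (val, bip, float(rho))
    return best


def random_unrooted_tree(n_tips, seed):
    lt = gen_labeled_tree(TreeSimSpec(n_tips=n_tips, dpo_clade_size=0, seed=seed))
    return parse_newick(write_newick(lt), rooted=False)


# ---------------------------------------------------------------------------
# parsing

class TestNewick:
    def test_two_tip_tree(self):
        lt = parse_newick("(a:1,b:1);")
        assert sorted(lt.tip_labels()) == ["a", "b"]
        lengths = [leaf.edge.length for leaf in lt.tree.leaf_node_iter()]
        assert lengths == [1.0, 1.0]

    def test_states_from_side_table(self):
        lt = parse_newick(
            "((d1:1,d2:1):1,(a1:1,a2:1):1);",
            {"d1": "DPO", "d2": "DPO", "a1": "APO", "a2": "APO"},
        )
        assert len(lt.tip_labels()) == 4
        assert set(lt.tip_states.values()) == {"APO", "DPO"}

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValidationError, match="[Mm]alformed"):
            parse_newick("((a,b);")

    def test_unknown_tip_in_state_table_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            parse_newick("(a:1,b:1);", {"z": "APO"})

    def test_round_trip_preserves_topology_and_lengths(self):
        text = "((d1:0.5,d2:1.25):0.1,(a1:2.0,a2:0.75):0.3);"
        lt = parse_newick(text)
        again = parse_newick(write_newick(lt))
        assert write_newick(lt) == write_newick(again)


class TestMonophyly:
    def test_clean_clade(self):
        lt = parse_newick("((d1,d2),(a1,a2));",
                          {"d1": "DPO", "d2": "DPO", "a1": "APO", "a2": "APO"})
        assert is_monophyletic(lt, "DPO")

    def test_interleaved_states(self):
        lt = parse_newick("((d1,a1),(d2,a2));",
                          {"d1": "DPO", "d2": "DPO", "a1": "APO", "a2": "APO"})
        assert not is_monophyletic(lt, "DPO")

    def test_single_tip_is_a_clade(self):
        lt = parse_newick("((d1,a1),a2);", {"d1": "DPO", "a1": "APO", "a2": "APO"})
        assert is_monophyletic(lt, "DPO")

    def test_absent_state_rejected(self):
        lt = parse_newick("(a1,a2);", {"a1": "APO", "a2": "APO"})
        with pytest.raises(ValidationError, match="absent"):
            is_monophyletic(lt, "DPO")


class TestFitch:
    def argument_tree(self):
        return parse_newick(
            "(((d1:1,d2:1):1,a1:1):1,a2:1);",
            {"d1": "DPO", "d2": "DPO", "a1": "APO", "a2": "APO"},
        )

    def test_one_switch_free_root(self):
        assert fitch_min_changes(self.argument_tree(), "free").min_changes == 1

    def test_dpo_root_needs_two_switches(self):
        assert fitch_min_changes(self.argument_tree(), "DPO").min_changes == 2

    def test_uniform_states_zero_changes(self):
        lt = parse_newick("((a1,a2),a3);", {t: "APO" for t in ("a1", "a2", "a3")})
        assert fitch_min_changes(lt, "free").min_changes == 0
        assert fitch_min_changes(lt, "APO").min_changes == 0

    def test_unlabeled_tip_rejected(self):
        lt = parse_newick("(a1,a2);", {"a1": "APO"})
        with pytest.raises(ValidationError, match="without a state"):
            fitch_min_changes(lt)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        """Fitch equals brute force over all internal labelings, <= 12 tips."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        k = int(rng.integers(0, n + 1))
        lt = gen_labeled_tree(TreeSimSpec(n_tips=n, dpo_clade_size=k, seed=seed + 100))
        # scramble states so the clade structure is not always clean
        if rng.random() < 0.5:
            labels = lt.tip_labels()
            lt.tip_states = {t: STATES[rng.integers(2)] for t in labels}
        for constraint in ("free", "APO", "DPO"):
            got = fitch_min_changes(lt, constraint).min_changes
            assert got == brute_force_min_changes(lt, constraint)

    @pytest.mark.parametrize("seed", range(6))
    def test_constrained_minus_free_in_zero_one(self, seed):
        lt = gen_labeled_tree(TreeSimSpec(n_tips=8, dpo_clade_size=3, seed=seed))
        rng = np.random.default_rng(seed)
        lt.tip_states = {t: STATES[rng.integers(2)] for t in lt.tip_labels()}
        free = fitch_min_changes(lt, "free").min_changes
        for constraint in ("APO", "DPO"):
            diff = fitch_min_changes(lt, constraint).min_changes - free
            assert diff in (0, 1)

    @pytest.mark.parametrize("seed", range(10))
    def test_monophyletic_clade_reproduces_switch_argument(self, seed):
        """DPO clade away from the root: free/APO-rooted cost 1, DPO-rooted cost 2."""
        lt = gen_labeled_tree(TreeSimSpec(n_tips=10, dpo_clade_size=4, seed=seed))
        assert is_monophyletic(lt, "DPO")
        assert fitch_min_changes(lt, "free").min_changes == 1
        assert fitch_min_changes(lt, "APO").min_changes == 1
        assert fitch_min_changes(lt, "DPO").min_changes == 2

    def test_polytomy_resolved(self):
        # a 3-way DPO polytomy costs one switch under any binary resolution
        lt = parse_newick("((d1,d2,d3),a1);",
                          {"d1": "DPO", "d2": "DPO", "d3": "DPO", "a1": "APO"})
        assert fitch_min_changes(lt, "free").min_changes == 1
        assert fitch_min_changes(lt, "DPO").min_changes == 1


class TestMadRoot:
    def test_ultrametric_cherries_root_on_central_branch(self):
        lt = parse_newick("((a:1,b:1):1,(c:1,d:1):1);", rooted=False)
        rooted = mad_root(lt)
        kids = rooted.tree.seed_node.child_nodes()
        clades = sorted(
            "".join(sorted(x.taxon.label for x in k.leaf_iter())) for k in kids
        )
        assert clades in (["ab", "cd"],)
        assert rooted_rms_deviation(rooted.tree) == pytest.approx(0.0, abs=1e-12)

    def test_three_tip_tree_roots_on_long_branch(self):
        lt = parse_newick("(a:1,b:1,c:4);", rooted=False)
        rooted = mad_root(lt)
        # c sits alone on one side of the root
        sides = [
            {x.taxon.label for x in k.leaf_iter()}
            for k in rooted.tree.seed_node.child_nodes()
        ]
        assert {"c"} in sides

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_oracle(self, seed):
        """Best branch and position agree with dense grid + numeric refinement."""
        rng = np.random.default_rng(seed)
        lt = random_unrooted_tree(int(rng.integers(5, 9)), seed=seed + 50)
        scored = mad_score_edges(lt)
        best = min(scored, key=lambda r: r["rms"])
        grid_rms, grid_bip, grid_rho = oracle_grid_search(lt, n_rho=61)
        # implementation must be at least as good as any grid point
        assert best["rms"] <= grid_rms + 1e-9
        impl_bip = frozenset(
            x.taxon.label for x in best["edge"].head_node.leaf_iter()
        )
        all_tips = frozenset(lt.tip_labels())
        assert impl_bip in (grid_bip, all_tips - grid_bip)
        # refine the oracle position on that branch: agreement to 1e-6
        res = minimize_scalar(
            lambda r: oracle_objective(lt, impl_bip, min(1.0, max(0.0, r))),
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": 1e-10},
        )
        L = best["length"]
        assert abs(best["rho"] - res.x) * L < 1e-6
        assert best["rms"] == pytest.approx(res.fun, abs=1e-9)

    def test_tip_order_permutation_invariance(self):
        a = parse_newick("((a:1,b:2):0.5,(c:0.3,d:2.2):0.8,e:1.7);", rooted=False)
        b = parse_newick("(e:1.7,(d:2.2,c:0.3):0.8,(b:2,a:1):0.5);", rooted=False)
        ra, rb = mad_root(a), mad_root(b)
        clades_a = {
            frozenset(x.taxon.label for x in k.leaf_iter())
            for k in ra.tree.seed_node.child_nodes()
        }
        clades_b = {
            frozenset(x.taxon.label for x in k.leaf_iter())
            for k in rb.tree.seed_node.child_nodes()
        }
        assert clades_a == clades_b
        assert rooted_rms_deviation(ra.tree) == pytest.approx(rooted_rms_deviation(rb.tree))

    def test_too_few_tips_rejected(self):
        lt = parse_newick("(a:1,b:1);", rooted=False)
        with pytest.raises(ValidationError, match=">= 3"):
            mad_root(lt)

    def test_all_zero_lengths_rejected(self):
        lt = parse_newick("(a:0,b:0,c:0);", rooted=False)
        with pytest.raises(ValidationError, match="zero"):
            mad_root(lt)
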