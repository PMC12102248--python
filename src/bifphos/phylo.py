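"""Parsimony analysis of assimilatory vs dissimilatory phosphite oxidation.

Phosphite dehydrogenase (ptxD) occurs in organisms that oxidise phosphite
either assimilatorily (APO: phosphite as a phosphorus source) or
dissimilatorily (DPO: phosphite as an electron donor).  Given a gene tree
whose tips are labelled APO or DPO from co-occurring marker genes, this
module asks which metabolism is ancestral: if the DPO tips form a
monophyletic clade away from the root, a single APO→DPO switch explains the
distribution, whereas a DPO root would require two switches back to APO —
one extra change, hence less parsimonious.

Provided operations: Newick round-tripping with a tip→state side table,
monophyly testing, Fitch small parsimony with a free or fixed root state,
and minimal-ancestor-deviation (MAD) rooting of unrooted trees.  Trees are
handled through dendropy; the parsimony and rooting algorithms are
implemented here.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .sorption import ValidationError

logger = logging.getLogger(__name__)

STATES = ("APO", "DPO")


@dataclass
class LabeledTree:
    """A (rooted or unrooted) binary tree with APO/DPO tip states.

    ``tree`` is a dendropy Tree; ``tip_states`` maps taxon labels to states.
    Operations that require a root (monophyly, Fitch) check ``rooted``.
    """

    tree: dendropy.Tree
    tip_states: dict[str, str]
    rooted: bool = True

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def require_states(self) -> None:
        missing = [t for t in self.tip_labels() if t not in self.tip_states]
        if missing:
            raise ValidationError(f"tips without a state: {missing}")
        bad = {t: s for t, s in self.tip_states.items() if s not in STATES}
        if bad:
            raise ValidationError(f"states must be in {STATES}, got {bad}")


@dataclass(frozen=True)
class ParsimonyResult:
    min_changes: int
    root_state_constraint: str          # "free", "APO" or "DPO"
    optimal_root_states: frozenset[str]


def parse_newick(
    text: str,
    tip_states: Mapping[str, str] | None = None,
    rooted: bool = True,
) -> LabeledTree:
    """Parse a Newick string; states come from a side table, not tip labels."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted" if rooted else "force-unrooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"malformed Newick: {exc}") from exc
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    states = dict(tip_states or {})
    unknown = set(states) - labels
    if unknown:
        raise ValidationError(f"state table names tips absent from the tree: {sorted(unknown)}")
    return LabeledTree(tree=tree, tip_states=states, rooted=rooted)


def write_newick(lt: LabeledTree) -> str:
    """Serialise back to Newick (topology, lengths, labels preserved)."""
    return lt.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def is_monophyletic(lt: LabeledTree, state: str) -> bool:
    """True iff the tips carrying ``state`` are exactly the leaf set of one clade."""
    if not lt.rooted:
        raise ValidationError("monophyly test requires a rooted tree")
    lt.require_states()
    target = {t for t in lt.tip_labels() if lt.tip_states[t] == state}
    if not target:
        raise ValidationError(f"state {state!r} absent from the tree")
    if len(target) == 1:
        return True  # a single leaf is a (degenerate) clade
    taxa = [tx for tx in lt.tree.taxon_namespace if tx.label in target]
    mrca = lt.tree.mrca(taxa=taxa)
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade == target


def _resolved_copy(lt: LabeledTree) -> dendropy.Tree:
    """Clone the tree, binary-resolving any polytomies with zero-length edges."""
    tree = lt.tree.clone(depth=1)
    poly = any(len(nd.child_nodes()) > 2 for nd in tree.preorder_node_iter())
    if poly:
        logger.info("multifurcating node(s) resolved arbitrarily with zero-length branches")
        tree.resolve_polytomies(limit=2, update_bipartitions=False)
    return tree


def fitch_min_changes(lt: LabeledTree, root_state_constraint: str = "free") -> ParsimonyResult:
    """Minimum number of state changes on the tree (Fitch small parsimony).

    Post-order pass: a tip's state set is its observed state; an internal
    node takes the intersection of its children's sets when non-empty,
    otherwise their union at the cost of one change.  A root-state
    constraint is scored as an ancestral-state observation — a zero-length
    pseudo-tip of that state attached at the root — so the count increases
    by one exactly when the constrained state is not in the root's optimal
    set.
    """
    if not lt.rooted:
        raise ValidationError("Fitch parsimony requires a rooted tree")
    if root_state_constraint not in ("free",) + STATES:
        raise ValidationError(f"root_state_constraint must be 'free' or one of {STATES}")
    lt.require_states()
    tree = _resolved_copy(lt)

    changes = 0
    sets: dict[int, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            sets[id(nd)] = frozenset({lt.tip_states[nd.taxon.label]})
            continue
        children = [sets[id(c)] for c in nd.child_nodes()]
        acc = children[0]
        for s in children[1:]:
            inter = acc & s
            if inter:
                acc = inter
            else:
                acc = acc | s
                changes += 1
        sets[id(nd)] = acc
    root_set = sets[id(tree.seed_node)]
    if root_state_constraint != "free" and root_state_constraint not in root_set:
        changes += 1
    return ParsimonyResult(
        min_changes=changes,
        root_state_constraint=root_state_constraint,
        optimal_root_states=frozenset(root_set),
    )


# ---------------------------------------------------------------------------
# minimal ancestor deviation rooting

def _adjacency(tree: dendropy.Tree) -> dict[int, list[tuple[object, float]]]:
    adj: dict[int, list[tuple[object, float]]] = {}
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        ln = edge.length if edge.length is not None else 0.0
        adj.setdefault(id(edge.tail_node), []).append((edge.head_node, ln))
        adj.setdefault(id(edge.head_node), []).append((edge.tail_node, ln))
    return adj


def _distances_from(start, adj) -> dict[int, float]:
    """Path length from ``start`` to every node (trees: BFS with accumulation)."""
    dist = {id(start): 0.0}
    stack = [start]
    while stack:
        nd = stack.pop()
        for nbr, ln in adj.get(id(nd), []):
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(nd)] + ln
                stack.append(nbr)
    return dist


def mad_score_edges(lt: LabeledTree) -> list[dict]:
    """MAD objective for every candidate root branch.

    For a root placed at relative position rho (from the branch's head/child
    end) on a branch of length L, each tip pair (b, c) contributes the
    relative deviation |2*d(anc, b)/d(b, c) - 1|, where anc is the point on
    the b–c path nearest the root: the root itself for pairs spanning the
    branch, their meeting node otherwise.  rho minimising the sum of squared
    spanning-pair deviations has a closed form and is clamped to [0, 1]; the
    branch score is the root-mean-square deviation over all pairs.
    """
    tree = lt.tree
    tips = list(tree.leaf_node_iter())
    if len(tips) < 3:
        raise ValidationError("MAD rooting requires >= 3 tips")
    adj = _adjacency(tree)
    tip_dist = {id(t): _distances_from(t, adj) for t in tips}
    if all(
        tip_dist[id(a)][id(b)] == 0
        for a, b in itertools.combinations(tips, 2)
    ):
        raise ValidationError("all branch lengths zero: ancestor deviations undefined")

    results = []
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        head, tail = edge.head_node, edge.tail_node
        L = edge.length if edge.length is not None else 0.0
        below = set(id(x) for x in head.leaf_iter())
        side_a = [t for t in tips if id(t) in below]       # head (child) side
        side_b = [t for t in tips if id(t) not in below]   # tail side
        if not side_a or not side_b:
            continue

        # optimal rho from spanning pairs
        num = 0.0
        den = 0.0
        for b in side_a:
            d_bi = tip_dist[id(b)][id(head)]
            for c in side_b:
                d_bc = tip_dist[id(b)][id(c)]
                if d_bc == 0:
                    continue
                num += (d_bc - 2.0 * d_bi) / d_bc**2
                den += 2.0 / d_bc**2
        rho = 0.5 if (den == 0 or L == 0) else min(1.0, max(0.0, num / (den * L)))

        sq = 0.0
        n_pairs = 0
        for b in side_a:
            d_bi = tip_dist[id(b)][id(head)]
            for c in side_b:
                d_bc = tip_dist[id(b)][id(c)]
                if d_bc == 0:
                    continue
                sq += (2.0 * (d_bi + rho * L) / d_bc - 1.0) ** 2
                n_pairs += 1
        for side, anchor in ((side_a, head), (side_b, tail)):
            for b, c in itertools.combinations(side, 2):
                d_bc = tip_dist[id(b)][id(c)]
                if d_bc == 0:
                    continue
                # meeting node towards the root: d(b, anc) from three distances
                d_b_anchor = tip_dist[id(b)][id(anchor)]
                d_c_anchor = tip_dist[id(c)][id(anchor)]
                d_b_anc = 0.5 * (d_bc + d_b_anchor - d_c_anchor)
                sq += (2.0 * d_b_anc / d_bc - 1.0) ** 2
                n_pairs += 1
        results.append(
            {"edge": edge, "rho": rho, "rms": math.sqrt(sq / n_pairs), "length": L}
        )
    return results


def mad_root(lt: LabeledTree) -> LabeledTree:
    """Root an unrooted tree by minimal ancestor deviation.

    The branch (and position on it) minimising the RMS relative ancestor
    deviation becomes the root; ties go to the first branch in preorder
    traversal and are logged.
    """
    scored = mad_score_edges(lt)
    best = min(scored, key=lambda r: r["rms"])
    ties = [r for r in scored if math.isclose(r["rms"], best["rms"], rel_tol=1e-12, abs_tol=1e-15)]
    if len(ties) > 1:
        logger.info("MAD score tie across %d branches; first in preorder kept", len(ties))

    tree = lt.tree.clone(depth=1)
    # find the corresponding edge in the clone via the bipartition of tip labels
    target_tips = frozenset(x.taxon.label for x in best["edge"].head_node.leaf_iter())
    clone_edge = None
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if frozenset(x.taxon.label for x in edge.head_node.leaf_iter()) == target_tips:
            clone_edge = edge
            break
    assert clone_edge is not None
    L = clone_edge.length if clone_edge.length is not None else 0.0
    rho = best["rho"]
    # root splits the branch at distance rho*L from the head (child) node
    tree.reroot_at_edge(clone_edge, length1=(1.0 - rho) * L, length2=rho * L)
    tree.is_rooted = True
    return LabeledTree(tree=tree, tip_states=dict(lt.tip_states), rooted=True)


def states_from_frame(df) -> dict[str, str]:
    """Tip states from a two-column table (tip_id, state)."""
    return {str(r.iloc[0]): str(r.iloc[1]) for _, r in df.iterrows()}
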