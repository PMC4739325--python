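"""Ortholog-group linking and ancestral-presence assignment on a species tree.

Presence of a lncRNA across species (established by sequence orthology, hence
homologous / single-origin) is explained by one gain followed by losses; the
origin node minimizing the number of events is the last common ancestor (LCA).
When several origins are equally parsimonious the most recent one is chosen,
giving conservative conservation estimates: a lncRNA seen in mouse and rat but
not in primates is assigned to the rodent root rather than the mammalian root
with a loss in primates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Optional, Tuple, Union

import networkx as nx
from Bio import Phylo

__all__ = ["SpeciesTree", "PresenceProfile", "LcaResult", "link_ortholog_groups", "fitch_lca"]


@dataclass
class _Node:
    name: str
    children: list
    parent: Optional["_Node"] = None
    depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """Rooted species tree; internal nodes are auto-named node1, node2, ...
    in preorder when the Newick input leaves them unnamed. Multifurcations
    are allowed."""

    def __init__(self, newick: str):
        tree = Phylo.read(io.StringIO(newick), "newick")
        counter = [0]
        self.nodes: Dict[str, _Node] = {}

        def build(clade, depth: int) -> _Node:
            if clade.is_terminal():
                name = clade.name
                if not name:
                    raise ValueError("unnamed leaf in species tree")
            else:
                if clade.name:
                    name = clade.name
                else:
                    counter[0] += 1
                    name = f"node{counter[0]}"
            if name in self.nodes:
                raise ValueError(f"duplicate node name {name!r}")
            node = _Node(name=name, children=[], depth=depth)
            self.nodes[name] = node
            for ch in clade.clades:
                child = build(ch, depth + 1)
                child.parent = node
                node.children.append(child)
            return node

        self.root = build(tree.root, 0)
        self.leaves = [n for n in self.nodes.values() if n.is_leaf]
        if len(self.leaves) < 2:
            raise ValueError("species tree needs >= 2 leaves")

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves]

    def path_to_root(self, name: str) -> List[str]:
        node = self.nodes[name]
        out = [node.name]
        while node.parent is not None:
            node = node.parent
            out.append(node.name)
        return out

    def set_lca(self, names: Iterable[str]) -> str:
        """Plain last common ancestor of a set of leaves."""
        paths = [list(reversed(self.path_to_root(n))) for n in names]
        if not paths:
            raise ValueError("empty leaf set")
        lca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            level = {p[depth] for p in paths}
            if len(level) == 1:
                lca = level.pop()
            else:
                break
        return lca

    def present_leaves_under(self, name: str, present: set) -> int:
        def count(node: _Node) -> int:
            if node.is_leaf:
                return 1 if node.name in present else 0
            return sum(count(c) for c in node.children)

        return count(self.nodes[name])


PresenceProfile = Dict[str, bool]


@dataclass
class LcaResult:
    node: str
    tie_broken: bool


def _losses_under(tree: SpeciesTree, origin: str, present: set) -> int:
    """Number of loss events when the gene is gained at `origin`: edges from a
    node on a presence path to a child subtree with no present leaf."""

    def walk(node: _Node) -> Tuple[int, bool]:
        # returns (losses, subtree_has_present)
        if node.is_leaf:
            return 0, node.name in present
        losses = 0
        any_present = False
        absent_children = 0
        for c in node.children:
            sub_losses, has = walk(c)
            losses += sub_losses
            if has:
                any_present = True
            else:
                absent_children += 1
        if any_present:
            losses += absent_children
        return losses, any_present

    node = tree.nodes[origin]
    if node.is_leaf:
        return 0
    losses, has = walk(node)
    if not has:
        raise ValueError("origin subtree holds no present leaf")
    return losses


def fitch_lca(tree: SpeciesTree, profile: PresenceProfile) -> LcaResult:
    """Most-parsimonious single-origin ancestor of a presence/absence profile.

    Candidate origins are the set-LCA of present leaves and its ancestors up
    to the root; the cost of origin v is one gain (none when v is the root,
    which has no incoming edge) plus the losses needed below v. Among
    minimum-cost origins the most recent (deepest) is returned; tie_broken
    records whether other parsimony-optimal origins existed.
    """
    missing = set(tree.leaf_names()) - set(profile)
    if missing:
        raise ValueError(f"profile does not cover leaves: {sorted(missing)}")
    present = {name for name, p in profile.items() if p}
    if not present:
        raise ValueError("all-absent profile has no ancestor")
    base = tree.set_lca(present)
    candidates = []
    for name in tree.path_to_root(base):
        gain = 0 if tree.nodes[name].parent is None else 1
        cost = gain + _losses_under(tree, name, present)
        candidates.append((cost, -tree.nodes[name].depth, name))
    best_cost = min(c for c, _, _ in candidates)
    optimal = [c for c in candidates if c[0] == best_cost]
    optimal.sort(key=lambda c: c[1])  # deepest (most recent) first
    return LcaResult(node=optimal[0][2], tie_broken=len(optimal) > 1)


def link_ortholog_groups(
    pairwise: Iterable[Tuple[Hashable, Hashable]]
) -> List[frozenset]:
    """Greedy linking of pairwise orthologs into groups: given pairs {A,B}
    and {B,C}, the group {A,B,C} is formed even if {A,C} was never observed.
    Members are (species, transcript id) keys; returns connected components,
    deterministically ordered."""
    g = nx.Graph()
    for a, b in pairwise:
        g.add_edge(a, b)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: sorted(map(str, c)))
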