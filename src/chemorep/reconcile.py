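"""Duplication-loss parsimony reconciliation of a gene tree with a species
tree.

The gene tree is embedded into the species tree by the LCA mapping; a gene
node is a duplication iff one of its children maps to the same species
node, and losses are read off the mapping-path depth differences.  Events
are aggregated onto species branches, giving per-branch gains/losses and
ancestral copy numbers that satisfy, on every branch,

    child-side count = parent-side count + gains - losses >= 0.

A duplication mapped to species node ``s`` is counted as a gain on the
branch leading to ``s``; a loss on a branch means a lineage entered that
branch and died before its lower end.  Species nodes above the root of the
embedding carry count 0 (the family has not originated yet).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable

import dendropy
import pandas as pd


class MappingError(ValueError):
    """A gene leaf cannot be mapped to any species leaf."""


class PolytomyError(ValueError):
    """Reconciliation requires fully binary trees."""


def species_from_prefix(label: str) -> str:
    """Default leaf mapping: species is the token before the first '_'
    (or blank, for parsers that rewrite underscores as spaces)."""
    return label.replace(" ", "_").split("_", 1)[0]


def _check_binary(tree: dendropy.Tree, name: str) -> None:
    for nd in tree.preorder_node_iter():
        k = len(nd.child_nodes())
        if k not in (0, 2):
            raise PolytomyError(f"{name} has a node with {k} children; binary required")


def _node_key(nd: dendropy.Node) -> str:
    leaves = sorted(lf.taxon.label for lf in nd.leaf_iter() if lf.taxon)
    return leaves[0] if len(leaves) == 1 else "+".join(leaves)


@dataclasses.dataclass
class ReconciliationResult:
    duplications: int
    losses: int
    cost: float
    gains_per_branch: dict[str, int]     # keyed by child-side species node
    losses_per_branch: dict[str, int]
    counts: dict[str, int]               # ancestral/extant copy number per node
    mapping: dict[int, str]              # id(gene node) -> species node key
    root_key: str                        # species node where the family starts


def _reconcile_rooted(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                      species_of: Callable[[str], str],
                      dup_cost: float, loss_cost: float) -> ReconciliationResult:
    snodes: dict[str, dendropy.Node] = {}
    parent: dict[str, str | None] = {}
    depth: dict[str, int] = {}
    for nd in species_tree.preorder_node_iter():
        key = _node_key(nd)
        snodes[key] = nd
        parent[key] = _node_key(nd.parent_node) if nd.parent_node else None
        depth[key] = 0 if nd.parent_node is None else depth[parent[key]] + 1

    sleaf_by_label = {
        lf.taxon.label: _node_key(lf) for lf in species_tree.leaf_node_iter()
    }

    def anc_chain(key: str) -> list[str]:
        chain = [key]
        while parent[chain[-1]] is not None:
            chain.append(parent[chain[-1]])
        return chain

    def lca(a: str, b: str) -> str:
        seen = set(anc_chain(a))
        for k in anc_chain(b):
            if k in seen:
                return k
        raise RuntimeError("disconnected species tree")  # pragma: no cover

    # LCA mapping, postorder.
    M: dict[int, str] = {}
    for nd in gene_tree.postorder_node_iter():
        if nd.is_leaf():
            sp = species_of(nd.taxon.label)
            if sp not in sleaf_by_label:
                raise MappingError(f"gene leaf {nd.taxon.label!r} maps to unknown species {sp!r}")
            M[id(nd)] = sleaf_by_label[sp]
        else:
            c1, c2 = nd.child_nodes()
            M[id(nd)] = lca(M[id(c1)], M[id(c2)])

    gains: dict[str, int] = {k: 0 for k in snodes}
    losses: dict[str, int] = {k: 0 for k in snodes}
    n_dup = 0

    def path_down(top: str, bottom: str) -> list[str]:
        """Species nodes from top to bottom inclusive (bottom within top)."""
        chain = anc_chain(bottom)
        out = []
        for k in chain:
            out.append(k)
            if k == top:
                break
        return list(reversed(out))

    def off_path_child(u: str, on_path: str) -> str:
        c1, c2 = (_node_key(c) for c in snodes[u].child_nodes())
        return c2 if c1 == on_path else c1

    for nd in gene_tree.preorder_internal_node_iter():
        mv = M[id(nd)]
        children = nd.child_nodes()
        is_dup = any(M[id(c)] == mv for c in children)
        if is_dup:
            n_dup += 1
            gains[mv] += 1
        for c in children:
            mc = M[id(c)]
            if mc == mv:
                continue
            path = path_down(mv, mc)  # [mv, ..., mc]
            # Speciation: lineage enters the on-path child of mv for free;
            # duplication: it starts at mv, so mv's off-path branch loses too.
            start = 0 if is_dup else 1
            for idx in range(start, len(path) - 1):
                u = path[idx]
                losses[off_path_child(u, path[idx + 1])] += 1

    root_key = M[id(gene_tree.seed_node)]

    # Copy numbers: 1 lineage enters the branch above the embedding root.
    counts: dict[str, int] = {}
    for nd in species_tree.preorder_node_iter():
        key = _node_key(nd)
        if key == root_key:
            top = 1
        elif parent[key] is not None and parent[key] in counts and _in_subtree(
            key, root_key, parent
        ):
            top = counts[parent[key]]
        else:
            counts[key] = 0
            continue
        counts[key] = top + gains[key] - losses[key]
        if counts[key] < 0:  # pragma: no cover - guaranteed by construction
            raise RuntimeError("negative copy count; reconciliation bug")

    n_loss = sum(losses.values())
    return ReconciliationResult(
        duplications=n_dup,
        losses=n_loss,
        cost=dup_cost * n_dup + loss_cost * n_loss,
        gains_per_branch=gains,
        losses_per_branch=losses,
        counts=counts,
        mapping=M,
        root_key=root_key,
    )


def _in_subtree(key: str, root_key: str, parent: dict[str, str | None]) -> bool:
    k: str | None = key
    while k is not None:
        if k == root_key:
            return True
        k = parent[k]
    return False


def reconcile_dl(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                 species_of: Callable[[str], str] = species_from_prefix,
                 rooting: str = "fixed",
                 dup_cost: float = 1.0, loss_cost: float = 1.0) -> ReconciliationResult:
    """LCA-mapping duplication-loss reconciliation.

    ``rooting='minimize'`` reroots the gene tree on every edge and keeps the
    minimum-cost reconciliation, breaking ties by the lexicographically
    smallest root edge (identified by the smallest leaf label on each side).
    """
    _check_binary(species_tree, "species tree")
    if rooting == "fixed":
        _check_binary(gene_tree, "gene tree")
        return _reconcile_rooted(gene_tree, species_tree, species_of,
                                 dup_cost, loss_cost)
    if rooting != "minimize":
        raise ValueError("rooting must be 'fixed' or 'minimize'")

    best: tuple[float, tuple[str, str]] | None = None
    best_result: ReconciliationResult | None = None
    newick = gene_tree.as_string(schema="newick", unquoted_underscores=True)
    base = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    edges = [e for e in base.preorder_edge_iter()
             if e.head_node.parent_node is not None]
    for i in range(len(edges)):
        work = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        wedges = [e for e in work.preorder_edge_iter()
                  if e.head_node.parent_node is not None]
        edge = wedges[i]
        head_leaves = sorted(
            lf.taxon.label for lf in edge.head_node.leaf_iter() if lf.taxon
        )
        all_leaves = sorted(lf.taxon.label for lf in work.leaf_node_iter() if lf.taxon)
        other = sorted(set(all_leaves) - set(head_leaves))
        if not other:
            continue
        edge_key = tuple(sorted((head_leaves[0], other[0])))
        try:
            work.reroot_at_edge(edge, update_bipartitions=False)
            work.suppress_unifurcations()
            _check_binary(work, "gene tree")
            res = _reconcile_rooted(work, species_tree, species_of,
                                    dup_cost, loss_cost)
        except PolytomyError:
            continue
        key = (res.cost, edge_key)
        if best is None or key < best:
            best = key
            best_result = res
    if best_result is None:
        raise ValueError("no valid rooting found")
    return best_result


def event_table(result: ReconciliationResult,
                species_tree: dendropy.Tree) -> pd.DataFrame:
    """Per-branch gains/losses/copy-number table (one row per non-root branch)."""
    rows = []
    for nd in species_tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        key = _node_key(nd)
        pkey = _node_key(nd.parent_node)
        parent_count = result.counts.get(pkey, 0)
        if key == result.root_key:
            parent_count = 1  # the originating lineage enters this branch
        child_count = result.counts.get(key, 0)
        g = result.gains_per_branch.get(key, 0)
        l = result.losses_per_branch.get(key, 0)
        assert child_count == parent_count + g - l or not _in_subtree(
            key, result.root_key,
            {_node_key(x): (_node_key(x.parent_node) if x.parent_node else None)
             for x in species_tree.preorder_node_iter()},
        ), "per-branch conservation identity violated"
        rows.append(
            {"branch": key, "parent": pkey, "gains": g, "losses": l,
             "parent_count": parent_count, "child_count": child_count}
        )
    return pd.DataFrame(rows)
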