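"""Independent brute-force oracles used by the acceptance script."""

from __future__ import annotations

import math
import random

import dendropy


def _species_index(tree):
    nodes = list(tree.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    parent = [idx[id(n.parent_node)] if n.parent_node else -1 for n in nodes]
    leaves = {}
    for n in nodes:
        if n.is_leaf():
            leaves[n.taxon.label] = idx[id(n)]
    desc = [set() for _ in nodes]
    for i, n in enumerate(nodes):
        for m in n.preorder_iter():
            desc[i].add(idx[id(m)])
    depth = [0] * len(nodes)
    for i in range(len(nodes)):
        depth[i] = 0 if parent[i] < 0 else depth[parent[i]] + 1
    return nodes, parent, leaves, desc, depth


def brute_force_dl_cost(gene_tree, species_tree, species_of) -> float:
    """Minimum duplication+loss cost by exhaustive species-labeled DP,
    independent of the LCA-mapping shortcut."""
    nodes, parent, leaves, desc, depth = _species_index(species_tree)
    idx_of = {id(n): i for i, n in enumerate(nodes)}
    INF = math.inf
    memo = {}

    def cost(gnode, s):
        key = (id(gnode), s)
        if key in memo:
            return memo[key]
        if gnode.is_leaf():
            out = 0.0 if leaves[species_of(gnode.taxon.label)] == s else INF
            memo[key] = out
            return out
        c1, c2 = gnode.child_nodes()
        best = INF
        kids = nodes[s].child_nodes()
        for s1 in desc[s]:
            k1 = cost(c1, s1)
            if k1 == INF:
                continue
            for s2 in desc[s]:
                k2 = cost(c2, s2)
                if k2 == INF:
                    continue
                if kids:
                    i1 = next((ci for ci, c in enumerate(kids)
                               if s1 in desc[idx_of[id(c)]]), None)
                    i2 = next((ci for ci, c in enumerate(kids)
                               if s2 in desc[idx_of[id(c)]]), None)
                    if i1 is not None and i2 is not None and i1 != i2:
                        ev = (depth[s1] - depth[s] - 1) + (depth[s2] - depth[s] - 1)
                        best = min(best, k1 + k2 + ev)
                ev = 1 + (depth[s1] - depth[s]) + (depth[s2] - depth[s])
                best = min(best, k1 + k2 + ev)
        memo[key] = best
        return best

    return min(cost(gene_tree.seed_node, s) for s in range(len(nodes)))


def random_instance(rng: random.Random, n_species: int, n_genes: int):
    """A random species tree and a random binary species-labeled gene tree."""
    taxa = [chr(ord("A") + i) for i in range(n_species)]
    sp = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng
    )
    for lf, name in zip(sp.leaf_node_iter(), taxa):
        lf.taxon.label = name
    genes = [f"{rng.choice(taxa)}_g{i}" for i in range(n_genes)]
    newicks = list(genes)
    while len(newicks) > 1:
        i, j = rng.sample(range(len(newicks)), 2)
        merged = f"({newicks[i]},{newicks[j]})"
        newicks = [n for k, n in enumerate(newicks) if k not in (i, j)] + [merged]
    gt = dendropy.Tree.get(data=newicks[0] + ";", schema="newick",
                           preserve_underscores=True)
    return gt, sp
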