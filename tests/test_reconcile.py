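"""Duplication-loss reconciliation against an independent brute-force
oracle (species-labeled dynamic program over all valid embeddings)."""

import itertools
import math
import random

import dendropy
import numpy as np
import pytest

from chemorep.reconcile import (
    MappingError,
    PolytomyError,
    event_table,
    reconcile_dl,
)
from chemorep.simulate import simulate_family_evolution
from conftest import newick


# --- brute-force oracle ----------------------------------------------------


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
    for i, n in enumerate(nodes):
        depth[i] = 0 if parent[i] < 0 else depth[parent[i]] + 1
    return nodes, parent, leaves, desc, depth


def brute_force_dl_cost(gene_tree, species_tree, species_of) -> float:
    """Minimum duplication+loss cost over every valid node mapping,
    computed by exhaustive DP (independent of the LCA-mapping shortcut)."""
    nodes, parent, leaves, desc, depth = _species_index(species_tree)
    INF = math.inf

    def dist(a, b):  # b inside subtree of a
        return depth[b] - depth[a]

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
        for s1 in desc[s]:
            k1 = cost(c1, s1)
            if k1 == INF:
                continue
            for s2 in desc[s]:
                k2 = cost(c2, s2)
                if k2 == INF:
                    continue
                kids = [c for c in nodes[s].child_nodes()]
                # speciation only if s1, s2 under different children of s
                spec_ok = False
                if kids:
                    i1 = next((ci for ci, c in enumerate(kids)
                               if s1 in desc[_sid(c, nodes)]), None)
                    i2 = next((ci for ci, c in enumerate(kids)
                               if s2 in desc[_sid(c, nodes)]), None)
                    spec_ok = i1 is not None and i2 is not None and i1 != i2
                if spec_ok:
                    ev = (dist(s, s1) - 1) + (dist(s, s2) - 1)
                    best = min(best, k1 + k2 + ev)
                ev = 1 + dist(s, s1) + dist(s, s2)  # duplication at s
                best = min(best, k1 + k2 + ev)
        memo[key] = best
        return best

    def _sid(node, nodes):
        return nodes.index(node)

    root_best = min(cost(gene_tree.seed_node, s) for s in range(len(nodes)))
    return root_best


def _random_instance(rng: random.Random, n_species: int, n_genes: int):
    taxa = [chr(ord("A") + i) for i in range(n_species)]
    sp = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng
    )
    for lf, name in zip(sp.leaf_node_iter(), taxa):
        lf.taxon.label = name
    genes = [f"{rng.choice(taxa)}_g{i}" for i in range(n_genes)]
    # random binary gene-tree topology
    nodes = [f"{g}" for g in genes]
    newicks = [g for g in genes]
    while len(newicks) > 1:
        i, j = rng.sample(range(len(newicks)), 2)
        merged = f"({newicks[i]},{newicks[j]})"
        newicks = [n for k, n in enumerate(newicks) if k not in (i, j)] + [merged]
    gt = dendropy.Tree.get(data=newicks[0] + ";", schema="newick",
                           preserve_underscores=True)
    return gt, sp


class TestReconcileDl:
    def test_congruent_tree_is_fixed_point(self):
        st = newick("((A:1,B:1):1,C:2);")
        gt = newick("((A_g1,B_g1),C_g1);")
        r = reconcile_dl(gt, st)
        assert r.duplications == 0 and r.losses == 0
        assert all(v == 1 for v in r.counts.values())

    def test_single_duplication_on_terminal_branch(self):
        st = newick("(A:1,B:1);")
        gt = newick("((A_g1,A_g2),B_g1);")
        r = reconcile_dl(gt, st)
        assert r.duplications == 1 and r.losses == 0
        assert r.gains_per_branch["A"] == 1
        assert r.counts["A"] == 2 and r.counts["B"] == 1

    def test_missing_species_counted_as_loss(self):
        st = newick("((A:1,B:1):1,C:2);")
        r = reconcile_dl(newick("(A_g1,C_g1);"), st)
        assert r.duplications == 0 and r.losses == 1
        assert r.losses_per_branch["B"] == 1

    def test_unmapped_leaf_raises(self):
        st = newick("(A:1,B:1);")
        with pytest.raises(MappingError):
            reconcile_dl(newick("(A_g1,Z_g1);"), st)

    def test_polytomy_rejected(self):
        st = newick("(A:1,B:1);")
        with pytest.raises(PolytomyError):
            reconcile_dl(newick("(A_g1,A_g2,B_g1);"), st)

    def test_cost_matches_brute_force_on_random_instances(self):
        rng = random.Random(11)
        for rep in range(60):
            n_sp = rng.randint(2, 5)
            n_g = rng.randint(2, 7)
            gt, sp = _random_instance(rng, n_sp, n_g)
            mine = reconcile_dl(gt, sp)
            oracle = brute_force_dl_cost(gt, sp,
                                         lambda l: l.split("_", 1)[0])
            assert mine.cost == oracle, (
                f"rep {rep}: cost {mine.cost} != oracle {oracle}"
            )

    def test_rooting_minimize_never_worse_than_fixed(self):
        rng = random.Random(5)
        for rep in range(15):
            gt, sp = _random_instance(rng, 3, 5)
            fixed = reconcile_dl(gt, sp)
            best = reconcile_dl(gt, sp, rooting="minimize")
            assert best.cost <= fixed.cost


class TestEventTable:
    def test_zero_rates_give_zero_table(self):
        st = newick("((A:1,B:1):1,(C:1,D:1):1);")
        truth = simulate_family_evolution(st, birth=0.0, death=0.0,
                                          n_root=1, seed=3)
        r = reconcile_dl(truth.gene_tree, st)
        tab = event_table(r, st)
        assert (tab["gains"] == 0).all() and (tab["losses"] == 0).all()
        assert (tab["child_count"] == 1).all()

    def test_conservation_identity_on_random_families(self):
        st = newick("((A:1,B:1):1,(C:1,D:1):1);")
        for seed in range(40):
            truth = simulate_family_evolution(st, birth=0.3, death=0.2,
                                              n_root=1, seed=seed)
            if truth.extinct or len(truth.gene_tree.leaf_nodes()) < 2:
                continue
            try:
                r = reconcile_dl(truth.gene_tree, st)
            except PolytomyError:
                continue
            tab = event_table(r, st)
            ok = tab["child_count"] == tab["parent_count"] + tab["gains"] - tab["losses"]
            # rows above the family's origin legitimately show 0 = 0
            assert ok.all()

    def test_planted_burst_detected(self):
        st = newick("((A:1,B:1):1,(C:1,D:1):1);")
        hits = 0
        total = 0
        for seed in range(40):
            truth = simulate_family_evolution(
                st, birth={"A": 2.0}, death=0.0, n_root=1, seed=seed
            )
            if truth.extinct:
                continue
            total += 1
            if truth.tip_counts["A"] == max(truth.tip_counts.values()) and \
                    truth.tip_counts["A"] > 1:
                hits += 1
        assert total > 30 and hits / total >= 0.8

    def test_parsimony_recovers_low_rate_truth(self):
        st = newick("((A:1,B:1):1,(C:1,D:1):1);")
        agree = 0
        total = 0
        # at these rates a same-branch duplication-loss pair (invisible to
        # parsimony) is rare enough for event-count recovery
        for seed in range(80):
            truth = simulate_family_evolution(st, birth=0.03, death=0.03,
                                              n_root=1, seed=seed)
            if truth.extinct or len(truth.gene_tree.leaf_nodes()) < 2:
                continue
            try:
                r = reconcile_dl(truth.gene_tree, st)
            except PolytomyError:
                continue
            total += 1
            sim_events = sum(truth.gains.values()) + sum(truth.losses.values())
            inf_events = r.duplications + r.losses
            agree += inf_events == sim_events
        assert total >= 40
        assert agree / total >= 0.9
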