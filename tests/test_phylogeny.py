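import itertools
import math

import dendropy
import numpy as np
import pytest

from chemorep.io import SequenceRecord
from chemorep.phylogeny import (
    DistanceMatrix,
    IncomparablePairError,
    SaturatedDistanceError,
    assign_subfamily,
    bootstrap_support,
    column_information,
    nj_tree,
    poisson_distance_matrix,
)
from conftest import newick


def _rf(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Unrooted Robinson-Foulds distance."""
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns, rooting="force-unrooted")
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns, rooting="force-unrooted")
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


def _additive_dm(tree: dendropy.Tree) -> DistanceMatrix:
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    tx = {l: tree.taxon_namespace.get_taxon(l) for l in labels}
    n = len(labels)
    M = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        M[i, j] = M[j, i] = pdm.patristic_distance(tx[labels[i]], tx[labels[j]])
    return DistanceMatrix(labels, M, np.zeros((n, n), dtype=bool))


class TestPoissonDistance:
    def test_closed_form_and_identity(self):
        a = SequenceRecord("a", "A" * 90 + "C" * 10)
        b = SequenceRecord("b", "A" * 90 + "D" * 10)
        c = SequenceRecord("c", "A" * 90 + "C" * 10)
        dm = poisson_distance_matrix([a, b, c])
        i, j, k = (dm.labels.index(x) for x in "abc")
        assert dm.matrix[i, k] == 0.0
        assert abs(dm.matrix[i, j] - (-math.log(0.9))) < 1e-12

    def test_pairwise_deletion_of_gaps(self):
        # gap columns in one sequence excluded only for pairs involving it
        a = SequenceRecord("a", "AAAAACCCCC")
        b = SequenceRecord("b", "AAAAA-----")
        dm = poisson_distance_matrix([a, b])
        assert dm.matrix[0, 1] == 0.0  # 5 shared columns, all equal

    def test_saturated_pair_flagged(self):
        a = SequenceRecord("a", "AAAA")
        b = SequenceRecord("b", "CCCC")
        dm = poisson_distance_matrix([a, b])
        assert dm.saturated[0, 1]

    def test_no_shared_columns_is_error(self):
        a = SequenceRecord("a", "AA--")
        b = SequenceRecord("b", "--CC")
        with pytest.raises(IncomparablePairError):
            poisson_distance_matrix([a, b])


class TestNeighborJoining:
    def test_exact_recovery_from_additive_distances(self):
        t = newick("((a:1,b:2):1,(c:1.5,(d:0.5,e:0.5):1):0.5,f:3);")
        assert _rf(t, nj_tree(_additive_dm(t))) == 0

    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(7)
        for rep in range(20):
            taxa = [f"t{i}" for i in range(7)]
            sim = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=7,
                rng=__import__("random").Random(int(rng.integers(1 << 30))),
            )
            for i, lf in enumerate(sim.leaf_node_iter()):
                lf.taxon.label = taxa[i]
            for e in sim.preorder_edge_iter():
                if e.length is not None:
                    e.length = max(e.length, 0.05)
            assert _rf(sim, nj_tree(_additive_dm(sim))) == 0

    def test_three_point_lengths(self):
        labels = ["a", "b", "c"]
        M = np.array([[0, 3.0, 4.0], [3.0, 0, 5.0], [4.0, 5.0, 0]])
        t = nj_tree(DistanceMatrix(labels, M, np.zeros((3, 3), bool)))
        lengths = {l.taxon.label: l.edge.length for l in t.leaf_node_iter()}
        # three-point equations: la+lb=3, la+lc=4, lb+lc=5
        assert abs(lengths["a"] - 1.0) < 1e-9
        assert abs(lengths["b"] - 2.0) < 1e-9
        assert abs(lengths["c"] - 3.0) < 1e-9

    def test_taxon_order_invariance(self):
        t = newick("((a:1,b:2):1,(c:1.5,d:0.7):0.5,e:3);")
        dm = _additive_dm(t)
        perm = [3, 0, 4, 1, 2]
        labels2 = [dm.labels[i] for i in perm]
        M2 = dm.matrix[np.ix_(perm, perm)]
        t1 = nj_tree(dm)
        t2 = nj_tree(DistanceMatrix(labels2, M2, np.zeros((5, 5), bool)))
        assert _rf(t1, t2) == 0

    def test_saturated_refused(self):
        M = np.array([[0, np.inf, 1.0], [np.inf, 0, 1.0], [1.0, 1.0, 0]])
        sat = np.zeros((3, 3), bool)
        sat[0, 1] = sat[1, 0] = True
        dm = DistanceMatrix(["a", "b", "c"], M, sat)
        with pytest.raises(SaturatedDistanceError):
            nj_tree(dm)


class TestBootstrap:
    def _alignment(self):
        # two deep clades: 35% divergence leaves plenty of shared columns,
        # so no bootstrap replicate saturates the Poisson correction
        rng = np.random.default_rng(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(aas[i] for i in rng.integers(0, 20, 120))
        other = "".join(
            aas[(aas.index(c) + 3) % 20] if rng.random() < 0.35 else c
            for c in base
        )
        recs = []
        for i in range(5):
            s = list(base)
            s[i] = "W"
            recs.append(SequenceRecord(f"x{i}", "".join(s)))
        for i in range(5):
            s = list(other)
            s[i] = "W"
            recs.append(SequenceRecord(f"y{i}", "".join(s)))
        return recs

    def test_high_signal_split_support(self):
        t = bootstrap_support(self._alignment(), n_reps=50, seed=0)
        supports = [float(nd.label) for nd in t.preorder_internal_node_iter()
                    if nd.label is not None]
        assert max(supports) >= 95.0

    def test_single_replicate_supports_binary(self):
        t = bootstrap_support(self._alignment(), n_reps=1, seed=0)
        for nd in t.preorder_internal_node_iter():
            if nd.label is not None:
                assert float(nd.label) in (0.0, 100.0)

    def test_seed_determinism(self):
        t1 = bootstrap_support(self._alignment(), n_reps=20, seed=5)
        t2 = bootstrap_support(self._alignment(), n_reps=20, seed=5)
        s1 = sorted(nd.label for nd in t1.preorder_internal_node_iter() if nd.label)
        s2 = sorted(nd.label for nd in t2.preorder_internal_node_iter() if nd.label)
        assert s1 == s2


class TestAssignSubfamily:
    def _panel(self):
        rng = np.random.default_rng(3)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        refs, labels = [], {}
        for fam in range(3):
            base = "".join(aas[i] for i in rng.integers(0, 20, 100))
            for k in range(3):
                s = list(base)
                for pos in rng.integers(0, 100, 5):
                    s[pos] = aas[rng.integers(20)]
                rid = f"f{fam}_r{k}"
                refs.append(SequenceRecord(rid, "".join(s)))
                labels[rid] = str(fam)
        return refs, labels

    def test_mutated_copy_assigned_to_its_subfamily(self):
        refs, labels = self._panel()
        rng = np.random.default_rng(9)
        src = refs[4]  # family 1
        s = list(src.residues)
        for pos in rng.integers(0, 100, 8):
            s[pos] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
        q = SequenceRecord("query", "".join(s))
        assert assign_subfamily(q, refs, labels) == "1"

    def test_reference_is_its_own_label(self):
        refs, labels = self._panel()
        q = SequenceRecord("query", refs[7].residues)
        assert assign_subfamily(q, refs, labels) == labels[refs[7].id]

    def test_equidistant_query_unassigned(self):
        refs = [SequenceRecord("r1", "AAAA"), SequenceRecord("r2", "CCCC")]
        labels = {"r1": "1", "r2": "2"}
        q = SequenceRecord("q", "AACC")
        assert assign_subfamily(q, refs, labels) is None

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            assign_subfamily(SequenceRecord("q", "AAAA"), [], {})


class TestColumnInformation:
    def test_reference_values(self):
        recs = [SequenceRecord("a", "AAC"), SequenceRecord("b", "ACC"),
                SequenceRecord("c", "ADC"), SequenceRecord("d", "AEC")]
        # col0 conserved; col1 uniform over 4 residues; col2 conserved
        prof = column_information(recs)
        assert abs(prof.ic[0] - math.log2(20)) < 1e-12
        assert abs(prof.ic[1] - (math.log2(20) - 2.0)) < 1e-12

    def test_half_half_column(self):
        recs = [SequenceRecord(f"s{i}", "A" if i < 4 else "C") for i in range(8)]
        prof = column_information(recs)
        assert abs(prof.ic[0] - (math.log2(20) - 1.0)) < 1e-12

    def test_all_gap_column_flagged(self):
        recs = [SequenceRecord("a", "-A"), SequenceRecord("b", "-C")]
        prof = column_information(recs)
        assert prof.all_gap[0] and not prof.all_gap[1]
        assert np.isnan(prof.ic[0])

    def test_category_means_bounded(self):
        rng = np.random.default_rng(0)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        recs = [
            SequenceRecord(f"s{i}", "".join(aas[j] for j in rng.integers(0, 20, 30)))
            for i in range(6)
        ]
        cats = ["binding" if i % 2 else "other" for i in range(30)]
        prof = column_information(recs, cats)
        assert 0.0 <= prof.mean_ic("binding") <= math.log2(20)
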