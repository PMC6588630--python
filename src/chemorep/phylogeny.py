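"""Distance-based phylogenetics for receptor repertoires.

The tree engine is classical neighbor-joining over Poisson-corrected
protein distances with pairwise deletion of gap sites, evaluated by a
column-resampling bootstrap.  Subfamily assignment places a query on a
combined tree and reads the smallest pure reference clade; per-column
information content summarizes conservation of binding-site categories.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import dendropy
import numpy as np

from .io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}
MAX_IC_BITS = math.log2(20.0)


class SaturatedDistanceError(ValueError):
    """A pairwise distance is saturated (all shared sites differ)."""


class IncomparablePairError(ValueError):
    """A pair of sequences shares no gap-free columns."""


@dataclasses.dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray          # symmetric, zero diagonal
    saturated: np.ndarray       # boolean mask of saturated pairs

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)


def _alignment_array(records: Sequence[SequenceRecord]) -> np.ndarray:
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    return np.array([list(r.residues.upper()) for r in records])


def poisson_distance_matrix(records: Sequence[SequenceRecord]) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) with pairwise gap deletion.

    p is the mismatch fraction over columns where neither sequence has a
    gap.  A pair with p = 1 is flagged saturated (distance set to +inf);
    a pair with no shared gap-free columns raises
    :class:`IncomparablePairError`.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    arr = _alignment_array(records)
    is_gap = (arr == "-") | (arr == ".") | (arr == "X")
    n = len(records)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(is_gap[i] | is_gap[j])
            m = int(shared.sum())
            if m == 0:
                raise IncomparablePairError(
                    f"{records[i].id} and {records[j].id} share no gap-free columns"
                )
            p = float((arr[i, shared] != arr[j, shared]).sum()) / m
            if p >= 1.0:
                sat[i, j] = sat[j, i] = True
                d[i, j] = d[j, i] = np.inf
            else:
                d[i, j] = d[j, i] = -math.log1p(-p)
    return DistanceMatrix([r.id for r in records], d, sat)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix, *, allow_saturated: bool = False) -> dendropy.Tree:
    """Classical neighbor-joining (Saitou & Nei) on a distance matrix.

    Q-matrix ties are broken by the label-sorted smallest (i, j) pair so the
    topology is order-invariant; negative branch lengths are clamped to 0.
    Returns an unrooted tree (trifurcating seed node) for n >= 3.
    """
    if dm.saturated.any() and not allow_saturated:
        raise SaturatedDistanceError(
            "saturated distances present; pass allow_saturated=True to proceed"
        )
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    # Work on (label, node) clusters; distances in a dict keyed by cluster id.
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes: dict[int, dendropy.Node] = {}
    labels: dict[int, str] = {}
    for i, lab in enumerate(dm.labels):
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[i] = nd
        labels[i] = lab
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dm.matrix[i, j])
    next_id = n
    active = list(range(n))

    def dist(a: int, b: int) -> float:
        return D[(a, b)] if a < b else D[(b, a)]

    while len(active) > 2:
        r = len(active)
        totals = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        best_pair = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * dist(a, b) - totals[a] - totals[b]
                key = tuple(sorted((labels[a], labels[b])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key)
                    best_pair = (a, b)
        a, b = best_pair  # type: ignore[misc]
        dab = dist(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[next_id] = parent
        labels[next_id] = min(labels[a], labels[b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            key = (min(c, next_id), max(c, next_id))
            D[key] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1

    a, b = active
    root = dendropy.Node()
    final = max(dist(a, b), 0.0)
    # Attach the two remaining clusters around an unrooted seed node.
    if nodes[a].is_leaf() and nodes[b].is_leaf():
        nodes[a].edge.length = final / 2
        nodes[b].edge.length = final / 2
        root.add_child(nodes[a])
        root.add_child(nodes[b])
    else:
        inner, leafy = (a, b) if not nodes[a].is_leaf() else (b, a)
        root = nodes[inner]
        nodes[leafy].edge.length = final
        root.add_child(nodes[leafy])
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap


def _splits(tree: dendropy.Tree, all_labels: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, each canonicalized as the side
    not containing the lexicographically smallest overall label."""
    anchor = min(all_labels)
    out: set[frozenset[str]] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(
            lf.taxon.label for lf in nd.leaf_iter() if lf.taxon is not None
        )
        if anchor in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            out.add(side)
    return out


def bootstrap_support(records: Sequence[SequenceRecord], n_reps: int = 100,
                      seed: int = 0) -> dendropy.Tree:
    """NJ tree with split supports from column-resampled bootstrap replicates.

    Support = percentage of replicates whose NJ tree contains the split of
    the point-estimate tree; written to internal node labels.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    arr = _alignment_array(records)
    ncol = arr.shape[1]
    point = nj_tree(poisson_distance_matrix(records))
    all_labels = frozenset(r.id for r in records)
    counts: dict[frozenset[str], int] = {s: 0 for s in _splits(point, all_labels)}
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        boot = [
            SequenceRecord(r.id, "".join(arr[i, cols]))
            for i, r in enumerate(records)
        ]
        try:
            btree = nj_tree(poisson_distance_matrix(boot), allow_saturated=True)
        except (IncomparablePairError, ValueError):
            continue
        bsplits = _splits(btree, all_labels)
        for s in counts:
            if s in bsplits:
                counts[s] += 1
    for nd in point.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        side = frozenset(
            lf.taxon.label for lf in nd.leaf_iter() if lf.taxon is not None
        )
        if min(all_labels) in side:
            side = all_labels - side
        if side in counts:
            nd.label = f"{100.0 * counts[side] / n_reps:g}"
    return point


# ---------------------------------------------------------------------------
# Subfamily assignment


def assign_subfamily(query: SequenceRecord,
                     references: Sequence[SequenceRecord],
                     labels: dict[str, str]) -> str | None:
    """Assign a query protein to a reference subfamily.

    The query joins a combined NJ tree; walking rootward from the query
    leaf, the first neighborhood whose reference members all share one
    subfamily label gives the assignment.  If that neighborhood is mixed,
    the nearest reference by Poisson distance decides; a distance tie
    between subfamilies returns ``None`` (unassigned).
    """
    if not references:
        raise ValueError("reference panel is empty")
    missing = [r.id for r in references if r.id not in labels]
    if missing:
        raise ValueError(f"references without subfamily labels: {missing}")
    combined = [query] + list(references)
    dm = poisson_distance_matrix(combined)
    if len(references) >= 3:
        tree = nj_tree(dm, allow_saturated=True)
        qleaf = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == query.id
        )
        node = qleaf.parent_node
        while node is not None:
            members = {
                labels[lf.taxon.label]
                for lf in node.leaf_iter()
                if lf.taxon is not None and lf.taxon.label != query.id
            }
            if members:
                if len(members) == 1:
                    return members.pop()
                break
            node = node.parent_node
    # Fallback: nearest reference by distance, conservative on ties.
    dists = dm.matrix[0, 1:]
    order = np.argsort(dists, kind="stable")
    best = dists[order[0]]
    tied = {labels[references[i].id] for i in order if dists[i] <= best + 1e-12}
    return tied.pop() if len(tied) == 1 else None


# ---------------------------------------------------------------------------
# Reference-anchored projection (lightweight alignment for synthetic work)


def project_to_reference(records: Sequence[SequenceRecord],
                         reference: SequenceRecord) -> list[SequenceRecord]:
    """Align each sequence to a common reference and project onto the
    reference's columns (insertions relative to the reference dropped).

    This yields equal-length alignments for pipelines whose sequences are
    all homologous to one reference; it is not a substitute for a proper
    multiple aligner on deeply diverged data.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    try:  # free end gaps; attribute names changed across Biopython versions
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    ref = reference.residues.upper()
    out = []
    for rec in records:
        seq = "".join(c if c in _AA_INDEX else "A"
                      for c in rec.residues.upper())
        aln = aligner.align(ref, seq)[0]
        cols = ["-"] * len(ref)
        for (r0, r1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1]):
            for k in range(r1 - r0):
                cols[r0 + k] = rec.residues[q0 + k]
        out.append(SequenceRecord(rec.id, "".join(cols), rec.description))
    return out


# ---------------------------------------------------------------------------
# Conservation profiles


@dataclasses.dataclass
class ConservationProfile:
    ic: np.ndarray                       # bits per column (nan where all-gap)
    frequencies: np.ndarray              # columns x 20
    all_gap: np.ndarray                  # boolean mask
    categories: list[str] | None = None  # per-column site-category labels

    def mean_ic(self, category: str | None = None) -> float:
        mask = ~self.all_gap
        if category is not None:
            if self.categories is None:
                raise ValueError("profile carries no site categories")
            mask &= np.array([c == category for c in self.categories])
        if not mask.any():
            raise ValueError("no columns in requested category")
        return float(np.nanmean(self.ic[mask]))


def column_information(records: Sequence[SequenceRecord],
                       site_categories: Sequence[str] | None = None
                       ) -> ConservationProfile:
    """Per-column Shannon information content in bits over the 20-letter
    amino-acid alphabet, gaps excluded from the column counts."""
    arr = _alignment_array(records)
    ncol = arr.shape[1]
    if site_categories is not None and len(site_categories) != ncol:
        raise ValueError("site_categories length must match alignment columns")
    freqs = np.zeros((ncol, 20))
    ic = np.full(ncol, np.nan)
    all_gap = np.zeros(ncol, dtype=bool)
    for j in range(ncol):
        col = [c for c in arr[:, j] if c in _AA_INDEX]
        if not col:
            all_gap[j] = True
            continue
        for c in col:
            freqs[j, _AA_INDEX[c]] += 1
        freqs[j] /= len(col)
        nz = freqs[j][freqs[j] > 0]
        ic[j] = MAX_IC_BITS + float(np.sum(nz * np.log2(nz)))
    return ConservationProfile(
        ic, freqs, all_gap,
        list(site_categories) if site_categories is not None else None,
    )
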