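"""Ground-truth generators for every pipeline input.

Each generator is a pure function of its seed and parameters and returns
machine-readable truth alongside the data, so downstream suites can score
recovery exactly: genomes with planted intact/truncated/pseudogenized
receptor genes, gene families evolved by branch-specific birth-death on a
species tree, codon alignments with omega site classes, repertoire count
matrices with a group effect in one subfamily, and negative-binomial
expression counts with planted fold changes.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from . import codon as C
from .expression import ExpressionMatrix
from .io import SequenceRecord
from .reconcile import _node_key
from .repstats import RepertoireMatrix

# Reverse codon table for uniform back-translation (sense codons only).
_CODONS_OF_AA: dict[str, list[str]] = {}
for _c in C.CODONS:
    _CODONS_OF_AA.setdefault(C.translate_codon(_c), []).append(_c)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = sorted(C.STOPS)


# ---------------------------------------------------------------------------
# Receptor genome with planted genes


@dataclasses.dataclass
class Disruption:
    kind: str        # 'nonsense' | 'frameshift' | 'contig-edge'
    position: int    # CDS coordinate (nt)


@dataclasses.dataclass
class PlantedGene:
    name: str
    contig: str
    strand: str
    start: int       # forward-strand, 0-based half-open
    end: int
    status: str      # 'intact' | 'truncated' | 'pseudogene'
    disruptions: list[Disruption]
    subfamily: str | None = None
    protein: str = ""


@dataclasses.dataclass
class PlantedTruth:
    genes: list[PlantedGene]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.status == "pseudogene" and not g.disruptions:
                raise ValueError("pseudogene without disruption")
            if g.status == "intact" and g.disruptions:
                raise ValueError("intact gene with disruptions")


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform codon choice per amino acid (avoids codon-bias confounds)."""
    out = []
    for aa in protein:
        choices = _CODONS_OF_AA.get(aa)
        if not choices:
            raise ValueError(f"cannot back-translate residue {aa!r}")
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _mutate_protein(protein: str, divergence: float,
                    rng: np.random.Generator) -> str:
    out = list(protein)
    for i, aa in enumerate(out):
        if rng.random() < divergence:
            alt = _AA.replace(aa, "") or _AA
            out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def _plant_nonsense(cds: str, rng: np.random.Generator) -> tuple[str, Disruption]:
    """One substitution turning a random convertible sense codon into a stop.

    The first and last few codons are spared: a stop there truncates almost
    nothing and is not a detectable ORF disruption."""
    candidates = []
    for h in range(1, len(cds) // 3 - 5):
        cod = cds[3 * h:3 * h + 3]
        for pos in range(3):
            for n in "TCAG":
                if n != cod[pos] and cod[:pos] + n + cod[pos + 1:] in C.STOPS:
                    candidates.append((h, pos, n))
    if not candidates:
        raise ValueError("no codon convertible to a stop by one substitution")
    h, pos, n = candidates[rng.integers(len(candidates))]
    cut = 3 * h + pos
    return cds[:cut] + n + cds[cut + 1:], Disruption("nonsense", 3 * h)


def _plant_frameshift(cds: str, rng: np.random.Generator) -> tuple[str, Disruption]:
    """A 1-2 bp indel (not a multiple of 3) in the middle of the CDS."""
    k = int(rng.integers(1, 3))
    pos = int(rng.integers(len(cds) // 4, 3 * len(cds) // 4))
    if rng.random() < 0.5:
        ins = "".join("ACGT"[rng.integers(4)] for _ in range(k))
        return cds[:pos] + ins + cds[pos:], Disruption("frameshift", pos)
    return cds[:pos] + cds[pos + k:], Disruption("frameshift", pos)


def simulate_receptor_genome(seed_protein: SequenceRecord, n_intact: int,
                             n_truncated: int, n_pseudo: int,
                             divergence: float, contig_len: int, seed: int,
                             subfamily: str | None = None
                             ) -> tuple[list[SequenceRecord], PlantedTruth]:
    """Plant receptor-gene copies in random-background contigs.

    Each planted gene is a back-translated, amino-acid-mutated copy of the
    seed protein with a stop codon appended; pseudogenes get one nonsense
    substitution or a 1-2 bp indel, truncated genes hang off a contig end.
    One gene per contig; fully reproducible from the seed.
    """
    if not (0 <= divergence <= 0.5):
        raise ValueError("divergence must be in [0, 0.5]")
    if min(n_intact, n_truncated, n_pseudo) < 0:
        raise ValueError("counts must be >= 0")
    cds_len = 3 * (len(seed_protein.residues) + 1)
    if cds_len < 200:
        raise ValueError("seed protein too short for a >= 200 nt gene")
    if cds_len > contig_len:
        raise ValueError("gene longer than contig; increase contig_len")
    rng = np.random.default_rng(seed)
    contigs: list[SequenceRecord] = []
    genes: list[PlantedGene] = []
    statuses = (
        ["intact"] * n_intact + ["pseudogene"] * n_pseudo + ["truncated"] * n_truncated
    )
    for k, status in enumerate(statuses):
        prot = _mutate_protein(seed_protein.residues, divergence, rng)
        cds = back_translate(prot, rng) + _STOPS[rng.integers(len(_STOPS))]
        disruptions: list[Disruption] = []
        if status == "pseudogene":
            if rng.random() < 0.5:
                cds, d = _plant_nonsense(cds, rng)
            else:
                cds, d = _plant_frameshift(cds, rng)
            disruptions.append(d)
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"contig{k}"
        bg = rng.integers(0, 4, size=contig_len)
        contig = np.array(list("ACGT"))[bg]
        if status == "truncated":
            keep = int(len(cds) * rng.uniform(0.4, 0.7)) // 3 * 3
            keep = max(keep, 210)
            piece = cds[:keep]
            disruptions.append(Disruption("contig-edge", keep))
            insert = piece if strand == "+" else _revcomp(piece)
            # gene runs off the right (forward) end of the contig
            if strand == "+":
                contig[contig_len - len(insert):] = list(insert)
                start, end = contig_len - len(insert), contig_len
            else:
                contig[:len(insert)] = list(insert)
                start, end = 0, len(insert)
        else:
            pos = int(rng.integers(0, contig_len - len(cds) + 1))
            insert = cds if strand == "+" else _revcomp(cds)
            contig[pos:pos + len(insert)] = list(insert)
            start, end = pos, pos + len(insert)
        contigs.append(SequenceRecord(name, "".join(contig)))
        genes.append(
            PlantedGene(
                name=f"gene{k}", contig=name, strand=strand, start=start,
                end=end, status=status, disruptions=disruptions,
                subfamily=subfamily, protein=prot,
            )
        )
    return contigs, PlantedTruth(genes)


# ---------------------------------------------------------------------------
# Gene-family evolution by birth-death on a species tree


@dataclasses.dataclass
class FamilySimTruth:
    gene_tree: dendropy.Tree | None     # None when the family went extinct
    gains: dict[str, int]               # per species branch (child-node key)
    losses: dict[str, int]
    tip_counts: dict[str, int]
    extinct: bool


class _GLineage:
    __slots__ = ("children", "taxon", "length")

    def __init__(self, length: float = 0.0):
        self.children: list[_GLineage] = []
        self.taxon: str | None = None
        self.length = length


def simulate_family_evolution(species_tree: dendropy.Tree,
                              birth: float | dict[str, float],
                              death: float | dict[str, float],
                              n_root: int, seed: int) -> FamilySimTruth:
    """Evolve gene lineages by per-branch birth-death Poisson processes.

    ``birth``/``death`` are events per unit branch length, either global or
    per-branch dicts keyed by the child-side species node (leaf label, or
    '+'-joined sorted leaf labels for internal nodes).  Realized gains and
    losses are recorded per branch, so on every branch
    tip-side = root-side + gains - losses by construction.
    """
    if n_root < 1:
        raise ValueError("n_root must be >= 1")
    rng = np.random.default_rng(seed)

    def rate(spec: float | dict[str, float], key: str) -> float:
        r = spec.get(key, 0.0) if isinstance(spec, dict) else float(spec)
        if r < 0:
            raise ValueError("rates must be >= 0")
        return r

    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    tip_counts: dict[str, int] = {}

    def evolve_on_branch(lineage: _GLineage, t: float, b: float, d: float,
                         key: str) -> _GLineage | None:
        """Returns the (possibly duplicated) subtree surviving to branch end,
        with ``length`` accumulated; None if everything died."""
        total = b + d
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = math.inf
        if wait >= t:
            lineage.length += t
            return lineage
        lineage.length += wait
        if rng.random() < (b / total):
            gains[key] = gains.get(key, 0) + 1
            left = evolve_on_branch(_GLineage(), t - wait, b, d, key)
            right = evolve_on_branch(_GLineage(), t - wait, b, d, key)
            kids = [x for x in (left, right) if x is not None]
            if not kids:
                return None
            if len(kids) == 1:
                # suppress the unifurcation: absorb into this lineage
                kids[0].length += lineage.length
                return kids[0]
            lineage.children = kids
            return lineage
        losses[key] = losses.get(key, 0) + 1
        return None

    counter = {"g": 0}

    def descend(lineage: _GLineage, snode: dendropy.Node) -> _GLineage | None:
        if snode.is_leaf():
            sp = snode.taxon.label
            tip_counts[sp] = tip_counts.get(sp, 0) + 1
            counter["g"] += 1
            lineage.taxon = f"{sp}_g{counter['g']}"
            return lineage
        survivors = []
        for child in snode.child_nodes():
            key = _node_key(child)
            t = child.edge.length or 0.0
            b, d = rate(birth, key), rate(death, key)
            sub = evolve_on_branch(_GLineage(), t, b, d, key)
            if sub is None:
                continue
            # recurse into every tip of the within-branch subtree
            def settle(x: _GLineage) -> _GLineage | None:
                if not x.children:
                    return descend(x, child)
                kids = [settle(c) for c in x.children]
                kids = [k for k in kids if k is not None]
                if not kids:
                    return None
                if len(kids) == 1:
                    kids[0].length += x.length
                    return kids[0]
                x.children = kids
                return x
            settled = settle(sub)
            if settled is not None:
                survivors.append(settled)
        if not survivors:
            return None
        if len(survivors) == 1:
            survivors[0].length += lineage.length
            return survivors[0]
        lineage.children = survivors
        return lineage

    roots = []
    for _ in range(n_root):
        r = descend(_GLineage(), species_tree.seed_node)
        if r is not None:
            roots.append(r)
    for lf in species_tree.leaf_node_iter():
        tip_counts.setdefault(lf.taxon.label, 0)

    if not roots:
        return FamilySimTruth(None, gains, losses, tip_counts, True)

    def to_newick(x: _GLineage) -> str:
        if not x.children:
            return f"{x.taxon}:{x.length:.6f}"
        inner = ",".join(to_newick(c) for c in x.children)
        return f"({inner}):{x.length:.6f}"

    if len(roots) == 1:
        text = to_newick(roots[0]) + ";"
        if not roots[0].children:  # single surviving gene: degenerate tree
            text = f"({to_newick(roots[0])});"
    else:
        text = "(" + ",".join(to_newick(r) for r in roots) + ");"
    gene_tree = dendropy.Tree.get(data=text, schema="newick",
                                  preserve_underscores=True)
    return FamilySimTruth(gene_tree, gains, losses, tip_counts, False)


# ---------------------------------------------------------------------------
# Codon alignments (delegates to the GY94 machinery)


def simulate_codon_alignment(tree: dendropy.Tree,
                             site_classes: Sequence[tuple[float, float]],
                             kappa: float, codon_freqs=None,
                             n_codons: int = 300, seed: int = 0,
                             foreground: set[int] | None = None,
                             foreground_omegas: Sequence[float] | None = None):
    """See :func:`chemorep.codon.simulate_codon_alignment`."""
    return C.simulate_codon_alignment(
        tree, site_classes, kappa, codon_freqs, n_codons, seed,
        foreground=foreground, foreground_omegas=foreground_omegas,
    )


# ---------------------------------------------------------------------------
# Repertoire count matrices


def simulate_repertoire_matrix(n_group1: int, n_group2: int,
                               n_subfamilies: int, base_mean: float,
                               boosted_subfamily: int, boost: float,
                               seed: int) -> RepertoireMatrix:
    """Poisson counts, with the boosted subfamily's mean multiplied by
    ``boost`` in group 1 (the fright-reaction ecotype)."""
    if n_subfamilies < 2:
        raise ValueError("need >= 2 subfamilies")
    if boost < 1:
        raise ValueError("boost must be >= 1")
    if not (0 <= boosted_subfamily < n_subfamilies):
        raise ValueError("boosted_subfamily out of range")
    rng = np.random.default_rng(seed)
    species = [f"fright{i + 1}" for i in range(n_group1)] + [
        f"nofright{i + 1}" for i in range(n_group2)
    ]
    means = np.full((len(species), n_subfamilies), float(base_mean))
    means[:n_group1, boosted_subfamily] *= boost
    counts = rng.poisson(means)
    df = pd.DataFrame(
        counts, index=species,
        columns=[f"subfam{j + 1}" for j in range(n_subfamilies)],
    )
    ecotype = pd.Series([1] * n_group1 + [0] * n_group2, index=species)
    return RepertoireMatrix(df, ecotype)


# ---------------------------------------------------------------------------
# Expression counts


def simulate_expression_counts(n_genes: int, n_per_group: int,
                               dispersion: float, de_fraction: float,
                               log2fc: float, seed: int
                               ) -> tuple[ExpressionMatrix, np.ndarray]:
    """Negative-binomial counts with a planted fold change.

    Genes get log-normal baseline means; a ``de_fraction`` of genes have
    their mean multiplied by 2**log2fc in the 'after' condition (half up,
    half down when log2fc is interpreted symmetrically is not needed here:
    the shift is applied as given).  Returns the matrix and a boolean
    truth vector of differentially expressed genes.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if not (0 <= de_fraction <= 1):
        raise ValueError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    is_de = np.zeros(n_genes, dtype=bool)
    n_de = int(round(de_fraction * n_genes))
    if n_de:
        is_de[rng.choice(n_genes, size=n_de, replace=False)] = True
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"before_{i + 1}" for i in range(n_per_group)] + [
        f"after_{i + 1}" for i in range(n_per_group)
    ]
    mat = np.empty((n_genes, 2 * n_per_group), dtype=np.int64)
    r = 1.0 / dispersion
    for j in range(2 * n_per_group):
        mu = base.copy()
        if j >= n_per_group:
            mu[is_de] = mu[is_de] * (2.0 ** log2fc)
        p = r / (r + mu)
        mat[:, j] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    lengths = pd.Series(rng.integers(500, 3000, size=n_genes), index=genes)
    condition = pd.Series(
        ["before"] * n_per_group + ["after"] * n_per_group, index=samples
    )
    return ExpressionMatrix(counts, lengths, condition), is_de
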