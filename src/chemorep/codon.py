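"""GY94 codon substitution machinery shared by the selection models and the
codon-alignment simulator.

The rate matrix follows Goldman-Yang: a single-nucleotide change from codon
i to j has rate pi_j multiplied by kappa for transitions and by omega for
nonsynonymous changes; multi-nucleotide changes are forbidden.  Likelihoods
are computed by Felsenstein pruning with per-node rescaling, with the rate
matrix diagonalized once per (kappa, omega) via its reversible
symmetrization.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import dendropy
import numpy as np

NUCS = "TCAG"
STOPS = {"TAA", "TAG", "TGA"}
CODONS = [
    "".join(c) for c in itertools.product(NUCS, repeat=3) if "".join(c) not in STOPS
]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
N_CODONS = len(CODONS)  # 61

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}

AA_OF_CODON = np.array([_CODON_TABLE[c] for c in CODONS])

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop, 'X' for ambiguous."""
    codon = codon.upper().replace("U", "T")
    if codon in STOPS:
        return "*"
    return _CODON_TABLE.get(codon, "X")


def translate_cds(seq: str) -> str:
    return "".join(
        translate_codon(seq[i:i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def _single_change(ci: str, cj: str) -> tuple[int, str, str] | None:
    diff = [(k, ci[k], cj[k]) for k in range(3) if ci[k] != cj[k]]
    if len(diff) != 1:
        return None
    return diff[0]


# Precompute the sparse change structure: lists of (i, j, is_transition,
# is_nonsynonymous) for all single-nucleotide codon pairs.
_CHANGES: list[tuple[int, int, bool, bool]] = []
for _i, _ci in enumerate(CODONS):
    for _j, _cj in enumerate(CODONS):
        if _i == _j:
            continue
        d = _single_change(_ci, _cj)
        if d is None:
            continue
        _, a, b = d
        _CHANGES.append(
            (_i, _j, (a, b) in _TRANSITIONS, AA_OF_CODON[_i] != AA_OF_CODON[_j])
        )
_CH_I = np.array([c[0] for c in _CHANGES])
_CH_J = np.array([c[1] for c in _CHANGES])
_CH_TS = np.array([c[2] for c in _CHANGES])
_CH_NS = np.array([c[3] for c in _CHANGES])


def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_freqs(codon_seqs: Sequence[str]) -> np.ndarray:
    """F3X4 codon frequencies from position-specific nucleotide counts."""
    counts = np.ones((3, 4))  # +1 pseudocount keeps every codon reachable
    nuc_idx = {n: k for k, n in enumerate(NUCS)}
    for seq in codon_seqs:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            cod = seq[i:i + 3].upper()
            for pos in range(3):
                if cod[pos] in nuc_idx:
                    counts[pos, nuc_idx[cod[pos]]] += 1
    counts /= counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            counts[0, nuc_idx[c[0]]] * counts[1, nuc_idx[c[1]]] * counts[2, nuc_idx[c[2]]]
            for c in CODONS
        ]
    )
    return pi / pi.sum()


def gy94_rate_matrix(kappa: float, omega: float, codon_freqs: np.ndarray,
                     scale: bool = True) -> np.ndarray:
    """GY94 generator; with ``scale`` the mean rate at stationarity is 1."""
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("codon_freqs must be 61 positive values summing to 1")
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be non-negative")
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = np.ones(len(_CH_I))
    rates[_CH_TS] *= kappa
    rates[_CH_NS] *= omega
    Q[_CH_I, _CH_J] = rates * pi[_CH_J]
    Q[np.diag_indices(N_CODONS)] = -Q.sum(axis=1)
    if scale:
        mean_rate = -float(pi @ np.diag(Q))
        if mean_rate > 0:
            Q /= mean_rate
    return Q


def mixture_rate_matrices(kappa: float, omegas: Sequence[float],
                          proportions: Sequence[float],
                          codon_freqs: np.ndarray) -> list[np.ndarray]:
    """Unscaled-per-class generators jointly normalized so the mixture's
    mean rate at stationarity is 1 (sites in faster classes evolve faster)."""
    pi = np.asarray(codon_freqs, dtype=float)
    qs = [gy94_rate_matrix(kappa, w, pi, scale=False) for w in omegas]
    mean = sum(p * (-float(pi @ np.diag(q))) for p, q in zip(proportions, qs))
    if mean <= 0:
        raise ValueError("degenerate mixture rate")
    return [q / mean for q in qs]


class CodonTransitions:
    """Eigendecomposition of a reversible GY94 generator, giving P(t)."""

    def __init__(self, Q: np.ndarray, codon_freqs: np.ndarray):
        pi = np.asarray(codon_freqs, dtype=float)
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)  # symmetric up to round-off by reversibility
        evals, evecs = np.linalg.eigh(B)
        self._evals = evals
        self._left = evecs / sq[:, None] * 1.0
        self._right = (evecs * sq[:, None]).T
        self.pi = pi

    def probability(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# Alignment handling


def encode_codon_alignment(seqs: Sequence[str]) -> np.ndarray:
    """Codon alignment (equal-length, length % 3 == 0, no internal stops or
    gaps) encoded as an integer matrix n_seq x n_sites."""
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError("sequences have unequal lengths")
    (L,) = lens
    if L % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    out = np.empty((len(seqs), L // 3), dtype=np.int16)
    for i, s in enumerate(seqs):
        s = s.upper().replace("U", "T")
        for h in range(L // 3):
            cod = s[3 * h:3 * h + 3]
            if cod in STOPS:
                raise ValueError(f"internal stop codon at site {h} in sequence {i}")
            if cod not in CODON_INDEX:
                raise ValueError(f"unrecognized codon {cod!r}")
            out[i, h] = CODON_INDEX[cod]
    return out


def compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their weights, and pattern index per site."""
    patterns, inverse, counts = np.unique(
        codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts.astype(float), inverse


# ---------------------------------------------------------------------------
# Pruning likelihood


def pruning_loglik(tree: dendropy.Tree, patterns: np.ndarray,
                   taxa: Sequence[str], trans: "CodonTransitions",
                   scale: float = 1.0,
                   branch_trans: dict[int, "CodonTransitions"] | None = None
                   ) -> np.ndarray:
    """Per-pattern log-likelihood under one rate matrix (optionally
    branch-specific matrices keyed by ``id(node)``), branch lengths
    multiplied by ``scale``.  ``taxa`` gives the alignment row of each
    label.  The full lnL is ``weights @ result``."""
    taxon_row = {t: i for i, t in enumerate(taxa)}
    n_pat = patterns.shape[1]
    partial: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else nd.label
            if label not in taxon_row:
                raise ValueError(f"tree leaf {label!r} not in alignment")
            row = taxon_row[label]
            arr = np.zeros((n_pat, N_CODONS))
            arr[np.arange(n_pat), patterns[row]] = 1.0
            partial[id(nd)] = arr
            logscale[id(nd)] = np.zeros(n_pat)
        else:
            acc = np.ones((n_pat, N_CODONS))
            ls = np.zeros(n_pat)
            for child in nd.child_nodes():
                t = (child.edge.length or 0.0) * scale
                tr = trans
                if branch_trans is not None and id(child) in branch_trans:
                    tr = branch_trans[id(child)]
                P = tr.probability(t)
                acc *= partial[id(child)] @ P.T
                ls += logscale[id(child)]
                del partial[id(child)], logscale[id(child)]
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            acc /= mx[:, None]
            partial[id(nd)] = acc
            logscale[id(nd)] = ls + np.log(mx)
    root = tree.seed_node
    site = partial[id(root)] @ trans.pi
    site[site <= 0] = np.finfo(float).tiny
    return np.log(site) + logscale[id(root)]


# ---------------------------------------------------------------------------
# Simulation


def simulate_codon_alignment(tree: dendropy.Tree,
                             site_classes: Sequence[tuple[float, float]],
                             kappa: float, codon_freqs: np.ndarray | None,
                             n_codons: int, seed: int,
                             foreground: set[int] | None = None,
                             foreground_omegas: Sequence[float] | None = None
                             ) -> tuple[dict[str, str], np.ndarray]:
    """Simulate codon sequences on a tree under a GY94 site-class mixture.

    ``site_classes`` is a list of (proportion, omega); proportions must sum
    to 1.  With ``foreground`` (a set of ``id(node)`` for the foreground
    branches) and ``foreground_omegas``, sites of class k evolve under
    ``foreground_omegas[k]`` on those branches (branch-site simulation).
    Returns ({taxon: sequence}, true class index per site).
    """
    props = np.array([p for p, _ in site_classes], dtype=float)
    omegas = [w for _, w in site_classes]
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    if any(w < 0 for w in omegas):
        raise ValueError("omega must be non-negative")
    pi = uniform_codon_freqs() if codon_freqs is None else np.asarray(codon_freqs)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            raise ValueError("tree branch without a length")
    rng = np.random.default_rng(seed)
    classes = rng.choice(len(site_classes), size=n_codons, p=props)

    qs_raw = [gy94_rate_matrix(kappa, w, pi, scale=False) for w in omegas]
    bg_mean = sum(p * (-float(pi @ np.diag(q))) for p, q in zip(props, qs_raw))
    trans = [CodonTransitions(q / bg_mean, pi) for q in qs_raw]
    fg_trans = None
    if foreground is not None:
        if foreground_omegas is None or len(foreground_omegas) != len(omegas):
            raise ValueError("foreground_omegas must match site_classes")
        # foreground matrices share the background normalization so the
        # elevated omega classes genuinely accelerate the foreground branch
        fg_trans = [
            CodonTransitions(
                gy94_rate_matrix(kappa, w, pi, scale=False) / bg_mean, pi
            )
            for w in foreground_omegas
        ]

    states: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.choice(N_CODONS, size=n_codons, p=pi)
    }
    out: dict[str, str] = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            parent_state = states[id(nd.parent_node)]
            t = nd.edge.length or 0.0
            use_fg = foreground is not None and id(nd) in foreground
            child = np.empty(n_codons, dtype=np.int64)
            for k in range(len(site_classes)):
                tr = (fg_trans if use_fg else trans)[k]
                P = tr.probability(t)
                mask = classes == k
                ps = parent_state[mask]
                u = rng.random(ps.size)
                cum = np.cumsum(P, axis=1)
                child[mask] = np.array(
                    [np.searchsorted(cum[s], x) for s, x in zip(ps, u)]
                )
            np.clip(child, 0, N_CODONS - 1, out=child)
            states[id(nd)] = child
        if nd.is_leaf():
            lbl = nd.taxon.label if nd.taxon else str(nd.label)
            out[lbl] = "".join(CODONS[s] for s in states[id(nd)])
    return out, classes
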