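"""Sawyer-style gene-conversion detection.

Monomorphic and gap-containing columns are discarded; for every ordered
sequence pair the statistic is the best-scoring fragment over the
remaining polymorphic sites (with the default infinite mismatch penalty
this is the longest run of identical polymorphic sites).  Significance
comes from permuting the column order of the condensed matrix, jointly
across all sequences, which preserves the per-column allele configuration
while destroying physical clustering of identities.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .io import SequenceRecord


@dataclasses.dataclass
class Fragment:
    pair: tuple[str, str]
    start: int          # alignment coordinate (0-based) of first site
    end: int            # alignment coordinate of last site (inclusive)
    n_sites: int        # polymorphic sites spanned
    score: float


@dataclasses.dataclass
class ConversionTestResult:
    fragments: dict[tuple[str, str], Fragment | None]
    pair_p: dict[tuple[str, str], float]
    global_p: float
    n_permutations: int
    seed: int
    n_polymorphic: int


def condense_polymorphic(records: Sequence[SequenceRecord]) -> tuple[list[int], np.ndarray]:
    """Return original column indices and the condensed matrix of columns
    that carry >= 2 alleles; gap-containing columns are excluded."""
    if len(records) < 2:
        raise ValueError("need >= 2 aligned sequences")
    arr = np.array([list(r.residues.upper()) for r in records])
    if len({len(r.residues) for r in records}) != 1:
        raise ValueError("sequences are not aligned")
    keep: list[int] = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if np.any((col == "-") | (col == ".")):
            continue
        if len(set(col)) >= 2:
            keep.append(j)
    return keep, arr[:, keep]


def _best_segment(match: np.ndarray, penalty: float) -> tuple[float, int, int]:
    """Best-scoring segment of a 0/1 match vector under +1 per match and
    -penalty per mismatch (Kadane); infinite penalty = longest match run.
    Returns (score, start, end) in condensed coordinates; score 0 => none."""
    inf = math.isinf(penalty)
    best, bs, be = 0.0, -1, -1
    cur, start = 0.0, 0
    for i, m in enumerate(match):
        if m:
            if cur == 0:
                start = i
            cur += 1.0
        else:
            cur = 0.0 if inf else max(cur - penalty, 0.0)
        if cur > best:
            best, bs, be = cur, start, i
    return best, bs, be


def _segment_scores(match_matrix: np.ndarray, penalty: float,
                    coords: np.ndarray, span_unit: float) -> np.ndarray:
    """Row-wise maximal segment score of a boolean match matrix (rows are
    sequence pairs, columns polymorphic sites), vectorized over rows.

    The integer segment score is augmented by the fragment's physical span
    in alignment coordinates scaled into [0, 1): a deterministic,
    permutation-exchangeable tie-breaker that removes the heavy ties an
    integer statistic produces at the permutation maximum (which would
    otherwise make the test strongly conservative).
    """
    n_rows, m = match_matrix.shape
    cur = np.zeros(n_rows)
    best = np.zeros(n_rows)
    lo = np.full(n_rows, np.inf)
    hi = np.full(n_rows, -np.inf)
    inf_pen = math.isinf(penalty)
    for k in range(m):
        col = match_matrix[:, k]
        if inf_pen:
            cur = np.where(col, cur + 1.0, 0.0)
        else:
            cur = np.maximum(cur + np.where(col, 1.0, -penalty), 0.0)
        dead = cur == 0
        lo[dead] = np.inf
        hi[dead] = -np.inf
        c = float(coords[k])
        upd = col & ~dead
        np.minimum(lo, np.where(upd, c, np.inf), out=lo)
        np.maximum(hi, np.where(upd, c, -np.inf), out=hi)
        span = np.where(np.isfinite(hi - lo), (hi - lo) * span_unit, 0.0)
        np.maximum(best, cur + span, out=best)
    return best


def pairwise_fragments(records: Sequence[SequenceRecord],
                       mismatch_penalty: float = math.inf
                       ) -> dict[tuple[str, str], Fragment | None]:
    """Maximal identity fragments for every pair, in alignment coordinates."""
    sites, cond = condense_polymorphic(records)
    out: dict[tuple[str, str], Fragment | None] = {}
    n = cond.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            pair = (records[i].id, records[j].id)
            if cond.shape[1] == 0:
                out[pair] = None
                continue
            match = cond[i] == cond[j]
            score, s, e = _best_segment(match, mismatch_penalty)
            if score <= 0:
                out[pair] = None
            else:
                out[pair] = Fragment(pair, sites[s], sites[e], e - s + 1, score)
    return out


def conversion_test(records: Sequence[SequenceRecord], n_perm: int = 1000,
                    seed: int = 0,
                    mismatch_penalty: float = math.inf) -> ConversionTestResult:
    """Permutation test for anomalously long identical fragments.

    Pairwise p = (# permuted scores >= observed + 1) / (n_perm + 1); the
    global p uses the null distribution of the across-pair maximum, which
    handles multiplicity exactly under the shared permutation null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sites, cond = condense_polymorphic(records)
    fragments = pairwise_fragments(records, mismatch_penalty)
    pairs = list(fragments.keys())
    if cond.shape[1] < 2:
        return ConversionTestResult(
            fragments, {p: 1.0 for p in pairs}, 1.0, n_perm, seed, cond.shape[1]
        )
    # The permutation reorders columns jointly, so the pairwise match matrix
    # just permutes its columns too; precompute it once.  Physical site
    # coordinates stay in place; only the allele configurations move.
    n = cond.shape[0]
    idx_i, idx_j = np.triu_indices(n, k=1)
    match_matrix = cond[idx_i] == cond[idx_j]
    coords = np.asarray(sites, dtype=float)
    span_unit = 1.0 / (len(records[0].residues) + 1.0)
    observed = _segment_scores(match_matrix, mismatch_penalty, coords, span_unit)
    rng = np.random.default_rng(seed)
    ncol = cond.shape[1]
    exceed = np.zeros(len(pairs))
    exceed_max = 0
    obs_max = observed.max()
    for _ in range(n_perm):
        perm = rng.permutation(ncol)
        scores = _segment_scores(match_matrix[:, perm], mismatch_penalty,
                                 coords, span_unit)
        exceed += scores >= observed
        if scores.max() >= obs_max:
            exceed_max += 1
    pair_p = {
        p: float((exceed[k] + 1) / (n_perm + 1)) for k, p in enumerate(pairs)
    }
    global_p = float((exceed_max + 1) / (n_perm + 1))
    return ConversionTestResult(fragments, pair_p, global_p, n_perm, seed,
                                cond.shape[1])
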