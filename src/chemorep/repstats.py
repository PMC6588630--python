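"""Repertoire-ecotype association statistics.

Operates on a species x subfamily matrix of intact-gene counts with a
binary ecotype label per species (fright reaction present/absent):
2x2 contingency test for repertoire proportions, one-sample t test for
family-size ratios, centered PCA, rank-based ANOSIM with label
permutation, and phylogenetic logistic regression (in
:mod:`chemorep.phyloglm`).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class RepertoireMatrix:
    """Intact-gene counts per species (rows) and subfamily (columns)."""

    counts: pd.DataFrame          # species x subfamily, non-negative ints
    ecotype: pd.Series            # 1 = fright reaction, 0 = lacking

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.ecotype.index):
            self.ecotype = self.ecotype.reindex(self.counts.index)
            if self.ecotype.isna().any():
                raise ValueError("ecotype labels missing for some species")

    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("a species has zero total count; no proportions view")
        return self.counts.div(totals, axis=0)


def chisq_2x2(a: int, b: int, c: int, d: int,
              correction: str = "off") -> tuple[float, float]:
    """Pearson chi-square test of a 2x2 table [[a, b], [c, d]], df = 1.

    No continuity correction by default; ``correction='yates'`` applies it.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a zero row or column sum")
    if correction not in ("off", "yates"):
        raise ValueError("correction must be 'off' or 'yates'")
    stat, p, _, _ = stats.chi2_contingency(table, correction=(correction == "yates"))
    return float(stat), float(p)


def family_size_ratio_test(ratios: Sequence[float], reference: float
                           ) -> dict[str, float]:
    """Two-sided one-sample t test of mean(ratios) against ``reference``;
    also reports where the reference sits in the empirical distribution."""
    arr = np.asarray(ratios, dtype=float)
    if arr.size < 2 or not np.all(np.isfinite(arr)):
        raise ValueError("need >= 2 finite ratios")
    if np.allclose(arr, arr[0]):
        if arr[0] == reference:
            return {"t": 0.0, "p": 1.0, "mean": float(arr[0]),
                    "reference_quantile": float(np.mean(arr <= reference))}
        raise ValueError("zero variance in ratios")
    t, p = stats.ttest_1samp(arr, reference)
    return {
        "t": float(t), "p": float(p), "mean": float(arr.mean()),
        "reference_quantile": float(np.mean(arr <= reference)),
    }


# ---------------------------------------------------------------------------
# PCA


@dataclasses.dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray   # percent per component, sums to 100


def pca_repertoire(matrix: RepertoireMatrix, view: str = "counts") -> PcaResult:
    """Centered (unscaled) PCA of the repertoire matrix via SVD."""
    if view == "counts":
        X = matrix.counts.astype(float)
    elif view == "proportions":
        X = matrix.proportions()
    else:
        raise ValueError("view must be 'counts' or 'proportions'")
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 species and >= 2 subfamilies")
    centered = X.values - X.values.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("constant matrix; PCA undefined")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    var = s ** 2
    ve = 100.0 * var / var.sum()
    k = len(s)
    comp = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(U * s, index=X.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp),
        variance_explained=ve,
    )


# ---------------------------------------------------------------------------
# ANOSIM


@dataclasses.dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    metric: str
    unreliable: bool = False     # singleton group present


def _anosim_r(rank_dists: np.ndarray, within: np.ndarray) -> float:
    m = rank_dists.size
    rb = rank_dists[~within].mean()
    rw = rank_dists[within].mean()
    n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    return float((rb - rw) / (n * (n - 1) / 2.0 / 2.0))


def anosim(data: np.ndarray | pd.DataFrame, grouping: Sequence,
           n_perm: int = 999, seed: int = 0,
           metric: str = "euclidean") -> AnosimResult:
    """Analysis of similarities on Euclidean distances.

    Distances are rank-transformed globally (mean ranks on ties);
    R = (mean between-group rank - mean within-group rank) / (M / 4) with
    M = n(n-1)/2.  p is a label-permutation tail probability with the +1
    correction, so it is never exactly 0.
    """
    X = np.asarray(data, dtype=float)
    labels = np.asarray(list(grouping))
    if X.shape[0] != labels.size:
        raise ValueError("grouping length must match rows")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 groups")
    unreliable = bool((counts < 2).any())
    if metric == "euclidean":
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    elif metric == "precomputed":
        d = X
    else:
        raise ValueError("metric must be 'euclidean' or 'precomputed'")
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    vec = d[iu]
    ranks = stats.rankdata(vec)
    same = labels[iu[0]] == labels[iu[1]]
    r_obs = _anosim_r(ranks, same)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(ranks, same_p) >= r_obs:
            exceed += 1
    return AnosimResult(
        R=r_obs, p_value=float((exceed + 1) / (n_perm + 1)),
        n_permutations=n_perm, metric=metric, unreliable=unreliable,
    )
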