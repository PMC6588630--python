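"""Expression statistics for the before/after fright-reaction contrast.

Starts from a gene x sample raw-count matrix with gene lengths (the
interface a transcript quantifier emits): FPKM, the activity filter
(FPKM > 1 in at least half the samples), TMM library-scaling factors, and
Wilcoxon rank-sum contrasts between gene sets on expression levels and on
absolute before/after changes.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclasses.dataclass
class ExpressionMatrix:
    counts: pd.DataFrame          # genes x samples
    lengths: pd.Series            # bp per gene
    condition: pd.Series          # per sample: 'before' / 'after'
    gene_sets: pd.DataFrame | None = None   # boolean columns per gene set

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            raise ValueError("every sample needs a condition label")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def compute_fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """FPKM = count * 1e9 / (length_bp * library_size)."""
    lib = matrix.library_sizes
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return matrix.counts * 1e9 / np.outer(matrix.lengths.values, lib.values)


def filter_active(fpkm: pd.DataFrame, threshold: float = 1.0,
                  min_fraction: float = 0.5) -> pd.Index:
    """Genes with FPKM > threshold in at least ceil(min_fraction * n)
    samples ('transcriptionally active' genes)."""
    n = fpkm.shape[1]
    if n < 1:
        raise ValueError("need at least one sample")
    need = math.ceil(min_fraction * n)
    ok = (fpkm > threshold).sum(axis=1) >= need
    return fpkm.index[ok]


def tmm_factors(counts: pd.DataFrame, reference: str | int | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    For each sample against the reference: genes with a zero in either
    sample are excluded; the top/bottom ``trim_m`` of log-ratios (M) and
    ``trim_a`` of average log-intensities (A) are trimmed; the remaining M
    values are averaged with inverse approximate-variance weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("a sample has all-zero counts")
    if reference is None:
        # sample whose upper quartile of scaled counts is most typical
        uq = (counts / lib).quantile(0.75)
        reference = (uq - uq.mean()).abs().idxmin()
    ref = counts[reference].values.astype(float)
    nref = lib[reference]
    factors = {}
    for col in counts.columns:
        obs = counts[col].values.astype(float)
        nobs = lib[col]
        if col == reference:
            factors[col] = 1.0
            continue
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep], ref[keep]
        m = np.log2((o / nobs) / (r / nref))
        a = 0.5 * np.log2((o / nobs) * (r / nref))
        w = 1.0 / ((nobs - o) / (nobs * o) + (nref - r) / (nref * r))
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not sel.any():
            factors[col] = 1.0
            continue
        factors[col] = float(2 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel])))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      sides: str = "two") -> float:
    """Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact distribution when m + n <= 20 with no ties, otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    alternative = {"two": "two-sided", "greater": "greater"}.get(sides)
    if alternative is None:
        raise ValueError("sides must be 'two' or 'greater'")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.pvalue)


def differential_expression(matrix: ExpressionMatrix,
                            min_abs_log2fc: float = 1.0,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Fold-change-plus-rank-sum differential-expression call.

    A gene is called DE when |log2FC| of mean FPKM between conditions is at
    least ``min_abs_log2fc`` and its per-gene rank-sum p-value, BH-adjusted
    across genes, is below ``alpha``.  Library sizes are TMM-corrected
    first: without that, an asymmetric shift in a subset of genes deflates
    everything else's FPKM (composition bias) and inflates the false-call
    rate.  (A count-model exact test would have more power at 3 vs 3
    replicates; this nonparametric call is the conservative screen used
    downstream.)
    """
    factors = tmm_factors(matrix.counts)
    eff_lib = matrix.library_sizes * factors
    fpkm = matrix.counts * 1e9 / np.outer(matrix.lengths.values,
                                          eff_lib.values)
    before = fpkm.loc[:, matrix.condition == "before"]
    after = fpkm.loc[:, matrix.condition == "after"]
    lfc = np.log2((after.mean(axis=1) + 1e-9) / (before.mean(axis=1) + 1e-9))
    pvals = np.array([
        wilcoxon_rank_sum(before.loc[g], after.loc[g])
        for g in fpkm.index
    ])
    order = np.argsort(pvals)
    m = len(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank, idx in enumerate(order[::-1]):
        r = m - rank
        prev = min(prev, pvals[idx] * m / r)
        q[idx] = prev
    out = pd.DataFrame(
        {"log2fc": lfc, "p": pvals, "q_bh": q}, index=fpkm.index
    )
    out["is_de"] = (out["log2fc"].abs() >= min_abs_log2fc) & (out["q_bh"] < alpha)
    return out


def expression_change_summary(matrix: ExpressionMatrix,
                              partitions: dict[str, Sequence[str]]
                              ) -> dict[str, object]:
    """Per-gene condition means / absolute changes / log2 fold changes and
    rank-sum contrasts between each labeled gene set and its complement,
    on expression levels (before) and on absolute changes.

    ``partitions`` maps a set name to its gene ids; every comparison is
    set vs complement among genes present in the matrix.
    """
    for cond in ("before", "after"):
        if not (matrix.condition == cond).any():
            raise ValueError(f"no samples in condition {cond!r}")
    fpkm = compute_fpkm(matrix)
    before = fpkm.loc[:, matrix.condition == "before"].mean(axis=1)
    after = fpkm.loc[:, matrix.condition == "after"].mean(axis=1)
    per_gene = pd.DataFrame(
        {
            "mean_before": before,
            "mean_after": after,
            "abs_change": (after - before).abs(),
            "log2fc": np.log2((after + 1e-9) / (before + 1e-9)),
        }
    )
    contrasts = []
    for name, genes in partitions.items():
        members = per_gene.index.intersection(pd.Index(genes))
        others = per_gene.index.difference(members)
        if len(members) == 0 or len(others) == 0:
            continue
        contrasts.append(
            {
                "set": name,
                "n_in": len(members),
                "n_out": len(others),
                "level_p": wilcoxon_rank_sum(
                    per_gene.loc[members, "mean_before"],
                    per_gene.loc[others, "mean_before"],
                ),
                "abs_change_p": wilcoxon_rank_sum(
                    per_gene.loc[members, "abs_change"],
                    per_gene.loc[others, "abs_change"],
                ),
                "mean_change_direction": float(
                    np.sign(
                        (per_gene.loc[members, "mean_after"]
                         - per_gene.loc[members, "mean_before"]).mean()
                    )
                ),
            }
        )
    return {"per_gene": per_gene, "contrasts": pd.DataFrame(contrasts)}
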