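#!/usr/bin/env python
"""Before/after expression contrasts.

FPKM, the activity filter (FPKM > 1 in at least half the samples), TMM
scaling factors, and Wilcoxon rank-sum contrasts of expression levels and
absolute before/after changes between the planted "receptor" gene set and
the rest of the transcriptome.
"""

from pathlib import Path

import pandas as pd

from chemorep import io as cio
from chemorep.expression import (
    ExpressionMatrix,
    compute_fpkm,
    expression_change_summary,
    filter_active,
    tmm_factors,
)

RESULTS = Path("results")
STUDY = RESULTS / "study"

counts = cio.read_matrix(STUDY / "expression_counts.tsv")
lengths = cio.read_matrix(STUDY / "expression_lengths.tsv").iloc[:, 0]
truth = cio.read_matrix(STUDY / "expression_truth.tsv").iloc[:, 0]
condition = pd.Series(
    ["before" if c.startswith("before") else "after" for c in counts.columns],
    index=counts.columns,
)
mat = ExpressionMatrix(counts, lengths, condition)

fpkm = compute_fpkm(mat)
active = filter_active(fpkm, threshold=1.0, min_fraction=0.5)
tmm = tmm_factors(counts)
summary = expression_change_summary(
    mat, {"receptor": list(counts.index[truth.astype(bool)])}
)

summary["per_gene"].to_csv(RESULTS / "expression_per_gene.tsv", sep="\t")
summary["contrasts"].to_csv(RESULTS / "expression_contrasts.tsv", sep="\t",
                            index=False)
tmm.to_csv(RESULTS / "tmm_factors.tsv", sep="\t", header=["factor"])

row = summary["contrasts"].iloc[0]
print(f"{len(active)}/{counts.shape[0]} genes transcriptionally active "
      f"(FPKM > 1 in >= half the samples)")
print(f"TMM factors: {', '.join(f'{v:.3f}' for v in tmm)}")
print(f"receptor set vs rest: level rank-sum p = {row['level_p']:.3g}; "
      f"absolute-change rank-sum p = {row['abs_change_p']:.3g} "
      f"(planted fold change |log2FC| = 2 in the receptor set)")
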